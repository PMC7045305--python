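"""Pipeline configuration and seeded reproducibility.

The defaults reproduce the acquisition/analysis constants of the study the
pipeline re-implements: 15 Hz miniscope frame rate, 4× spatial downsampling,
a −10…+20 s peri-event window with a 10-point moving average, ±2 s
pre/post comparison windows, a 2-SD responder rule, 20-s trial separation
and cue timeout, a 60-min analysis window, a k = 10 / 1000-shuffle spatial
clustering test, and α = 0.05.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

__all__ = ["PipelineConfig", "substream", "spawn_rng"]


@dataclass
class PipelineConfig:
    frame_rate_hz: float = 15.0
    spatial_downsample: int = 4
    perievent_window_s: tuple[float, float] = (-10.0, 20.0)
    smoothing_points: int = 10
    pre_window_s: tuple[float, float] = (-2.0, 0.0)
    post_window_s: tuple[float, float] = (0.0, 2.0)
    responder_sd_threshold: float = 2.0
    min_trial_separation_s: float = 20.0
    cue_timeout_s: float = 20.0
    analysis_limit_min: float = 60.0
    knn_k: int = 10
    n_shuffles: int = 1000
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.perievent_window_s = tuple(self.perievent_window_s)
        self.pre_window_s = tuple(self.pre_window_s)
        self.post_window_s = tuple(self.post_window_s)
        for name in ("perievent_window_s", "pre_window_s", "post_window_s"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds must be ordered, got ({lo}, {hi})")
        positives = dict(
            frame_rate_hz=self.frame_rate_hz,
            spatial_downsample=self.spatial_downsample,
            smoothing_points=self.smoothing_points,
            responder_sd_threshold=self.responder_sd_threshold,
            min_trial_separation_s=self.min_trial_separation_s,
            cue_timeout_s=self.cue_timeout_s,
            analysis_limit_min=self.analysis_limit_min,
            knn_k=self.knn_k,
            n_shuffles=self.n_shuffles,
        )
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("perievent_window_s", "pre_window_s", "post_window_s"):
            d[name] = list(d[name])
        return d


def substream(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage child of one global seed.

    The rule is ``SeedSequence([seed, crc32(stage)])``: the same (seed, stage)
    pair always yields the same stream, and different stages never collide in
    practice because CRC-32 of the stage name enters the entropy pool.
    """
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])


def spawn_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for ``stage`` derived from the global ``seed``."""
    return np.random.default_rng(substream(seed, stage))
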