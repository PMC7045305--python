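"""Core data containers shared by all pipeline stages.

Conventions
-----------
* Time is in seconds from session start, 0-based.  Sample ``i`` of a trace
  sampled at ``fs`` Hz covers time ``i / fs`` (left-edge convention).
* Fluorescence traces are ΔF/F unless a container says otherwise.
* Spatial coordinates are in pixels; no physical calibration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceMovie",
    "TraceSet",
    "EventTrain",
    "EventStats",
    "BehaviorSession",
    "PeriEventTensor",
    "PopulationResponse",
    "CellFootprintSet",
    "SpatialPattern",
    "GroundTruth",
    "KernelParams",
]

CELL_TYPES = ("Glu", "GABA", "Penk")
SESSION_TYPES = ("SA", "Ext1", "Ext10", "Reinst")


@dataclass
class FluorescenceMovie:
    """Frame stack (T × H × W) with its acquisition frame rate.

    ``is_dff`` distinguishes raw fluorescence from ΔF/F-normalized frames.
    """

    data: np.ndarray
    frame_rate_hz: float
    is_dff: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be T×H×W, got shape {self.data.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FluorescenceMovie):
            return NotImplemented
        return (
            np.allclose(self.data, other.data, rtol=0, atol=1e-12)
            and np.isclose(self.frame_rate_hz, other.frame_rate_hz)
            and self.is_dff == other.is_dff
        )


@dataclass
class TraceSet:
    """Per-cell fluorescence traces: cells × samples, one sampling rate.

    ``cell_types`` and ``session`` carry the experimental labels used for
    group-level aggregation downstream.
    """

    data: np.ndarray
    frame_rate_hz: float
    cell_types: np.ndarray | None = None
    session: str = ""
    is_dff: bool = True

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.cell_types is None:
            self.cell_types = np.array([""] * self.n_cells, dtype=object)
        else:
            self.cell_types = np.asarray(self.cell_types, dtype=object)
            if len(self.cell_types) != self.n_cells:
                raise ValueError("cell_types length must equal number of cells")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.frame_rate_hz

    def times(self) -> np.ndarray:
        """Left-edge sample times in seconds."""
        return np.arange(self.n_samples) / self.frame_rate_hz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceSet):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.data, other.data, rtol=0, atol=1e-12)
            and np.isclose(self.frame_rate_hz, other.frame_rate_hz)
            and list(self.cell_types) == list(other.cell_types)
            and self.session == other.session
            and self.is_dff == other.is_dff
        )


@dataclass
class EventTrain:
    """Per-cell calcium-transient times (s) and amplitudes (ΔF/F units).

    Invariants: times strictly increasing per cell, amplitudes positive,
    all times within the session duration.
    """

    times: list[np.ndarray]
    amplitudes: list[np.ndarray]
    duration_s: float
    cell_types: np.ndarray | None = None
    session: str = ""

    def __post_init__(self) -> None:
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.amplitudes = [np.asarray(a, dtype=float) for a in self.amplitudes]
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must have one entry per cell")
        for i, (t, a) in enumerate(zip(self.times, self.amplitudes)):
            if len(t) != len(a):
                raise ValueError(f"cell {i}: times/amplitudes length mismatch")
            if len(t) and np.any(np.diff(t) <= 0):
                raise ValueError(f"cell {i}: event times must be strictly increasing")
            if len(t) and (t[0] < 0 or t[-1] >= self.duration_s):
                raise ValueError(f"cell {i}: event times outside [0, duration)")
            if np.any(a <= 0):
                raise ValueError(f"cell {i}: amplitudes must be > 0")
        if self.cell_types is None:
            self.cell_types = np.array([""] * self.n_cells, dtype=object)
        else:
            self.cell_types = np.asarray(self.cell_types, dtype=object)

    @property
    def n_cells(self) -> int:
        return len(self.times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTrain):
            return NotImplemented
        if self.n_cells != other.n_cells or not np.isclose(self.duration_s, other.duration_s):
            return False
        for t1, t2, a1, a2 in zip(self.times, other.times, self.amplitudes, other.amplitudes):
            if len(t1) != len(t2) or not np.allclose(t1, t2, rtol=0, atol=1e-9):
                return False
            if not np.allclose(a1, a2, rtol=0, atol=1e-9):
                return False
        return list(self.cell_types) == list(other.cell_types) and self.session == other.session


@dataclass
class EventStats:
    """Per-cell event rates/amplitudes plus group mean ± SEM summaries."""

    per_cell: pd.DataFrame  # columns: cell, cell_type, session, rate_per_min, mean_amplitude
    per_group: pd.DataFrame  # columns: cell_type, session, n_cells, rate_mean, rate_sem, amp_mean, amp_sem
    limit_min: float


@dataclass
class BehaviorSession:
    """Timestamped operant event log for one session.

    ``events`` columns: ``time_s`` (float), ``event`` (str, one of
    active_poke / inactive_poke / cue_on / cue_off / infusion), ``cued``
    (bool; meaningful for active pokes — True when the poke fell outside
    any running cue timeout and therefore triggered programmed consequences).
    """

    events: pd.DataFrame
    session_type: str
    duration_s: float

    REQUIRED_COLUMNS = ("time_s", "event", "cued")

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ValueError(
                f"unknown session_type {self.session_type!r}; expected one of {SESSION_TYPES}"
            )
        for col in self.REQUIRED_COLUMNS:
            if col not in self.events.columns:
                raise ValueError(f"BehaviorSession events missing column {col!r}")
        self.events = self.events.sort_values("time_s", kind="stable").reset_index(drop=True)

    def of_type(self, event: str) -> pd.DataFrame:
        return self.events[self.events["event"] == event]

    def active_poke_times(self) -> np.ndarray:
        return self.of_type("active_poke")["time_s"].to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BehaviorSession):
            return NotImplemented
        if self.session_type != other.session_type or not np.isclose(
            self.duration_s, other.duration_s
        ):
            return False
        a, b = self.events, other.events
        if len(a) != len(b):
            return False
        return (
            np.allclose(a["time_s"], b["time_s"], rtol=0, atol=1e-9)
            and (a["event"].to_numpy() == b["event"].to_numpy()).all()
            and (a["cued"].to_numpy(dtype=bool) == b["cued"].to_numpy(dtype=bool)).all()
        )


@dataclass
class PeriEventTensor:
    """Smoothed, z-scored peri-event activity: cells × trials × time bins.

    ``bin_times`` holds the left-edge offset of each bin relative to the
    aligned event, spanning the configured window (default −10 … +20 s).
    """

    values: np.ndarray
    bin_times: np.ndarray
    trial_times: np.ndarray
    session_type: str
    cell_types: np.ndarray | None = None
    frame_rate_hz: float = 15.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("PeriEventTensor values must be cells × trials × bins")
        if self.values.shape[2] != len(self.bin_times):
            raise ValueError("bin_times length must equal the number of time bins")
        if self.cell_types is None:
            self.cell_types = np.array([""] * self.values.shape[0], dtype=object)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def trial_average(self) -> np.ndarray:
        """Per-cell trial-averaged trace (cells × bins), NaN-trials excluded."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)


@dataclass
class PopulationResponse:
    """Per-cell peri-event summaries and the group-level magnitude curves."""

    per_cell: pd.DataFrame  # cell, cell_type, pre, post, abs_pre, abs_post, cls
    mean_abs_trace: np.ndarray  # cells × bins, |z| of the trial average
    bin_times: np.ndarray
    group_fractions: pd.DataFrame  # cell_type, increased, decreased, unchanged (fractions)
    session_type: str = ""


@dataclass
class CellFootprintSet:
    """Spatial components from source extraction: maps and their centroids."""

    maps: np.ndarray  # n_cells × H × W, rectified (non-negative)
    centroids: np.ndarray  # n_cells × 2, (x, y) in px, intensity-weighted

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.maps.ndim != 3 or self.maps.shape[0] != self.centroids.shape[0]:
            raise ValueError("maps must be n_cells × H × W with one centroid per cell")

    @property
    def n_cells(self) -> int:
        return self.maps.shape[0]


@dataclass
class SpatialPattern:
    """2-D point pattern with its field bounds and generating mode."""

    points: np.ndarray  # n × 2 (x, y) px
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    mode: str = "CSR"  # "CSR" or "clustered"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("bounds must describe a non-degenerate rectangle")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if x.min() < xmin or x.max() > xmax or y.min() < ymin or y.max() > ymax:
                raise ValueError("all points must lie within the field bounds")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)


@dataclass
class KernelParams:
    """Shape of the fluorescence transient evoked by one calcium event.

    A fast genetically encoded indicator (GCaMP6f-like) is modelled as a
    difference of exponentials with a sub-second rise and a ~0.6 s decay;
    ``peak_dff`` is the mean event amplitude in ΔF/F units.
    """

    rise_tau_s: float = 0.2
    decay_tau_s: float = 0.6
    peak_dff: float = 0.25

    def __post_init__(self) -> None:
        if min(self.rise_tau_s, self.decay_tau_s, self.peak_dff) <= 0:
            raise ValueError("kernel parameters must all be > 0")
        if self.decay_tau_s <= self.rise_tau_s:
            raise ValueError("decay_tau_s must exceed rise_tau_s")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak kernel sampled at offsets ``t`` (s) from event onset."""
        t = np.asarray(t, dtype=float)
        tp_ = np.maximum(t, 0.0)  # avoid overflow for far-negative offsets
        h = np.where(
            t >= 0,
            np.exp(-tp_ / self.decay_tau_s) - np.exp(-tp_ / self.rise_tau_s),
            0.0,
        )
        # analytic peak of the double exponential
        tp = (
            self.rise_tau_s
            * self.decay_tau_s
            / (self.decay_tau_s - self.rise_tau_s)
            * np.log(self.decay_tau_s / self.rise_tau_s)
        )
        peak = np.exp(-tp / self.decay_tau_s) - np.exp(-tp / self.rise_tau_s)
        return h / peak


@dataclass
class GroundTruth:
    """Everything the synthetic generators know that downstream stages must recover."""

    event_times: list[np.ndarray] = field(default_factory=list)
    event_amplitudes: list[np.ndarray] = field(default_factory=list)
    cell_centroids: np.ndarray | None = None
    cell_types: np.ndarray | None = None
    upstream_labels: np.ndarray | None = None

    def rates_per_min(self, duration_s: float) -> np.ndarray:
        return np.array([len(t) / (duration_s / 60.0) for t in self.event_times])
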