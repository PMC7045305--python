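"""Synthetic data with exported ground truth for every downstream stage.

The generators emulate the statistical structure the analyses assume:

* GCaMP6f-like fluorescence transients riding on noisy baselines, fired by
  homogeneous Poisson event trains at per-cell-type rates;
* one-photon movies with Gaussian cell footprints, static background,
  optional rigid drift of known schedule, and pixel noise;
* FR1 cocaine self-administration sessions with 20-s cue timeouts,
  extinction sessions that decay to well below 40% of day-1 responding,
  and cued-reinstatement sessions;
* clustered (Thomas-type parent–offspring) versus completely spatially
  random (CSR) point patterns;
* Bernoulli D1/D2 upstream-label draws for input-fraction counting, and
  multinomial marker tables for colocalization counting.

Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    BehaviorSession,
    FluorescenceMovie,
    GroundTruth,
    KernelParams,
    SpatialPattern,
    TraceSet,
)

__all__ = [
    "BehaviorParams",
    "ClusterParams",
    "gen_traces",
    "gen_movie",
    "gen_behavior",
    "gen_point_pattern",
    "gen_input_labels",
    "gen_marker_table",
]

AMPLITUDE_LOGNORMAL_SIGMA = 0.25  # right-skewed event amplitudes


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_traces(
    n_cells: int,
    duration_s: float,
    rate_per_min: float,
    kernel: KernelParams | None = None,
    snr: float = 8.0,
    seed=0,
    frame_rate_hz: float = 15.0,
    cell_type: str = "Glu",
    session: str = "",
    baseline_drift_amp: float = 0.0,
    baseline_drift_period_s: float = 120.0,
) -> tuple[TraceSet, GroundTruth]:
    """Poisson event trains convolved with a transient kernel, plus noise.

    Events are homogeneous Poisson at ``rate_per_min``; each adds one kernel
    transient with amplitude drawn lognormally around ``kernel.peak_dff``
    (so the mean amplitude equals ``peak_dff``).  White Gaussian baseline
    noise is scaled so that ``peak_dff / noise_sd = snr``; an optional slow
    sinusoidal baseline drift exercises ΔF/F robustness.
    """
    kernel = kernel or KernelParams()
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if duration_s < 5.0 * kernel.decay_tau_s:
        raise ValueError(
            f"duration_s={duration_s} too short for one transient "
            f"(need >= {5.0 * kernel.decay_tau_s:.2f} s)"
        )
    rng = _rng(seed)
    n_samples = int(round(duration_s * frame_rate_hz))
    t_grid = np.arange(n_samples) / frame_rate_hz
    noise_sd = kernel.peak_dff / snr
    mu = np.log(kernel.peak_dff) - AMPLITUDE_LOGNORMAL_SIGMA**2 / 2.0

    # kernel support long enough that the tail is numerically negligible
    support = np.arange(int(round(10 * kernel.decay_tau_s * frame_rate_hz)))
    kernel_samples = kernel.evaluate(support / frame_rate_hz)

    data = rng.normal(0.0, noise_sd, size=(n_cells, n_samples))
    if baseline_drift_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_cells)
        data += baseline_drift_amp * np.sin(
            2 * np.pi * t_grid[None, :] / baseline_drift_period_s + phases[:, None]
        )
    event_times: list[np.ndarray] = []
    event_amps: list[np.ndarray] = []
    for i in range(n_cells):
        n_events = rng.poisson(rate_per_min * duration_s / 60.0)
        times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
        # strictly increasing times (ties have probability ~0 but are illegal)
        while n_events > 1 and np.any(np.diff(times) <= 0):
            times = np.sort(times + rng.normal(0, 1e-9, size=n_events))
        amps = np.exp(rng.normal(mu, AMPLITUDE_LOGNORMAL_SIGMA, size=n_events))
        for t0, a in zip(times, amps):
            start = int(round(t0 * frame_rate_hz))
            stop = min(start + len(kernel_samples), n_samples)
            data[i, start:stop] += a * kernel_samples[: stop - start]
        event_times.append(times)
        event_amps.append(amps)

    traces = TraceSet(
        data=data,
        frame_rate_hz=frame_rate_hz,
        cell_types=np.array([cell_type] * n_cells, dtype=object),
        session=session,
        is_dff=True,
    )
    truth = GroundTruth(
        event_times=event_times,
        event_amplitudes=event_amps,
        cell_types=np.array([cell_type] * n_cells, dtype=object),
    )
    return traces, truth


def drift_schedule(n_frames: int, drift_px: float, frame_rate_hz: float, period_s: float = 30.0):
    """Deterministic slow rigid-drift schedule: (n_frames × 2) row/col shifts."""
    t = np.arange(n_frames) / frame_rate_hz
    return np.column_stack(
        [
            drift_px * np.sin(2 * np.pi * t / period_s),
            drift_px * np.cos(2 * np.pi * t / period_s) - drift_px,
        ]
    )


def gen_movie(
    footprint_centroids: np.ndarray,
    traces: TraceSet,
    noise_sd: float = 0.01,
    drift_px: float = 0.0,
    seed=0,
    frame_shape: tuple[int, int] = (64, 64),
    footprint_sigma_px: float = 2.0,
    background: float = 1.0,
    cell_baseline: float = 0.5,
    drift_period_s: float = 30.0,
) -> tuple[FluorescenceMovie, np.ndarray]:
    """Render traces as Gaussian footprints over a static background.

    Each cell contributes ``footprint × (cell_baseline + trace)`` so cells
    are visible at rest; frames are rigidly shifted by a slow sinusoidal
    drift of amplitude ``drift_px`` (the planted per-frame shifts are
    returned for recovery tests) and white pixel noise is added last.
    Identical overlapping centroids produce a warning, not an error.
    """
    import warnings

    centroids = np.asarray(footprint_centroids, dtype=float).reshape(-1, 2)
    H, W = frame_shape
    if len(centroids):
        if centroids[:, 0].min() < 0 or centroids[:, 0].max() >= W:
            raise ValueError("centroid x outside frame")
        if centroids[:, 1].min() < 0 or centroids[:, 1].max() >= H:
            raise ValueError("centroid y outside frame")
        if len(np.unique(centroids, axis=0)) < len(centroids):
            warnings.warn("identical overlapping centroids", stacklevel=2)
    if len(centroids) != traces.n_cells:
        raise ValueError("one centroid per trace is required")
    rng = _rng(seed)
    T = traces.n_samples
    yy, xx = np.mgrid[0:H, 0:W]
    footprints = np.empty((len(centroids), H, W))
    for i, (cx, cy) in enumerate(centroids):
        footprints[i] = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * footprint_sigma_px**2))

    base = np.full((H, W), background)
    frames = np.empty((T, H, W))
    activity = cell_baseline + traces.data  # n_cells × T
    for t in range(T):
        frames[t] = base
        if len(centroids):
            frames[t] += np.tensordot(activity[:, t], footprints, axes=(0, 0))

    shifts = drift_schedule(T, drift_px, traces.frame_rate_hz, drift_period_s)
    if drift_px != 0.0:
        for t in range(T):
            frames[t] = ndimage.shift(frames[t], shifts[t], order=1, mode="nearest")
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    movie = FluorescenceMovie(frames, frame_rate_hz=traces.frame_rate_hz, is_dff=False)
    return movie, shifts


@dataclass
class BehaviorParams:
    """Operant-session generator settings.

    Poke rates are means of the renewal process (exponential inter-poke
    intervals with a 1-s refractory floor).  The extinction-day-10 rate is
    one fifth of day 1, so expected Ext10 responding sits well below the
    40%-of-Ext1 extinction criterion.
    """

    duration_s: float = 7200.0
    active_rate_per_min: dict | None = None
    inactive_rate_per_min: float = 0.1
    refractory_s: float = 1.0
    cue_duration_s: float = 5.0
    cue_timeout_s: float = 20.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.active_rate_per_min is None:
            self.active_rate_per_min = {"SA": 0.8, "Ext1": 0.5, "Ext10": 0.1, "Reinst": 0.6}


def _renewal_times(rng, rate_per_min: float, duration_s: float, refractory_s: float):
    if rate_per_min <= 0:
        return np.array([], dtype=float)
    mean_gap = 60.0 / rate_per_min
    if mean_gap <= refractory_s:
        raise ValueError("rate too high for the refractory floor")
    times = []
    t = rng.exponential(mean_gap - refractory_s)
    while t < duration_s:
        times.append(t)
        t += refractory_s + rng.exponential(mean_gap - refractory_s)
    return np.array(times)


def gen_behavior(
    session_type: str, params: BehaviorParams | None = None, seed=0
) -> BehaviorSession:
    """Simulate one operant session's event stream.

    SA: every active poke outside a running cue timeout triggers an infusion
    plus a tone/light cue and starts a fresh ``cue_timeout_s`` timeout.
    Ext1/Ext10: pokes have no programmed consequence.  Reinst: cued seeking —
    pokes outside the timeout trigger the cue only.  Pokes landing inside a
    timeout are logged with ``cued=False``.
    """
    params = params or BehaviorParams()
    if session_type not in params.active_rate_per_min:
        raise ValueError(f"unknown session_type {session_type!r}")
    rng = _rng(seed)
    active = _renewal_times(
        rng, params.active_rate_per_min[session_type], params.duration_s, params.refractory_s
    )
    inactive = _renewal_times(
        rng, params.inactive_rate_per_min, params.duration_s, params.refractory_s
    )

    rows = [(t, "inactive_poke", False) for t in inactive]
    timeout_until = -np.inf
    for t in active:
        if session_type in ("SA", "Reinst") and t >= timeout_until:
            rows.append((t, "active_poke", True))
            rows.append((t, "cue_on", False))
            rows.append((min(t + params.cue_duration_s, params.duration_s), "cue_off", False))
            if session_type == "SA":
                rows.append((t, "infusion", False))
            timeout_until = t + params.cue_timeout_s
        else:
            rows.append((t, "active_poke", False))
    df = pd.DataFrame(rows, columns=["time_s", "event", "cued"])
    return BehaviorSession(events=df, session_type=session_type, duration_s=params.duration_s)


@dataclass
class ClusterParams:
    """Thomas-process settings: parents uniform in the field, offspring
    isotropic Gaussian around their parent (``sigma_px``)."""

    n_parents: int = 10
    sigma_px: float = 10.0


def gen_point_pattern(
    n: int,
    mode: str = "CSR",
    cluster_params: ClusterParams | None = None,
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0),
    seed=0,
) -> SpatialPattern:
    """Draw exactly ``n`` points: uniform (CSR) or parent–offspring clustered.

    Clustered offspring falling outside the field are redrawn so the pattern
    is truncated to the bounds with exactly ``n`` points.
    """
    if n < 12:
        raise ValueError("n must be >= 12 (k-NN analyses need k+2 points)")
    rng = _rng(seed)
    xmin, ymin, xmax, ymax = bounds
    if mode == "CSR":
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, size=n), rng.uniform(ymin, ymax, size=n)]
        )
    elif mode == "clustered":
        cp = cluster_params or ClusterParams()
        parents = np.column_stack(
            [
                rng.uniform(xmin, xmax, size=cp.n_parents),
                rng.uniform(ymin, ymax, size=cp.n_parents),
            ]
        )
        assignment = rng.integers(0, cp.n_parents, size=n)
        pts = parents[assignment] + rng.normal(0.0, cp.sigma_px, size=(n, 2))
        for _ in range(1000):
            bad = (
                (pts[:, 0] < xmin)
                | (pts[:, 0] > xmax)
                | (pts[:, 1] < ymin)
                | (pts[:, 1] > ymax)
            )
            if not bad.any():
                break
            k = int(bad.sum())
            pts[bad] = parents[rng.integers(0, cp.n_parents, size=k)] + rng.normal(
                0.0, cp.sigma_px, size=(k, 2)
            )
        else:
            pts = np.clip(pts, [xmin, ymin], [xmax, ymax])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SpatialPattern(points=pts, bounds=bounds, mode=mode)


def gen_input_labels(n_inputs: int, p_d1: float, seed=0) -> pd.DataFrame:
    """i.i.d. Bernoulli D1/D2 labels for rabies-traced upstream cells."""
    if not 0.0 <= p_d1 <= 1.0:
        raise ValueError("p_d1 must lie in [0, 1]")
    rng = _rng(seed)
    draws = rng.random(n_inputs) < p_d1
    return pd.DataFrame(
        {"cell": np.arange(n_inputs), "label": np.where(draws, "D1", "D2")}
    )


def gen_marker_table(
    n: int,
    p_glu: float = 0.23,
    p_vgat: float = 0.73,
    p_penk: float = 0.16,
    seed=0,
) -> pd.DataFrame:
    """Boolean marker table emulating in situ hybridization counts.

    Cells are glutamatergic (Vglut2+) with probability ``p_glu``, GABAergic
    (Vgat+) with probability ``p_vgat`` (mutually exclusive; the remainder
    is unlabeled), and the enkephalinergic subpopulation (Penk+) is nested
    inside the Vgat+ class with conditional probability ``p_penk / p_vgat``
    so its marginal is ``p_penk``.
    """
    if p_glu + p_vgat > 1.0 + 1e-12:
        raise ValueError("p_glu + p_vgat must not exceed 1")
    if p_penk > p_vgat:
        raise ValueError("nested Penk marginal cannot exceed the Vgat marginal")
    rng = _rng(seed)
    u = rng.random(n)
    vglut2 = u < p_glu
    vgat = (u >= p_glu) & (u < p_glu + p_vgat)
    penk = vgat & (rng.random(n) < (p_penk / p_vgat if p_vgat > 0 else 0.0))
    return pd.DataFrame({"Vglut2": vglut2, "Vgat": vgat, "Penk": penk})
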