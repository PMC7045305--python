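"""Ca²⁺ transient (event) detection and session-level event statistics.

Events are found on each ΔF/F trace with a peak-finder: a light moving
average suppresses sample-level noise, then local maxima are kept when
their prominence exceeds a robust-noise multiple (MAD units) and the rise
from the preceding trough happens within a physiological rise window.
Event rates and amplitudes are summarised per cell and aggregated by
cell type × session, restricted to the configured analysis window
(first 60 min by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .types import BehaviorSession, EventStats, EventTrain, TraceSet

__all__ = [
    "DetectionParams",
    "detect_events",
    "event_stats",
    "cumulative_events",
    "extinction_criterion",
]


@dataclass
class DetectionParams:
    """Peak-finder settings.

    First pass: the trace is smoothed with a short moving average
    (``presmooth_points``; ~0.33 s at 15 Hz, matched to the transient
    timescale) and local maxima are kept when their prominence exceeds
    ``thresh_mads`` robust-SD units (1.4826 × median absolute deviation
    of the smoothed trace) with the prominence window limited to
    ``max_rise_s`` on each side (a rise-time gate) and peaks closer than
    ``min_separation_s`` merged keeping the larger one.  The default
    threshold of 6 keeps the false-event rate on pure noise well below
    0.1/min.

    Second pass (``resolve_overlaps``): the mean transient waveform is
    estimated from isolated first-pass events and the trace is Wiener-
    deconvolved against it (regularizer ``deconv_reg`` × the template
    spectrum's peak power); impulses above ``deconv_height_frac`` of the
    median first-pass impulse height become the final events, resolving
    transients that pile up closer than the first-pass separation, down
    to a floor of ``min_resolve_samples`` samples.  Without this pass a
    Poisson train is undercounted in proportion to its rate because
    overlapping transients merge into single prominent maxima.
    """

    thresh_mads: float = 6.0
    max_rise_s: float = 2.0
    min_separation_s: float = 0.4
    presmooth_points: int = 5
    resolve_overlaps: bool = True
    deconv_reg: float = 0.05
    deconv_height_frac: float = 0.40
    min_resolve_samples: int = 2
    min_isolated_for_template: int = 5


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x.astype(float)
    c = np.cumsum(np.concatenate([[0.0], x]))
    half_left = n // 2
    half_right = n - half_left - 1
    idx = np.arange(len(x))
    lo = np.clip(idx - half_left, 0, len(x))
    hi = np.clip(idx + half_right + 1, 0, len(x))
    return (c[hi] - c[lo]) / (hi - lo)


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _rise_onset_index(sm: np.ndarray, peak: int, base: int) -> int:
    """Latest sample before ``peak`` where the smoothed trace is still below
    40% of the rise — a noise-robust proxy for the transient onset (the
    40% crossing of a fast-rise kernel sits within one sample of onset)."""
    level = sm[base] + 0.4 * (sm[peak] - sm[base])
    below = np.flatnonzero(sm[base : peak + 1] <= level)
    return base + (below[-1] if len(below) else 0)


def _detect_one(x: np.ndarray, fs: float, p: DetectionParams):
    """Detect events on one trace; returns (times_s, amplitudes)."""
    sm = _moving_average(x, p.presmooth_points)
    sd = _robust_sd(sm)
    if sd == 0.0:
        return np.array([]), np.array([])
    wlen = max(3, 2 * int(round(p.max_rise_s * fs)) + 1)
    distance = max(1, int(round(p.min_separation_s * fs)))
    peaks, props = find_peaks(sm, prominence=p.thresh_mads * sd, wlen=wlen, distance=distance)
    trace_amps = sm[peaks] - sm[props["left_bases"]]

    def fallback():
        onsets = np.array(
            [_rise_onset_index(sm, pk, lb) for pk, lb in zip(peaks, props["left_bases"])]
        )
        return onsets / fs, trace_amps

    if not p.resolve_overlaps or len(peaks) == 0:
        return fallback()

    # template: median waveform of isolated events, aligned at their peak
    pre = int(round(0.5 * fs))
    post = int(round(2.5 * fs))
    iso_mask = np.ones(len(peaks), dtype=bool)
    if len(peaks) > 1:
        gaps = np.diff(peaks)
        near = gaps < 2 * fs
        iso_mask[:-1] &= ~near
        iso_mask[1:] &= ~near
    segs = []
    for pk in peaks[iso_mask]:
        if pk - pre >= 0 and pk + post <= len(x):
            seg = x[pk - pre : pk + post].copy()
            seg -= np.median(seg[: pre // 2])
            if seg[pre] > 0:
                segs.append(seg / seg[pre])
    if len(segs) < p.min_isolated_for_template:
        return fallback()
    template = np.median(np.asarray(segs), axis=0)
    t_peak = int(np.argmax(template))
    rise = np.flatnonzero(template[: t_peak + 1] >= 0.4 * template[t_peak])
    onset_lag = t_peak - (rise[0] if len(rise) else 0)

    # Wiener deconvolution against the template, impulse aligned at the peak
    h = np.zeros(len(x))
    h[: len(template)] = template
    H = np.fft.rfft(np.roll(h, -t_peak))
    reg = p.deconv_reg * np.abs(H).max() ** 2
    s = np.fft.irfft(np.fft.rfft(x) * np.conj(H) / (np.abs(H) ** 2 + reg), len(x))
    impulse_h = np.array([s[max(0, pk - 3) : pk + 4].max() for pk in peaks])
    s_sd = _robust_sd(s)
    height = max(p.deconv_height_frac * float(np.median(impulse_h)), 5.0 * s_sd)
    dpk, _ = find_peaks(s, height=height, distance=p.min_resolve_samples)
    if len(dpk) == 0:
        return fallback()

    # amplitudes: deconvolved impulse heights calibrated to trace units
    scale = float(np.median(trace_amps)) / float(np.median(impulse_h))
    amplitudes = s[dpk] * scale
    onset_times = (dpk - onset_lag) / fs
    ok = (onset_times >= 0) & (onset_times < len(x) / fs) & (amplitudes > 0)
    return onset_times[ok], amplitudes[ok]


def detect_events(traces: TraceSet, params: DetectionParams | None = None) -> EventTrain:
    """Find calcium events on each ΔF/F trace.

    Returns an EventTrain with event times at the estimated transient onset
    and amplitudes in ΔF/F units (peak minus preceding trough, via the
    deconvolution calibration when the overlap-resolving pass runs).
    """
    params = params or DetectionParams()
    bad = [i for i in range(traces.n_cells) if not np.all(np.isfinite(traces.data[i]))]
    if bad:
        raise ValueError(f"non-finite samples in cells {bad}")
    fs = traces.frame_rate_hz
    times: list[np.ndarray] = []
    amps: list[np.ndarray] = []
    for i in range(traces.n_cells):
        t, a = _detect_one(traces.data[i], fs, params)
        times.append(t)
        amps.append(a)
    return EventTrain(
        times=times,
        amplitudes=amps,
        duration_s=traces.duration_s,
        cell_types=traces.cell_types,
        session=traces.session,
    )


def event_stats(events: EventTrain, limit_min: float = 60.0) -> EventStats:
    """Per-cell rates and amplitudes within the analysis window, with
    cell-type × session group means ± SEM."""
    if limit_min <= 0:
        raise ValueError("limit_min must be > 0")
    limit_s = min(limit_min * 60.0, events.duration_s)
    eff_min = limit_s / 60.0
    rows = []
    for i, (t, a) in enumerate(zip(events.times, events.amplitudes)):
        in_win = t < limit_s
        n = int(in_win.sum())
        rows.append(
            {
                "cell": i,
                "cell_type": events.cell_types[i],
                "session": events.session,
                "n_events": n,
                "rate_per_min": n / eff_min,
                "mean_amplitude": float(a[in_win].mean()) if n else np.nan,
            }
        )
    per_cell = pd.DataFrame(rows)
    if len(per_cell):
        g = per_cell.groupby(["cell_type", "session"], dropna=False)
        per_group = g.agg(
            n_cells=("cell", "size"),
            rate_mean=("rate_per_min", "mean"),
            rate_sem=("rate_per_min", "sem"),
            amp_mean=("mean_amplitude", "mean"),
            amp_sem=("mean_amplitude", "sem"),
        ).reset_index()
    else:
        per_group = pd.DataFrame(
            columns=["cell_type", "session", "n_cells", "rate_mean", "rate_sem", "amp_mean", "amp_sem"]
        )
    return EventStats(per_cell=per_cell, per_group=per_group, limit_min=eff_min)


def cumulative_events(
    events: EventTrain, bin_s: float = 60.0, limit_min: float | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-cell cumulative event counts over time plus group mean curves.

    Returns ``(bin_edges, per_cell_cumulative, group_means)`` where the
    curves count events with time < right bin edge, restricted to the
    analysis window (the full recording when ``limit_min`` is None).
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    limit_s = events.duration_s if limit_min is None else min(limit_min * 60.0, events.duration_s)
    edges = np.arange(0.0, limit_s + bin_s, bin_s)
    if edges[-1] < limit_s:
        edges = np.append(edges, limit_s)
    curves = np.empty((events.n_cells, len(edges) - 1), dtype=int)
    for i, t in enumerate(events.times):
        counts, _ = np.histogram(t[t < limit_s], bins=edges)
        curves[i] = np.cumsum(counts)
    df = pd.DataFrame(curves)
    df["cell_type"] = list(events.cell_types)
    group_means = df.groupby("cell_type").mean()
    return edges, curves, group_means


def extinction_criterion(sessions: Sequence[BehaviorSession]) -> bool:
    """True iff active pokes on Ext10 are strictly below 40% of Ext1.

    ``sessions`` must contain one Ext1 and one Ext10 session for a subject.
    """
    by_type = {s.session_type: s for s in sessions}
    try:
        ext1, ext10 = by_type["Ext1"], by_type["Ext10"]
    except KeyError as exc:
        raise ValueError("sessions must include both Ext1 and Ext10") from exc
    n1 = len(ext1.active_poke_times())
    n10 = len(ext10.active_poke_times())
    if n1 == 0:
        raise ValueError("Ext1 active-poke count is zero; criterion undefined")
    return n10 < 0.40 * n1
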