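"""Nose-poke-aligned analysis: trial selection, peri-event tensors,
population response magnitude, and responder classification.

For each selected trial a −10…+20 s window of each cell's ΔF/F trace is
extracted, smoothed with a running 10-point moving average, and z-scored
against that same windowed segment; windows are then averaged across
trials per cell.  Population magnitude uses the absolute z trace so that
activated and inhibited cells both contribute positively; responders are
cells whose mean post-poke activity (0–2 s) deviates more than 2 SD from
their pre-poke baseline (−2–0 s).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import BehaviorSession, PeriEventTensor, PopulationResponse, TraceSet

__all__ = [
    "select_trials",
    "build_perievent",
    "population_response",
    "classify_cells",
    "order_heatmap",
]


def select_trials(
    session: BehaviorSession,
    min_separation_s: float = 20.0,
    limit_min: float = 60.0,
) -> np.ndarray:
    """Trial (nose-poke) times eligible for peri-event averaging.

    Extinction sessions: active pokes at least ``min_separation_s`` from
    both the previous and the next active poke, to prevent signal
    cross-contamination.  Cued sessions (SA, reinstatement): only cued
    pokes — those outside the 20-s cue timeout.  Only pokes within the
    first ``limit_min`` minutes are used.
    """
    pokes = session.of_type("active_poke")
    t = pokes["time_s"].to_numpy(dtype=float)
    if session.session_type in ("Ext1", "Ext10"):
        keep = np.ones(len(t), dtype=bool)
        if len(t) > 1:
            gaps = np.diff(t)
            keep[:-1] &= gaps >= min_separation_s
            keep[1:] &= gaps >= min_separation_s
        selected = t[keep]
    elif session.session_type in ("SA", "Reinst"):
        selected = t[pokes["cued"].to_numpy(dtype=bool)]
    else:  # pragma: no cover - constructor forbids other types
        raise ValueError(f"unknown session type {session.session_type!r}")
    selected = selected[selected < limit_min * 60.0]
    if len(selected) == 0:
        warnings.warn("no trials survive selection", stacklevel=2)
    return selected


def _moving_average_centered(x: np.ndarray, n: int) -> np.ndarray:
    """Centered running mean with a shrinking window at the edges.

    For even ``n`` the window covers ``n//2`` samples to the left and
    ``n - n//2 - 1`` to the right of each sample.
    """
    if n <= 1:
        return x.astype(float)
    c = np.cumsum(np.concatenate([[0.0], x]))
    idx = np.arange(len(x))
    lo = np.clip(idx - n // 2, 0, len(x))
    hi = np.clip(idx + (n - n // 2 - 1) + 1, 0, len(x))
    return (c[hi] - c[lo]) / (hi - lo)


def build_perievent(
    traces: TraceSet,
    trial_times: np.ndarray,
    window_s: tuple[float, float] = (-10.0, 20.0),
    smoothing_points: int = 10,
    zscore_scope: str = "window",
    session_type: str = "Ext1",
) -> PeriEventTensor:
    """Cells × trials × bins tensor of smoothed, z-scored peri-event activity.

    Smoothing precedes z-scoring; by default each segment is standardized
    against its own within-window mean and SD (``zscore_scope='window'``);
    ``zscore_scope='trace'`` standardizes against the whole-trace moments
    instead.  Trials without a full window inside the recording are dropped
    (logged); zero-variance windows yield NaN for that cell × trial.
    """
    fs = traces.frame_rate_hz
    w0, w1 = window_s
    if not w0 < w1:
        raise ValueError("window bounds must be ordered")
    nb = int(round((w1 - w0) * fs))
    trial_times = np.asarray(trial_times, dtype=float)
    starts = np.round((trial_times + w0) * fs).astype(int)
    ok = (starts >= 0) & (starts + nb <= traces.n_samples)
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} trial(s) without a full peri-event window",
            stacklevel=2,
        )
    starts, kept_times = starts[ok], trial_times[ok]

    values = np.full((traces.n_cells, len(starts), nb), np.nan)
    for ci in range(traces.n_cells):
        full = traces.data[ci]
        if zscore_scope == "trace":
            sm_full = _moving_average_centered(full, smoothing_points)
            mu_t, sd_t = sm_full.mean(), sm_full.std(ddof=0)
        for ti, s in enumerate(starts):
            seg = _moving_average_centered(full[s : s + nb], smoothing_points)
            if zscore_scope == "window":
                mu, sd = seg.mean(), seg.std(ddof=0)
            elif zscore_scope == "trace":
                mu, sd = mu_t, sd_t
            else:
                raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
            if sd == 0:
                warnings.warn(
                    f"zero-variance window for cell {ci}, trial {ti}; dropped",
                    stacklevel=2,
                )
                continue
            values[ci, ti] = (seg - mu) / sd
    return PeriEventTensor(
        values=values,
        bin_times=w0 + np.arange(nb) / fs,
        trial_times=kept_times,
        session_type=session_type,
        cell_types=traces.cell_types,
        frame_rate_hz=fs,
    )


def _window_mask(bin_times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # half-open, right-closed: the poke instant belongs to exactly one window
    return (bin_times > lo) & (bin_times <= hi)


def population_response(
    tensor: PeriEventTensor,
    pre_window_s: tuple[float, float] = (-2.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 2.0),
    sd_threshold: float = 2.0,
) -> PopulationResponse:
    """Magnitude analysis plus responder classes for one session's tensor.

    The per-cell trial-averaged z trace is rectified (absolute value) so
    increases and decreases both register; pre/post means over the ±2 s
    windows quantify the population response magnitude.  Classes come from
    :func:`classify_cells` on the non-rectified averages.
    """
    if tensor.n_cells == 0 or tensor.n_trials == 0:
        raise ValueError("empty peri-event tensor")
    avg = tensor.trial_average()  # cells × bins
    abs_avg = np.abs(avg)
    pre_m = _window_mask(tensor.bin_times, *pre_window_s)
    post_m = _window_mask(tensor.bin_times, *post_window_s)
    classes = classify_cells(
        tensor, pre_window_s=pre_window_s, post_window_s=post_window_s, sd_threshold=sd_threshold
    )
    per_cell = classes.copy()
    per_cell["abs_pre"] = np.nanmean(abs_avg[:, pre_m], axis=1)
    per_cell["abs_post"] = np.nanmean(abs_avg[:, post_m], axis=1)

    frac_rows = []
    for ctype, grp in per_cell.groupby("cell_type", dropna=False):
        counts = grp["cls"].value_counts()
        n = len(grp)
        frac_rows.append(
            {
                "cell_type": ctype,
                "n_cells": n,
                "increased": counts.get("increased", 0) / n,
                "decreased": counts.get("decreased", 0) / n,
                "unchanged": counts.get("unchanged", 0) / n,
            }
        )
    return PopulationResponse(
        per_cell=per_cell,
        mean_abs_trace=abs_avg,
        bin_times=tensor.bin_times,
        group_fractions=pd.DataFrame(frac_rows),
        session_type=tensor.session_type,
    )


def classify_cells(
    tensor: PeriEventTensor,
    pre_window_s: tuple[float, float] = (-2.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 2.0),
    sd_threshold: float = 2.0,
    baseline_scope: str = "average",
) -> pd.DataFrame:
    """Label each cell increased / decreased / unchanged.

    Default (``baseline_scope='average'``): baseline mean and SD come from
    the trial-averaged trace over the pre window, and a cell is increased
    (decreased) when its mean post-window activity exceeds (falls below)
    baseline by more than ``sd_threshold`` SDs.  ``'per_trial'`` pools the
    pre-window samples of all trials for the baseline moments instead.
    Zero-SD baselines are classified unchanged and flagged.
    """
    avg = tensor.trial_average()
    pre_m = _window_mask(tensor.bin_times, *pre_window_s)
    post_m = _window_mask(tensor.bin_times, *post_window_s)
    rows = []
    for ci in range(tensor.n_cells):
        if baseline_scope == "average":
            base = avg[ci, pre_m]
        elif baseline_scope == "per_trial":
            base = tensor.values[ci][:, pre_m].ravel()
            base = base[np.isfinite(base)]
        else:
            raise ValueError(f"unknown baseline_scope {baseline_scope!r}")
        b_mean = float(np.nanmean(base))
        b_sd = float(np.nanstd(base, ddof=0))
        post = float(np.nanmean(avg[ci, post_m]))
        pre = float(np.nanmean(avg[ci, pre_m]))
        flagged = b_sd == 0
        if flagged or np.isnan(post):
            cls = "unchanged"
        elif post > b_mean + sd_threshold * b_sd:
            cls = "increased"
        elif post < b_mean - sd_threshold * b_sd:
            cls = "decreased"
        else:
            cls = "unchanged"
        rows.append(
            {
                "cell": ci,
                "cell_type": tensor.cell_types[ci],
                "pre": pre,
                "post": post,
                "baseline_sd": b_sd,
                "cls": cls,
                "flagged_zero_sd": flagged,
            }
        )
    return pd.DataFrame(rows)


def order_heatmap(per_cell: pd.DataFrame) -> np.ndarray:
    """Row order for peri-event heatmaps: increased cells first, then
    unchanged, then decreased, each sorted by post−pre change descending;
    cell id breaks ties so the ordering is permutation-invariant."""
    rank = {"increased": 0, "unchanged": 1, "decreased": 2}
    df = per_cell.assign(
        _rank=per_cell["cls"].map(rank), _delta=per_cell["post"] - per_cell["pre"]
    )
    ordered = df.sort_values(
        by=["_rank", "_delta", "cell"], ascending=[True, False, True], kind="stable"
    )
    return ordered["cell"].to_numpy()
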