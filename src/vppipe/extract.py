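"""Movie → per-cell ΔF/F traces.

The preprocessing chain has a fixed order — spatial downsampling, rigid
motion correction, ΔF/F normalization, then PCA/ICA source extraction with
an automated component quality check.  ``run_extraction`` executes the
chain; the individual stages are exposed for testing and reuse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from sklearn.decomposition import PCA, FastICA

from .types import CellFootprintSet, FluorescenceMovie, TraceSet

__all__ = [
    "downsample_spatial",
    "motion_correct_rigid",
    "compute_dff",
    "extract_sources",
    "qc_components",
    "QCCriteria",
    "run_extraction",
]


def downsample_spatial(movie: FluorescenceMovie, factor: int) -> FluorescenceMovie:
    """Block-mean pooling by ``factor`` in both spatial dimensions.

    Frames whose height/width are not divisible by the factor are cropped to
    the largest divisible region (top-left anchored).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return movie
    T, H, W = movie.shape
    Hc, Wc = (H // factor) * factor, (W // factor) * factor
    if Hc == 0 or Wc == 0:
        raise ValueError("movie smaller than one downsampling block")
    data = movie.data[:, :Hc, :Wc]
    pooled = data.reshape(T, Hc // factor, factor, Wc // factor, factor).mean(axis=(2, 4))
    return FluorescenceMovie(pooled, movie.frame_rate_hz, is_dff=movie.is_dff)


def motion_correct_rigid(
    movie: FluorescenceMovie,
    reference: np.ndarray | int | None = None,
    max_shift_px: float = 10.0,
    upsample_factor: int = 20,
) -> tuple[FluorescenceMovie, np.ndarray]:
    """Rigid-body translation correction against a reference image.

    Per-frame (row, col) shifts are estimated by subpixel phase
    cross-correlation, clamped to ``max_shift_px``, and applied by linear
    interpolation.  The reference defaults to the temporal mean image.
    Returns the corrected movie and the estimated shifts (T × 2) — the
    translation that was applied to re-align each frame.
    """
    data = movie.data
    if reference is None:
        ref = data.mean(axis=0)
    elif isinstance(reference, (int, np.integer)):
        ref = data[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
    if not np.any(ref != ref.flat[0]):
        warnings.warn("constant reference image; no motion estimated", stacklevel=2)
        return movie, np.zeros((movie.n_frames, 2))

    shifts = np.empty((movie.n_frames, 2))
    corrected = np.empty_like(data)
    for t in range(movie.n_frames):
        sh, _, _ = phase_cross_correlation(
            ref, data[t], upsample_factor=upsample_factor, normalization=None
        )
        sh = np.clip(sh, -max_shift_px, max_shift_px)
        shifts[t] = sh
        corrected[t] = ndimage.shift(data[t], sh, order=1, mode="nearest")
    return FluorescenceMovie(corrected, movie.frame_rate_hz, is_dff=movie.is_dff), shifts


def _running_percentile_baseline(x: np.ndarray, fs: float, q: float, window_s: float):
    size = max(3, int(round(window_s * fs)))
    return ndimage.percentile_filter(x, percentile=q, size=size, mode="nearest")


def compute_dff(
    obj: FluorescenceMovie | TraceSet,
    baseline_method: str = "running_percentile",
    percentile: float = 20.0,
    window_s: float = 30.0,
):
    """(F − F₀)/F₀ normalization of a movie or trace set.

    F₀ is a running 20th-percentile over a 30-s window by default, or the
    global temporal mean (``baseline_method='global_mean'``).  A baseline
    that is zero or negative anywhere is an error (the raw signal must be
    offset to positive fluorescence first).
    """
    if isinstance(obj, FluorescenceMovie):
        T = obj.n_frames
        flat = obj.data.reshape(T, -1).T  # pixels × T
        out = np.empty_like(flat)
        fs = obj.frame_rate_hz
    elif isinstance(obj, TraceSet):
        flat = obj.data
        out = np.empty_like(flat)
        fs = obj.frame_rate_hz
    else:
        raise TypeError("compute_dff expects a FluorescenceMovie or TraceSet")

    for i, x in enumerate(flat):
        if baseline_method == "running_percentile":
            f0 = _running_percentile_baseline(x, fs, percentile, window_s)
        elif baseline_method == "global_mean":
            f0 = np.full_like(x, x.mean())
        else:
            raise ValueError(f"unknown baseline_method {baseline_method!r}")
        if np.any(f0 <= 0):
            kind = "pixel" if isinstance(obj, FluorescenceMovie) else "cell"
            raise ValueError(f"non-positive baseline at {kind} {i}")
        out[i] = (x - f0) / f0

    if isinstance(obj, FluorescenceMovie):
        return FluorescenceMovie(
            out.T.reshape(obj.shape), obj.frame_rate_hz, is_dff=True
        )
    return TraceSet(
        out,
        obj.frame_rate_hz,
        cell_types=obj.cell_types,
        session=obj.session,
        is_dff=True,
    )


def extract_sources(
    movie: FluorescenceMovie,
    n_components: int,
    ica_weight: float = 0.1,
    max_iter: int = 1000,
    random_state: int = 0,
) -> tuple[CellFootprintSet, TraceSet]:
    """PCA dimensionality reduction followed by spatio-temporal ICA.

    The movie (T × pixels) is reduced to ``n_components`` principal
    components; ICA then unmixes the concatenation of the temporal scores
    and the spatial eigenimages, weighted by ``ica_weight`` ∈ [0, 1]
    (0 = purely temporal, 1 = purely spatial).  Each component's sign is
    fixed so its temporal trace has non-negative skewness (calcium
    transients are positive-going); footprints are rectified and
    intensity-weighted centroids computed.
    """
    if not 0.0 <= ica_weight <= 1.0:
        raise ValueError("ica_weight must lie in [0, 1]")
    T, H, W = movie.shape
    X = movie.data.reshape(T, H * W)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("zero-variance movie: no sources to extract")
    n_components = int(min(n_components, T - 1, H * W))

    pca = PCA(n_components=n_components, random_state=random_state)
    U = pca.fit_transform(X)  # T × n, temporal scores
    V = pca.components_  # n × pixels, spatial eigenimages

    # standardize each route so the mixing weight is meaningful
    Us = (U - U.mean(axis=0)) / (U.std(axis=0) + 1e-12)
    Vs = (V - V.mean(axis=1, keepdims=True)) / (V.std(axis=1, keepdims=True) + 1e-12)
    joint = np.vstack([(1.0 - ica_weight) * Us, ica_weight * Vs.T])  # (T+P) × n

    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        random_state=random_state,
    )
    ica.fit(joint)
    W_unmix = ica.components_  # n × n

    traces = U @ W_unmix.T  # T × n
    maps = W_unmix @ V  # n × pixels

    # positive-going transients: enforce non-negative temporal skewness
    from scipy.stats import skew

    signs = np.where(skew(traces, axis=0) < 0, -1.0, 1.0)
    traces *= signs
    maps *= signs[:, None]

    maps = maps.reshape(n_components, H, W)
    rect = np.clip(maps, 0.0, None)
    centroids = np.empty((n_components, 2))
    yy, xx = np.mgrid[0:H, 0:W]
    for i in range(n_components):
        # weight only the footprint core so diffuse residual noise does not
        # drag the centroid toward the frame centre
        m = rect[i] * (rect[i] >= 0.3 * rect[i].max())
        total = m.sum()
        if total <= 0:
            centroids[i] = (W / 2.0, H / 2.0)
        else:
            centroids[i] = ((m * xx).sum() / total, (m * yy).sum() / total)

    footprints = CellFootprintSet(maps=rect, centroids=centroids)
    trace_set = TraceSet(traces.T, movie.frame_rate_hz, is_dff=movie.is_dff)
    return footprints, trace_set


@dataclass
class QCCriteria:
    """Automated surrogate for manual component curation.

    A component passes when its footprint is compact (fraction of total
    footprint energy within ``compact_radius_px`` of the centroid), its
    trace is positively skewed (transient-like), and its active footprint
    area lies within plausible soma bounds.
    """

    min_compactness: float = 0.5
    compact_radius_px: float = 5.0
    min_skewness: float = 0.2
    min_area_px: int = 2
    max_area_px: int = 400
    area_threshold_frac: float = 0.3  # of footprint max, defines "active" area


def qc_components(
    footprints: CellFootprintSet,
    traces: TraceSet,
    criteria: QCCriteria | None = None,
) -> tuple[CellFootprintSet, TraceSet, list[dict]]:
    """Keep components that look like cells; log rejections with reasons."""
    from scipy.stats import skew

    criteria = criteria or QCCriteria()
    keep: list[int] = []
    log: list[dict] = []
    H, W = footprints.maps.shape[1:] if footprints.n_cells else (0, 0)
    yy, xx = (np.mgrid[0:H, 0:W] if H else (None, None))
    for i in range(footprints.n_cells):
        m = footprints.maps[i]
        reasons = []
        total = m.sum()
        if total <= 0:
            reasons.append("empty footprint")
        else:
            cx, cy = footprints.centroids[i]
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            compactness = m[r2 <= criteria.compact_radius_px**2].sum() / total
            if compactness < criteria.min_compactness:
                reasons.append(f"compactness {compactness:.2f} < {criteria.min_compactness}")
            area = int((m > criteria.area_threshold_frac * m.max()).sum())
            if not criteria.min_area_px <= area <= criteria.max_area_px:
                reasons.append(f"area {area} px outside [{criteria.min_area_px}, {criteria.max_area_px}]")
        s = float(skew(traces.data[i]))
        if s < criteria.min_skewness:
            reasons.append(f"trace skewness {s:.2f} < {criteria.min_skewness}")
        if reasons:
            log.append({"component": i, "accepted": False, "reasons": reasons})
        else:
            keep.append(i)
            log.append({"component": i, "accepted": True, "reasons": []})

    kept_fp = CellFootprintSet(
        maps=footprints.maps[keep] if keep else np.empty((0, H, W)),
        centroids=footprints.centroids[keep] if keep else np.empty((0, 2)),
    )
    kept_tr = TraceSet(
        traces.data[keep] if keep else np.empty((0, traces.n_samples)),
        traces.frame_rate_hz,
        cell_types=np.asarray(traces.cell_types, dtype=object)[keep] if keep else None,
        session=traces.session,
        is_dff=traces.is_dff,
    )
    return kept_fp, kept_tr, log


def run_extraction(
    movie: FluorescenceMovie,
    n_components: int,
    downsample_factor: int = 1,
    ica_weight: float = 0.1,
    qc: QCCriteria | None = None,
    baseline_method: str = "global_mean",
) -> tuple[CellFootprintSet, TraceSet, np.ndarray]:
    """The full fixed-order chain: downsample → motion-correct → ΔF/F → PCA/ICA → QC."""
    movie = downsample_spatial(movie, downsample_factor)
    movie, shifts = motion_correct_rigid(movie)
    movie = compute_dff(movie, baseline_method=baseline_method)
    footprints, traces = extract_sources(movie, n_components=n_components, ica_weight=ica_weight)
    footprints, traces, _ = qc_components(footprints, traces, qc)
    return footprints, traces, shifts
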