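"""Spatial clustering test, colocalization/density counting, rabies
input-fraction quantification, and subpopulation arithmetic.

The clustering test compares the mean distance to the k-th nearest
neighbor (k = 10) of the observed cell centroids with the same statistic
on shuffled datasets — the same number of points redistributed uniformly
over the field, repeated 1000 times.  A one-sample t statistic of the
shuffle distribution against the observed value is reported alongside an
empirical permutation p-value; the clustering decision uses the
permutation p, which is calibrated at the nominal level by construction
(the t formulation's standard error shrinks with the number of shuffles
and therefore overstates significance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import t as t_dist

from .stats import chi_square
from .types import SpatialPattern

__all__ = [
    "KnnResult",
    "DensityTable",
    "InputFractionTable",
    "knn_clustering_test",
    "count_colocalization",
    "input_fractions",
    "derive_subpopulation_fractions",
]


@dataclass
class KnnResult:
    observed: float
    null: np.ndarray
    t: float
    df: int
    p_t: float
    p: float  # one-sided permutation p toward clustering
    clustered: bool
    k: int
    alpha: float
    degenerate: bool = False


def _knn_statistic(points: np.ndarray, k: int, mode: str = "kth") -> float:
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=k + 1)  # column 0 is the point itself
    if mode == "kth":
        per_point = dists[:, k]
    elif mode == "mean_of_k":
        per_point = dists[:, 1 : k + 1].mean(axis=1)
    else:
        raise ValueError(f"unknown statistic mode {mode!r}")
    return float(per_point.mean())


def knn_clustering_test(
    pattern: SpatialPattern | np.ndarray,
    k: int = 10,
    n_shuffles: int = 1000,
    seed=0,
    alpha: float = 0.05,
    statistic: str = "kth",
    region: tuple[float, float, float, float] | None = None,
) -> KnnResult:
    """Shuffle test for spatial clustering of a 2-D point pattern.

    The shuffle region defaults to the pattern's declared field bounds;
    for a bare point array (no known field) the bounding box of the
    observed points is used.  ``clustered`` is True when the observed mean
    k-NN distance is below the null mean and the one-sided permutation p
    is below ``alpha``.
    """
    if isinstance(pattern, SpatialPattern):
        points = pattern.points
        region = region or pattern.bounds
    else:
        points = np.asarray(pattern, dtype=float).reshape(-1, 2)
    n = len(points)
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} points, got {n}")
    if region is None:
        region = (
            points[:, 0].min(),
            points[:, 1].min(),
            points[:, 0].max(),
            points[:, 1].max(),
        )
    degenerate = bool(np.all(points == points[0]))
    if degenerate:
        warnings.warn("degenerate pattern: all points identical", stacklevel=2)
        observed = 0.0
    else:
        observed = _knn_statistic(points, k, statistic)

    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = region
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, size=n), rng.uniform(ymin, ymax, size=n)]
        )
        null[s] = _knn_statistic(pts, k, statistic)

    se = null.std(ddof=1) / np.sqrt(n_shuffles)
    t_stat = (null.mean() - observed) / se if se > 0 else np.inf
    df = n_shuffles - 1
    p_t = 2.0 * t_dist.sf(abs(t_stat), df)
    p_perm = (1.0 + np.sum(null <= observed)) / (n_shuffles + 1.0)
    clustered = bool(observed < null.mean() and p_perm < alpha)
    return KnnResult(
        observed=observed,
        null=null,
        t=float(t_stat),
        df=df,
        p_t=float(p_t),
        p=float(p_perm),
        clustered=clustered,
        k=k,
        alpha=alpha,
        degenerate=degenerate,
    )


@dataclass
class DensityTable:
    """Marker counts and percentages for a field of cells.

    ``marginals``: one row per marker (count, pct of all cells).
    ``combinations``: the disjoint Venn partition over all markers; its
    counts sum to ``n``.
    """

    marginals: pd.DataFrame
    combinations: pd.DataFrame
    n: int

    def pct(self, marker: str) -> float:
        row = self.marginals[self.marginals["marker"] == marker]
        if not len(row):
            raise KeyError(marker)
        return float(row["pct"].iloc[0])


def count_colocalization(labels: pd.DataFrame) -> DensityTable:
    """Counts/percentages per marker and per marker combination.

    ``labels`` is a boolean DataFrame with one column per marker and one
    row per cell.
    """
    markers = list(labels.columns)
    bools = labels.astype(bool)
    n = len(bools)
    marginals = pd.DataFrame(
        {
            "marker": markers,
            "count": [int(bools[m].sum()) for m in markers],
        }
    )
    marginals["pct"] = 100.0 * marginals["count"] / n if n else 0.0

    combo_rows = []
    for combo in product([False, True], repeat=len(markers)):
        mask = np.ones(n, dtype=bool)
        for m, v in zip(markers, combo):
            mask &= bools[m].to_numpy() == v
        count = int(mask.sum())
        name = "+".join(m for m, v in zip(markers, combo) if v) or "none"
        combo_rows.append({"combination": name, "count": count})
    combos = pd.DataFrame(combo_rows)
    combos["pct"] = 100.0 * combos["count"] / n if n else 0.0
    assert combos["count"].sum() == n  # disjoint partition conserves cells
    return DensityTable(marginals=marginals, combinations=combos, n=n)


@dataclass
class InputFractionTable:
    """Per-starter-type D1/D2 input counts with pairwise chi-square tests."""

    per_type: pd.DataFrame  # starter_type, n, d1, d2, d1_pct
    pairwise: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["type_a", "type_b", "chi2", "df", "p_raw", "p_bonferroni"]
        )
    )

    def d1_pct(self, starter_type: str) -> float:
        row = self.per_type[self.per_type["starter_type"] == starter_type]
        if not len(row):
            raise KeyError(starter_type)
        return float(row["d1_pct"].iloc[0])


def input_fractions(label_tables: dict[str, pd.DataFrame]) -> InputFractionTable:
    """D1 input percentages per starter type, with pairwise 2×2 chi-squares.

    Each table must have a ``label`` column of 'D1'/'D2' values.  With two
    or more starter types, all pairwise D1/D2 × type contingency tests are
    run, Bonferroni-adjusted across the number of pairs.
    """
    if not label_tables:
        raise ValueError("at least one starter-type label table is required")
    rows = []
    for name, tbl in label_tables.items():
        if "label" not in tbl.columns:
            raise ValueError(f"label table {name!r} missing 'label' column")
        labels = tbl["label"].to_numpy()
        bad = set(labels) - {"D1", "D2"}
        if bad:
            raise ValueError(f"label table {name!r} has unknown labels {sorted(bad)}")
        d1 = int((labels == "D1").sum())
        n = len(labels)
        rows.append(
            {"starter_type": name, "n": n, "d1": d1, "d2": n - d1, "d1_pct": 100.0 * d1 / n}
        )
    per_type = pd.DataFrame(rows)

    pair_rows = []
    names = list(label_tables)
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        ra = per_type[per_type["starter_type"] == a].iloc[0]
        rb = per_type[per_type["starter_type"] == b].iloc[0]
        table = np.array([[ra["d1"], ra["d2"]], [rb["d1"], rb["d2"]]], dtype=int)
        res = chi_square(table, bonferroni_m=len(pairs))
        pair_rows.append(
            {
                "type_a": a,
                "type_b": b,
                "chi2": res.statistic,
                "df": res.df,
                "p_raw": res.p_uncorrected,
                "p_bonferroni": res.p,
            }
        )
    pairwise = pd.DataFrame(
        pair_rows, columns=["type_a", "type_b", "chi2", "df", "p_raw", "p_bonferroni"]
    )
    return InputFractionTable(per_type=per_type, pairwise=pairwise)


def derive_subpopulation_fractions(penk_pct: float, vgat_pct: float) -> tuple[int, int]:
    """Share of the GABAergic population that is enkephalinergic.

    From whole-population marker percentages (e.g., Penk 16%, Vgat 73%),
    the Penk share of the GABA class is ``round(100 · Penk% / Vgat%)`` and
    its complement is the enkephalin-negative share — 22% and 78% at the
    printed densities.
    """
    if vgat_pct <= 0:
        raise ValueError("Vgat percentage must be > 0")
    if penk_pct < 0:
        raise ValueError("Penk percentage must be >= 0")
    share = int(round(100.0 * penk_pct / vgat_pct))
    return share, 100 - share
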