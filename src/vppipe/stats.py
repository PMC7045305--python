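"""The inferential tests applied across the pipeline.

Paired and one-sample t tests, repeated-measures ANOVA with the
Greenhouse–Geisser sphericity correction (one-way within-subject and
two-way mixed designs), the Student–Newman–Keuls stepwise post hoc
procedure on the studentized range, and Pearson chi-square tests with
Bonferroni adjustment.  Computational backends are scipy and pingouin;
every result is wrapped in a uniform :class:`StatResult`.

Convention: post hoc comparisons are only meaningful after a significant
omnibus F (classical gating); :func:`newman_keuls` itself does not check
this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "StatResult",
    "paired_t",
    "one_sample_t",
    "rm_anova",
    "mixed_anova",
    "newman_keuls",
    "chi_square",
]


@dataclass
class StatResult:
    """One test's outcome: statistic, (possibly fractional) df, p value."""

    name: str
    statistic: float
    df: float | tuple
    p: float
    p_uncorrected: float | None = None
    correction: str | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p={self.p} outside [0, 1]")


def paired_t(x, y) -> StatResult:
    """Two-sided paired Student's t test; df = n − 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(x - y == (x - y)[0]) and (x - y)[0] == 0.0:
        return StatResult("paired t", 0.0, len(x) - 1, 1.0)
    res = sps.ttest_rel(x, y)
    return StatResult("paired t", float(res.statistic), len(x) - 1, float(res.pvalue))


def one_sample_t(sample, mu: float = 0.0) -> StatResult:
    """Two-sided one-sample t test of a sample mean against ``mu``."""
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1 or len(sample) < 2:
        raise ValueError("sample must be 1-D with n >= 2")
    res = sps.ttest_1samp(sample, mu)
    return StatResult("one-sample t", float(res.statistic), len(sample) - 1, float(res.pvalue))


def _wide_to_long(data) -> pd.DataFrame:
    wide = pd.DataFrame(np.asarray(data, dtype=float))
    long = wide.reset_index().melt(id_vars="index", var_name="cond", value_name="y")
    return long.rename(columns={"index": "subject"})


def rm_anova(data, gg_correction: bool = True) -> StatResult:
    """One-way within-subject (repeated-measures) ANOVA.

    ``data`` is subjects × conditions (array or wide DataFrame) with no
    missing cells.  With ``gg_correction`` the Greenhouse–Geisser epsilon
    from the sample covariance of the repeated measures scales both df,
    and the p value uses the corrected (fractional) df.
    """
    arr = np.asarray(pd.DataFrame(data), dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing cells are not supported (no imputation)")
    n_subj, k = arr.shape
    if k < 2 or n_subj < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    long = _wide_to_long(arr)
    df1, df2 = k - 1, (k - 1) * (n_subj - 1)
    # degenerate input (identical conditions per subject): F = 0 by
    # definition and the covariance of the repeated measures is singular,
    # so sphericity is treated as trivially satisfied
    if np.allclose(arr, arr[:, [0]]):
        eps = 1.0
        return StatResult(
            "RM-ANOVA", 0.0, (df1 * eps, df2 * eps) if gg_correction else (df1, df2), 1.0,
            p_uncorrected=1.0, correction="GG" if gg_correction else None, epsilon=eps,
        )
    res = pg.rm_anova(
        data=long, dv="y", within="cond", subject="subject", correction=True, detailed=True
    ).iloc[0]
    eps = 1.0 if k == 2 else float(res["eps"])  # sphericity holds trivially at 2 levels
    F = float(res["F"])
    p_unc = float(res["p_unc"])
    if gg_correction:
        p_gg = res.get("p_GG_corr", np.nan)
        p = float(p_gg) if np.isfinite(p_gg) else float(sps.f.sf(F, eps * df1, eps * df2))
        return StatResult(
            "RM-ANOVA",
            F,
            (eps * df1, eps * df2),
            p,
            p_uncorrected=p_unc,
            correction="GG",
            epsilon=eps,
        )
    return StatResult("RM-ANOVA", F, (df1, df2), p_unc, epsilon=eps)


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "y",
    within: str = "cond",
    between: str = "group",
    subject: str = "subject",
    gg_correction: bool = True,
) -> dict[str, StatResult]:
    """Two-way mixed ANOVA: a between-units factor (e.g., cell type) crossed
    with a within-units factor (e.g., session).

    Returns StatResults keyed by source: the between main effect, the
    within main effect, and their interaction.  The GG correction applies
    to the within-involving effects.
    """
    res = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject, correction=True
    )
    # GG epsilon from the subject × within-level means (one value per design)
    pivot = data.pivot_table(index=subject, columns=within, values=dv)
    k = pivot.shape[1]
    eps_design = 1.0 if k == 2 else float(pg.epsilon(pivot, correction="gg"))
    out: dict[str, StatResult] = {}
    for _, row in res.iterrows():
        source = str(row["Source"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        eps = None if source == between else eps_design
        use_gg = gg_correction and eps is not None
        if use_gg:
            p = float(sps.f.sf(float(row["F"]), eps * df1, eps * df2))
        else:
            p = float(row["p_unc"])
        dfs = (eps * df1, eps * df2) if use_gg else (df1, df2)
        key = "interaction" if source.lower() == "interaction" else source
        out[key] = StatResult(
            f"mixed ANOVA [{source}]",
            float(row["F"]),
            dfs,
            p,
            p_uncorrected=float(row["p_unc"]),
            correction="GG" if use_gg else None,
            epsilon=eps if use_gg else None,
        )
    return out


def newman_keuls(
    means,
    ms_error: float,
    df_error: float,
    n_per_group,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Student–Newman–Keuls stepwise post hoc comparisons.

    Means are ranked; each pair is tested with the studentized range at a
    critical value depending on the span r between the ranked means.  A
    pair inside a non-rejected wider span is declared non-significant
    (non-significance propagation), implemented by carrying the largest
    blocking p value inward.  Returns a long DataFrame with raw and
    effective p values and the significance decision at ``alpha``.
    """
    means = np.asarray(means, dtype=float)
    kg = len(means)
    if kg < 2:
        raise ValueError("need at least two group means")
    n_per_group = np.broadcast_to(np.asarray(n_per_group, dtype=float), (kg,))
    order = np.argsort(means, kind="stable")
    sorted_means = means[order]

    p_raw = np.full((kg, kg), np.nan)
    for i in range(kg):
        for j in range(i + 1, kg):
            r = j - i + 1
            nh = 2.0 / (1.0 / n_per_group[order[i]] + 1.0 / n_per_group[order[j]])
            q = (sorted_means[j] - sorted_means[i]) / np.sqrt(ms_error / nh)
            p_raw[i, j] = float(sps.studentized_range.sf(q, r, df_error))

    # propagate non-significance from wider spans inward
    p_eff = p_raw.copy()
    for width in range(kg - 1, 0, -1):
        for i in range(kg - width):
            j = i + width
            blockers = []
            if i > 0:
                blockers.append(p_eff[i - 1, j])
            if j < kg - 1:
                blockers.append(p_eff[i, j + 1])
            blocking = [b for b in blockers if b >= alpha]
            if blocking:
                p_eff[i, j] = max(p_raw[i, j], max(blocking))

    rows = []
    for i in range(kg):
        for j in range(i + 1, kg):
            rows.append(
                {
                    "group_a": int(order[i]),
                    "group_b": int(order[j]),
                    "span_r": j - i + 1,
                    "q": float(
                        (sorted_means[j] - sorted_means[i])
                        / np.sqrt(
                            ms_error
                            / (2.0 / (1.0 / n_per_group[order[i]] + 1.0 / n_per_group[order[j]]))
                        )
                    ),
                    "p_raw": p_raw[i, j],
                    "p": p_eff[i, j],
                    "significant": bool(p_eff[i, j] < alpha),
                }
            )
    return pd.DataFrame(rows)


def chi_square(table, bonferroni_m: int = 1) -> StatResult:
    """Pearson chi-square test of independence with Bonferroni adjustment.

    ``table`` is a non-negative integer contingency table; no continuity
    correction is applied.  The adjusted p is ``min(1, m · p)``.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("table must hold non-negative integer counts")
        table = np.round(table).astype(int)
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    res = sps.chi2_contingency(table, correction=False)
    expected = res.expected_freq
    if np.any(expected <= 0):
        raise ValueError("expected counts must be > 0")
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p_adj = min(1.0, bonferroni_m * float(res.pvalue))
    return StatResult(
        "chi-square",
        float(res.statistic),
        df,
        p_adj,
        p_uncorrected=float(res.pvalue),
        correction=f"Bonferroni m={bonferroni_m}" if bonferroni_m > 1 else None,
    )
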