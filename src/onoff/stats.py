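"""Statistics harness: normality-gated tests, FDR, multi-group ANOVA.

The gating mirrors standard practice in the field: Shapiro-Wilk on the
(paired differences of the) data decides between the parametric test
(paired/unpaired t) and its non-parametric counterpart (Wilcoxon
signed-rank / Mann-Whitney U); families of related hypotheses are adjusted
with Benjamini-Hochberg FDR; multi-group comparisons gate on Levene's
homoscedasticity test between classic and Welch ANOVA, followed by Tukey
HSD contrasts.  Effect sizes: bias-corrected Hedge's g for t-tests,
rank-biserial correlation for rank tests, partial eta-squared for ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "PairedResult",
    "MultigroupResult",
    "paired_compare",
    "fdr_adjust",
    "multigroup_compare",
    "hedges_g",
]

ALPHA = 0.05


@dataclass
class PairedResult:
    """One gated two-sample comparison, shaped like a stats-table row."""

    test_name: str
    statistic: float
    p_value: float
    effect_name: str
    effect_size: float
    n: int
    normality_p: float
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must be in [0, 1]")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    def to_row(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p": self.p_value,
            "effect_method": self.effect_name,
            "effect": self.effect_size,
            "n": self.n,
            "p_adjusted": self.adjusted_p,
        }


@dataclass
class MultigroupResult:
    """Omnibus ANOVA (classic or Welch) plus Tukey HSD contrasts."""

    test_name: str
    statistic: float
    p_value: float
    effect_name: str
    effect_size: float
    group_ns: list[int]
    levene_p: float
    posthoc: pd.DataFrame = field(repr=False, default=None)


def _j_correction(df: float) -> float:
    """Small-sample bias correction J = 1 - 3 / (4 df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(a: np.ndarray, b: np.ndarray | None = None, paired: bool = True) -> float:
    """Bias-corrected standardized mean difference.

    Paired designs standardize the mean difference by the SD of the
    differences; unpaired designs use the pooled SD.
    """
    a = np.asarray(a, dtype=np.float64)
    if paired:
        d = a if b is None else a - np.asarray(b, dtype=np.float64)
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            return 0.0
        return float(d.mean() / sd * _j_correction(n - 1))
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled * _j_correction(df))


def _rank_biserial_wilcoxon(d: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation from signed ranks."""
    d = d[d != 0]
    if not d.size:
        return 0.0
    ranks = sps.rankdata(np.abs(d))
    total = ranks.sum()
    r_plus = ranks[d > 0].sum()
    return float(2.0 * r_plus / total - 1.0)


def _rank_biserial_mwu(a: np.ndarray, b: np.ndarray, u_stat: float) -> float:
    return float(2.0 * u_stat / (a.size * b.size) - 1.0)


def paired_compare(
    values_a, values_b, paired: bool = True, alpha: float = ALPHA
) -> PairedResult:
    """Normality-gated two-sample comparison.

    Paired: Shapiro-Wilk on the differences (P > alpha) gates a paired t
    (effect: Hedge's g on differences) versus a Wilcoxon signed-rank
    (effect: matched-pairs rank-biserial).  Unpaired: Shapiro-Wilk on each
    group gates an unpaired t versus Mann-Whitney U.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if paired and a.size != b.size:
        raise ValueError("paired comparison needs equal-length samples")
    if min(a.size, b.size) < 3:
        raise ValueError("need n >= 3 per sample")

    if paired:
        d = a - b
        if np.allclose(d, d[0]):
            # constant differences: Shapiro is undefined; a zero-variance
            # difference carries no test either way
            norm_p = 1.0
            if d[0] == 0:
                return PairedResult("paired t-test", 0.0, 1.0, "hedges_g", 0.0,
                                    a.size, norm_p)
        else:
            norm_p = float(sps.shapiro(d).pvalue)
        if norm_p > alpha:
            res = sps.ttest_rel(a, b)
            return PairedResult("paired t-test", float(res.statistic),
                                float(res.pvalue), "hedges_g",
                                hedges_g(d, paired=True), a.size, norm_p)
        res = sps.wilcoxon(a, b)
        return PairedResult("Wilcoxon signed-rank", float(res.statistic),
                            float(res.pvalue), "rank_biserial",
                            _rank_biserial_wilcoxon(d), a.size, norm_p)

    pa = float(sps.shapiro(a).pvalue) if not np.allclose(a, a[0]) else 0.0
    pb = float(sps.shapiro(b).pvalue) if not np.allclose(b, b[0]) else 0.0
    norm_p = min(pa, pb)
    if norm_p > alpha:
        res = sps.ttest_ind(a, b)
        return PairedResult("unpaired t-test", float(res.statistic),
                            float(res.pvalue), "hedges_g",
                            hedges_g(a, b, paired=False),
                            a.size + b.size, norm_p)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return PairedResult("Mann-Whitney U", float(res.statistic),
                        float(res.pvalue), "rank_biserial",
                        _rank_biserial_mwu(a, b, float(res.statistic)),
                        a.size + b.size, norm_p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def multigroup_compare(groups: list, alpha: float = ALPHA) -> MultigroupResult:
    """Levene-gated one-way ANOVA with Tukey HSD post-hoc contrasts.

    Homoscedastic data get the classic one-way ANOVA; otherwise Welch's
    ANOVA.  The post-hoc table reports every pairwise Tukey contrast.
    Effect size is partial eta-squared from the between/within partition.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 3:
        raise ValueError("need at least 3 groups")
    if any(a.size < 3 for a in arrays):
        raise ValueError("every group needs n >= 3")

    levene_p = float(sps.levene(*arrays).pvalue)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    eta_p = float(ss_between / (ss_between + ss_within)) if ss_between + ss_within else 0.0

    if levene_p > alpha:
        res = sps.f_oneway(*arrays)
        name, stat, p = "one-way ANOVA", float(res.statistic), float(res.pvalue)
    else:
        import pingouin as pg

        long = pd.DataFrame({
            "value": np.concatenate(arrays),
            "group": np.concatenate([np.full(a.size, i) for i, a in enumerate(arrays)]),
        })
        tbl = pg.welch_anova(data=long, dv="value", between="group")
        name, stat, p = "Welch ANOVA", float(tbl["F"][0]), float(tbl["p_unc"][0])

    tk = sps.tukey_hsd(*arrays)
    pairs = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pairs.append({
                "group_a": i,
                "group_b": j,
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p": float(tk.pvalue[i, j]),
                "significant": bool(tk.pvalue[i, j] < alpha),
            })
    posthoc = pd.DataFrame(pairs)
    return MultigroupResult(name, stat, p, "partial_eta_sq", eta_p,
                            [a.size for a in arrays], levene_p, posthoc)
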