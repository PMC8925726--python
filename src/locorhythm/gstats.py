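"""Group-comparison statistics with effect sizes.

Two-group comparisons use the independent two-tailed t test (pooled
variance by default, Welch optional) with Cohen's d, or the Mann-Whitney
U test with the rank-biserial correlation; "auto" picks between them with
a Shapiro-Wilk normality screen on each group at alpha = 0.05.  Paired
designs use the paired t or the Wilcoxon signed-rank test; multi-group
designs a one-way ANOVA with Tukey HSD post hoc comparisons.

Sign conventions: Cohen's d = (mean_a - mean_b) / pooled SD, so d > 0
means group a tends larger.  Rank-biserial r = 1 - 2*U_a/(n_a*n_b) with
U_a the number of (a, b) pairs where a exceeds b (ties count 1/2), so
r > 0 means group *b* tends larger; negate for the opposite convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_independent",
    "compare_paired",
    "anova_tukey",
    "cohens_d",
    "rank_biserial",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    effect_size: float | None
    effect_type: str | None
    n: tuple[int, ...]
    notes: list[str] | None = None


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation; d(a,b) = -d(b,a)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        return 0.0 if a.mean() == b.mean() else float(np.sign(a.mean() - b.mean()) * np.inf)
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U_a = number of (a, b) pairs with a > b, ties counting 1/2."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def rank_biserial(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-biserial correlation r = 1 - 2*U_a/(n_a*n_b), in [-1, 1]."""
    ua = _u_statistic(a, b)
    return float(1.0 - 2.0 * ua / (len(a) * len(b)))


def _groups_normal(a: np.ndarray, b: np.ndarray) -> bool:
    if len(a) < 3 or len(b) < 3:
        return False  # Shapiro needs n >= 3; be conservative
    return (stats.shapiro(a).pvalue > SHAPIRO_ALPHA
            and stats.shapiro(b).pvalue > SHAPIRO_ALPHA)


def compare_independent(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "auto",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample comparison: t test, Mann-Whitney U, or auto-selected.

    auto uses the t test when both groups pass a Shapiro-Wilk normality
    screen at alpha = 0.05, the Mann-Whitney U test otherwise.  The MWU p
    is exact (permutation enumeration) when min(n_a, n_b) <= 8 and the
    data are tie-free, with the tie-corrected normal approximation as
    fallback.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    notes: list[str] = []
    if method == "auto":
        method = "t" if _groups_normal(a, b) else "mwu"
        notes.append(f"auto-selected {method}")

    if method == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t test needs n >= 2 per group")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(
            test_name="t_two_tailed",
            statistic=float(res.statistic) if np.isfinite(res.statistic) else 0.0,
            p_value=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
            effect_size=cohens_d(a, b),
            effect_type="cohens_d",
            n=(len(a), len(b)),
            notes=notes or None,
        )
    if method != "mwu":
        raise ValueError("method must be 'auto', 't' or 'mwu'")

    if len(a) < 1 or len(b) < 1:
        raise ValueError("Mann-Whitney needs n >= 1 per group")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if np.all(a[0] == np.concatenate([a, b])):
        # fully tied data carry no ordering information
        return GroupComparison("mann_whitney_u", _u_statistic(a, b), 1.0,
                               0.0, "rank_biserial", (len(a), len(b)),
                               notes=notes + ["all-tied"])
    exact = min(len(a), len(b)) <= 8 and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return GroupComparison(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=rank_biserial(a, b),
        effect_type="rank_biserial",
        n=(len(a), len(b)),
        notes=notes or None,
    )


def compare_paired(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "t_paired",
) -> GroupComparison:
    """Paired comparison: paired t on differences or Wilcoxon signed-rank.

    Wilcoxon drops zero differences and uses the exact distribution for
    n <= 15 tie-free differences.  Degenerate inputs (no non-zero
    differences, or zero-variance differences for the t) raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired comparison needs equal-length vectors")
    d = a - b

    if method == "t_paired":
        if len(d) < 2:
            raise ValueError("paired t needs n >= 2")
        if np.allclose(d.std(ddof=1), 0.0):
            raise ValueError("zero-variance differences: paired t undefined")
        res = stats.ttest_rel(a, b)
        sd = d.std(ddof=1)
        return GroupComparison(
            test_name="t_paired",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            effect_size=float(d.mean() / sd),
            effect_type="cohens_d",
            n=(len(a),),
        )
    if method != "wilcoxon":
        raise ValueError("method must be 't_paired' or 'wilcoxon'")

    nz = d[d != 0]
    if len(nz) < 2:
        raise ValueError("Wilcoxon needs >= 2 non-zero differences")
    ties = len(np.unique(np.abs(nz))) < len(nz)
    mode = "exact" if (len(nz) <= 15 and not ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=mode,
                         zero_method="wilcox")
    n = len(nz)
    # matched-pairs rank-biserial: (W+ - W-) / total rank sum
    total = n * (n + 1) / 2
    w_plus = float(np.sum(stats.rankdata(np.abs(nz))[nz > 0]))
    rb = (2.0 * w_plus - total) / total
    return GroupComparison(
        test_name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=float(rb),
        effect_type="rank_biserial",
        n=(len(a),),
        notes=["zero-differences dropped"] if len(nz) < len(d) else None,
    )


def anova_tukey(groups: list[np.ndarray]) -> dict:
    """One-way ANOVA with Tukey HSD post hoc pairwise comparisons.

    Returns {"f": F, "p": p, "pairs": [(i, j, mean_diff, p_adj), ...]}.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # all groups identical
        f, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*groups)
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairs.append((i, j,
                          float(groups[i].mean() - groups[j].mean()),
                          float(hsd.pvalue[i, j])))
    return {"f": float(f), "p": float(p), "pairs": pairs}
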