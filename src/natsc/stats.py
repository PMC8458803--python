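"""Nonparametric group-comparison battery for small two-group imaging cohorts.

Implements the statistical toolkit appropriate to a small (n ~ 10 vs 12)
case-control imaging study: two-sided Wilcoxon rank-sum (Mann-Whitney)
comparisons for continuous measures, Fisher's exact or Pearson chi-square for
categorical demographics, Spearman rank correlations for clinical covariates,
and Bonferroni family-wise control across the six ROI comparisons
(alpha/m = 0.05/6, displayed as 0.008).

Small-sample exactness: the rank-sum p-value is computed by exhaustive
enumeration of group assignments (a midrank permutation test, valid with
ties) whenever the pooled sample size is <= 12; larger samples use the
normal approximation with tie and continuity corrections.  Spearman p-values
are exact permutation values for n <= 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "rank_sum_test",
    "fisher_exact",
    "chi2_test",
    "spearman",
    "bonferroni",
    "compare_groups",
    "BonferroniResult",
    "GroupComparisonResult",
    "EXACT_RANKSUM_MAX_N",
]

#: Largest pooled sample size for which the rank-sum p is computed exactly.
EXACT_RANKSUM_MAX_N = 12


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two samples.

    For pooled size n <= 12 the p-value is exact: every C(n, n_a) assignment
    of the pooled observations to the two groups is enumerated and the
    two-sided p is the fraction of assignments whose rank sum deviates from
    its null mean at least as much as the observed one (midranks handle
    ties; without ties this reproduces the classical exact rank-sum
    distribution).  Larger samples use the normal approximation with tie and
    continuity corrections.  A pooled sample that is entirely constant gives
    p = 1 (no evidence of any shift).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    n, na = pooled.size, a.size
    if n <= EXACT_RANKSUM_MAX_N:
        ranks = sps.rankdata(pooled)
        w_obs = ranks[:na].sum()
        mu = na * (n + 1) / 2.0
        d_obs = abs(w_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), na):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-9:
                hits += 1
        return hits / total
    return float(
        sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The two-sided p sums the hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (the usual convention).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or not np.allclose(t, np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = np.round(t).astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi2_test(table) -> float:
    """Pearson chi-square p for an r x c count table, (r-1)(c-1) df.

    No Yates continuity correction (the pipeline switches to Fisher's exact
    test instead when any expected count is below 5).
    """
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: expected counts undefined")
    res = sps.chi2_contingency(t, correction=False)
    return float(res[1])


def chi2_statistic(table) -> float:
    """Pearson chi-square statistic (sum of (O-E)^2/E) for an r x c table."""
    t = np.asarray(table, dtype=float)
    return float(sps.chi2_contingency(t, correction=False)[0])


def categorical_test(table) -> float:
    """Pipeline policy for categorical comparisons.

    Fisher's exact test when the table is 2x2 and any expected count is
    below 5, Pearson chi-square otherwise.
    """
    t = np.asarray(table, dtype=float)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape == (2, 2) and (expected < 5).any():
        return fisher_exact(np.round(t).astype(int))
    return chi2_test(t)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) and its two-sided p-value.

    For n <= 8 the p-value is exact, from the permutation distribution of
    rho over all n! orderings; larger n uses the t approximation.  If either
    input is constant the correlation is undefined: returns (nan, nan) so
    callers can flag and exclude the pair from reports.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        perms = np.array(list(permutations(range(n))))
        ry_c = (ry - ry.mean()) / ry.std()
        rx_c = (rx - rx.mean()) / rx.std()
        rhos = (rx_c[perms] * ry_c).mean(axis=1)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return (rho, p)


@dataclass(frozen=True)
class BonferroniResult:
    """Family-wise threshold and per-test significance flags."""

    corrected_threshold: float  # alpha / m, full precision
    display_threshold: float  # rounded to 3 decimals for table display
    flags: tuple[bool, ...]


def bonferroni(alpha: float, m: int, pvalues=()) -> BonferroniResult:
    """Bonferroni correction: threshold alpha/m, strict-inequality flags.

    With the study's alpha = 0.05 and m = 6 ROI comparisons the displayed
    threshold is 0.008; the exact value 0.05/6 is used for flagging.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    pvalues = tuple(float(p) for p in pvalues)
    if any(p < 0 or p > 1 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    thr = alpha / m
    return BonferroniResult(
        corrected_threshold=thr,
        display_threshold=round(thr, 3),
        flags=tuple(p < thr for p in pvalues),
    )


@dataclass
class GroupComparisonResult:
    """Per-ROI/measure group comparison table plus the correction applied."""

    table: pd.DataFrame  # roi, measure, means/SDs, p, significance flag
    alpha: float
    n_comparisons: int
    corrected_threshold: float

    def to_text(self) -> str:
        lines = [
            "Group comparison (iPD vs HC), Wilcoxon rank-sum, two-sided",
            f"alpha = {self.alpha}, Bonferroni over {self.n_comparisons} TSC "
            f"comparisons -> p < {round(self.corrected_threshold, 3)}",
            "",
        ]
        for _, r in self.table.iterrows():
            star = " *" if r["significant_after_bonferroni"] else ""
            lines.append(
                f"{r['roi']:>12s} {r['measure']:>4s}: iPD {r['mean_ipd']:6.2f} ± "
                f"{r['sd_ipd']:5.2f} vs HC {r['mean_hc']:6.2f} ± {r['sd_hc']:5.2f}, "
                f"p = {r['p_uncorrected']:.3f}{star}"
            )
        lines.append("")
        lines.append("* survives Bonferroni correction (TSC family)")
        return "\n".join(lines)


def compare_groups(cohort: pd.DataFrame, alpha: float = 0.05, measures=("tsc", "nvol")) -> GroupComparisonResult:
    """Run the per-ROI group-comparison battery on a cohort table.

    ``cohort`` has one row per subject with columns ``subject_id``, ``group``
    (values "iPD"/"HC") and ``<roi>_tsc`` / ``<roi>_nvol`` value columns.
    Each ROI x measure cell is compared between groups with the two-sided
    rank-sum test; Bonferroni correction is applied across the TSC family
    only (the volume comparisons are reported uncorrected, as a secondary
    family).  Both groups must have at least 2 subjects.
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort table needs a 'group' column")
    bad = set(cohort["group"]) - {"iPD", "HC"}
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    ipd = cohort[cohort["group"] == "iPD"]
    hc = cohort[cohort["group"] == "HC"]
    if len(ipd) < 2 or len(hc) < 2:
        raise ValueError("each group needs >= 2 subjects for a comparison")

    rois = sorted(
        {c.rsplit("_", 1)[0] for c in cohort.columns if c.endswith(("_tsc", "_nvol"))},
        key=lambda r: list(cohort.columns).index(f"{r}_tsc") if f"{r}_tsc" in cohort.columns else 0,
    )
    rows = []
    for measure in measures:
        for roi in rois:
            col = f"{roi}_{measure}"
            if col not in cohort.columns:
                continue
            a, b = ipd[col].to_numpy(float), hc[col].to_numpy(float)
            rows.append(
                {
                    "roi": roi,
                    "measure": measure,
                    "mean_ipd": a.mean(),
                    "sd_ipd": a.std(ddof=1),
                    "mean_hc": b.mean(),
                    "sd_hc": b.std(ddof=1),
                    "p_uncorrected": rank_sum_test(a, b),
                }
            )
    table = pd.DataFrame(rows)
    tsc_rows = table["measure"] == "tsc"
    m = max(int(tsc_rows.sum()), 1)
    corr = bonferroni(alpha, m, table.loc[tsc_rows, "p_uncorrected"])
    table["significant_after_bonferroni"] = False
    table.loc[tsc_rows, "significant_after_bonferroni"] = list(corr.flags)
    return GroupComparisonResult(
        table=table,
        alpha=alpha,
        n_comparisons=m,
        corrected_threshold=corr.corrected_threshold,
    )
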