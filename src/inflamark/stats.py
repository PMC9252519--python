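"""Nonparametric group comparisons for marker distributions.

All comparisons in this pipeline are rank-based (the marker distributions are
right-skewed): Mann-Whitney for two independent groups, Kruskal-Wallis for
three or more, Wilcoxon signed-rank for the same marker at two timepoints in
the same patients, and Pearson chi-square for qualitative contingency tables.
Tests are two-sided at alpha = 0.05; no multiplicity correction is applied by
default (Benjamini-Hochberg is available as an opt-in helper).

Computation delegates to scipy.stats; this module fixes the conventions
(exact vs asymptotic switch-over, tie and zero handling, reporting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, cohort_to_frame
from .indices import MARKER_NAMES, add_marker_columns

__all__ = [
    "TestResult",
    "mann_whitney_test",
    "kruskal_wallis_test",
    "wilcoxon_signed_rank_test",
    "chi_square_test",
    "association_table",
    "marker_frame",
    "benjamini_hochberg",
]

# exact p-values are used up to these sizes; beyond them the normal /
# chi-square approximations are accurate at desk precision
MW_EXACT_MAX_N = 8
WILCOXON_EXACT_MAX_N = 15


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    exact: bool = False
    degenerate: bool = False
    warnings: tuple[str, ...] = ()


def _as_arrays(*samples):
    out = []
    for s in samples:
        a = np.asarray(s, dtype=float)
        if a.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite value in sample")
        out.append(a)
    return out


def mann_whitney_test(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U counts case-over-control wins with ties at half weight. The p-value is
    exact (full enumeration) when both samples have n <= 8 and there are no
    ties; otherwise the normal approximation with tie-corrected variance and
    continuity correction is used.
    """
    x, y = _as_arrays(x, y)
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    exact = no_ties and len(x) <= MW_EXACT_MAX_N and len(y) <= MW_EXACT_MAX_N
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "mann_whitney", (len(x), len(y)), exact=exact)


def kruskal_wallis_test(*groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) for >= 3 groups."""
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs >= 3 groups; "
                         "use mann_whitney_test for 2")
    arrs = _as_arrays(*groups)
    pooled = np.concatenate(arrs)
    if np.unique(pooled).size == 1:
        # all observations identical: no evidence against equality
        return TestResult(0.0, 1.0, "kruskal_wallis",
                          tuple(len(a) for a in arrs), degenerate=True)
    res = sps.kruskal(*arrs)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "kruskal_wallis", tuple(len(a) for a in arrs))


def wilcoxon_signed_rank_test(paired_before, paired_after,
                              alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Differences ``after - before`` are ranked by magnitude; zero differences
    are dropped (Wilcoxon's original treatment). W is the smaller of the
    positive/negative rank sums; the p-value is exact for n <= 15 non-zero
    differences, normal approximation with continuity correction otherwise.
    All differences zero yields a degenerate flagged result with p = 1.
    """
    b, a = _as_arrays(paired_before, paired_after)
    if len(b) != len(a):
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = int(np.count_nonzero(d))
    if nz == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank",
                          (len(b), len(a)), exact=True, degenerate=True)
    exact = nz <= WILCOXON_EXACT_MAX_N
    res = sps.wilcoxon(a, b, zero_method="wilcox",
                       alternative=alternative,
                       method="exact" if exact else "approx",
                       correction=not exact)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon_signed_rank", (len(b), len(a)), exact=exact)


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    Emits a warning in the result when any expected count is below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("table must be a 2-D array of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    res = sps.chi2_contingency(t, correction=False)
    warns = ()
    if np.any(res.expected_freq < 5):
        warns = ("expected count < 5 in at least one cell",)
    return TestResult(float(res.statistic), float(res.pvalue), "chi_square",
                      tuple(int(n) for n in t.sum(axis=1)), warnings=warns)


def marker_frame(cohort: Cohort, timepoint: str = "dx") -> pd.DataFrame:
    """Per-subject marker table at one timepoint ('dx' or 'pre').

    Subjects without a complete panel at that timepoint get missing marker
    values and are excluded downstream, never imputed.
    """
    if timepoint not in ("dx", "pre"):
        raise ValueError("timepoint must be 'dx' or 'pre'")
    df = cohort_to_frame(cohort)
    sfx = f"_{timepoint}"
    out = add_marker_columns(df, neut="neut" + sfx, lymph="lymph" + sfx,
                             plt="plt" + sfx, hb="hb" + sfx)
    cols = ["id", "group", "sex", "age", "tnm", "t_stage", "n_stage",
            "m_stage", "location", "symptom", "differentiation",
            *MARKER_NAMES]
    return out[cols]


_STRATUM_ORDER = {
    "tnm": ["I", "II", "III", "IV"],
    "location": ["rectal", "left", "right"],
    "differentiation": ["G1", "G2", "G3"],
}


def association_table(cohort: Cohort, marker: str, stratifier: str):
    """Per-stratum median/IQR of a marker among cases, with an omnibus test.

    ``stratifier`` is one of tnm, location, t_stage, n_stage, m_stage,
    differentiation, symptom. Returns ``(table, TestResult)`` where the table
    has one row per stratum (n, median, q1, q3) and the test is
    Kruskal-Wallis for >= 3 populated strata, Mann-Whitney for exactly 2.
    """
    if marker not in MARKER_NAMES:
        raise ValueError(f"unknown marker {marker!r}")
    df = marker_frame(cohort, "dx")
    df = df[(df["group"] == "case") & df[marker].notna()
            & df[stratifier].notna()]
    if df.empty:
        raise ValueError(f"stratifier {stratifier!r} absent for all subjects")

    order = _STRATUM_ORDER.get(stratifier)
    levels = (
        [v for v in order if v in set(df[stratifier])] if order
        else sorted(df[stratifier].unique())
    )
    groups = [df.loc[df[stratifier] == lv, marker].to_numpy() for lv in levels]
    if len(groups) < 2:
        raise ValueError(
            f"stratifier {stratifier!r} has a single stratum; nothing to compare")

    rows = [{
        "stratum": lv, "n": len(g),
        "median": float(np.median(g)),
        "q1": float(np.percentile(g, 25)),
        "q3": float(np.percentile(g, 75)),
    } for lv, g in zip(levels, groups)]
    table = pd.DataFrame(rows)
    test = (mann_whitney_test(groups[0], groups[1]) if len(groups) == 2
            else kruskal_wallis_test(*groups))
    return table, test


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional extension; the primary analysis reports
    unadjusted per-test p at alpha = 0.05)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
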