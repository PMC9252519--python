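"""Empirical ROC curves, AUC with DeLong inference, and Youden-optimal cutoffs.

Conventions
-----------
* Positivity direction is fixed: higher marker values are more disease-like.
  No automatic orientation is performed.
* The positivity rule is inclusive: a subject is test-positive when its score
  is greater than or equal to the cutoff.
* Candidate cutoffs are the observed score values themselves (not midpoints),
  so any selected operating point is exactly recomputable from the data.

The AUC is the Mann-Whitney placement estimator: the proportion of
case-control pairs in which the case scores higher, ties counted half. Its
standard error and the covariance between two AUCs measured on the same
subjects use the DeLong structural components (per-subject placement values),
giving Wald confidence intervals and the paired z-test for comparing two
correlated ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import TestResult

__all__ = [
    "ROCCurve",
    "AUCResult",
    "empirical_roc",
    "auc",
    "delong_paired_test",
    "youden_cutoff",
]


@dataclass(frozen=True)
class ROCCurve:
    """Operating points at every observed cutoff, descending.

    The first point is the degenerate all-negative classifier (cutoff +inf,
    Se=0, Sp=1); the last cutoff is the minimum observed value, where every
    subject is test-positive (Se=1, Sp=0 unless controls tie)."""

    cutoffs: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray

    def trapezoidal_auc(self) -> float:
        """Area under the (1-Sp, Se) polygon; equals the placement AUC."""
        fpr = 1.0 - self.specificities
        return float(np.trapezoid(self.sensitivities, fpr))


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float            # DeLong standard error; nan when m or n == 1
    ci95: tuple[float, float] | None

    def __post_init__(self):
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
                raise ValueError("ci95 must contain auc")


def _check(scores) -> np.ndarray:
    a = np.asarray(scores, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite score")
    return a


def empirical_roc(case_scores, control_scores) -> ROCCurve:
    """One operating point per unique observed value (rule: score >= cutoff),
    preceded by the degenerate all-negative point."""
    cases = _check(case_scores)
    controls = _check(control_scores)
    cuts = np.unique(np.concatenate([cases, controls]))[::-1]
    cuts = np.concatenate([[np.inf], cuts])
    # inclusive rule via searchsorted on sorted copies
    cs = np.sort(cases)
    ks = np.sort(controls)
    se = 1.0 - np.searchsorted(cs, cuts, side="left") / cases.size
    sp = np.searchsorted(ks, cuts, side="left") / controls.size
    return ROCCurve(cutoffs=cuts, sensitivities=se, specificities=sp)


def _placements(cases: np.ndarray, controls: np.ndarray):
    """Per-subject placement values.

    v10[i] = fraction of controls below case i (ties half);
    v01[j] = fraction of cases above control j (ties half).
    mean(v10) == mean(v01) == AUC.
    """
    ks = np.sort(controls)
    below = np.searchsorted(ks, cases, side="left")
    tie_k = np.searchsorted(ks, cases, side="right") - below
    v10 = (below + 0.5 * tie_k) / controls.size
    cs = np.sort(cases)
    above = cases.size - np.searchsorted(cs, controls, side="right")
    tie_c = (np.searchsorted(cs, controls, side="right")
             - np.searchsorted(cs, controls, side="left"))
    v01 = (above + 0.5 * tie_c) / cases.size
    return v10, v01


def auc(case_scores, control_scores) -> AUCResult:
    """Placement-form AUC with DeLong variance and 95% Wald CI.

    With a single case or a single control the between-subject variance
    component is undefined; se is nan and ci95 is None (flagged, not guessed).
    """
    cases = _check(case_scores)
    controls = _check(control_scores)
    v10, v01 = _placements(cases, controls)
    a = float(np.mean(v10))
    if cases.size < 2 or controls.size < 2:
        return AUCResult(auc=a, se=float("nan"), ci95=None)
    var = (np.var(v10, ddof=1) / cases.size
           + np.var(v01, ddof=1) / controls.size)
    se = float(np.sqrt(var))
    z = sps.norm.ppf(0.975)
    lo = max(0.0, a - z * se)
    hi = min(1.0, a + z * se)
    return AUCResult(auc=a, se=se, ci95=(lo, hi))


def delong_paired_test(case_scores_a, control_scores_a,
                       case_scores_b, control_scores_b) -> TestResult:
    """DeLong z-test for two AUCs measured on the same subjects.

    The variance of the AUC difference subtracts twice the covariance of the
    shared structural components, which is what makes the paired comparison
    valid for two markers computed from the same blood draws.
    """
    ca, ka = _check(case_scores_a), _check(control_scores_a)
    cb, kb = _check(case_scores_b), _check(control_scores_b)
    if ca.size != cb.size or ka.size != kb.size:
        raise ValueError("paired markers must score identical subject sets")
    if ca.size < 2 or ka.size < 2:
        raise ValueError("need >= 2 cases and >= 2 controls")
    v10a, v01a = _placements(ca, ka)
    v10b, v01b = _placements(cb, kb)
    auc_a, auc_b = float(np.mean(v10a)), float(np.mean(v10b))
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / ca.size + np.var(d01, ddof=1) / ka.size)
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else float("inf") * np.sign(diff)
    else:
        z = diff / float(np.sqrt(var))
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return TestResult(float(z), min(p, 1.0), "delong_paired",
                      (ca.size, ka.size))


def youden_cutoff(case_scores, control_scores):
    """Cutoff maximizing J = Se + Sp - 1 over observed-value cutoffs.

    Ties on J are broken toward larger specificity, then the smaller cutoff.
    Returns ``(cutoff, J, Se, Sp)``.
    """
    cases = _check(case_scores)
    controls = _check(control_scores)
    cuts = np.unique(np.concatenate([cases, controls]))
    cs, ks = np.sort(cases), np.sort(controls)
    se = 1.0 - np.searchsorted(cs, cuts, side="left") / cases.size
    sp = np.searchsorted(ks, cuts, side="left") / controls.size
    j = se + sp - 1.0
    # lexicographic argmax: J desc, Sp desc, cutoff asc
    best = 0
    for i in range(1, cuts.size):
        if (j[i], sp[i], -cuts[i]) > (j[best], sp[best], -cuts[best]):
            best = i
    return float(cuts[best]), float(j[best]), float(se[best]), float(sp[best])
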