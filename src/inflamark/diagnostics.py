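"""2x2 diagnostic performance and the positive-marker-count odds-ratio cascade.

A marker is *positive* when its value is greater than or equal to its cutoff
(inclusive rule). From a 2x2 table (TP/FP/FN/TN against disease status) we
report sensitivity, specificity, predictive values, and the odds ratio with a
95% log-odds (Woolf) confidence interval::

    CI = exp( ln OR +/- 1.96 * sqrt(1/TP + 1/FP + 1/FN + 1/TN) )

When any cell is zero, 0.5 is added to every cell (Haldane-Anscombe) before
the OR/CI and the result is flagged as corrected.

The cascade counts, per subject, how many of the four markers are positive at
their cutoffs and contrasts each count k in {1,2,3,4} against a reference
count (default 0) in a case-vs-control 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .indices import MARKER_NAMES, MarkerValues
from .stats import marker_frame

__all__ = [
    "ConfusionTable",
    "DiagnosticSummary",
    "classify",
    "summarize",
    "marker_positivity",
    "marker_count_or_cascade",
]

Z95 = 1.96  # conventional two-sided 95% normal quantile


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticSummary:
    se: float
    sp: float
    ppv: float
    npv: float
    odds_ratio: float
    or_ci95: tuple[float, float]
    corrected: bool = False    # Haldane-Anscombe 0.5 applied

    def __post_init__(self):
        lo, hi = self.or_ci95
        if not (lo - 1e-12 <= self.odds_ratio <= hi + 1e-12):
            raise ValueError("or_ci95 must contain odds_ratio")


def classify(case_scores, control_scores, cutoff: float) -> ConfusionTable:
    """Count TP/FP/FN/TN at a cutoff with the inclusive (>=) positivity rule."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("empty sample")
    tp = int(np.count_nonzero(cases >= cutoff))
    fp = int(np.count_nonzero(controls >= cutoff))
    return ConfusionTable(tp=tp, fp=fp, fn=cases.size - tp,
                          tn=controls.size - fp)


def woolf_or_ci(tp: float, fp: float, fn: float, tn: float,
                z: float = Z95) -> tuple[float, float, float]:
    """Odds ratio with log-odds (Woolf) CI from (possibly corrected) cells."""
    or_ = (tp * tn) / (fp * fn)
    se_log = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    return (or_, math.exp(math.log(or_) - z * se_log),
            math.exp(math.log(or_) + z * se_log))


def summarize(table: ConfusionTable) -> DiagnosticSummary:
    """Se/Sp/PPV/NPV and OR with 95% Woolf CI from a 2x2 table.

    A zero row or column margin leaves the corresponding proportion
    undefined and raises; a zero *cell* with positive margins triggers the
    Haldane-Anscombe correction for the OR/CI only (proportions keep the raw
    counts).
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("empty case or control margin: Se/Sp undefined")
    if tp + fp == 0 or fn + tn == 0:
        raise ValueError("empty test-positive or test-negative margin: "
                         "PPV/NPV undefined")
    corrected = 0 in (tp, fp, fn, tn)
    cells = [c + 0.5 for c in (tp, fp, fn, tn)] if corrected \
        else [float(c) for c in (tp, fp, fn, tn)]
    or_, lo, hi = woolf_or_ci(*cells)
    return DiagnosticSummary(
        se=tp / (tp + fn), sp=tn / (tn + fp),
        ppv=tp / (tp + fp), npv=tn / (tn + fn),
        odds_ratio=or_, or_ci95=(lo, hi), corrected=corrected,
    )


def marker_positivity(subject_markers: MarkerValues,
                      cutoffs: dict) -> int:
    """Number of the four markers at or above their cutoffs (0-4)."""
    missing = [m for m in MARKER_NAMES if m not in cutoffs]
    if missing:
        raise ValueError(f"cutoffs missing for {missing}")
    vals = [subject_markers[m] for m in MARKER_NAMES]
    if any(v is None or not math.isfinite(v) for v in vals):
        raise ValueError("subject has a missing marker value")
    return sum(v >= cutoffs[m] for v, m in zip(vals, MARKER_NAMES))


def marker_count_or_cascade(cohort: Cohort, cutoffs: dict,
                            reference: int = 0) -> pd.DataFrame:
    """Odds ratio of case status for each positive-marker count vs reference.

    Subjects need all four at-diagnosis markers (complete cases only;
    exclusions are reported in the ``n_excluded`` attribute of the frame).
    For each k != reference the 2x2 table (case/control) x (count==k /
    count==reference) is summarised by the Woolf OR/CI, Haldane-corrected
    when a cell is zero.
    """
    df = marker_frame(cohort, "dx")
    complete = df[list(MARKER_NAMES)].notna().all(axis=1)
    d = df[complete].copy()
    if d.empty:
        raise ValueError("no subject with complete at-diagnosis markers")
    counts = np.zeros(len(d), dtype=int)
    for m in MARKER_NAMES:
        counts += (d[m].to_numpy() >= cutoffs[m]).astype(int)
    d["n_positive"] = counts

    ref_case = int(((d["group"] == "case") & (d["n_positive"] == reference)).sum())
    ref_ctrl = int(((d["group"] == "control") & (d["n_positive"] == reference)).sum())
    if ref_case + ref_ctrl == 0:
        raise ValueError(f"reference stratum (count == {reference}) is empty; "
                         "cascade undefined")

    rows = []
    for k in sorted(set(range(5)) - {reference}):
        a = int(((d["group"] == "case") & (d["n_positive"] == k)).sum())
        b = int(((d["group"] == "control") & (d["n_positive"] == k)).sum())
        # Woolf cells as (tp, fp, fn, tn) = (cases_k, controls_k,
        # cases_ref, controls_ref): OR = (a * ref_ctrl) / (b * ref_case)
        corrected = 0 in (a, b, ref_case, ref_ctrl)
        cells = ([c + 0.5 for c in (a, b, ref_case, ref_ctrl)] if corrected
                 else [float(c) for c in (a, b, ref_case, ref_ctrl)])
        or_, lo, hi = woolf_or_ci(*cells)
        rows.append({"n_positive": k, "cases": a, "controls": b,
                     "ref_cases": ref_case, "ref_controls": ref_ctrl,
                     "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                     "corrected": corrected})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = int((~complete).sum())
    out.attrs["reference"] = reference
    return out
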