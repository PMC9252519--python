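"""2x2 diagnostic summaries, Woolf CIs, and the marker-count cascade."""

import numpy as np
import pytest

import inflamark as im
from inflamark.cohort import Cohort, Subject
from inflamark.diagnostics import (ConfusionTable, classify,
                                   marker_count_or_cascade,
                                   marker_positivity, summarize)
from inflamark.indices import CBCPanel, MarkerValues
from inflamark.roc import youden_cutoff

CUTOFFS = {"nlr": 2.28, "plr": 122.40, "sii": 616.50, "np_lhb": 43.90}


# --- classify -----------------------------------------------------------

def test_classify_direct_count():
    t = classify([50, 40], [30, 45], cutoff=43.90)
    assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)


def test_classify_cutoff_below_all_scores():
    t = classify([5, 6], [7, 8], cutoff=1.0)
    assert t.fn == 0 and t.tn == 0
    assert t.tp == 2 and t.fp == 2


def test_classify_inclusive_rule_at_cutoff():
    t = classify([43.90], [43.90], cutoff=43.90)
    assert t.tp == 1 and t.fp == 1


def test_classify_margins_match_sample_sizes(rng):
    cs = rng.normal(size=37)
    ks = rng.normal(size=53)
    t = classify(cs, ks, 0.0)
    assert t.tp + t.fn == 37 and t.fp + t.tn == 53


# --- summarize ----------------------------------------------------------

def test_summarize_symmetric_table():
    s = summarize(ConfusionTable(7, 7, 7, 7))
    assert s.se == s.sp == s.ppv == s.npv == 0.5
    assert s.odds_ratio == pytest.approx(1.0)
    assert not s.corrected


def test_summarize_zero_cell_haldane_corrected():
    s = summarize(ConfusionTable(tp=10, fp=0, fn=5, tn=20))
    assert s.corrected
    # corrected cells (10.5, 0.5, 5.5, 20.5)
    assert s.odds_ratio == pytest.approx(10.5 * 20.5 / (0.5 * 5.5))
    assert s.or_ci95[0] < s.odds_ratio < s.or_ci95[1]
    assert s.se == pytest.approx(10 / 15)  # proportions stay uncorrected


def test_summarize_empty_margin_rejected():
    with pytest.raises(ValueError):
        summarize(ConfusionTable(0, 5, 0, 5))     # no cases
    with pytest.raises(ValueError):
        summarize(ConfusionTable(0, 0, 5, 5))     # nobody test-positive


def test_or_ci_against_statsmodels(rng):
    from statsmodels.stats.contingency_tables import Table2x2
    for _ in range(25):
        tp, fp, fn, tn = rng.integers(1, 200, size=4)
        s = summarize(ConfusionTable(int(tp), int(fp), int(fn), int(tn)))
        ref = Table2x2(np.array([[tp, fp], [fn, tn]]))
        assert s.odds_ratio == pytest.approx(ref.oddsratio)
        lo, hi = ref.oddsratio_confint(0.05)
        assert s.or_ci95 == pytest.approx((lo, hi), rel=1e-4)


def test_or_equals_se_sp_odds_identity(rng):
    """OR = [Se/(1-Se)] * [Sp/(1-Sp)] for tables built by classify."""
    for _ in range(20):
        cs = rng.normal(1, 1, size=80)
        ks = rng.normal(0, 1, size=80)
        s = summarize(classify(cs, ks, 0.5))
        implied = (s.se / (1 - s.se)) * (s.sp / (1 - s.sp))
        assert s.odds_ratio == pytest.approx(implied, rel=1e-12)


def test_youden_point_cross_module_consistency(default_markers):
    """summarize(classify(. , youden cutoff)) reproduces the (Se, Sp)
    reported by youden_cutoff exactly."""
    for m in im.MARKER_NAMES:
        cs = default_markers.loc[default_markers.group == "case", m].dropna()
        ks = default_markers.loc[default_markers.group == "control", m].dropna()
        cut, j, se, sp = youden_cutoff(cs.to_numpy(), ks.to_numpy())
        s = summarize(classify(cs.to_numpy(), ks.to_numpy(), cut))
        assert s.se == pytest.approx(se, abs=1e-12)
        assert s.sp == pytest.approx(sp, abs=1e-12)


# --- marker positivity & cascade ---------------------------------------

def test_positivity_inclusive_at_cutoffs():
    mv = MarkerValues(nlr=2.28, plr=122.40, sii=616.50, np_lhb=43.90)
    assert marker_positivity(mv, CUTOFFS) == 4


def test_positivity_all_below():
    mv = MarkerValues(nlr=1.0, plr=50.0, sii=100.0, np_lhb=5.0)
    assert marker_positivity(mv, CUTOFFS) == 0


def test_positivity_mixed_pattern():
    mv = MarkerValues(nlr=2.30, plr=100.0, sii=700.0, np_lhb=40.0)
    assert marker_positivity(mv, CUTOFFS) == 2


def _panel_for_markers(nlr, plr, sii, np_lhb):
    """Invert (nlr, plr, sii, np_lhb) -> (N, L, P, Hb); the map is a
    bijection onto valid panels when Hb = sii/np_lhb lands in 3-25 g/dL."""
    p = sii / nlr
    ell = p / plr
    n = nlr * ell
    hb = sii / np_lhb
    return CBCPanel(n, ell, p, hb)


def test_marker_inversion_helper_round_trips():
    panel = _panel_for_markers(2.5, 130.0, 700.0, 50.0)
    mv = im.compute_all(panel)
    assert (mv.nlr, mv.plr, mv.sii, mv.np_lhb) == (
        pytest.approx(2.5), pytest.approx(130.0), pytest.approx(700.0),
        pytest.approx(50.0))


def _toy_cohort(case_counts, ctrl_counts):
    """Cohort whose positive-marker counts are exactly as prescribed.

    counts maps k in 0..4 -> number of subjects with exactly k positive
    markers (positivity assigned in the fixed marker order)."""
    pos = {m: 1.10 * CUTOFFS[m] for m in im.MARKER_NAMES}
    neg = {m: 0.80 * CUTOFFS[m] for m in im.MARKER_NAMES}
    subjects = []

    def add(group, prefix, counts):
        i = 0
        for k, n in counts.items():
            for _ in range(n):
                vals = {m: (pos[m] if j < k else neg[m])
                        for j, m in enumerate(im.MARKER_NAMES)}
                panel = _panel_for_markers(**vals)
                subjects.append(Subject(
                    id=f"{prefix}{i:03d}", group=group, sex="M", age=60,
                    panel_dx=CBCPanel(
                        panel.neutrophils, panel.lymphocytes,
                        panel.platelets, panel.hemoglobin,
                        draw_offset_months=0.0 if group == "case" else -1.0)))
                i += 1

    add("case", "c", case_counts)
    add("control", "k", ctrl_counts)
    return Cohort(subjects=subjects)


def test_cascade_hand_arithmetic():
    """k=2 stratum cases=8/controls=4 vs reference (k=0) cases=2/controls=10
    gives OR = (8*10)/(4*2) = 10."""
    cohort = _toy_cohort({0: 2, 2: 8}, {0: 10, 2: 4})
    table = marker_count_or_cascade(cohort, CUTOFFS, reference=0)
    row = table[table.n_positive == 2].iloc[0]
    assert row["odds_ratio"] == pytest.approx(10.0)
    assert not row["corrected"]


def test_cascade_identical_distributions_give_unit_or():
    cohort = _toy_cohort({0: 6, 1: 4, 3: 5}, {0: 6, 1: 4, 3: 5})
    table = marker_count_or_cascade(cohort, CUTOFFS, reference=0)
    populated = table[(table.cases + table.controls) > 0]
    assert np.allclose(populated["odds_ratio"], 1.0)


def test_cascade_empty_reference_rejected():
    cohort = _toy_cohort({2: 5}, {3: 5})
    with pytest.raises(ValueError, match="reference"):
        marker_count_or_cascade(cohort, CUTOFFS, reference=0)


def test_cascade_monotone_at_population_scale():
    """With correlated markers and a calibrated disease effect, the odds of
    being a case rise strictly with the number of positive markers once the
    count strata are well populated (5,000 per arm)."""
    import dataclasses
    from inflamark.simulate import default_config, generate_cohort
    big = generate_cohort(dataclasses.replace(default_config(seed=19),
                                              n_cases=5000, n_controls=5000))
    table = marker_count_or_cascade(big, CUTOFFS, reference=0)
    ors = table.sort_values("n_positive")["odds_ratio"].to_numpy()
    assert np.all(np.diff(ors) > 0)
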