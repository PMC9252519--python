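# Methods

`inflamark` evaluates four blood-cell-based inflammation indices as diagnostic
markers for colorectal cancer (CRC) in a matched case-control design. This
note records the statistical model, the choices we made where the design was
genuinely open, and what the synthetic cohort does and does not emulate.

## The indices

From one complete blood count (absolute counts in 10^9/L, hemoglobin in g/dL):

| index  | formula           | interpretation |
|--------|-------------------|----------------|
| NLR    | N / L             | neutrophil-to-lymphocyte ratio |
| PLR    | P / L             | platelet-to-lymphocyte ratio |
| SII    | (P × N) / L       | systemic immune-inflammation index |
| NP/LHb | (N × P) / (L × Hb)| SII scaled by hemoglobin, so tumor-associated anemia raises the index |

The four are deterministic functions of one panel, hence strongly correlated
by construction: SII = NLR × P and NP/LHb = SII / Hb (identities enforced to
1e-12 relative tolerance). All values are kept in double precision; rounding
(half-up, 2 decimals) happens only when report tables are formatted. Units
are fixed — no auto-detection — so values are directly comparable to the
conventional positivity cutoffs NLR 2.28, PLR 122.40, SII 616.50,
NP/LHb 43.90. A hemoglobin outside 3–25 g/dL is rejected as a probable unit
error rather than silently converted.

## Design, matching

Cases carry a mandatory panel at diagnosis (offset 0) and optionally a
pre-diagnosis panel drawn 3–12 months earlier; controls carry one panel from
the year before a normal screening colonoscopy. When several draws are
eligible, the one nearest the index event (smallest |offset|) is used.
Missing analytes propagate to missing marker values; such subjects are
excluded from ROC and cascade stages, never imputed.

Matching is 1:1 by sex and age ±5 years (inclusive). The published design
does not state an algorithm, so we use a deterministic two-phase procedure:
greedy nearest-age first (candidate pairs ordered by |Δage|, case id,
control id), then an augmenting-path repair (Kuhn's algorithm,
nearest-age-first neighbour order) that guarantees the maximum attainable
pair count — plain greedy can strand a matchable case when two cases compete
for one control. No RNG is involved; unmatched cases are reported, not
dropped.

## Hypothesis tests

All group comparisons are rank-based and two-sided at α = 0.05, with no
multiplicity correction in the primary analysis (a Benjamini–Hochberg helper
is available but off by default): Mann–Whitney for two independent groups,
Kruskal–Wallis (tie-corrected, χ² limit) for three or more, Wilcoxon
signed-rank for paired timepoints (zero differences dropped), Pearson χ²
without continuity correction for contingency tables. Exact p-values are
used for Mann–Whitney when both n ≤ 8 without ties and for Wilcoxon when
n ≤ 15 after zero-dropping; beyond that, normal approximations with tie
correction and continuity correction. Computation delegates to scipy.stats;
this package fixes the conventions. Human-readable reports never print
"p = 0.000"; values below 0.001 print as "< 0.001" (full precision is kept
in JSON outputs).

## ROC, DeLong, Youden

Positivity direction is fixed (higher = more disease-like) and the rule is
inclusive (score ≥ cutoff). Candidate cutoffs are the observed values only,
so any chosen operating point is exactly recomputable from the data. The
AUC is the Mann–Whitney placement estimator (ties count ½); its variance
uses the DeLong structural components, var = S₁₀/m + S₀₁/n, with a Wald 95%
CI clipped to [0, 1]. Two markers measured on the same subjects are compared
with the paired DeLong z-test, whose variance subtracts twice the covariance
of the shared components. The Youden cutoff maximizes J = Se + Sp − 1; ties
break toward larger specificity, then the smaller cutoff. With a single case
or control the DeLong variance is undefined and is flagged (NaN/absent), not
guessed.

## 2×2 diagnostics and the cascade

From TP/FP/FN/TN: Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), OR = (TP·TN)/(FP·FN) with the Woolf (log-odds) 95% CI
exp(ln OR ± 1.96·√(1/TP+1/FP+1/FN+1/TN)). A zero cell triggers the
Haldane–Anscombe correction (+0.5 to every cell) for the OR/CI only, with a
`corrected` flag; the raw proportions are unchanged. The Woolf method was
selected because recomputing it from the published confusion tables
reproduces the published CI bounds to their printed precision (13 of 14
printed values exactly; the SII upper bound recomputes to 16.83 where 16.84
is printed, a 1-ulp rounding difference at the third decimal).

The marker-count cascade counts, per subject with all four markers, how many
are positive at their cutoffs, then contrasts each count k ∈ {1,2,3,4}
against a reference count (default 0, configurable) in a case-vs-control 2×2
table with the same Woolf OR/CI machinery. Complete cases only; exclusions
are reported.

## Synthetic cohort: what it emulates

The generator simulates the four analytes, not the indices, so the markers
inherit the deterministic functional correlations of real hemograms. Counts
are log-normal, hemoglobin normal (clipped to 3.5–24.5 g/dL). Defaults are
the study conditions: 214 cases and 214 controls matched by sex and age ±5
years (controls are generated pairwise against cases, so a full matching
always exists), 131 cases with a pre-diagnosis panel drawn 3–12 months
before diagnosis (offset distribution centred near 6 months), TNM stage
frequencies 36/51/81/46, locations 56/84/73 (rectal/left/right), 140/214
male, case age ~N(67.08, 11.08²).

Disease shifts act multiplicatively on the NP/LHb scale and are split onto
the analytes as N^0.4 · P^0.4 / Hb^0.2 (neutrophilia and thrombocytosis rise
with burden, hemoglobin falls — the anemia mechanism). A subject's total
multiplier is `timepoint_effect × dx_effect × stage_effect × location_effect`.
Calibration, done by log-moment matching:

* control analyte medians (N 3.696, L 2.443, P 203.9 × 10^9/L, Hb
  14.82 g/dL) chosen so each marker's control positivity rate at the
  conventional cutoffs equals the reported specificities (18.7%, 16.4%,
  9.3%, 7.9% positive controls for NLR/PLR/SII/NP-LHb);
* normalized stage multipliers (0.5752, 1.1609, 0.9888, 1.3327 for I–IV)
  and the overall case shift (timepoint 1.5 × dx 1.5974 ≈ 2.40) chosen so
  simulated per-stage NP/LHb medians land on the reported stage medians
  (28.69 / 57.90 / 49.32 / 66.47); verified to fall inside the reported
  stage IQRs at n = 5,000/stage;
* location multipliers (0.70, 0.97, 1.33) encode the rectal < left colon <
  right colon gradient; their frequency-weighted geometric mean is ≈ 1.

The pre-diagnosis panel is the at-diagnosis panel shrunk toward control
levels by `dx_effect` plus log-normal repeat-measurement noise (σ = 0.12).
The pre-diagnosis effect size is a free parameter (the underlying medians
were published only graphically); timepoint_effect = 1.5 makes the
pre-diagnosis median sit midway between control and diagnosis on the log
scale, and is documented as a choice, not a fit.

A single integer seed drives one numpy Generator; identical seed + config
yields a bit-identical cohort (CSV bytes included). With all effects at 1 and
equal case/control baselines, case and control distributions are
statistically indistinguishable (null config, verified by test).

What the generator does **not** emulate: real between-analyte dependence
beyond the shared disease severity (e.g. a common white-cell production
factor correlating N and L), covariate-dependent missingness, laboratory
batch effects, or the individual-level data of any real cohort. Passing
tests therefore show that the pipeline's statistics behave correctly under a
realistic correlation structure — not that the generator reproduces any real
population's AUCs. Simulated AUCs (~0.80–0.83 for NP/LHb) run slightly above
the published 0.78, which is acceptable because no acceptance quantity
depends on matching the printed AUCs.

### A note on the cascade at study size

Strict monotonicity of the cascade ORs in k is a population property of the
calibrated generator (at 50,000/arm the ORs are ≈ 1.7 / 5.4 / 11.5 / 13.3,
strictly increasing). At 214/arm the intermediate count strata contain
single-digit control counts and the ordering of adjacent ORs flips by
sampling noise in roughly half of random seeds. Tests therefore assert
strict monotonicity on a 5,000/arm cohort (same defaults) and, at study
size, the gross pattern that the all-positive stratum carries a higher OR
than the one-positive stratum.

## Numerical choices

* Rounding for report tables: half-up at 2 decimals (matching how the
  reference tables print); computation always in double precision.
* z = 1.96 (not the exact 0.975 quantile) in Woolf CIs, matching the
  conventional formula; the difference is ~1e-5 relative.
* Ties: Mann–Whitney U counts ties at ½; AUC placement values likewise, so
  U/(n₁n₂) equals the AUC identically (tested on tied instances).
* Degenerate inputs are flagged, not patched: all-zero paired differences
  give p = 1 with a `degenerate` flag; single-subject arms give NaN DeLong
  variance; empty cascade reference raises.
* Pipeline bundles are written to a temporary directory and renamed into
  place; outputs contain no timestamps, so identical config + seed gives
  byte-identical bundles (tested by hashing).

## Problem sizes used by the test suite

Oracle-equivalence properties run on hundreds of small random instances;
DeLong CI coverage uses 2,000 cohorts of 100/arm against a truth estimated
from one 150,000/arm cohort; the paired-DeLong variance check uses a
2,000-resample bootstrap at 500/arm; generator calibration checks use
5,000/stage and 5,000/arm. The full suite completes in well under a minute
on one CPU.

## Known limitations

* The matcher optimizes pair count with a nearest-age preference but does
  not minimize total age discrepancy among maximum matchings.
* Exact OR CIs (conditional / mid-p) are out of scope; Woolf only.
* No smoothed or binormal-fitted ROC, partial AUC, or time-dependent ROC.
* T/N/M component codes in the generator are crude stage-consistent
  assignments, sufficient for exercising the association stage only.
* The cascade conditions on complete-case subjects; no missingness model.
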