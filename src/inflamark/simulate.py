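"""Seeded synthetic cohort generator emulating a matched CRC case-control study.

The generator simulates the CBC components (neutrophils, lymphocytes,
platelets, hemoglobin) rather than the composite indices, so the four derived
markers are automatically correlated the way they are in real hemograms —
essential for the positive-marker-count odds-ratio cascade, which would be
meaningless with independent markers.

Model
-----
* Counts are log-normal (strictly positive, right-skewed); hemoglobin is
  normal (approximately symmetric), clipped to a physiologic window.
* Disease shifts act multiplicatively on the NP/LHb scale. A subject's total
  multiplier is ``timepoint_effect * dx_effect * stage_effect * location_effect``
  and is split onto the analytes as ``N ** 0.4 * P ** 0.4 / Hb ** 0.2``:
  neutrophilia and thrombocytosis rise with disease burden while hemoglobin
  falls (tumor-associated anemia).
* ``stage_effects`` are normalised multipliers relative to the average case
  (their frequency-weighted geometric mean is ~1), calibrated by log-moment
  matching so that simulated per-stage NP/LHb medians land on the study's
  reported stage medians; ``location_effects`` likewise encode the
  rectal < left colon < right colon gradient.
* A fraction of cases (default 131/214) also carries a pre-diagnosis panel,
  drawn 3-12 months before diagnosis: the at-diagnosis analytes shrunk toward
  control levels by ``dx_effect`` plus repeat-measurement noise.
* Controls are generated pairwise against the cases: same sex, age within
  +/-5 years, so a fully matched cohort always exists.

A single integer seed drives one numpy Generator; identical seed + config
gives a bit-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .cohort import Cohort, Subject
from .indices import CBCPanel

__all__ = ["GeneratorConfig", "default_config", "generate_cohort"]

# Split of an index-scale multiplier m onto analytes: N *= m^0.4, P *= m^0.4,
# Hb /= m^0.2  =>  NP/LHb *= m exactly.
EXP_N, EXP_P, EXP_HB = 0.4, 0.4, 0.2

_PRE_MONTHS = np.arange(3, 13)
_PRE_MONTH_W = np.array([5, 8, 10, 9, 7, 5, 3, 2, 1, 1], float)   # median 6
_CTRL_MONTHS = np.arange(0, 13)
_CTRL_MONTH_W = np.array([4, 10, 9, 8, 7, 6, 5, 4, 3, 2, 1, 1, 1], float)  # median 3

_SYMPTOMS = ("rectal_bleeding", "habit_change", "anemia", "abdominal_pain",
             "constitutional", "obstruction", "other", None)
_DIFFS = ("G1", "G2", "G3", None)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_cases: int = 214
    n_controls: int = 214
    pre_dx_fraction: float = 131 / 214

    # control-group analyte distributions (counts 10^9/L, Hb g/dL);
    # medians chosen so each marker's control positivity rate at the
    # conventional cutoffs matches the reported specificities
    ctrl_neut_median: float = 3.696
    ctrl_neut_sigma: float = 0.35
    ctrl_lymph_median: float = 2.443
    ctrl_lymph_sigma: float = 0.30
    ctrl_plt_median: float = 203.9
    ctrl_plt_sigma: float = 0.25
    ctrl_hb_mean: float = 14.82
    ctrl_hb_sd: float = 1.1

    # case-group baselines (before disease multipliers); wider dispersion
    case_neut_median: float = 3.696
    case_neut_sigma: float = 0.45
    case_lymph_median: float = 2.443
    case_lymph_sigma: float = 0.35
    case_plt_median: float = 203.9
    case_plt_sigma: float = 0.28
    case_hb_mean: float = 14.82
    case_hb_sd: float = 1.5

    # multiplicative effects on the NP/LHb scale
    timepoint_effect: float = 1.5      # pre-diagnosis vs control
    dx_effect: float = 1.5974          # at-diagnosis vs pre-diagnosis
    stage_effects: tuple[float, float, float, float] = (
        0.5752, 1.1609, 0.9888, 1.3327)         # TNM I-IV, geo-mean ~1
    location_effects: tuple[float, float, float] = (0.70, 0.97, 1.33)

    # tumor-variable frequencies
    stage_probs: tuple[float, ...] = (36 / 214, 51 / 214, 81 / 214, 46 / 214)
    location_probs: tuple[float, ...] = (56 / 213, 84 / 213, 73 / 213)
    symptom_probs: tuple[float, ...] = (
        37 / 214, 33 / 214, 33 / 214, 28 / 214,
        15 / 214, 14 / 214, 22 / 214, 32 / 214)      # incl. missing
    diff_probs: tuple[float, ...] = (37 / 214, 125 / 214, 32 / 214, 20 / 214)

    sex_ratio: float = 140 / 214       # proportion male
    age_mean: float = 67.08
    age_sd: float = 11.08

    pre_noise_sigma: float = 0.12      # repeat-measurement log-noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not 0 <= self.pre_dx_fraction <= 1:
            raise ValueError("pre_dx_fraction must be in [0, 1]")
        for f in ("ctrl_neut_sigma", "ctrl_lymph_sigma", "ctrl_plt_sigma",
                  "ctrl_hb_sd", "case_neut_sigma", "case_lymph_sigma",
                  "case_plt_sigma", "case_hb_sd", "ctrl_neut_median",
                  "ctrl_lymph_median", "ctrl_plt_median", "ctrl_hb_mean",
                  "case_neut_median", "case_lymph_median", "case_plt_median",
                  "case_hb_mean", "timepoint_effect", "dx_effect"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        if any(e <= 0 for e in self.stage_effects + self.location_effects):
            raise ValueError("effect multipliers must be > 0")
        for name in ("stage_probs", "location_probs", "symptom_probs",
                     "diff_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kwargs = dict(d)
        for k in ("stage_effects", "location_effects", "stage_probs",
                  "location_probs", "symptom_probs", "diff_probs"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


def default_config(seed: int = 0) -> GeneratorConfig:
    """The calibrated study conditions (214 cases / 214 matched controls,
    131 with a pre-diagnosis panel) under which the test suite runs."""
    return GeneratorConfig(seed=seed)


def _tnm_components(rng: np.random.Generator, stage_idx: np.ndarray):
    """Crude T/N/M codes consistent with the sampled TNM stage."""
    n = stage_idx.size
    t = np.empty(n, int)
    nn = np.empty(n, int)
    m = np.zeros(n, int)
    u = rng.random((3, n))
    for i, k in enumerate(stage_idx):
        if k == 0:        # stage I: small tumor, no nodes
            t[i] = 1 if u[0, i] < 0.5 else 2
            nn[i] = 0
        elif k == 1:      # stage II: invasive, node-negative
            t[i] = 3 if u[0, i] < 0.7 else 4
            nn[i] = 0
        elif k == 2:      # stage III: node-positive
            t[i] = 2 + int(u[0, i] < 0.8) + int(u[0, i] < 0.3)
            nn[i] = 1 if u[1, i] < 0.6 else 2
        else:             # stage IV: metastatic
            t[i] = 3 if u[0, i] < 0.5 else 4
            nn[i] = int(np.searchsorted([0.3, 0.7], u[1, i], side="right"))
            m[i] = 1
    return t, nn, m


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw one cohort under ``config``; deterministic in ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nc, nk = cfg.n_cases, cfg.n_controls

    # --- cases ---------------------------------------------------------
    case_sex = np.where(rng.random(nc) < cfg.sex_ratio, "M", "F")
    case_age = np.clip(np.rint(rng.normal(cfg.age_mean, cfg.age_sd, nc)),
                       30, 94).astype(int)
    stage_idx = rng.choice(4, size=nc, p=np.asarray(cfg.stage_probs))
    loc_idx = rng.choice(3, size=nc, p=np.asarray(cfg.location_probs))
    sym_idx = rng.choice(len(_SYMPTOMS), size=nc,
                         p=np.asarray(cfg.symptom_probs))
    diff_idx = rng.choice(len(_DIFFS), size=nc, p=np.asarray(cfg.diff_probs))
    t_code, n_code, m_code = _tnm_components(rng, stage_idx)

    lnm = (math.log(cfg.timepoint_effect * cfg.dx_effect)
           + np.log(np.asarray(cfg.stage_effects))[stage_idx]
           + np.log(np.asarray(cfg.location_effects))[loc_idx])

    neut_dx = (cfg.case_neut_median * np.exp(EXP_N * lnm)
               * np.exp(rng.normal(0, cfg.case_neut_sigma, nc)))
    lymph_dx = (cfg.case_lymph_median
                * np.exp(rng.normal(0, cfg.case_lymph_sigma, nc)))
    plt_dx = (cfg.case_plt_median * np.exp(EXP_P * lnm)
              * np.exp(rng.normal(0, cfg.case_plt_sigma, nc)))
    hb_dx = np.clip(rng.normal(cfg.case_hb_mean, cfg.case_hb_sd, nc)
                    * np.exp(-EXP_HB * lnm), 3.5, 24.5)

    # pre-diagnosis subset: at-diagnosis analytes shrunk toward control
    # levels by dx_effect, plus repeat-measurement noise
    n_pre = int(round(cfg.pre_dx_fraction * nc))
    pre_idx = np.sort(rng.permutation(nc)[:n_pre])
    has_pre = np.zeros(nc, bool)
    has_pre[pre_idx] = True
    shrink = math.log(cfg.dx_effect)
    s = cfg.pre_noise_sigma
    neut_pre = neut_dx * math.exp(-EXP_N * shrink) * np.exp(
        rng.normal(0, s, nc))
    lymph_pre = lymph_dx * np.exp(rng.normal(0, s, nc))
    plt_pre = plt_dx * math.exp(-EXP_P * shrink) * np.exp(rng.normal(0, s, nc))
    hb_pre = np.clip(hb_dx * math.exp(EXP_HB * shrink)
                     * (1 + rng.normal(0, 0.03, nc)), 3.5, 24.5)
    pre_months = rng.choice(_PRE_MONTHS, size=nc,
                            p=_PRE_MONTH_W / _PRE_MONTH_W.sum())

    # --- controls ------------------------------------------------------
    n_paired = min(nc, nk)
    ctrl_sex = np.empty(nk, dtype=case_sex.dtype if nc else "<U1")
    ctrl_age = np.empty(nk, int)
    ctrl_sex[:n_paired] = case_sex[:n_paired]
    ctrl_age[:n_paired] = case_age[:n_paired] + rng.integers(-5, 6, n_paired)
    if nk > n_paired:
        extra = nk - n_paired
        ctrl_sex[n_paired:] = np.where(rng.random(extra) < cfg.sex_ratio,
                                       "M", "F")
        ctrl_age[n_paired:] = np.clip(
            np.rint(rng.normal(cfg.age_mean, cfg.age_sd, extra)),
            30, 94).astype(int)

    neut_k = cfg.ctrl_neut_median * np.exp(
        rng.normal(0, cfg.ctrl_neut_sigma, nk))
    lymph_k = cfg.ctrl_lymph_median * np.exp(
        rng.normal(0, cfg.ctrl_lymph_sigma, nk))
    plt_k = cfg.ctrl_plt_median * np.exp(rng.normal(0, cfg.ctrl_plt_sigma, nk))
    hb_k = np.clip(rng.normal(cfg.ctrl_hb_mean, cfg.ctrl_hb_sd, nk), 3.5, 24.5)
    ctrl_months = rng.choice(_CTRL_MONTHS, size=nk,
                             p=_CTRL_MONTH_W / _CTRL_MONTH_W.sum())

    # --- assemble ------------------------------------------------------
    subjects: list[Subject] = []
    for i in range(nc):
        panel_pre = None
        if has_pre[i]:
            panel_pre = CBCPanel(
                float(neut_pre[i]), float(lymph_pre[i]), float(plt_pre[i]),
                float(hb_pre[i]), draw_offset_months=-float(pre_months[i]))
        subjects.append(Subject(
            id=f"case_{i + 1:04d}", group="case",
            sex=str(case_sex[i]), age=int(case_age[i]),
            panel_dx=CBCPanel(float(neut_dx[i]), float(lymph_dx[i]),
                              float(plt_dx[i]), float(hb_dx[i]),
                              draw_offset_months=0.0),
            panel_pre=panel_pre,
            tnm=("I", "II", "III", "IV")[stage_idx[i]],
            t_stage=int(t_code[i]), n_stage=int(n_code[i]),
            m_stage=int(m_code[i]),
            location=("rectal", "left", "right")[loc_idx[i]],
            symptom=_SYMPTOMS[sym_idx[i]],
            differentiation=_DIFFS[diff_idx[i]],
        ))
    for j in range(nk):
        subjects.append(Subject(
            id=f"ctrl_{j + 1:04d}", group="control",
            sex=str(ctrl_sex[j]), age=int(ctrl_age[j]),
            panel_dx=CBCPanel(float(neut_k[j]), float(lymph_k[j]),
                              float(plt_k[j]), float(hb_k[j]),
                              draw_offset_months=-float(ctrl_months[j])),
        ))
    pairs = [(f"case_{i + 1:04d}", f"ctrl_{i + 1:04d}")
             for i in range(n_paired)]
    return Cohort(subjects=subjects, pairs=pairs)
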