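"""Subject/cohort data model, CSV round-trip, validation and case-control matching.

A cohort is one row per subject. Cases carry a mandatory at-diagnosis CBC panel
(``*_dx`` columns) and optionally a pre-diagnosis panel (``*_pre``, drawn 3-12
months before diagnosis). Controls carry only the pre-colonoscopy panel, stored
in the ``*_dx`` slot with a non-positive draw offset. Matching is 1:1 by sex and
age within +/-5 years, greedy on nearest age with deterministic lexicographic
tie-breaks so results are reproducible without an RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .indices import CBCPanel, PanelValidationError

__all__ = [
    "Subject",
    "Cohort",
    "RowError",
    "MatchResult",
    "CohortValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "match_controls",
    "COHORT_COLUMNS",
]

TNM_STAGES = ("I", "II", "III", "IV")
LOCATIONS = ("rectal", "left", "right")
SYMPTOMS = ("rectal_bleeding", "habit_change", "anemia", "abdominal_pain",
            "constitutional", "obstruction", "other")
DIFFERENTIATIONS = ("G1", "G2", "G3")

COHORT_COLUMNS = [
    "id", "group", "sex", "age",
    "neut_dx", "lymph_dx", "plt_dx", "hb_dx", "offset_dx",
    "neut_pre", "lymph_pre", "plt_pre", "hb_pre", "offset_pre",
    "tnm", "t_stage", "n_stage", "m_stage",
    "location", "symptom", "differentiation",
    "matched_control_id",
]

AGE_WINDOW = 5  # +/- years for a valid case-control pair


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Subject:
    """One study participant (case or control) with up to two CBC panels."""

    id: str
    group: str                      # "case" | "control"
    sex: str                        # "M" | "F"
    age: int
    panel_dx: CBCPanel | None = None
    panel_pre: CBCPanel | None = None
    tnm: str | None = None
    t_stage: int | None = None
    n_stage: int | None = None
    m_stage: int | None = None
    location: str | None = None
    symptom: str | None = None
    differentiation: str | None = None

    @property
    def is_case(self) -> bool:
        return self.group == "case"

    def validation_errors(self) -> list[str]:
        """Named rule violations; empty list means the subject is valid."""
        errs = []
        if self.group not in ("case", "control"):
            errs.append(f"group: unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            errs.append(f"sex: unknown sex {self.sex!r}")
        if not (0 < self.age < 120):
            errs.append(f"age: implausible age {self.age}")
        if self.group == "case":
            if self.panel_dx is None:
                errs.append("case_panel_dx: cases must carry an at-diagnosis panel")
            elif self.panel_dx.draw_offset_months != 0:
                errs.append("case_panel_dx_offset: at-diagnosis draw offset must be 0")
        if self.group == "control":
            if self.panel_dx is not None and not (
                    -12 <= self.panel_dx.draw_offset_months <= 0):
                errs.append("control_panel_offset: control draw must be within "
                            "the year before colonoscopy")
            for f in ("tnm", "t_stage", "n_stage", "m_stage", "location",
                      "symptom", "differentiation"):
                if getattr(self, f) is not None:
                    errs.append(f"control_tumor_var: controls carry no {f}")
            if self.panel_pre is not None:
                errs.append("control_panel_pre: controls have a single panel")
        if self.panel_pre is not None and not (
                -12 <= self.panel_pre.draw_offset_months <= -3):
            errs.append("panel_pre_offset: pre-diagnosis draw must be 3-12 "
                        "months before diagnosis")
        if self.tnm is not None and self.tnm not in TNM_STAGES:
            errs.append(f"tnm: unknown stage {self.tnm!r}")
        if self.location is not None and self.location not in LOCATIONS:
            errs.append(f"location: unknown location {self.location!r}")
        if self.symptom is not None and self.symptom not in SYMPTOMS:
            errs.append(f"symptom: unknown symptom {self.symptom!r}")
        if (self.differentiation is not None
                and self.differentiation not in DIFFERENTIATIONS):
            errs.append(f"differentiation: unknown grade {self.differentiation!r}")
        return errs


@dataclass
class Cohort:
    """A collection of subjects plus optional 1:1 case-control pairs."""

    subjects: list[Subject] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    age_window: int = AGE_WINDOW

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dup}")
        by_id = {s.id: s for s in self.subjects}
        for case_id, ctrl_id in self.pairs:
            a, b = by_id.get(case_id), by_id.get(ctrl_id)
            if a is None or b is None:
                raise CohortValidationError(
                    f"pair ({case_id}, {ctrl_id}) references unknown subject")
            if a.sex != b.sex:
                raise CohortValidationError(
                    f"pair ({case_id}, {ctrl_id}) crosses sex")
            if abs(a.age - b.age) > self.age_window:
                raise CohortValidationError(
                    f"pair ({case_id}, {ctrl_id}) exceeds the "
                    f"+/-{self.age_window}-year age window")

    @property
    def cases(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "case"]

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "control"]

    def subject(self, id: str) -> Subject:
        for s in self.subjects:
            if s.id == id:
                return s
        raise KeyError(id)

    def __len__(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class RowError:
    row: int          # 0-based data-row index in the CSV
    id: str
    rule: str


@dataclass
class MatchResult:
    cohort: Cohort
    unmatched_cases: list[str]
    unused_controls: list[str]


def _panel_to_row(panel: CBCPanel | None, suffix: str) -> dict:
    if panel is None:
        return {f"{k}_{suffix}": None
                for k in ("neut", "lymph", "plt", "hb", "offset")}
    return {
        f"neut_{suffix}": panel.neutrophils,
        f"lymph_{suffix}": panel.lymphocytes,
        f"plt_{suffix}": panel.platelets,
        f"hb_{suffix}": panel.hemoglobin,
        f"offset_{suffix}": panel.draw_offset_months,
    }


def _row_panel(row: pd.Series, suffix: str) -> CBCPanel | None:
    vals = [row.get(f"{k}_{suffix}") for k in ("neut", "lymph", "plt", "hb")]
    if all(pd.isna(v) for v in vals):
        return None
    if any(pd.isna(v) for v in vals):
        raise PanelValidationError(
            f"panel_{suffix}: partially missing analytes")
    off = row.get(f"offset_{suffix}")
    return CBCPanel(float(vals[0]), float(vals[1]), float(vals[2]),
                    float(vals[3]),
                    0.0 if pd.isna(off) else float(off))


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Tabular view of a cohort, one row per subject (the CSV layout)."""
    ctrl_of = dict(cohort.pairs)
    rows = []
    for s in cohort.subjects:
        row = {
            "id": s.id, "group": s.group, "sex": s.sex, "age": s.age,
            **_panel_to_row(s.panel_dx, "dx"),
            **_panel_to_row(s.panel_pre, "pre"),
            "tnm": s.tnm, "t_stage": s.t_stage, "n_stage": s.n_stage,
            "m_stage": s.m_stage, "location": s.location,
            "symptom": s.symptom, "differentiation": s.differentiation,
            "matched_control_id": ctrl_of.get(s.id),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write the cohort as UTF-8 comma-separated text; absent fields are
    empty cells, never sentinel numbers."""
    df = cohort_to_frame(cohort)
    df.to_csv(path, index=False, na_rep="", lineterminator="\n")


def read_cohort_csv(path) -> tuple[Cohort, list[RowError]]:
    """Read and validate a cohort CSV.

    Returns the cohort of valid rows together with a report of rejected rows
    (each with the named rule it violated). File-level problems — missing
    mandatory columns, duplicated ids — raise :class:`CohortValidationError`.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str, "matched_control_id": str},
                         float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise CohortValidationError(f"unreadable cohort CSV {path}: {e}") from e
    mandatory = {"id", "group", "sex", "age"}
    missing = mandatory - set(df.columns)
    if missing:
        raise CohortValidationError(f"missing mandatory columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise CohortValidationError(f"duplicate subject ids: {dup}")

    subjects, errors = [], []
    pair_col = {}
    for i, row in df.iterrows():
        sid = str(row["id"])
        try:
            subj = Subject(
                id=sid,
                group=str(row["group"]),
                sex=str(row["sex"]),
                age=int(row["age"]),
                panel_dx=_row_panel(row, "dx"),
                panel_pre=_row_panel(row, "pre"),
                tnm=None if pd.isna(row.get("tnm")) else str(row["tnm"]),
                t_stage=None if pd.isna(row.get("t_stage")) else int(row["t_stage"]),
                n_stage=None if pd.isna(row.get("n_stage")) else int(row["n_stage"]),
                m_stage=None if pd.isna(row.get("m_stage")) else int(row["m_stage"]),
                location=None if pd.isna(row.get("location")) else str(row["location"]),
                symptom=None if pd.isna(row.get("symptom")) else str(row["symptom"]),
                differentiation=(None if pd.isna(row.get("differentiation"))
                                 else str(row["differentiation"])),
            )
        except (PanelValidationError, ValueError) as e:
            errors.append(RowError(int(i), sid, str(e)))
            continue
        errs = subj.validation_errors()
        if errs:
            errors.extend(RowError(int(i), sid, rule) for rule in errs)
            continue
        subjects.append(subj)
        mc = row.get("matched_control_id")
        if mc is not None and not pd.isna(mc):
            pair_col[sid] = str(mc)

    kept = {s.id for s in subjects}
    pairs = [(c, k) for c, k in pair_col.items() if c in kept and k in kept]
    return Cohort(subjects=subjects, pairs=pairs), errors


def match_controls(cases: Sequence[Subject], pool: Sequence[Subject],
                   age_window: int = AGE_WINDOW) -> MatchResult:
    """1:1 nearest-age same-sex matching without replacement.

    Two deterministic phases, no RNG:

    1. *Greedy*: candidate pairs within the age window are sorted by
       (|age difference|, case id, control id) and accepted whenever both
       ends are still unused.
    2. *Repair*: any case left unmatched is placed, if possible, via an
       augmenting path through the feasibility graph (Kuhn's algorithm with
       neighbours visited nearest-age-first). This guarantees the maximum
       attainable number of pairs — plain greedy can strand a matchable case
       when two cases compete for the same control — while keeping greedy's
       nearest-age preference for the pairs it already made.

    Cases that remain unmatched are reported, never silently dropped.
    """
    for s in cases:
        if s.group != "case":
            raise CohortValidationError(f"{s.id} in cases is not a case")
    for s in pool:
        if s.group != "control":
            raise CohortValidationError(f"{s.id} in pool is not a control")

    candidates = sorted(
        (abs(c.age - k.age), c.id, k.id)
        for c in cases for k in pool
        if c.sex == k.sex and abs(c.age - k.age) <= age_window
    )
    used_case: set[str] = set()
    used_ctrl: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for _, cid, kid in candidates:
        if cid in used_case or kid in used_ctrl:
            continue
        pairs.append((cid, kid))
        used_case.add(cid)
        used_ctrl.add(kid)

    # augmenting-path repair: maximum-cardinality completion of the greedy
    # matching (Kuhn's algorithm, nearest-age-first neighbour order)
    neighbours: dict[str, list[str]] = {}
    for d, cid, kid in candidates:
        neighbours.setdefault(cid, []).append(kid)   # already sorted by (d, kid)
    ctrl_of = {c: k for c, k in pairs}
    case_of = {k: c for c, k in pairs}

    def try_augment(cid: str, visited: set[str]) -> bool:
        for kid in neighbours.get(cid, []):
            if kid in visited:
                continue
            visited.add(kid)
            if kid not in case_of or try_augment(case_of[kid], visited):
                ctrl_of[cid] = kid
                case_of[kid] = cid
                return True
        return False

    for cid in sorted(s.id for s in cases if s.id not in used_case):
        try_augment(cid, set())
    pairs = sorted(ctrl_of.items())
    used_case = set(ctrl_of)

    matched_ctrl = {k for _, k in pairs}
    cohort = Cohort(
        subjects=list(cases) + [s for s in pool if s.id in matched_ctrl],
        pairs=pairs,
        age_window=age_window,
    )
    return MatchResult(
        cohort=cohort,
        unmatched_cases=sorted(s.id for s in cases if s.id not in used_case),
        unused_controls=sorted(s.id for s in pool if s.id not in matched_ctrl),
    )
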