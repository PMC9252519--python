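"""End-to-end analysis pipeline: cohort -> indices -> comparisons -> ROC ->
diagnostics, written atomically as a reproducible report bundle.

The bundle layout mirrors the analysis stages::

    outdir/
      cohort.csv          simulated cohort (only when simulating)
      markers.csv         per-subject indices at diagnosis
      longitudinal.json   control vs pre-diagnosis vs at-diagnosis comparisons
      associations/       per-marker, per-stratifier median/IQR tables
      roc/<marker>.csv    operating points (cutoff, se, sp)
      roc/auc.json        AUC + DeLong CI per marker, pairwise DeLong tests
      diagnostics.csv     per-marker cutoff, TP/FP/FN/TN, Se/Sp/PPV/NPV, OR (CI)
      cascade.csv         positive-marker-count odds-ratio cascade
      run.log             config echo and stage trace (no timestamps)
      manifest.json       version, seed, input checksum

Outputs are written to a temporary sibling directory and renamed into place
on success, so a failed run never leaves a half-written bundle. Identical
config + seed reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import math
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort_csv, write_cohort_csv
from .diagnostics import classify, marker_count_or_cascade, summarize
from .indices import MARKER_NAMES
from .roc import auc, delong_paired_test, empirical_roc, youden_cutoff
from .simulate import GeneratorConfig, generate_cohort
from .stats import (association_table, mann_whitney_test, marker_frame,
                    wilcoxon_signed_rank_test)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "format_p"]

ASSOCIATION_STRATIFIERS = ("tnm", "location", "t_stage", "n_stage",
                           "m_stage", "differentiation", "symptom")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    outdir: str | Path
    input: str | Path | None = None
    simulate: GeneratorConfig | None = None
    markers: tuple[str, ...] = MARKER_NAMES
    cutoffs: dict | None = None       # None => Youden-derived from the cohort
    alpha: float = 0.05
    seed: int = 0
    cascade_reference: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of input/simulate must be given")
        unknown = set(self.markers) - set(MARKER_NAMES)
        if unknown:
            raise ValueError(f"unknown markers: {sorted(unknown)}")
        if self.cutoffs is not None:
            missing = set(self.markers) - set(self.cutoffs)
            if missing:
                raise ValueError(f"fixed cutoffs missing for {sorted(missing)}")


def format_p(p: float) -> str:
    """Human-readable p-value; never prints 0 (floors at '< 0.001')."""
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3f}"


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals for report tables."""
    return math.floor(x * 100 + 0.5) / 100


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the path of the completed bundle."""
    outdir = Path(config.outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=f".{outdir.name}.tmp-",
                                dir=outdir.parent))
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        # --- stage: cohort ------------------------------------------------
        try:
            if config.simulate is not None:
                gen = GeneratorConfig.from_dict(
                    {**config.simulate.to_dict(), "seed": config.seed})
                cohort = generate_cohort(gen)
                write_cohort_csv(cohort, tmp / "cohort.csv")
                log(f"cohort: simulated {len(cohort.cases)} cases / "
                    f"{len(cohort.controls)} controls (seed {config.seed})")
                input_checksum = _sha256(tmp / "cohort.csv")
            else:
                cohort, rejected = read_cohort_csv(config.input)
                if rejected:
                    log(f"cohort: rejected {len(rejected)} rows "
                        f"({[e.rule for e in rejected[:5]]}...)")
                log(f"cohort: read {len(cohort.cases)} cases / "
                    f"{len(cohort.controls)} controls from {config.input}")
                input_checksum = _sha256(Path(config.input))
        except Exception as e:
            raise PipelineError(f"stage cohort failed: {e}") from e

        markers = list(config.markers)

        # --- stage: indices ----------------------------------------------
        try:
            dx = marker_frame(cohort, "dx")
            pre = marker_frame(cohort, "pre")
            dx.to_csv(tmp / "markers.csv", index=False, lineterminator="\n")
            log(f"indices: {int(dx[list(markers)].notna().all(axis=1).sum())} "
                "subjects with complete at-diagnosis markers")
        except Exception as e:
            raise PipelineError(f"stage indices failed: {e}") from e

        case_dx = dx[dx.group == "case"]
        ctrl_dx = dx[dx.group == "control"]

        # --- stage: longitudinal -----------------------------------------
        try:
            longi = {}
            paired = dx.merge(pre[["id", *markers]], on="id",
                              suffixes=("", "_pre"))
            paired = paired[paired.group == "case"]
            for m in markers:
                cc = case_dx[m].dropna().to_numpy()
                kk = ctrl_dx[m].dropna().to_numpy()
                pp = paired[[m + "_pre", m]].dropna()
                mw_dx = mann_whitney_test(cc, kk)
                mw_pre = mann_whitney_test(pp[m + "_pre"].to_numpy(), kk) \
                    if len(pp) else None
                wil = wilcoxon_signed_rank_test(
                    pp[m + "_pre"].to_numpy(), pp[m].to_numpy()) \
                    if len(pp) else None
                longi[m] = {
                    "median_control": float(np.median(kk)),
                    "median_pre_dx": (float(pp[m + "_pre"].median())
                                      if len(pp) else None),
                    "median_dx": float(np.median(cc)),
                    "p_dx_vs_control": mw_dx.p_value,
                    "p_pre_vs_control": (mw_pre.p_value if mw_pre else None),
                    "p_dx_vs_pre": (wil.p_value if wil else None),
                    "n_paired": int(len(pp)),
                }
            (tmp / "longitudinal.json").write_text(
                json.dumps(longi, indent=2, sort_keys=True) + "\n")
            log("longitudinal: control vs pre-dx vs dx comparisons written")
        except Exception as e:
            raise PipelineError(f"stage longitudinal failed: {e}") from e

        # --- stage: associations -----------------------------------------
        try:
            adir = tmp / "associations"
            adir.mkdir()
            for strat in ASSOCIATION_STRATIFIERS:
                for m in markers:
                    try:
                        table, test = association_table(cohort, m, strat)
                    except ValueError:
                        continue   # stratifier absent or single stratum
                    table["marker"] = m
                    table["p_value"] = test.p_value
                    table["method"] = test.method
                    table.to_csv(adir / f"{strat}_{m}.csv", index=False,
                                 lineterminator="\n")
            log("associations: per-stratifier tables written")
        except Exception as e:
            raise PipelineError(f"stage associations failed: {e}") from e

        # --- stage: roc ---------------------------------------------------
        try:
            rdir = tmp / "roc"
            rdir.mkdir()
            scores = {m: (case_dx[m].dropna().to_numpy(),
                          ctrl_dx[m].dropna().to_numpy()) for m in markers}
            auc_block = {}
            for m in markers:
                cs, ks = scores[m]
                curve = empirical_roc(cs, ks)
                pd.DataFrame({
                    "cutoff": curve.cutoffs,
                    "se": curve.sensitivities,
                    "sp": curve.specificities,
                }).to_csv(rdir / f"{m}.csv", index=False, lineterminator="\n")
                r = auc(cs, ks)
                auc_block[m] = {"auc": r.auc, "se": r.se,
                                "ci95": list(r.ci95) if r.ci95 else None}
            pairwise = {}
            complete = dx[dx[list(markers)].notna().all(axis=1)]
            ccm = complete[complete.group == "case"]
            kkm = complete[complete.group == "control"]
            for i, a_ in enumerate(markers):
                for b_ in markers[i + 1:]:
                    t = delong_paired_test(
                        ccm[a_].to_numpy(), kkm[a_].to_numpy(),
                        ccm[b_].to_numpy(), kkm[b_].to_numpy())
                    pairwise[f"{a_}_vs_{b_}"] = {"z": t.statistic,
                                                 "p": t.p_value}
            (rdir / "auc.json").write_text(json.dumps(
                {"auc": auc_block, "delong_pairwise": pairwise},
                indent=2, sort_keys=True) + "\n")
            log("roc: curves and DeLong AUC inference written")
        except Exception as e:
            raise PipelineError(f"stage roc failed: {e}") from e

        # --- stage: diagnostics ------------------------------------------
        try:
            cutoffs = dict(config.cutoffs) if config.cutoffs else {
                m: youden_cutoff(*scores[m])[0] for m in markers}
            rows = []
            for m in markers:
                cs, ks = scores[m]
                tab = classify(cs, ks, cutoffs[m])
                s = summarize(tab)
                rows.append({
                    "marker": m, "cutoff": cutoffs[m],
                    "tp": tab.tp, "fp": tab.fp, "fn": tab.fn, "tn": tab.tn,
                    "se_pct": _round2(100 * s.se),
                    "sp_pct": _round2(100 * s.sp),
                    "ppv_pct": _round2(100 * s.ppv),
                    "npv_pct": _round2(100 * s.npv),
                    "odds_ratio": _round2(s.odds_ratio),
                    "or_ci_low": _round2(s.or_ci95[0]),
                    "or_ci_high": _round2(s.or_ci95[1]),
                    "corrected": s.corrected,
                })
            pd.DataFrame(rows).to_csv(tmp / "diagnostics.csv", index=False,
                                      lineterminator="\n")
            log(f"diagnostics: cutoff mode "
                f"{'fixed' if config.cutoffs else 'youden-auto'}")
        except Exception as e:
            raise PipelineError(f"stage diagnostics failed: {e}") from e

        # --- stage: cascade ----------------------------------------------
        try:
            if set(MARKER_NAMES) <= set(cutoffs):
                casc = marker_count_or_cascade(
                    cohort, cutoffs, reference=config.cascade_reference)
                casc.to_csv(tmp / "cascade.csv", index=False,
                            lineterminator="\n")
                log(f"cascade: reference count {config.cascade_reference}, "
                    f"{casc.attrs['n_excluded']} subjects excluded")
            else:
                log("cascade: skipped (needs cutoffs for all four markers)")
        except Exception as e:
            raise PipelineError(f"stage cascade failed: {e}") from e

        # --- manifest & log ----------------------------------------------
        manifest = {
            "inflamark_version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "markers": markers,
            "cutoffs": {m: float(c) for m, c in cutoffs.items()},
            "input_sha256": input_checksum,
            "simulated": config.simulate is not None,
        }
        (tmp / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        cfg_echo = {"seed": config.seed,
                    "alpha": config.alpha, "markers": markers}
        if config.simulate is not None:
            cfg_echo["simulate"] = config.simulate.to_dict()
        else:
            cfg_echo["input"] = str(config.input)
        (tmp / "run.log").write_text(
            "config: " + json.dumps(cfg_echo, sort_keys=True) + "\n"
            + "\n".join(log_lines) + "\n")

        if outdir.exists():
            shutil.rmtree(outdir)
        tmp.replace(outdir)
        return outdir
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
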