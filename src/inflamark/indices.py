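"""Blood-cell-based inflammatory indices derived from a complete blood count.

Four composite indices are computed from one CBC panel:

* NLR    = N / L                 (neutrophil-to-lymphocyte ratio)
* PLR    = P / L                 (platelet-to-lymphocyte ratio)
* SII    = (P * N) / L           (systemic immune-inflammation index)
* NP/LHb = (N * P) / (L * Hb)    (SII normalised by hemoglobin concentration)

Units are fixed: absolute cell counts in 10^9 cells/L and hemoglobin in g/dL.
This makes index values directly comparable to the conventional positivity
cutoffs (NLR 2.28, PLR 122.40, SII 616.50, NP/LHb 43.90). No unit conversion
is attempted; a hemoglobin value outside a physiologic sanity window
(3-25 g/dL) is rejected as a probable unit error (e.g. g/L input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PanelValidationError",
    "CBCPanel",
    "MarkerValues",
    "MARKER_NAMES",
    "compute_nlr",
    "compute_plr",
    "compute_sii",
    "compute_np_lhb",
    "compute_all",
    "add_marker_columns",
]

#: Canonical marker order used throughout the package.
MARKER_NAMES = ("nlr", "plr", "sii", "np_lhb")

HB_WINDOW = (3.0, 25.0)


class PanelValidationError(ValueError):
    """A CBC panel violates a physiologic or positivity constraint."""


@dataclass(frozen=True)
class CBCPanel:
    """One blood draw's absolute counts (10^9/L) and hemoglobin (g/dL).

    ``draw_offset_months`` is signed months relative to the index event
    (diagnosis for cases, screening colonoscopy for controls): 0 means at
    diagnosis, negative means before.
    """

    neutrophils: float
    lymphocytes: float
    platelets: float
    hemoglobin: float
    draw_offset_months: float = 0.0

    def __post_init__(self) -> None:
        for name in ("neutrophils", "lymphocytes", "platelets", "hemoglobin"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise PanelValidationError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )
        lo, hi = HB_WINDOW
        if not (lo <= self.hemoglobin <= hi):
            raise PanelValidationError(
                f"hemoglobin {self.hemoglobin} g/dL outside sanity window "
                f"[{lo}, {hi}] — check units (expected g/dL, not g/L)"
            )
        if not math.isfinite(self.draw_offset_months):
            raise PanelValidationError("draw_offset_months must be finite")


@dataclass(frozen=True)
class MarkerValues:
    """The four derived indices for one panel (unitless ratios; SII and
    NP/LHb carry the platelet count's 10^9/L scale)."""

    nlr: float
    plr: float
    sii: float
    np_lhb: float

    def __getitem__(self, marker: str) -> float:
        if marker not in MARKER_NAMES:
            raise KeyError(marker)
        return getattr(self, marker)


def compute_nlr(panel: CBCPanel) -> float:
    """Neutrophil-to-lymphocyte ratio N/L."""
    return panel.neutrophils / panel.lymphocytes


def compute_plr(panel: CBCPanel) -> float:
    """Platelet-to-lymphocyte ratio P/L."""
    return panel.platelets / panel.lymphocytes


def compute_sii(panel: CBCPanel) -> float:
    """Systemic immune-inflammation index (P*N)/L."""
    return panel.platelets * panel.neutrophils / panel.lymphocytes


def compute_np_lhb(panel: CBCPanel) -> float:
    """Hemoglobin-adjusted index (N*P)/(L*Hb), Hb in g/dL."""
    return (panel.neutrophils * panel.platelets) / (
        panel.lymphocytes * panel.hemoglobin
    )


def compute_all(panel: CBCPanel) -> MarkerValues:
    """All four indices from one panel; fields equal the single-index ops."""
    return MarkerValues(
        nlr=compute_nlr(panel),
        plr=compute_plr(panel),
        sii=compute_sii(panel),
        np_lhb=compute_np_lhb(panel),
    )


def add_marker_columns(df, neut="neut", lymph="lymph", plt="plt", hb="hb",
                       suffix=""):
    """Append nlr/plr/sii/np_lhb columns to a DataFrame of panel columns.

    Vectorised counterpart of :func:`compute_all` for tabular pipelines.
    Rows with any missing analyte get missing marker values (propagated,
    never imputed). Non-positive analytes raise.
    """
    import numpy as np

    n, ell, p, h = (df[c].astype(float) for c in (neut, lymph, plt, hb))
    present = ~(n.isna() | ell.isna() | p.isna() | h.isna())
    if ((n[present] <= 0) | (ell[present] <= 0) | (p[present] <= 0)
            | (h[present] <= 0)).any():
        raise PanelValidationError("non-positive analyte in input table")
    out = df.copy()
    out["nlr" + suffix] = np.where(present, n / ell, np.nan)
    out["plr" + suffix] = np.where(present, p / ell, np.nan)
    out["sii" + suffix] = np.where(present, p * n / ell, np.nan)
    out["np_lhb" + suffix] = np.where(present, p * n / (ell * h), np.nan)
    return out
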