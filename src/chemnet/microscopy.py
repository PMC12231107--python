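"""Protein abundance and localization scoring from per-cell tables.

Each cell carries a GFP intensity (the tagged protein), an RFP
intensity (a constitutive reference channel) and a compartment label.
Abundance is summarised per strain as the median per-cell GFP/RFP
ratio — the median resists the bright-aggregate outliers common in
high-content imaging — and a strain is flagged when the treated median
changes by more than ``cutoff`` percent versus control.  Localization
is summarised as compartment fraction vectors; a shift is called when
the modal compartment changes and the new modal compartment gains at
least ``min_shift`` percentage points of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import COMPARTMENTS

__all__ = ["AbundanceCall", "LocalizationCall", "abundance_change",
           "localization_call", "score_microscopy", "InsufficientCellsError"]


class InsufficientCellsError(ValueError):
    """Raised when a condition has fewer cells than the calling floor."""


@dataclass(frozen=True)
class AbundanceCall:
    strain: str
    pct_change: float
    flagged: bool
    n_control: int
    n_treated: int


@dataclass(frozen=True)
class LocalizationCall:
    strain: str
    from_compartment: str
    to_compartment: str
    shifted: bool
    control_fractions: dict
    treated_fractions: dict


def _check_cells(df: pd.DataFrame, label: str, min_cells: int) -> None:
    if len(df) < min_cells:
        raise InsufficientCellsError(
            f"{label}: {len(df)} cells < required {min_cells}")
    if (df["gfp"] <= 0).any() or (df["rfp"] <= 0).any():
        raise ValueError(f"{label}: intensities must be positive")


def abundance_change(control: pd.DataFrame, treated: pd.DataFrame, *,
                     cutoff: float = 20.0, min_cells: int = 50,
                     strain: str = "") -> AbundanceCall:
    """Percent change of the median per-cell GFP/RFP ratio, treated vs control."""
    _check_cells(control, f"{strain or 'control'} (control)", min_cells)
    _check_cells(treated, f"{strain or 'treated'} (treated)", min_cells)
    med_c = float(np.median(control["gfp"] / control["rfp"]))
    med_t = float(np.median(treated["gfp"] / treated["rfp"]))
    pct = (med_t / med_c - 1.0) * 100.0
    return AbundanceCall(
        strain=strain, pct_change=float(pct),
        flagged=bool(abs(pct) > cutoff),
        n_control=len(control), n_treated=len(treated),
    )


def compartment_fractions(cells: pd.DataFrame) -> dict[str, float]:
    """Fraction of cells per compartment (keys cover the full vocabulary)."""
    labels = cells["compartment"]
    unknown = set(labels) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartment labels: {sorted(unknown)}")
    counts = labels.value_counts()
    n = len(cells)
    return {c: float(counts.get(c, 0)) / n for c in COMPARTMENTS}


def localization_call(control: pd.DataFrame, treated: pd.DataFrame, *,
                      min_shift: float = 20.0, min_cells: int = 50,
                      strain: str = "") -> LocalizationCall:
    """Modal-compartment localization shift between conditions.

    shifted is True when the treated modal compartment differs from the
    control modal compartment AND its treated fraction exceeds its
    control fraction by at least ``min_shift`` percentage points.
    """
    _check_cells(control, f"{strain or 'control'} (control)", min_cells)
    _check_cells(treated, f"{strain or 'treated'} (treated)", min_cells)
    fc = compartment_fractions(control)
    ft = compartment_fractions(treated)
    modal_c = max(fc, key=lambda c: (fc[c], c))
    modal_t = max(ft, key=lambda c: (ft[c], c))
    shifted = (modal_t != modal_c
               and (ft[modal_t] - fc[modal_t]) * 100.0 >= min_shift)
    return LocalizationCall(
        strain=strain, from_compartment=modal_c, to_compartment=modal_t,
        shifted=bool(shifted), control_fractions=fc, treated_fractions=ft,
    )


def score_microscopy(cells: pd.DataFrame, *, cutoff: float = 20.0,
                     min_cells: int = 50, min_shift: float = 20.0,
                     control_condition: str = "control",
                     treated_condition: str = "treated") -> pd.DataFrame:
    """Score every strain in a per-cell table for abundance and localization.

    Strains with too few cells in either condition are reported with
    call ``insufficient_cells`` instead of raising.  Returns a table
    strain / pct_change / flagged / from_loc / to_loc / shifted.
    """
    rows = []
    for strain, g in cells.groupby("strain", sort=True):
        ctrl = g[g["condition"] == control_condition]
        treat = g[g["condition"] == treated_condition]
        try:
            ab = abundance_change(ctrl, treat, cutoff=cutoff,
                                  min_cells=min_cells, strain=strain)
            loc = localization_call(ctrl, treat, min_shift=min_shift,
                                    min_cells=min_cells, strain=strain)
        except InsufficientCellsError:
            rows.append((strain, np.nan, False, "", "", False, "insufficient_cells"))
            continue
        rows.append((strain, ab.pct_change, ab.flagged, loc.from_compartment,
                     loc.to_compartment, loc.shifted, "ok"))
    return pd.DataFrame(rows, columns=["strain", "pct_change", "flagged",
                                       "from_loc", "to_loc", "shifted", "status"])
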