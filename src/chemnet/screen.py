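"""Plate normalization and two-stage hit calling for deletion-library screens.

Covers the two screen designs of a chemical-genetic study in yeast:

* an SGA epistasis screen crossing a query deletion (e.g. the drug
  target's gene) into the deletion library, scored against the
  multiplicative expectation of the single mutants and anchored to a
  phenotypically neutral reference double mutant, and
* a chemical-genomic screen of the deletion library grown with drug vs
  vehicle, scored as percent residual growth.

Hit calling is two-stage: a permissive screen stage requiring an effect
plus p < alpha in at least ``min_screens`` of ``n_screens`` independent
screens, then a validation stage on replicate liquid growth with
tighter effect thresholds (defaults: sensitive < 75%, resistant > 130%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import GrowthRecord, mid_log_index, percent_growth

__all__ = [
    "EpistasisInputs", "normalize_plate", "epistasis_score",
    "chemgen_score", "call_hits",
]

SCREEN_THRESHOLDS = (40.0, 140.0)
VALIDATION_THRESHOLDS = (75.0, 130.0)


# ---------------------------------------------------------------------------
# Plate normalization
# ---------------------------------------------------------------------------

def normalize_plate(sizes: np.ndarray) -> np.ndarray:
    """Normalize a colony-size plate grid for spatial artefacts.

    Sizes are divided by the plate median; row and column effects are
    then estimated from interior (non-border) positions only, by
    alternating median division until convergence, and divided out of
    the full rows and columns.  Border positions — which never enter a
    median estimate — are finally rescaled by the border/interior
    median ratio, correcting the nutrient-surplus edge effect of pinned
    arrays.  Missing colonies are NaN and stay NaN.  The interior
    median of the output is 1, and the transform is idempotent (a
    normalized plate is a fixed point).
    """
    x = np.asarray(sizes, dtype=float)
    if x.ndim != 2 or min(x.shape) < 3:
        raise ValueError("plate grid must be 2-D with at least 3 rows and columns")
    n_valid = np.isfinite(x).sum()
    if n_valid == 0:
        raise ValueError("all-missing plate")
    if n_valid < 0.5 * x.size:
        raise ValueError("more than half of plate positions are missing")
    if np.nanmin(x) < 0:
        raise ValueError("colony sizes must be >= 0")

    x = x / np.nanmedian(x)
    interior = np.zeros(x.shape, dtype=bool)
    interior[1:-1, 1:-1] = True

    # Row/column effects from interior cells only; border rows and
    # columns carry no own-median effect, so the border rescale below
    # cannot feed back into the polish.
    n_rows, n_cols = x.shape
    for _ in range(200):
        row_med = np.ones(n_rows)
        row_med[1:-1] = [_nanmedian_or_one(x[r, 1:-1]) for r in range(1, n_rows - 1)]
        x = x / row_med[:, None]
        col_med = np.ones(n_cols)
        col_med[1:-1] = [_nanmedian_or_one(x[1:-1, c]) for c in range(1, n_cols - 1)]
        x = x / col_med[None, :]
        if max(np.abs(row_med - 1).max(), np.abs(col_med - 1).max()) < 1e-13:
            break

    ratio = _nanmedian_or_one(x[~interior]) / _nanmedian_or_one(x[interior])
    x[~interior] = x[~interior] / ratio

    # Anchor the interior median at exactly 1 (row/column passes leave a
    # residual scale on non-square plates).
    x = x / _nanmedian_or_one(x[interior])
    return x


def _nanmedian_or_one(values: np.ndarray) -> float:
    m = np.nanmedian(values) if np.isfinite(values).any() else 1.0
    return m if np.isfinite(m) and m > 0 else 1.0


# ---------------------------------------------------------------------------
# Epistasis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpistasisInputs:
    """Growth measurements entering the SGA epistasis ratio.

    g_double: query×array double mutant; g_query: query single mutant;
    g_array: array single mutant; g_wt: wild type; g_ref: the observed
    growth of the neutral reference double mutant (the his3Δ analogue of
    the query cross), whose own score is forced to 100.
    """

    g_double: float
    g_query: float
    g_array: float
    g_wt: float

    def __post_init__(self) -> None:
        if self.g_double < 0:
            raise ValueError("double-mutant growth must be >= 0")
        for name in ("g_query", "g_array", "g_wt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 for a defined score")


def _raw_epistasis(e: EpistasisInputs) -> float:
    return (e.g_double / e.g_query) / (e.g_array / e.g_wt) * 100.0


def epistasis_score(e: EpistasisInputs,
                    reference: EpistasisInputs | None = None) -> float:
    """SGA epistasis score: ((double/query) / (array/wt)) × 100.

    100 means the double mutant matches the multiplicative expectation
    of the two single mutants; lower values indicate an aggravating
    (synthetic-sick) interaction.  When ``reference`` is given, scores
    are rescaled so the reference double (a neutral control cross)
    scores exactly 100.
    """
    score = _raw_epistasis(e)
    if reference is not None:
        ref_score = _raw_epistasis(reference)
        if ref_score <= 0:
            raise ValueError("reference double's raw score must be > 0")
        score *= 100.0 / ref_score
    return float(score)


# ---------------------------------------------------------------------------
# Chemical-genomic scoring
# ---------------------------------------------------------------------------

def chemgen_score(records: list[GrowthRecord],
                  treated_condition: str = "treated",
                  vehicle_condition: str = "vehicle",
                  window: tuple[float, float] = (0.3, 0.5),
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Per-strain percent growth under drug relative to vehicle.

    For each strain the vehicle replicate curves are averaged, the
    mid-log time point located on that mean control curve, and percent
    growth computed from replicate ODs at that time point.  Strains
    present in only one condition are reported unscored rather than
    silently dropped.

    Returns (scores table with columns strain/score/n_treated/n_vehicle,
    list of unscored strain ids).
    """
    by_strain: dict[str, dict[str, list[GrowthRecord]]] = {}
    for rec in records:
        by_strain.setdefault(rec.strain, {}).setdefault(rec.condition, []).append(rec)

    rows = []
    unscored: list[str] = []
    for strain in sorted(by_strain):
        conds = by_strain[strain]
        if treated_condition not in conds or vehicle_condition not in conds:
            unscored.append(strain)
            continue
        vehicle = sorted(conds[vehicle_condition], key=lambda r: r.replicate)
        treated = sorted(conds[treated_condition], key=lambda r: r.replicate)
        times = vehicle[0].times
        mean_control = GrowthRecord(
            strain, vehicle_condition, 0, times,
            tuple(np.mean([r.od600 for r in vehicle], axis=0)))
        idx = mid_log_index(mean_control, window)
        t_od = np.array([r.od600[idx] for r in treated])
        v_od = np.array([r.od600[idx] for r in vehicle])
        score = percent_growth(t_od, v_od)
        rows.append((strain, score, len(treated), len(vehicle)))
    table = pd.DataFrame(rows, columns=["strain", "score", "n_treated", "n_vehicle"])
    return table, unscored


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------

def _one_sample_p(scores: np.ndarray, null_value: float = 100.0) -> float:
    """Two-tailed one-sample t p-value against the neutral score."""
    if scores.size < 2 or np.std(scores, ddof=1) == 0:
        return np.nan
    t, p = stats.ttest_1samp(scores, null_value)
    return float(p)


def call_hits(scores: pd.DataFrame, *, stage: str = "validation",
              thresholds: tuple[float, float] | None = None,
              alpha: float = 0.05, min_screens: int = 2,
              use_effect_thresholds: bool = True,
              vehicle_scores: pd.DataFrame | None = None,
              inviable_floor: float = 10.0,
              bh_correct: bool = False) -> pd.DataFrame:
    """Call sensitive/resistant strains from per-screen percent-growth scores.

    ``scores`` has columns strain, screen, replicate, score (screen may
    be constant at validation stage).  Screen stage: a strain is a
    putative hit when its per-screen mean crosses the effect threshold
    with p < alpha (one-sample t vs 100 across replicates) in at least
    ``min_screens`` screens, all in the same direction.  Validation
    stage: replicates are pooled per strain and the call made once.

    ``use_effect_thresholds=False`` calls on significance alone (used
    for null calibration).  Strains whose vehicle-condition growth is
    below ``inviable_floor`` percent (when ``vehicle_scores`` is given)
    are reported as inviable and excluded from sensitive/resistant calls.

    Returns a table strain / mean_score / p / call / screens_supporting,
    sorted by strain id.
    """
    required = {"strain", "screen", "replicate", "score"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    if stage not in ("screen", "validation"):
        raise ValueError(f"unknown stage {stage!r}")
    if thresholds is None:
        thresholds = SCREEN_THRESHOLDS if stage == "screen" else VALIDATION_THRESHOLDS
    lower, upper = thresholds
    if lower >= upper:
        raise ValueError("lower threshold must be below upper threshold")

    inviable: set[str] = set()
    if vehicle_scores is not None:
        veh_mean = vehicle_scores.groupby("strain")["score"].mean()
        inviable = set(veh_mean.index[veh_mean < inviable_floor])

    rows = []
    for strain, g in scores.groupby("strain", sort=True):
        if stage == "screen":
            directions = []
            pvals = []
            for _, sg in g.groupby("screen"):
                vals = sg["score"].to_numpy(dtype=float)
                mean = vals.mean()
                p = _one_sample_p(vals)
                pvals.append(p)
                sig = (not np.isnan(p)) and p < alpha
                low = mean < lower if use_effect_thresholds else True
                high = mean > upper if use_effect_thresholds else True
                if sig and low and mean < 100:
                    directions.append(-1)
                elif sig and high and mean > 100:
                    directions.append(+1)
                else:
                    directions.append(0)
            mean_all = g["score"].mean()
            p_all = min((p for p in pvals if not np.isnan(p)), default=np.nan)
            n_neg = directions.count(-1)
            n_pos = directions.count(+1)
            if strain in inviable:
                call, support = "inviable", 0
            elif n_neg >= min_screens:
                call, support = "sensitive", n_neg
            elif n_pos >= min_screens:
                call, support = "resistant", n_pos
            else:
                call, support = "none", max(n_neg, n_pos)
            rows.append((strain, mean_all, p_all, call, support))
        else:
            vals = g["score"].to_numpy(dtype=float)
            if vals.size < 2:
                raise ValueError(f"strain {strain!r}: validation stage needs >= 2 replicates")
            mean = vals.mean()
            p = _one_sample_p(vals)
            sig = (not np.isnan(p)) and p < alpha
            if strain in inviable:
                call = "inviable"
            elif sig and (mean < lower if use_effect_thresholds else mean < 100):
                call = "sensitive"
            elif sig and (mean > upper if use_effect_thresholds else mean > 100):
                call = "resistant"
            else:
                call = "none"
            rows.append((strain, mean, p, call, 1 if call in ("sensitive", "resistant") else 0))

    table = pd.DataFrame(rows, columns=["strain", "mean_score", "p", "call",
                                        "screens_supporting"])
    if bh_correct:
        from .enrichment import bh_adjust
        ok = table["p"].notna()
        adj = table["p"].copy()
        adj.loc[ok] = bh_adjust(table.loc[ok, "p"].tolist())
        table["p_adj"] = adj
        demote = ok & (table["p_adj"] >= alpha) & table["call"].isin(["sensitive", "resistant"])
        table.loc[demote, "call"] = "none"
    return table
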