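"""Growth-curve and endpoint statistics.

Implements the quantitative phenotype readouts of a humanized-yeast
drug-sensitivity study: mid-log time-point selection, percent residual
growth (treated OD600 / vehicle OD600 × 100), four-parameter log-logistic
dose-response (IC50) fitting, a Bliss-style drug-drug synergy ratio,
dye-exclusion percent viability, and sterol composition fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthRecord", "mid_log_index", "percent_growth", "fit_ic50",
    "synergy_percent", "viability_percent", "sterol_fractions", "two_sample_t",
    "MidLogNotReachedError", "NoDoseDependenceError",
]


class MidLogNotReachedError(ValueError):
    """Raised when a control curve never enters the mid-log OD window."""


class NoDoseDependenceError(ValueError):
    """Raised when responses are too flat to support a dose-response fit."""


@dataclass(frozen=True)
class GrowthRecord:
    """One strain × condition × replicate OD600 time course."""

    strain: str
    condition: str
    replicate: int
    times: tuple[float, ...]
    od600: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.size != od.size:
            raise ValueError("times and od600 must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(od)) or np.any(od < 0):
            raise ValueError("od600 values must be finite and >= 0")


def mid_log_index(control: GrowthRecord, window: tuple[float, float] = (0.3, 0.5)) -> int:
    """Earliest time index at which the control OD lies inside ``window``.

    Boundaries are inclusive.  Raises :class:`MidLogNotReachedError` if no
    time point falls in the window (the curve either never reaches it or
    jumps across it between readings).
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("mid-log window lower bound must be below upper bound")
    od = np.asarray(control.od600, dtype=float)
    in_window = np.nonzero((od >= lo) & (od <= hi))[0]
    if in_window.size == 0:
        raise MidLogNotReachedError(
            f"strain {control.strain!r}: control never at mid-log "
            f"(OD window [{lo}, {hi}])")
    return int(in_window[0])


def percent_growth(treated, control) -> float:
    """Percent residual growth: (treated OD / control OD) × 100.

    Accepts scalars or per-replicate arrays.  Equal-length arrays are
    paired by index and the per-pair percentages averaged; unequal
    lengths fall back to the mean over all treated × control pairs.
    """
    t = np.atleast_1d(np.asarray(treated, dtype=float))
    c = np.atleast_1d(np.asarray(control, dtype=float))
    if np.any(c <= 0):
        raise ValueError("control OD must be > 0")
    if t.size == c.size:
        return float(np.mean(t / c) * 100.0)
    return float(np.mean(t[:, None] / c[None, :]) * 100.0)


def _four_pl(logdose: np.ndarray, log_ic50: float, hill: float,
             top: float, bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logdose - log_ic50)))


def fit_ic50(doses, responses, *, top_cap: float = 120.0) -> dict:
    """Least-squares 4-parameter log-logistic fit of percent growth vs dose.

    Model: response = bottom + (top − bottom) / (1 + (dose/IC50)^hill),
    fitted on log10(dose).  ``bottom`` is constrained to [0, top_cap] and
    ``top`` to (0, top_cap] to stabilise small-n fits on the percent
    scale.  Replicates are passed as repeated (dose, response) pairs.

    Returns {ic50, hill, top, bottom, rss, extrapolated}.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must align")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct doses for a 4-parameter fit")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    span = responses.max() - responses.min()
    if span < 10.0:
        raise NoDoseDependenceError(
            f"response span {span:.1f} < 10 percentage points; no dose dependence")

    logd = np.log10(doses)
    # Start at the midpoint dose with a unit Hill slope in the direction
    # of the observed trend.
    slope_sign = 1.0 if responses[np.argmin(logd)] >= responses[np.argmax(logd)] else -1.0
    x0 = np.array([np.median(logd), slope_sign, min(responses.max(), top_cap),
                   max(responses.min(), 0.0)])
    lower = np.array([logd.min() - 6, -20.0, 1e-6, 0.0])
    upper = np.array([logd.max() + 6, 20.0, top_cap, top_cap])
    x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)

    def resid(p):
        return _four_pl(logd, *p) - responses

    fit = optimize.least_squares(resid, x0, bounds=(lower, upper),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not fit.success:
        raise RuntimeError(
            f"IC50 fit did not converge (best residual {np.sum(fit.fun**2):.3g})")
    log_ic50, hill, top, bottom = fit.x
    ic50 = 10.0 ** log_ic50
    return {
        "ic50": float(ic50),
        "hill": float(hill),
        "top": float(top),
        "bottom": float(bottom),
        "rss": float(np.sum(fit.fun ** 2)),
        "extrapolated": bool(ic50 < doses.min() or ic50 > doses.max()),
    }


def synergy_percent(growth_combo: float, growth_drug_b_alone: float,
                    growth_drug_a_alone: float, growth_vehicle: float) -> float:
    """Drug-combination growth relative to the multiplicative expectation.

    Returns ((combo / drug A alone) / (drug B alone / vehicle)) × 100.
    Under Bliss-style non-interaction (combo = A·B/vehicle) the value is
    100; values below 100 indicate the combination suppresses growth more
    than the product of the single-agent effects (synergy).
    """
    for name, v in (("combo", growth_combo), ("drug B alone", growth_drug_b_alone),
                    ("drug A alone", growth_drug_a_alone), ("vehicle", growth_vehicle)):
        if v < 0:
            raise ValueError(f"{name} growth must be >= 0")
    if growth_drug_a_alone == 0 or growth_drug_b_alone == 0 or growth_vehicle == 0:
        raise ZeroDivisionError("single-agent and vehicle growth must be > 0")
    return float((growth_combo / growth_drug_a_alone)
                 / (growth_drug_b_alone / growth_vehicle) * 100.0)


def viability_percent(unlabeled: int, labeled: int) -> float:
    """Percent of cells excluding the dead-cell stain.

    unlabeled / (labeled + unlabeled) × 100.
    """
    if unlabeled < 0 or labeled < 0 or int(unlabeled) != unlabeled or int(labeled) != labeled:
        raise ValueError("cell counts must be non-negative integers")
    total = unlabeled + labeled
    if total == 0:
        raise ValueError("total cell count must be > 0")
    return float(unlabeled / total * 100.0)


def sterol_fractions(squalene: float, lanosterol: float,
                     ergosterol: float) -> tuple[float, float, float]:
    """Each sterol's percent of the squalene+lanosterol+ergosterol total."""
    amounts = np.array([squalene, lanosterol, ergosterol], dtype=float)
    if np.any(amounts < 0):
        raise ValueError("sterol amounts must be >= 0")
    total = amounts.sum()
    if total <= 0:
        raise ValueError("at least one sterol amount must be > 0")
    fr = amounts / total * 100.0
    return float(fr[0]), float(fr[1]), float(fr[2])


def two_sample_t(group_a, group_b, *, welch: bool = False) -> dict:
    """Two-tailed two-sample t-test (classical equal-variance Student by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return {"t": 0.0, "p": 1.0}
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {"t": float(t), "p": float(p)}
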