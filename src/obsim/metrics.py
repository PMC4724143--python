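"""Reported statistics: population coverage, Gini inequity, reallocation
accounting and target adjustment.

Coverage is the fraction of the female population aged 15-49 whose grid
cell is within the drive-time threshold (class LE30) of the nearest
retained hospital, accumulated nationally and per municipality.  Inequity
across municipalities is summarized by the Gini coefficient of the
per-municipality coverage fractions (0 = identical access everywhere,
1 = maximal inequality).  Reallocation accounting mirrors the closure
bookkeeping: deliveries and staff in closed hospitals must be absorbed by
the retained ones, while per-hospital averages after intensification depend
only on how many hospitals remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .access import AccessClass, LE30, THRESHOLD_NEAR_MIN
from .errors import ConfigurationError, DataError, UndefinedMetricError

__all__ = [
    "CoverageResult",
    "GiniResult",
    "AbsorptionRow",
    "population_coverage",
    "gini",
    "reallocation_accounting",
    "adjust_target",
    "intensification_percentage",
    "DEFAULT_REPORTING_FRACTION",
    "NATIONAL_BASELINE_HOSPITALS",
]

DEFAULT_REPORTING_FRACTION = 0.985
NATIONAL_BASELINE_HOSPITALS = 1075


@dataclass
class CoverageResult:
    """Population within the threshold, nationally and per municipality."""

    threshold_min: float
    covered_pop: float
    total_pop: float
    fraction: float
    per_municipality: pd.DataFrame  # municipality_id, covered, total, fraction


def population_coverage(access: AccessClass, cells: pd.DataFrame,
                        threshold_min: float = THRESHOLD_NEAR_MIN
                        ) -> CoverageResult:
    """Sum female population over cells classed LE30; unreachable cells stay
    in the denominator.  Municipalities with zero population get fraction
    NaN (they contribute nothing to either sum)."""
    frame = cells[["id", "municipality_id", "female_pop_15_49"]].merge(
        pd.DataFrame({"id": access.cell_ids, "label": access.labels}),
        on="id", validate="one_to_one")
    total = float(frame["female_pop_15_49"].sum())
    if total == 0:
        raise UndefinedMetricError("total population is zero; coverage undefined")
    frame["covered"] = np.where(frame["label"] == LE30,
                                frame["female_pop_15_49"], 0.0)
    by_muni = (frame.groupby("municipality_id", as_index=False)
               .agg(covered=("covered", "sum"),
                    total=("female_pop_15_49", "sum")))
    with np.errstate(invalid="ignore", divide="ignore"):
        by_muni["fraction"] = np.where(by_muni["total"] > 0,
                                       by_muni["covered"] / by_muni["total"],
                                       np.nan)
    covered = float(frame["covered"].sum())
    return CoverageResult(threshold_min=threshold_min, covered_pop=covered,
                          total_pop=total, fraction=covered / total,
                          per_municipality=by_muni)


@dataclass(frozen=True)
class GiniResult:
    value: float
    weighted: bool
    n_units: int


def gini(values: Sequence[float],
         weights: Sequence[float] | None = None) -> GiniResult:
    """Gini coefficient of non-negative values, optionally weighted.

    Equals the mean absolute pairwise difference divided by twice the mean,
    computed through the Lorenz-curve form on sorted values (exact for
    ties).  Requires a positive mean; an all-zero input is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise DataError("gini requires a non-empty 1-D value array")
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise DataError("gini values must be finite and >= 0")
    if weights is None:
        w = np.ones_like(x)
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
            raise DataError("weights must be non-negative, same shape, not all zero")
        weighted = True
    if float(x @ w) == 0.0:
        raise UndefinedMetricError("gini undefined: weighted mean is zero")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    p = ws / ws.sum()
    s = np.cumsum(p * xs)
    s_prev = np.concatenate([[0.0], s[:-1]])
    g = 1.0 - float(np.sum(p * (s_prev + s)) / s[-1])
    return GiniResult(value=g, weighted=weighted, n_units=len(x))


@dataclass
class AbsorptionRow:
    """One row of the reallocation table for a (scenario, k) pair."""

    scenario_label: str
    target_k: int
    retained_n: int
    hospitals_absorbed: int
    births_absorbed: float
    obstetricians_closed: float
    midwives_closed: float
    births_per_hospital_after: float
    obstetricians_per_hospital_after: float
    midwives_per_hospital_after: float


def reallocation_accounting(hospitals: pd.DataFrame, retained) -> AbsorptionRow:
    """Closure bookkeeping for a retained set.

    Absorbed deliveries/staff are the sums over *closed* hospitals; the
    per-hospital-after figures divide the unchanged national totals by the
    retained count, hence they depend only on |retained|, never on which
    scenario chose the set.
    """
    ids = list(getattr(retained, "hospital_ids", retained))
    known = set(hospitals["id"])
    unknown = [h for h in ids if h not in known]
    if unknown:
        raise DataError(f"retained ids not in baseline: {unknown[:5]}")
    if len(ids) == 0:
        raise UndefinedMetricError(
            "per-hospital-after statistics undefined for an empty retained set")
    kept = hospitals["id"].isin(set(ids))
    closed = hospitals[~kept]
    totals = hospitals[["deliveries_per_month", "obstetricians_fte",
                        "midwives_fte"]].sum()
    n_ret = len(ids)
    return AbsorptionRow(
        scenario_label=getattr(retained, "scenario_label", "custom"),
        target_k=getattr(retained, "target_k", n_ret),
        retained_n=n_ret,
        hospitals_absorbed=len(hospitals) - n_ret,
        births_absorbed=float(closed["deliveries_per_month"].sum()),
        obstetricians_closed=float(closed["obstetricians_fte"].sum()),
        midwives_closed=float(closed["midwives_fte"].sum()),
        births_per_hospital_after=float(totals["deliveries_per_month"]) / n_ret,
        obstetricians_per_hospital_after=float(totals["obstetricians_fte"]) / n_ret,
        midwives_per_hospital_after=float(totals["midwives_fte"]) / n_ret,
    )


def adjust_target(national_estimate: int,
                  r: float = DEFAULT_REPORTING_FRACTION) -> int:
    """Scale a national hospital-count target by the reporting fraction r
    (the share of births occurring in survey-reported areas), rounding half
    up: 1000 -> 985, 800 -> 788, 600 -> 591 at r = 0.985."""
    if national_estimate < 1:
        raise ConfigurationError("national_estimate must be >= 1")
    if not 0.0 < r <= 1.0:
        raise ConfigurationError("reporting fraction must lie in (0, 1]")
    adjusted = int((Decimal(str(national_estimate)) * Decimal(str(r)))
                   .quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return max(adjusted, 1)


def intensification_percentage(k: int, baseline_n: int
                               = NATIONAL_BASELINE_HOSPITALS) -> float:
    """Retained share of the baseline hospital stock, in percent (full
    precision; round at the reporting layer)."""
    if baseline_n < 1:
        raise ConfigurationError("baseline_n must be >= 1")
    return 100.0 * k / baseline_n
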