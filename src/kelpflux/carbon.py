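"""Oxygen-to-carbon conversion and the per-period summer carbon budget.

Oxygen fluxes become carbon fluxes through the photosynthetic quotient
(PQ, mol O2 evolved per mol CO2 fixed; 1.13 for *Saccharina latissima*),
scaled from hourly to daily rates by the photoperiod.  Biomass production
becomes carbon assimilation through the mean tissue carbon fraction.  The
budget table collects per-period means +/- SE of GPP, NPP, R and BP in
mg C/d, and the fractions module expresses BP and |R| as percentages of
GPP — the residual being carbon that left the blade in dissolved form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .growth import PeriodCoefficientTable
from .incubation import PERIODS, OxygenFluxResult

__all__ = [
    "CARBON_MOLAR_MASS",
    "NITROGEN_MOLAR_MASS",
    "DEFAULT_PQ",
    "CarbonRates",
    "BudgetFractions",
    "oxygen_to_carbon_daily",
    "carbon_assimilation",
    "cn_ratio",
    "budget_fractions",
    "assemble_budget_table",
]

CARBON_MOLAR_MASS = 12.011  # g/mol (12.01 used in the daily-rate conversion)
NITROGEN_MOLAR_MASS = 14.007  # g/mol

#: Photosynthetic quotient for S. latissima in shallow turbid water.
DEFAULT_PQ = 1.13

PQMode = Literal["divide", "multiply"]


def oxygen_to_carbon_daily(
    oxygen_rate: float,
    pq: float = DEFAULT_PQ,
    photoperiod_h: float = 15.5,
    mode: PQMode = "divide",
) -> float:
    """Convert a per-individual oxygen rate (umol O2/h) to mg C/d.

    The PQ relates O2 evolved to CO2 fixed.  With ``mode="divide"`` (the
    stoichiometric convention, default) carbon = oxygen / PQ; the
    ``"multiply"`` mode applies the coefficient the other way round for
    comparison with analyses written that way.  The umol C/h rate is scaled
    by the carbon molar mass of 12.01 g/mol, divided by 1000 (ug -> mg) and
    multiplied by the photoperiod in hours.  Sign is preserved, so a
    (negative) respiration rate stays a carbon loss.
    """
    if not 0 < photoperiod_h <= 24:
        raise ValueError("photoperiod must lie in (0, 24] hours")
    if pq <= 0:
        raise ValueError("PQ must be positive")
    if mode == "divide":
        carbon_umol_h = oxygen_rate / pq
    elif mode == "multiply":
        carbon_umol_h = oxygen_rate * pq
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return carbon_umol_h * 12.01 / 1000.0 * photoperiod_h


def carbon_assimilation(bp: float, c_avg: float) -> float:
    """Carbon bound into new tissue: BP (mg DW/d) * C_avg (mg C/mg DW)."""
    if bp < 0:
        raise ValueError("biomass production must be non-negative")
    if not 0 < c_avg < 1:
        raise ValueError("c_avg must lie in (0, 1) mg C per mg DW")
    return bp * c_avg


def cn_ratio(c_mass_mg: float, n_mass_mg: float) -> float:
    """Molar C:N ratio from elemental masses (mg)."""
    if c_mass_mg <= 0 or n_mass_mg <= 0:
        raise ValueError("elemental masses must be positive")
    return (c_mass_mg / CARBON_MOLAR_MASS) / (n_mass_mg / NITROGEN_MOLAR_MASS)


@dataclass(frozen=True)
class CarbonRates:
    """Daily carbon rates for one period (mg C/d; r_c <= 0)."""

    period: str
    gpp_c: float
    npp_c: float
    r_c: float
    bp_c: Optional[float] = None
    pq: float = DEFAULT_PQ
    photoperiod_h: float = 15.5

    def __post_init__(self) -> None:
        if self.pq <= 0:
            raise ValueError("PQ must be positive")


@dataclass(frozen=True)
class BudgetFractions:
    """Carbon-budget partition as percentages of GPP.

    ``implied_doc_fraction`` is the bookkeeping residual
    100 - (BP% + |R|%): carbon fixed but neither respired nor bound into
    tissue, i.e. an upper bound on dissolved-organic release.  It is not a
    DOC measurement.
    """

    bp_over_gpp: float
    r_over_gpp: float
    combined_over_gpp: float
    implied_doc_fraction: float

    def rounded(self) -> "BudgetFractions":
        return BudgetFractions(
            *(round(v) for v in (
                self.bp_over_gpp,
                self.r_over_gpp,
                self.combined_over_gpp,
                self.implied_doc_fraction,
            ))
        )


def budget_fractions(rates: CarbonRates) -> BudgetFractions:
    """Express BP and |R| as percentages of GPP (full precision)."""
    if rates.gpp_c <= 0:
        raise ValueError("GPP must be positive to form budget fractions")
    bp = rates.bp_c if rates.bp_c is not None else float("nan")
    bp_pct = 100.0 * bp / rates.gpp_c
    r_pct = 100.0 * abs(rates.r_c) / rates.gpp_c
    combined = bp_pct + r_pct
    return BudgetFractions(
        bp_over_gpp=bp_pct,
        r_over_gpp=r_pct,
        combined_over_gpp=combined,
        implied_doc_fraction=100.0 - combined,
    )


def _mean_se(values: Sequence[float]) -> tuple[float, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


def assemble_budget_table(
    flux_results: Iterable[OxygenFluxResult],
    bp_by_period: dict[str, Sequence[float]],
    coefficients: PeriodCoefficientTable | None = None,
    pq: float = DEFAULT_PQ,
    mode: PQMode = "divide",
    periods: Sequence[str] = PERIODS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-period carbon budget and its fractions.

    For each incubation the per-gram oxygen fluxes are scaled to the whole
    individual (flux * dry weight, umol O2/h), converted to mg C/d with the
    period photoperiod, and averaged within periods.  ``bp_by_period`` maps
    a period to the per-individual biomass-production values (mg DW/d) from
    the growth cohort; these are converted with the period's mean tissue
    carbon fraction.  Periods with no data in a column get NA plus a reason,
    never a silent drop.  Note the respiratory carbon loss is scaled by the
    photoperiod like the other rates — a deliberate, flagged assumption, not
    a 24 h loss.

    Returns (budget table, fractions table).
    """
    coefficients = coefficients or PeriodCoefficientTable.default()
    by_period: dict[str, list[OxygenFluxResult]] = {p: [] for p in periods}
    for res in flux_results:
        if res.period not in by_period:
            raise ValueError(f"unknown period {res.period!r} for {res.incubation_id}")
        by_period[res.period].append(res)

    budget_rows = []
    fraction_rows = []
    for period in periods:
        coeffs = coefficients.for_period(period)
        row: dict = {"period": period, "photoperiod_h": coeffs.photoperiod_h, "pq": pq}
        results = by_period[period]
        row["n_incubations"] = len(results)
        if results:
            per_ind = {
                "gpp": [
                    oxygen_to_carbon_daily(r.gpp * r.dry_weight_g, pq, coeffs.photoperiod_h, mode)
                    for r in results
                ],
                "npp": [
                    oxygen_to_carbon_daily(r.npp * r.dry_weight_g, pq, coeffs.photoperiod_h, mode)
                    for r in results
                ],
                "r": [
                    oxygen_to_carbon_daily(r.r * r.dry_weight_g, pq, coeffs.photoperiod_h, mode)
                    for r in results
                ],
            }
            for name, vals in per_ind.items():
                mean, se = _mean_se(vals)
                row[f"{name}_mg_c_per_day"] = mean
                row[f"{name}_se"] = se
                if se is None:
                    row["reason"] = "single incubation: SE undefined"
        else:
            for name in ("gpp", "npp", "r"):
                row[f"{name}_mg_c_per_day"] = None
                row[f"{name}_se"] = None
            row["reason"] = "no incubations in period"

        bp_values = bp_by_period.get(period)
        if bp_values is not None and len(bp_values) > 0:
            bp_c = [carbon_assimilation(bp, coeffs.c_avg) for bp in bp_values]
            mean, se = _mean_se(bp_c)
            row["bp_mg_c_per_day"] = mean
            row["bp_se"] = se
            row["n_growth"] = len(bp_c)
        else:
            row["bp_mg_c_per_day"] = None
            row["bp_se"] = None
            row["n_growth"] = 0
            row.setdefault("reason", "no growth data for period")
        budget_rows.append(row)

        if results:
            rates = CarbonRates(
                period=period,
                gpp_c=row["gpp_mg_c_per_day"],
                npp_c=row["npp_mg_c_per_day"],
                r_c=row["r_mg_c_per_day"],
                bp_c=row["bp_mg_c_per_day"],
                pq=pq,
                photoperiod_h=coeffs.photoperiod_h,
            )
            frac = budget_fractions(rates)
            fraction_rows.append(
                {
                    "period": period,
                    "bp_over_gpp_pct": frac.bp_over_gpp,
                    "r_over_gpp_pct": frac.r_over_gpp,
                    "combined_over_gpp_pct": frac.combined_over_gpp,
                    "implied_doc_fraction_pct": frac.implied_doc_fraction,
                }
            )

    budget = pd.DataFrame(budget_rows)
    fractions = pd.DataFrame(fraction_rows)
    return budget, fractions
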