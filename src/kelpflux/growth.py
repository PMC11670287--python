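"""Tagged-individual growth, blade erosion, and biomass production.

Blades are hole-punched at 10 and 15 cm above the stipe-blade junction;
meristematic growth at the blade base pushes the holes outward, so the hole
displacement between visits divided by the elapsed days is the linear growth
rate G (cm/d).  Blade length changes more slowly than G because the apex
erodes: erosion = G - dBL/dt.  Mid-blade segments give B_base (g WW per cm
of blade), the WW:DW ratio, and tissue C/N fractions, which together turn a
linear growth rate into a dry-mass production rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthObservation",
    "SegmentSample",
    "PeriodCoefficients",
    "GrowthRates",
    "linear_growth_rate",
    "estimate_b_base",
    "ww_dw_ratio",
    "biomass_production",
    "erosion_rate",
    "PeriodCoefficientTable",
    "DEFAULT_COEFFICIENTS",
    "period_of_date",
    "cohort_rates",
]


#: Standard punch positions above the stipe-blade junction (cm).
PUNCH_POSITIONS: tuple[float, float] = (10.0, 15.0)


@dataclass(frozen=True)
class GrowthObservation:
    """One visit to one tagged individual.

    ``hole_distances`` are the distances measured at arrival for the holes
    punched at the previous visit (``None`` for a hole lost to erosion or
    grazing).  When ``holes_repunched`` is true the diver punched fresh
    holes before leaving, so the state carried into the next interval is
    ``punched_at``, not the measured distances.  The first (tagging) visit
    is recorded with ``holes_repunched=True`` and no measured distances.
    """

    individual_id: str
    date: Date
    hole_distances: tuple[Optional[float], ...]  # cm from stipe-blade junction
    blade_length: float  # cm
    holes_repunched: bool = False
    punched_at: tuple[float, ...] = PUNCH_POSITIONS

    def __post_init__(self) -> None:
        if self.blade_length <= 0:
            raise ValueError("blade length must be positive")
        for d in self.hole_distances:
            if d is not None and d < 0:
                raise ValueError("hole distances must be non-negative")
            if d is not None and d > self.blade_length:
                raise ValueError("hole distance cannot exceed blade length")

    def outgoing_hole_state(self) -> tuple[Optional[float], ...]:
        """Hole distances as the diver leaves (start of the next interval)."""
        if self.holes_repunched:
            return tuple(self.punched_at)
        return tuple(self.hole_distances)


@dataclass(frozen=True)
class SegmentSample:
    """A ~5 cm mid-blade segment with weights and elemental fractions."""

    individual_id: str
    date: Date
    segment_length: float  # cm
    wet_weight: float  # g
    dry_weight: float  # g
    carbon_fraction: float  # mg C per mg DW
    nitrogen_fraction: float  # mg N per mg DW

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment length must be positive")
        if not 0 < self.dry_weight < self.wet_weight:
            raise ValueError("need 0 < DW < WW")
        if not (0 < self.nitrogen_fraction < self.carbon_fraction < 1):
            raise ValueError("need 0 < N fraction < C fraction < 1")


@dataclass(frozen=True)
class PeriodCoefficients:
    """Conversion coefficients attached to one growth period."""

    period: str
    b_base: float  # g WW per cm blade
    ww_dw_ratio: float  # dimensionless, > 1
    c_avg: float  # mg C per mg DW
    photoperiod_h: float  # daylight hours

    def __post_init__(self) -> None:
        if min(self.b_base, self.c_avg, self.photoperiod_h) <= 0:
            raise ValueError("coefficients must be positive")
        if self.ww_dw_ratio <= 1:
            raise ValueError("WW:DW ratio must exceed 1")


@dataclass(frozen=True)
class GrowthRates:
    """Rates over one observation interval of one individual.

    The bookkeeping identity ``erosion_rate = G - elongation_rate`` holds
    exactly whenever G is defined.
    """

    individual_id: str
    start: Date
    end: Date
    G: Optional[float]  # cm/d, hole-displacement growth
    elongation_rate: float  # cm/d, dBL/dt, any sign
    erosion_rate: Optional[float]  # cm/d
    n_holes_used: int
    flags: tuple[str, ...] = ()
    reason: Optional[str] = None  # set when G is missing


def linear_growth_rate(
    obs_start: GrowthObservation, obs_end: GrowthObservation
) -> GrowthRates:
    """Growth rate from hole displacement between two visits.

    Start distances are the holes as the diver left them at the first visit
    (the punch positions when holes were renewed there); end distances are
    the measurements at the second visit, matched by hole identity.
    Per-hole rate = (end distance - start distance) / days; G averages the
    matched holes.  Negative per-hole displacements are treated as
    measurement anomalies (flagged, excluded) unless every hole is negative,
    in which case the negative mean is kept but flagged, since a uniformly
    negative displacement more likely reflects a datum error than anomaly.
    """
    if obs_start.individual_id != obs_end.individual_id:
        raise ValueError("observations belong to different individuals")
    days = (obs_end.date - obs_start.date).days
    if days <= 0:
        raise ValueError("end date must follow start date")

    elongation = (obs_end.blade_length - obs_start.blade_length) / days

    def _missing(reason: str) -> GrowthRates:
        return GrowthRates(
            individual_id=obs_start.individual_id,
            start=obs_start.date,
            end=obs_end.date,
            G=None,
            elongation_rate=elongation,
            erosion_rate=None,
            n_holes_used=0,
            reason=reason,
        )

    rates = []
    for d0, d1 in zip(obs_start.outgoing_hole_state(), obs_end.hole_distances):
        if d0 is None or d1 is None:
            continue
        rates.append((d1 - d0) / days)
    if not rates:
        return _missing("no matchable holes (all lost)")

    flags: list[str] = []
    positive = [r for r in rates if r >= 0]
    if len(positive) < len(rates):
        flags.append("negative-hole-displacement")
    used = positive if positive else rates
    G = float(np.mean(used))
    return GrowthRates(
        individual_id=obs_start.individual_id,
        start=obs_start.date,
        end=obs_end.date,
        G=G,
        elongation_rate=elongation,
        erosion_rate=G - elongation,
        n_holes_used=len(used),
        flags=tuple(flags),
    )


def estimate_b_base(segments: Sequence[SegmentSample]) -> tuple[float, float, int]:
    """Mean wet weight per cm of blade: (mean, sd, n) over segments."""
    if not segments:
        raise ValueError("no segments")
    ratios = np.array([s.wet_weight / s.segment_length for s in segments])
    sd = 0.0 if ratios.size == 1 else float(ratios.std(ddof=1))
    return float(ratios.mean()), sd, int(ratios.size)


def ww_dw_ratio(segments: Sequence[SegmentSample]) -> float:
    """Mean wet:dry weight ratio over segments."""
    if not segments:
        raise ValueError("no segments")
    return float(np.mean([s.wet_weight / s.dry_weight for s in segments]))


def biomass_production(G: float, coeffs: PeriodCoefficients) -> float:
    """Daily dry-mass production in mg DW/d.

    BP_ww = G * B_base gives g WW/d; dividing by the WW:DW ratio converts
    wet to dry mass, and the factor 1000 converts g to mg:
    BP = G * B_base / ratio * 1000.
    """
    if G < 0:
        raise ValueError("G must be non-negative; erosion is handled separately")
    return G * coeffs.b_base / coeffs.ww_dw_ratio * 1000.0


def erosion_rate(G: float, elongation_rate: float) -> float:
    """Apical erosion: growth not expressed as blade-length change (cm/d)."""
    return G - elongation_rate


# --- period bookkeeping ----------------------------------------------------

#: Default per-period coefficients.  B_base and WW:DW come from the three
#: destructive sampling events (late May, early August, mid September); each
#: event's coefficients apply to the growth periods it brackets.  Photoperiods
#: are site daylight hours per month.
DEFAULT_COEFFICIENTS: dict[str, PeriodCoefficients] = {
    "June": PeriodCoefficients("June", b_base=0.88, ww_dw_ratio=10.5, c_avg=0.295, photoperiod_h=15.5),
    "July": PeriodCoefficients("July", b_base=0.884, ww_dw_ratio=7.3, c_avg=0.295, photoperiod_h=15.5),
    "early-August": PeriodCoefficients("early-August", b_base=0.884, ww_dw_ratio=7.3, c_avg=0.295, photoperiod_h=14.5),
    "late-August": PeriodCoefficients("late-August", b_base=0.88, ww_dw_ratio=9.0, c_avg=0.295, photoperiod_h=14.5),
    "September": PeriodCoefficients("September", b_base=0.88, ww_dw_ratio=9.0, c_avg=0.295, photoperiod_h=12.5),
}


def period_of_date(d: Date) -> str:
    """Map a calendar date (interval midpoint) onto a named growth period."""
    if d.month == 6:
        return "June"
    if d.month == 7:
        return "July"
    if d.month == 8:
        return "early-August" if d.day <= 15 else "late-August"
    if d.month == 9:
        return "September"
    raise ValueError(f"{d} is outside the configured June-September season")


@dataclass
class PeriodCoefficientTable:
    """Period -> coefficients mapping, overridable from config."""

    coefficients: dict[str, PeriodCoefficients]

    @classmethod
    def default(cls) -> "PeriodCoefficientTable":
        return cls(dict(DEFAULT_COEFFICIENTS))

    def for_period(self, period: str) -> PeriodCoefficients:
        try:
            return self.coefficients[period]
        except KeyError:
            raise ValueError(f"no coefficients configured for period {period!r}")

    def for_date(self, d: Date) -> PeriodCoefficients:
        return self.for_period(period_of_date(d))


def cohort_rates(
    observations: Iterable[GrowthObservation],
    coefficients: PeriodCoefficientTable | None = None,
) -> pd.DataFrame:
    """Per-individual, per-interval growth table for a tagged cohort.

    Consecutive visit pairs of each individual yield one row with G,
    elongation, erosion, the interval's period (by midpoint), and BP
    (mg DW/d) computed from the period coefficients.  Missing intervals
    (tag loss, repunched holes) are kept as rows with NA rates and a reason
    rather than dropped.
    """
    coefficients = coefficients or PeriodCoefficientTable.default()
    by_ind: dict[str, list[GrowthObservation]] = {}
    for obs in observations:
        by_ind.setdefault(obs.individual_id, []).append(obs)

    rows = []
    for ind, obs_list in by_ind.items():
        obs_list = sorted(obs_list, key=lambda o: o.date)
        if len({o.date for o in obs_list}) != len(obs_list):
            raise ValueError(f"duplicate visit dates for individual {ind}")
        for o0, o1 in zip(obs_list, obs_list[1:]):
            rates = linear_growth_rate(o0, o1)
            midpoint = o0.date + (o1.date - o0.date) / 2
            try:
                period = period_of_date(midpoint)
            except ValueError:
                period = None
            bp = None
            if rates.G is not None and rates.G >= 0 and period is not None:
                bp = biomass_production(rates.G, coefficients.for_period(period))
            rows.append(
                {
                    "individual_id": ind,
                    "start": o0.date,
                    "end": o1.date,
                    "period": period,
                    "G_cm_per_day": rates.G,
                    "elongation_cm_per_day": rates.elongation_rate,
                    "erosion_cm_per_day": rates.erosion_rate,
                    "bp_mg_dw_per_day": bp,
                    "n_holes_used": rates.n_holes_used,
                    "flags": ";".join(rates.flags),
                    "reason": rates.reason,
                }
            )
    return pd.DataFrame(rows)
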