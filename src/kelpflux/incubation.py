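"""Chamber photorespirometry: O2 time series -> NPP, R, GPP.

A sealed 20 L chamber encloses one kelp blade in situ.  The incubation runs
dark (respiration) for 40 min, then the opaque bag is removed and after a
10 min light-acclimation interval a 40 min light phase (net photosynthesis)
follows.  An optode logs dissolved O2 (mg/L) and temperature every minute.
Fluxes are the linear O2 slopes of each phase, scaled by chamber volume and
normalised to the blade's dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "O2_MOLAR_MASS",
    "IncubationProtocol",
    "IncubationSeries",
    "PhaseSegmentation",
    "SlopeFit",
    "OxygenFluxResult",
    "segment_phases",
    "fit_o2_slope",
    "flux_from_slope",
    "compute_fluxes",
]

#: Molar mass of O2 in g/mol, for the mg -> umol conversion.
O2_MOLAR_MASS = 31.998

PERIODS = ("June", "July", "early-August", "late-August", "September")


@dataclass(frozen=True)
class IncubationProtocol:
    """Phase durations in minutes, plus handling of transition transients."""

    dark_minutes: float = 40.0
    acclimation_minutes: float = 10.0
    light_minutes: float = 40.0
    pre_roll_minutes: float = 0.0
    transition_trim_minutes: float = 1.0

    @property
    def total_minutes(self) -> float:
        return self.dark_minutes + self.acclimation_minutes + self.light_minutes


@dataclass
class IncubationSeries:
    """One chamber deployment: the logged trace plus blade metadata."""

    incubation_id: str
    period: str
    minutes: np.ndarray  # minutes since logging start
    o2: np.ndarray  # dissolved O2, mg/L
    temperature: np.ndarray  # degC
    dry_weight_g: float
    chamber_volume_l: float = 20.0
    protocol: IncubationProtocol = field(default_factory=IncubationProtocol)

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (self.minutes.shape == self.o2.shape == self.temperature.shape):
            raise ValueError("minutes, o2 and temperature must have equal length")
        if np.any(np.diff(self.minutes) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.o2 <= 0):
            raise ValueError("dissolved O2 must stay positive")
        if self.dry_weight_g <= 0:
            raise ValueError("kelp dry weight must be positive")
        if self.chamber_volume_l <= 0:
            raise ValueError("chamber volume must be positive")
        duration = self.minutes[-1] - self.minutes[0]
        needed = self.protocol.total_minutes + self.protocol.pre_roll_minutes - 1.0
        if duration < needed:
            raise ValueError(
                f"series covers {duration:.1f} min but the protocol needs "
                f">= {needed:.1f} min"
            )


Window = tuple[float, float]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Closed minute-offset windows for the three protocol phases."""

    dark_window: Window
    acclimation_window: Window
    light_window: Window


def segment_phases(series: IncubationSeries) -> PhaseSegmentation:
    """Cut the trace into dark / acclimation / light windows.

    Windows follow the protocol durations, offset by any pre-roll, with a
    one-minute trim at every phase transition to drop the transient caused
    by handling the dark bag.
    """
    p = series.protocol
    t0 = series.minutes[0] + p.pre_roll_minutes
    trim = p.transition_trim_minutes
    dark_end = t0 + p.dark_minutes
    acc_end = dark_end + p.acclimation_minutes
    light_end = acc_end + p.light_minutes
    if series.minutes[-1] < light_end - 1.0:
        raise ValueError(
            f"series ends at {series.minutes[-1]:.1f} min; achievable windows "
            f"end at dark={dark_end:.0f}, acclimation={acc_end:.0f}, "
            f"light={light_end:.0f} min"
        )
    return PhaseSegmentation(
        dark_window=(t0, dark_end - trim),
        acclimation_window=(dark_end + trim, acc_end - trim),
        light_window=(acc_end + trim, light_end),
    )


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of O2 against time over one phase window."""

    slope: float  # mg O2 L^-1 h^-1
    slope_se: float
    r2: float  # nan when O2 has zero variance
    n_points: int
    window_used: Window
    degenerate: bool = False  # flat trace, r2 undefined
    sub_window_used: bool = False  # linearity fallback engaged

    @property
    def linear(self) -> bool:
        return self.degenerate or (np.isfinite(self.r2) and self.r2 >= 0.95)


def _ols_slope(minutes: np.ndarray, o2: np.ndarray, window: Window) -> SlopeFit:
    hours = minutes / 60.0
    if np.var(o2) == 0.0:
        return SlopeFit(
            slope=0.0,
            slope_se=0.0,
            r2=float("nan"),
            n_points=int(o2.size),
            window_used=window,
            degenerate=True,
        )
    res = stats.linregress(hours, o2)
    return SlopeFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        r2=float(res.rvalue**2),
        n_points=int(o2.size),
        window_used=window,
    )


def fit_o2_slope(
    series: IncubationSeries,
    window: Window,
    min_points: int = 10,
    linearity_r2: float = 0.95,
) -> SlopeFit:
    """Fit the O2 drawdown/evolution slope (mg/L/h) over a window.

    If the full-window fit falls below the linearity threshold, the longest
    contiguous sub-window of at least ``min_points`` samples reaching the
    threshold is used instead (ties broken by r2) and the result is flagged.
    This automates the salvage applied when a sensor fails partway through a
    phase and only a shorter stretch is usable.
    """
    lo, hi = window
    mask = (series.minutes >= lo) & (series.minutes <= hi)
    t = series.minutes[mask]
    y = series.o2[mask]
    if t.size < min_points:
        raise ValueError(
            f"window ({lo:g}, {hi:g}) holds {t.size} points; need >= {min_points}"
        )
    if np.var(t) == 0.0:
        raise ValueError("zero time-variance in window")
    fit = _ols_slope(t, y, window)
    if fit.degenerate or fit.r2 >= linearity_r2:
        return fit

    # exhaustive search over contiguous sub-windows (n is tens of points)
    best: Optional[SlopeFit] = None
    n = t.size
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            cand = _ols_slope(t[i:j], y[i:j], (float(t[i]), float(t[j - 1])))
            if cand.degenerate or cand.r2 < linearity_r2:
                continue
            if (
                best is None
                or cand.n_points > best.n_points
                or (cand.n_points == best.n_points and cand.r2 > best.r2)
            ):
                best = cand
    if best is None:
        # nothing reaches the threshold: keep the full-window fit, flagged
        return SlopeFit(
            slope=fit.slope,
            slope_se=fit.slope_se,
            r2=fit.r2,
            n_points=fit.n_points,
            window_used=fit.window_used,
            sub_window_used=True,
        )
    return SlopeFit(
        slope=best.slope,
        slope_se=best.slope_se,
        r2=best.r2,
        n_points=best.n_points,
        window_used=best.window_used,
        sub_window_used=True,
    )


def flux_from_slope(
    fit: SlopeFit | float, chamber_volume_l: float, dry_weight_g: float
) -> float:
    """Standardise an O2 slope to umol O2 g^-1 DW h^-1.

    flux = slope [mg/L/h] * volume [L] / dry weight [g] * 1000 / 31.998.
    The sign of the slope is preserved.
    """
    if dry_weight_g <= 0:
        raise ValueError("dry weight must be positive")
    if chamber_volume_l <= 0:
        raise ValueError("chamber volume must be positive")
    slope = fit.slope if isinstance(fit, SlopeFit) else float(fit)
    return slope * chamber_volume_l / dry_weight_g * (1000.0 / O2_MOLAR_MASS)


@dataclass(frozen=True)
class OxygenFluxResult:
    """Dry-weight-standardised fluxes for one incubation.

    ``r`` follows the oxygen-consumption sign convention (<= 0 expected);
    ``gpp = npp + |r|`` by construction.
    """

    incubation_id: str
    period: str
    npp: float  # umol O2 g^-1 DW h^-1
    r: float  # umol O2 g^-1 DW h^-1, <= 0 expected
    gpp: float
    dry_weight_g: float
    dark_fit: SlopeFit
    light_fit: SlopeFit
    flags: tuple[str, ...] = ()


def compute_fluxes(
    series: IncubationSeries,
    min_points: int = 10,
    linearity_r2: float = 0.95,
) -> OxygenFluxResult:
    """Full per-incubation flux estimate: R (dark), NPP (light), GPP.

    A positive dark slope is physically unexpected (O2 production in the
    dark) and yields a warning flag rather than an error, since mild sensor
    drift can produce it.
    """
    seg = segment_phases(series)
    try:
        dark_fit = fit_o2_slope(series, seg.dark_window, min_points, linearity_r2)
        light_fit = fit_o2_slope(series, seg.light_window, min_points, linearity_r2)
    except ValueError as exc:
        raise ValueError(f"incubation {series.incubation_id}: {exc}") from exc

    r = flux_from_slope(dark_fit, series.chamber_volume_l, series.dry_weight_g)
    npp = flux_from_slope(light_fit, series.chamber_volume_l, series.dry_weight_g)
    gpp = npp + abs(r)

    flags: list[str] = []
    if r > 0:
        flags.append("positive-dark-slope")
    for name, fit in (("dark", dark_fit), ("light", light_fit)):
        if fit.sub_window_used:
            flags.append(f"{name}-sub-window")
        if fit.degenerate:
            flags.append(f"{name}-degenerate")
        elif not fit.linear:
            flags.append(f"{name}-nonlinear")

    return OxygenFluxResult(
        incubation_id=series.incubation_id,
        period=series.period,
        npp=npp,
        r=r,
        gpp=gpp,
        dry_weight_g=series.dry_weight_g,
        dark_fit=dark_fit,
        light_fit=light_fit,
        flags=tuple(flags),
    )
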