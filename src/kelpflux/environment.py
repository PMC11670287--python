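"""Environmental logger streams: salinity, light calibration, and aggregation.

Conductivity/temperature/light loggers moored next to the kelp bed produce
the covariates for the flux analysis.  This module converts raw conductivity
to practical salinity (PSS-78), calibrates lux readings from planar pendant
loggers against a quantum PAR sensor, and aggregates channels over incubation
windows and calendar days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvSeries",
    "LuxParCalibration",
    "WindowStat",
    "salinity_from_conductivity",
    "conductivity_from_salinity",
    "calibrate_lux_to_par",
    "window_mean",
    "daily_summary",
]

#: Conductivity of standard seawater, C(35, 15, 0), in mS/cm.
C_35_15_0 = 42.914

# PSS-78 polynomial coefficients (UNESCO 1983, EOS-80).
_A = (0.0080, -0.1692, 25.3851, 14.0941, -7.0261, 2.7081)
_B = (0.0005, -0.0056, -0.0066, -0.0375, 0.0636, -0.0144)
_C = (0.6766097, 2.00564e-2, 1.104259e-4, -6.9698e-7, 1.0031e-9)
_D = (3.426e-2, 4.464e-4, 4.215e-1, -3.107e-3)
_E = (2.070e-5, -6.370e-10, 3.989e-15)
_K = 0.0162


class SalinityRangeWarning(UserWarning):
    """Computed salinity fell outside the PSS-78 validity range (2-42)."""


def _pss78_from_ratio(R, t, p):
    """Practical salinity from conductivity ratio R = C/C(35,15,0)."""
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    rt = _C[0] + t * (_C[1] + t * (_C[2] + t * (_C[3] + t * _C[4])))
    Rp = 1.0 + p * (_E[0] + p * (_E[1] + p * _E[2])) / (
        1.0 + _D[0] * t + _D[1] * t * t + (_D[2] + _D[3] * t) * R
    )
    Rt = R / (Rp * rt)
    sqRt = np.sqrt(Rt)

    S = (
        _A[0]
        + _A[1] * sqRt
        + _A[2] * Rt
        + _A[3] * Rt * sqRt
        + _A[4] * Rt * Rt
        + _A[5] * Rt * Rt * sqRt
    )
    dS = (t - 15.0) / (1.0 + _K * (t - 15.0)) * (
        _B[0]
        + _B[1] * sqRt
        + _B[2] * Rt
        + _B[3] * Rt * sqRt
        + _B[4] * Rt * Rt
        + _B[5] * Rt * Rt * sqRt
    )
    return S + dS


def salinity_from_conductivity(
    conductivity: float | np.ndarray,
    temperature: float | np.ndarray,
    pressure: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Convert conductivity to practical salinity on the PSS-78 scale.

    Parameters
    ----------
    conductivity
        In situ conductivity in mS/cm (must be positive).
    temperature
        In situ temperature in degrees Celsius (IPTS-68), valid -2 to 35.
    pressure
        Sea pressure in dbar (>= 0).  The moored loggers sit at 1-5 m depth
        so the default of 0 dbar is adequate for this site.

    Returns
    -------
    Practical salinity (dimensionless).  Values outside the PSS-78 validity
    range of 2-42 raise :class:`SalinityRangeWarning` but are still returned.
    """
    c = np.asarray(conductivity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if np.any(c <= 0):
        raise ValueError("conductivity must be positive (mS/cm)")
    if np.any((t < -2.0) | (t > 35.0)):
        raise ValueError("temperature outside supported range -2 to 35 degC")
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative (dbar)")

    S = _pss78_from_ratio(c / C_35_15_0, t, p)
    if np.any((S < 2.0) | (S > 42.0)):
        warnings.warn(
            "practical salinity outside PSS-78 validity range (2-42)",
            SalinityRangeWarning,
            stacklevel=2,
        )
    if np.isscalar(conductivity) and S.ndim == 0:
        return float(S)
    return S


def conductivity_from_salinity(
    salinity: float, temperature: float, pressure: float = 0.0
) -> float:
    """Invert PSS-78: conductivity (mS/cm) giving the requested salinity.

    Solved numerically (Brent's method on the conductivity ratio); used by
    the synthetic logger generator to emit conductivity traces whose derived
    salinity matches a target.
    """
    from scipy.optimize import brentq

    if salinity <= 0:
        raise ValueError("salinity must be positive")
    ratio = brentq(
        lambda R: _pss78_from_ratio(R, temperature, pressure) - salinity,
        1e-6,
        3.0,
        xtol=1e-12,
    )
    return float(ratio * C_35_15_0)


@dataclass(frozen=True)
class LuxParCalibration:
    """Through-origin lux -> PAR conversion: ``par = coefficient * lux``."""

    coefficient: float  # umol photons m^-2 s^-1 per lux
    n_pairs: int
    fit_r2: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("calibration coefficient must be positive")
        if not 0.0 <= self.fit_r2 <= 1.0:
            raise ValueError("fit_r2 must lie in [0, 1]")

    def convert(self, lux: float | np.ndarray) -> float | np.ndarray:
        return self.coefficient * np.asarray(lux, dtype=float)


def calibrate_lux_to_par(
    lux: Sequence[float], par: Sequence[float], min_pairs: int = 10
) -> LuxParCalibration:
    """Fit the lux -> PAR coefficient from simultaneous sensor readings.

    A through-origin least-squares slope (zero light must map to zero PAR):
    ``k = sum(lux*par) / sum(lux**2)``.  The reported r2 is the uncentred
    coefficient of determination appropriate for a no-intercept fit.
    """
    x = np.asarray(lux, dtype=float)
    y = np.asarray(par, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("lux and par must be 1-d sequences of equal length")
    if x.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} paired readings, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("degenerate design: all lux values identical")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("degenerate design: all lux values zero")
    k = float(np.sum(x * y) / sxx)
    rss = float(np.sum((y - k * x) ** 2))
    syy = float(np.sum(y * y))
    r2 = 1.0 if syy == 0.0 else max(0.0, 1.0 - rss / syy)
    return LuxParCalibration(coefficient=k, n_pairs=int(x.size), fit_r2=r2)


class WindowStat(NamedTuple):
    mean: float
    n: int


_CHANNELS = ("irradiance_lux", "irradiance_par", "temperature", "conductivity")


@dataclass
class EnvSeries:
    """A moored-logger time series (nominal 1-min or 60-min cadence).

    Wraps a timestamp-indexed DataFrame with any of the channels
    ``irradiance_lux``, ``irradiance_par``, ``temperature``, ``conductivity``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise TypeError("EnvSeries data must be indexed by timestamps")
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        known = [c for c in df.columns if c in _CHANNELS]
        if not known:
            raise ValueError(f"no recognised channels among {list(df.columns)}")
        for ch in ("irradiance_lux", "irradiance_par"):
            if ch in df and np.any(df[ch].dropna() < 0):
                raise ValueError(f"negative values in {ch}")
        if "conductivity" in df and np.any(df["conductivity"].dropna() <= 0):
            raise ValueError("conductivity must be positive")

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c in _CHANNELS]

    @classmethod
    def from_csv(
        cls,
        path,
        timestamp_col: str = "timestamp",
        column_map: dict[str, str] | None = None,
    ) -> "EnvSeries":
        """Read a logger export.  ``column_map`` renames dialect-specific
        column names onto the canonical channel names."""
        df = pd.read_csv(path, parse_dates=[timestamp_col])
        if column_map:
            df = df.rename(columns=column_map)
        df = df.set_index(timestamp_col).sort_index()
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="timestamp")

    def salinity(self, pressure: float = 0.0) -> pd.Series:
        """Derived practical-salinity channel (requires conductivity + temperature)."""
        if "conductivity" not in self.data or "temperature" not in self.data:
            raise ValueError("salinity requires conductivity and temperature channels")
        s = salinity_from_conductivity(
            self.data["conductivity"].to_numpy(),
            self.data["temperature"].to_numpy(),
            pressure,
        )
        return pd.Series(s, index=self.data.index, name="salinity")


def window_mean(
    series: EnvSeries, start, end, channel: str
) -> WindowStat:
    """Mean of a channel over the closed window [start, end].

    Boundary samples are included once.  Used for e.g. the mean irradiance
    over the duration of an incubation.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if channel == "salinity":
        col = series.salinity()
    else:
        if channel not in series.data:
            raise KeyError(f"channel {channel!r} not present")
        col = series.data[channel]
    sel = col.loc[start:end].dropna()
    if sel.empty:
        raise ValueError(
            f"no samples for channel {channel!r} in window [{start}, {end}]"
        )
    return WindowStat(mean=float(sel.mean()), n=int(sel.size))


def daily_summary(series: EnvSeries, date) -> pd.DataFrame:
    """Per-channel mean and sample SD for one calendar day.

    Returns a frame indexed by channel with columns ``mean``, ``sd``, ``n``
    and ``degenerate`` (True when only a single sample was available, in
    which case the SD is reported as 0).
    """
    day = pd.Timestamp(date).normalize()
    mask = series.data.index.normalize() == day
    sub = series.data.loc[mask]
    if sub.empty:
        raise ValueError(f"no samples on {day.date()}")
    rows = {}
    channels = dict(sub[series.channels].items())
    if "conductivity" in sub.columns and "temperature" in sub.columns:
        channels["salinity"] = series.salinity().loc[mask]
    for name, col in channels.items():
        vals = col.dropna()
        if vals.empty:
            continue
        n = int(vals.size)
        rows[name] = {
            "mean": float(vals.mean()),
            "sd": 0.0 if n == 1 else float(vals.std(ddof=1)),
            "n": n,
            "degenerate": n == 1,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
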