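"""Synthetic study data with known ground truth.

Every input the pipeline consumes can be generated here: chamber O2 traces
following the dark(40')/acclimation(10')/light(40') protocol, a tagged
growth cohort with hole displacement, apical erosion and tag loss,
moored-logger environment series with diel light, tides and conductivity
consistent with a target salinity, and driver-regression scenarios with
known coefficients.  Defaults emulate the summer conditions of a subarctic
*Saccharina latissima* bed in the lower St. Lawrence estuary: monthly
temperature / irradiance / salinity means, flux ranges, growth-rate and
biomass-coefficient magnitudes.

Randomness contract: a single root seed; every operation derives an
independent substream as ``SeedSequence([seed, crc32(stream_name)])``, so
generated pieces are reproducible independently of call order.  Ground
truth travels in sidecar structures (and ``truth.json`` on disk), never
inside the data files the pipeline reads.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from datetime import date as Date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import EnvSeries, conductivity_from_salinity
from .growth import (
    PUNCH_POSITIONS,
    GrowthObservation,
    SegmentSample,
    period_of_date,
)
from .incubation import (
    O2_MOLAR_MASS,
    IncubationProtocol,
    IncubationSeries,
)

__all__ = [
    "SimulationConfig",
    "simulate_incubation",
    "simulate_incubations",
    "simulate_growth_cohort",
    "simulate_environment",
    "simulate_calibration_pairs",
    "simulate_driver_scenario",
    "write_run_inputs",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the root seed (order-independent derivation)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


#: Monthly environment targets: (temp mean, temp SD, PAR mean, PAR SD,
#: salinity mean, salinity SD).  Keyed by growth period.
ENV_TARGETS: dict[str, tuple[float, float, float, float, float, float]] = {
    "June": (8.0, 2.0, 227.0, 356.0, 20.2, 1.5),
    "July": (9.7, 1.5, 344.0, 517.0, 21.4, 1.4),
    "early-August": (10.1, 1.2, 333.0, 402.0, 22.0, 1.2),
    "late-August": (9.1, 1.6, 296.0, 365.0, 23.3, 1.4),
    "September": (8.5, 0.9, 255.0, 333.0, 23.8, 0.9),
}

PHOTOPERIOD_H = {"June": 15.5, "July": 15.5, "early-August": 14.5,
                 "late-August": 14.5, "September": 12.5}

#: Incubation campaigns: period -> (n chambers, campaign start date).
INCUBATION_CAMPAIGNS: dict[str, tuple[int, Date]] = {
    "June": (8, Date(2022, 6, 12)),
    "July": (6, Date(2022, 7, 26)),
    "early-August": (6, Date(2022, 8, 19)),
    "September": (6, Date(2022, 9, 20)),
}

#: Cohort visit dates (first = tagging/punching visit).
VISIT_DATES = (
    Date(2022, 5, 25),
    Date(2022, 6, 20),
    Date(2022, 7, 22),
    Date(2022, 8, 15),
    Date(2022, 9, 8),
)

#: Destructive segment samplings: date -> (n individuals, true WW:DW ratio).
SEGMENT_EVENTS: dict[Date, tuple[int, float]] = {
    Date(2022, 5, 27): (7, 10.5),
    Date(2022, 8, 5): (5, 7.3),
    Date(2022, 9, 12): (10, 9.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator (defaults = emulation targets)."""

    seed: int = 0
    # --- incubations ---
    npp_range: tuple[float, float] = (50.0, 350.0)  # umol O2 g^-1 DW h^-1
    r_range: tuple[float, float] = (-75.0, -15.0)
    o2_noise_sd: float = 0.02  # mg/L optode noise
    o2_start: float = 9.0  # mg/L at chamber closure
    dry_weight_range: tuple[float, float] = (4.0, 15.0)  # g per blade
    acclimation_tau_min: float = 3.0
    # --- growth cohort ---
    cohort_size: int = 40
    growth_mean: float = 1.38  # cm/d
    growth_sd: float = 0.55
    erosion_mean: float = 1.0  # cm/d
    erosion_sd: float = 0.3
    hole_noise_sd: float = 0.3  # cm measurement error on hole distances
    blade_noise_sd: float = 0.5  # cm measurement error on blade length
    initial_blade_mean: float = 41.2  # cm at tagging
    initial_blade_sd: float = 8.0
    tag_loss_probability: float = 0.15
    # --- segments / coefficients ---
    b_base_mean: float = 0.88  # g WW per cm
    b_base_cv: float = 0.08
    segment_length_mean: float = 5.0
    segment_length_sd: float = 0.3
    c_avg: float = 0.295  # mg C per mg DW
    c_frac_sd: float = 0.01
    n_frac: float = 0.0155
    n_frac_sd: float = 0.001
    # --- environment ---
    cloud_sigma: float = 0.8  # lognormal sd of multiplicative light noise
    tidal_attenuation: float = 0.15
    diel_temp_amplitude: float = 0.5
    lux_par_coefficient: float = 0.038

    def __post_init__(self) -> None:
        if not 0 <= self.tag_loss_probability <= 1:
            raise ValueError("tag_loss_probability must lie in [0, 1]")
        for name in ("o2_noise_sd", "growth_sd", "erosion_sd", "hole_noise_sd",
                     "blade_noise_sd", "c_frac_sd", "n_frac_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# --- incubations -----------------------------------------------------------

def _flux_to_slope(flux: float, dry_weight: float, volume: float) -> float:
    """Invert the standardisation: per-gram flux -> O2 slope in mg/L/h."""
    return flux * dry_weight / volume * (O2_MOLAR_MASS / 1000.0)


def simulate_incubation(
    config: SimulationConfig,
    true_npp: float,
    true_r: float,
    dry_weight: float,
    period: str,
    incubation_id: str = "sim-001",
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> IncubationSeries:
    """One chamber O2 trace whose phase slopes encode the requested fluxes.

    Dark and light phases are exactly linear with slopes implied by
    ``true_r`` and ``true_npp``; the acclimation interval relaxes
    exponentially (time constant ``acclimation_tau_min``) from the dark to
    the light slope.  Gaussian sensor noise is added on top, so a zero-noise
    series round-trips through the flux estimator exactly.
    """
    if rng is None:
        rng = _rng(config.seed, f"incubation:{incubation_id}")
    noise = config.o2_noise_sd if noise_sd is None else noise_sd
    protocol = IncubationProtocol()
    volume = 20.0

    minutes = np.arange(0.0, protocol.total_minutes + 1.0)
    s_dark = _flux_to_slope(true_r, dry_weight, volume) / 60.0  # mg/L/min
    s_light = _flux_to_slope(true_npp, dry_weight, volume) / 60.0
    tau = config.acclimation_tau_min

    t_dark_end = protocol.dark_minutes
    t_acc_end = t_dark_end + protocol.acclimation_minutes
    o2 = np.empty_like(minutes)
    for i, t in enumerate(minutes):
        if t <= t_dark_end:
            o2[i] = config.o2_start + s_dark * t
        elif t <= t_acc_end:
            dt = t - t_dark_end
            o2[i] = (
                config.o2_start
                + s_dark * t_dark_end
                + s_light * dt
                + (s_dark - s_light) * tau * (1.0 - np.exp(-dt / tau))
            )
        else:
            o2_acc_end = (
                config.o2_start
                + s_dark * t_dark_end
                + s_light * protocol.acclimation_minutes
                + (s_dark - s_light)
                * tau
                * (1.0 - np.exp(-protocol.acclimation_minutes / tau))
            )
            o2[i] = o2_acc_end + s_light * (t - t_acc_end)
    if o2.min() <= 0.2:
        raise ValueError(
            "implied O2 would approach zero within the protocol; shorten the "
            "dark phase or lower |R| / raise the starting concentration"
        )
    if noise > 0:
        o2 = o2 + rng.normal(0.0, noise, size=o2.shape)

    temp = ENV_TARGETS[period][0] + rng.normal(0.0, 0.05, size=o2.shape)
    return IncubationSeries(
        incubation_id=incubation_id,
        period=period,
        minutes=minutes,
        o2=o2,
        temperature=temp,
        dry_weight_g=dry_weight,
        chamber_volume_l=volume,
        protocol=protocol,
    )


def simulate_incubations(
    config: SimulationConfig,
    campaigns: dict[str, tuple[int, Date]] | None = None,
) -> tuple[list[IncubationSeries], pd.DataFrame]:
    """A full season of chamber deployments plus the ground-truth table.

    True NPP and R are drawn uniformly from the configured ranges, dry
    weights uniformly from the blade-size range; campaign dates stagger the
    chambers one day apart.  Returns (series list, truth table) where the
    truth table has one row per incubation with the drawn values.
    """
    campaigns = campaigns or INCUBATION_CAMPAIGNS
    rng = _rng(config.seed, "incubations")
    series: list[IncubationSeries] = []
    truth_rows = []
    for period, (n, start_date) in campaigns.items():
        for i in range(n):
            iid = f"{period}-{i + 1:02d}"
            true_npp = rng.uniform(*config.npp_range)
            true_r = rng.uniform(*config.r_range)
            dw = rng.uniform(*config.dry_weight_range)
            day = start_date + timedelta(days=i)
            start = datetime.combine(day, datetime.min.time()) + timedelta(hours=11)
            series.append(
                simulate_incubation(
                    config, true_npp, true_r, dw, period, incubation_id=iid, rng=rng
                )
            )
            truth_rows.append(
                {
                    "incubation_id": iid,
                    "period": period,
                    "true_npp": true_npp,
                    "true_r": true_r,
                    "true_gpp": true_npp + abs(true_r),
                    "dry_weight_g": dw,
                    "start": start.isoformat(),
                    "end": (start + timedelta(minutes=90)).isoformat(),
                }
            )
    return series, pd.DataFrame(truth_rows)


# --- growth cohort ---------------------------------------------------------

def simulate_growth_cohort(
    config: SimulationConfig,
    visit_dates: tuple[Date, ...] = VISIT_DATES,
) -> tuple[list[GrowthObservation], list[SegmentSample], dict]:
    """Tagged cohort with latent growth, erosion, tag loss and replacement.

    Each individual carries a latent growth rate G per interval (normal,
    truncated at zero) and an erosion rate; holes punched at 10 and 15 cm
    at each visit are displaced by G*dt (plus measurement noise) by the
    next visit, and blade length follows BL' = BL + (G - erosion)*dt.  Lost
    tags (probability per interval) end an individual's record; a
    replacement is tagged at the next visit to keep the cohort size.
    Returns (observations, segment samples, ground truth).
    """
    rng = _rng(config.seed, "growth-cohort")
    observations: list[GrowthObservation] = []
    truth_intervals = []

    next_id = [0]

    def new_individual() -> dict:
        next_id[0] += 1
        return {
            "id": f"kelp-{next_id[0]:03d}",
            "bl": max(10.0, rng.normal(config.initial_blade_mean, config.initial_blade_sd)),
        }

    def observe(ind: dict, d: Date, distances: tuple) -> None:
        """Record a visit: measured old-hole distances + fresh repunch."""
        bl_meas = max(ind["bl"] + rng.normal(0.0, config.blade_noise_sd), 1.0)
        clipped = tuple(
            None if x is None else float(min(max(x, 0.0), bl_meas)) for x in distances
        )
        observations.append(
            GrowthObservation(
                individual_id=ind["id"],
                date=d,
                hole_distances=clipped,
                blade_length=bl_meas,
                holes_repunched=True,  # holes renewed at every visit
            )
        )

    active = [new_individual() for _ in range(config.cohort_size)]
    for ind in active:
        observe(ind, visit_dates[0], (None, None))

    for v0, v1 in zip(visit_dates, visit_dates[1:]):
        dt = (v1 - v0).days
        survivors = []
        for ind in active:
            if rng.uniform() < config.tag_loss_probability:
                continue  # dislodged; record simply stops
            G = max(0.0, rng.normal(config.growth_mean, config.growth_sd))
            erosion = max(0.0, rng.normal(config.erosion_mean, config.erosion_sd))
            midpoint = v0 + (v1 - v0) / 2
            truth_intervals.append(
                {
                    "individual_id": ind["id"],
                    "start": v0.isoformat(),
                    "end": v1.isoformat(),
                    "period": period_of_date(midpoint),
                    "true_G": G,
                    "true_erosion": erosion,
                }
            )
            bl_true = max(5.0, ind["bl"] + (G - erosion) * dt)
            # a hole whose true position has passed the (eroding) apex is gone
            distances = tuple(
                None
                if p + G * dt >= bl_true
                else p + G * dt + rng.normal(0.0, config.hole_noise_sd)
                for p in PUNCH_POSITIONS
            )
            ind["bl"] = bl_true
            observe(ind, v1, distances)
            survivors.append(ind)
        while len(survivors) < config.cohort_size:
            ind = new_individual()
            observe(ind, v1, (None, None))
            survivors.append(ind)
        active = survivors

    segments: list[SegmentSample] = []
    seg_truth = []
    for d, (n, wwdw) in SEGMENT_EVENTS.items():
        for i in range(n):
            length = rng.normal(config.segment_length_mean, config.segment_length_sd)
            ww = config.b_base_mean * length * np.exp(
                rng.normal(0.0, config.b_base_cv)
            )
            dw = ww / wwdw * np.exp(rng.normal(0.0, 0.03))
            c_frac = float(np.clip(rng.normal(config.c_avg, config.c_frac_sd), 0.05, 0.6))
            n_frac = float(np.clip(rng.normal(config.n_frac, config.n_frac_sd), 0.002, 0.05))
            segments.append(
                SegmentSample(
                    individual_id=f"seg-{d.isoformat()}-{i + 1:02d}",
                    date=d,
                    segment_length=float(length),
                    wet_weight=float(ww),
                    dry_weight=float(dw),
                    carbon_fraction=c_frac,
                    nitrogen_fraction=n_frac,
                )
            )
        seg_truth.append(
            {"date": d.isoformat(), "n": n, "true_ww_dw": wwdw,
             "true_b_base": config.b_base_mean}
        )

    truth = {
        "growth_mean": config.growth_mean,
        "growth_sd": config.growth_sd,
        "erosion_mean": config.erosion_mean,
        "intervals": truth_intervals,
        "segments": seg_truth,
        "c_avg": config.c_avg,
        "n_frac": config.n_frac,
    }
    return observations, segments, truth


# --- environment -----------------------------------------------------------

def simulate_environment(
    config: SimulationConfig,
    start: Date | str,
    end: Date | str,
    freq: str = "60min",
    channels: tuple[str, ...] = ("irradiance_par", "irradiance_lux",
                                 "temperature", "conductivity"),
) -> EnvSeries:
    """Moored-logger series over a date range (hourly by default).

    Light is a half-sine diel curve (solar noon at 12:00, day length = the
    monthly photoperiod) times a tidal-attenuation factor (12.42 h period)
    times lognormal cloud noise with unit mean; the deterministic part of
    each month is rescaled so its sample mean hits the monthly target, so
    realised monthly means match the configured ones up to the noise.
    Night-time light is exactly zero.  Conductivity is obtained from the
    target salinity series by numerically inverting the PSS-78 relation, so
    the derived-salinity round trip is exact to solver tolerance.
    """
    idx = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq=freq)
    if idx.empty:
        raise ValueError("empty date range")
    rng = _rng(config.seed, f"environment:{idx[0].isoformat()}:{freq}")

    months = np.array([period_of_date(ts.date()) for ts in idx])
    hours = idx.hour + idx.minute / 60.0
    t_hours = (idx - idx[0]).total_seconds() / 3600.0

    # light: deterministic shape, rescaled per period, times cloud noise
    shape = np.zeros(len(idx))
    for i, (period, h) in enumerate(zip(months, hours)):
        daylen = PHOTOPERIOD_H[period]
        sunrise = 12.0 - daylen / 2.0
        if sunrise <= h <= sunrise + daylen:
            diel = np.sin(np.pi * (h - sunrise) / daylen)
            tide = 1.0 - config.tidal_attenuation * 0.5 * (
                1.0 + np.cos(2.0 * np.pi * t_hours[i] / 12.42)
            )
            shape[i] = diel * tide
    par = np.zeros(len(idx))
    cloud = np.exp(
        rng.normal(-config.cloud_sigma**2 / 2.0, config.cloud_sigma, len(idx))
    )
    for period in np.unique(months):
        mask = months == period
        target = ENV_TARGETS[period][2]
        mean_shape = shape[mask].mean()
        if mean_shape > 0:
            par[mask] = shape[mask] * (target / mean_shape) * cloud[mask]

    temp = np.empty(len(idx))
    sal = np.empty(len(idx))
    for period in np.unique(months):
        mask = months == period
        t_mean, t_sd, _, _, s_mean, s_sd = ENV_TARGETS[period]
        resid_sd = np.sqrt(max(t_sd**2 - config.diel_temp_amplitude**2 / 2.0, 0.01))
        temp[mask] = (
            t_mean
            + config.diel_temp_amplitude * np.sin(2 * np.pi * (hours[mask] - 15) / 24)
            + rng.normal(0.0, resid_sd, mask.sum())
        )
        sal[mask] = np.clip(rng.normal(s_mean, s_sd, mask.sum()), 5.0, 40.0)

    data = {}
    if "irradiance_par" in channels:
        data["irradiance_par"] = par
    if "irradiance_lux" in channels:
        data["irradiance_lux"] = par / config.lux_par_coefficient * np.exp(
            rng.normal(0.0, 0.02, len(idx))
        )
    if "temperature" in channels:
        data["temperature"] = temp
    if "conductivity" in channels:
        data["conductivity"] = np.array(
            [conductivity_from_salinity(s, t) for s, t in zip(sal, temp)]
        )
    return EnvSeries(pd.DataFrame(data, index=idx))


def simulate_calibration_pairs(
    config: SimulationConfig,
    n: int = 500,
    noise_sd: float = 2.0,
    lux_max: float = 12000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (lux, PAR) readings: par = k*lux + Gaussian noise."""
    rng = _rng(config.seed, "calibration-pairs")
    lux = rng.uniform(0.0, lux_max, n)
    par = np.clip(
        config.lux_par_coefficient * lux + rng.normal(0.0, noise_sd, n), 0.0, None
    )
    return lux, par


# --- driver scenarios ------------------------------------------------------

def simulate_driver_scenario(
    config: SimulationConfig,
    n: int = 26,
    coefficients: dict[str, float] | None = None,
    correlation: np.ndarray | None = None,
    target_r2: float | None = None,
    noise_sd: float | None = None,
    response: str = "flux",
) -> tuple[pd.DataFrame, dict]:
    """Regression dataset with known coefficients for attribution testing.

    Standardised predictors (temperature, salinity, light) are drawn from a
    multivariate normal with the requested correlation; the response is the
    configured linear combination plus Gaussian noise.  Either ``noise_sd``
    is given directly, or ``target_r2`` calibrates it so the population
    signal fraction equals the target.  Returns (frame, truth).
    """
    coefficients = coefficients or {"temperature": 0.0, "salinity": 0.0, "light": 0.5}
    names = list(coefficients)
    p = len(names)
    if correlation is None:
        correlation = np.eye(p)
    correlation = np.asarray(correlation, dtype=float)
    try:
        chol = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix must be positive definite")

    rng = _rng(config.seed, "driver-scenario")
    Z = rng.standard_normal((n, p)) @ chol.T
    beta = np.array([coefficients[c] for c in names])
    signal = Z @ beta
    signal_var = float(beta @ correlation @ beta)  # population variance
    if noise_sd is None:
        if target_r2 is None:
            noise_sd = 1.0
        elif not 0 < target_r2 <= 1:
            raise ValueError("target_r2 must lie in (0, 1]")
        elif target_r2 == 1.0:
            noise_sd = 0.0
        else:
            noise_sd = float(np.sqrt(signal_var * (1.0 / target_r2 - 1.0)))
    y = signal + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)

    frame = pd.DataFrame(Z, columns=names)
    frame[response] = y
    truth = {
        "coefficients": dict(coefficients),
        "noise_sd": float(noise_sd),
        "signal_variance": signal_var,
        "population_r2": signal_var / (signal_var + noise_sd**2)
        if (signal_var + noise_sd**2) > 0
        else 0.0,
    }
    return frame, truth


# --- run-directory emission ------------------------------------------------

def write_run_inputs(config: SimulationConfig, outdir: str | Path) -> Path:
    """Emit a complete synthetic run directory.

    Layout: ``incubations/<id>.csv`` (timestamp-free minute series),
    ``incubations_manifest.csv``, ``growth.csv``, ``segments.csv``,
    ``environment.csv``, ``truth.json`` and ``config.json``.  The truth
    sidecar is never read by the analysis stages.
    """
    outdir = Path(outdir)
    (outdir / "incubations").mkdir(parents=True, exist_ok=True)

    series, flux_truth = simulate_incubations(config)
    manifest_rows = []
    for s in series:
        pd.DataFrame(
            {"minute": s.minutes, "o2_mg_per_l": s.o2, "temp_c": s.temperature}
        ).to_csv(outdir / "incubations" / f"{s.incubation_id}.csv", index=False)
        manifest_rows.append(
            {
                "incubation_id": s.incubation_id,
                "period": s.period,
                "dry_weight_g": s.dry_weight_g,
                "chamber_volume_l": s.chamber_volume_l,
            }
        )
    manifest = pd.DataFrame(manifest_rows).merge(
        flux_truth[["incubation_id", "start", "end"]], on="incubation_id"
    )  # deployment times are observable metadata, not ground truth
    manifest.to_csv(outdir / "incubations_manifest.csv", index=False)

    observations, segments, growth_truth = simulate_growth_cohort(config)
    pd.DataFrame(
        [
            {
                "individual_id": o.individual_id,
                "date": o.date.isoformat(),
                "hole1_cm": o.hole_distances[0],
                "hole2_cm": o.hole_distances[1] if len(o.hole_distances) > 1 else None,
                "blade_length_cm": o.blade_length,
                "repunched": o.holes_repunched,
            }
            for o in observations
        ]
    ).to_csv(outdir / "growth.csv", index=False)
    pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "date": s.date.isoformat(),
                "length_cm": s.segment_length,
                "ww_g": s.wet_weight,
                "dw_g": s.dry_weight,
                "c_frac": s.carbon_fraction,
                "n_frac": s.nitrogen_fraction,
            }
            for s in segments
        ]
    ).to_csv(outdir / "segments.csv", index=False)

    env = simulate_environment(config, Date(2022, 6, 1), Date(2022, 9, 28))
    env.to_csv(outdir / "environment.csv")

    truth = {
        "fluxes": flux_truth.to_dict(orient="records"),
        "growth": growth_truth,
        "env_targets": {k: list(v) for k, v in ENV_TARGETS.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2))
    return outdir
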