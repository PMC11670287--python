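"""Run orchestration: simulate -> fluxes -> growth -> budget -> attribution.

Each stage reads and writes plain CSV/JSON in the run directory so any
stage can be rerun or inspected standalone; a manifest records the config
hash, seed and per-stage row counts for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import pandas as pd

from . import carbon
from .attribution import analyze_drivers, assemble_driver_dataset
from .environment import EnvSeries, LuxParCalibration
from .growth import (
    DEFAULT_COEFFICIENTS,
    GrowthObservation,
    PeriodCoefficients,
    PeriodCoefficientTable,
    SegmentSample,
    cohort_rates,
    estimate_b_base,
    ww_dw_ratio,
)
from .incubation import IncubationProtocol, IncubationSeries, compute_fluxes
from .simulate import PHOTOPERIOD_H, SimulationConfig, write_run_inputs

__all__ = ["RunConfig", "run_pipeline", "render_report"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: Path
    input_dir: Path | None = None  # default: <output_dir>/inputs (simulated)
    seed: int = 0
    simulate: bool = True
    pq: float = carbon.DEFAULT_PQ
    pq_mode: str = "divide"
    ww_dw_source: str = "computed"  # "computed" from segments | "fixtures"
    photoperiods: dict[str, float] = field(default_factory=lambda: dict(PHOTOPERIOD_H))
    lux_par_coefficient: float = 0.038
    linearity_r2: float = 0.95

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        if self.pq <= 0:
            raise ValueError("PQ must be positive")
        if self.pq_mode not in ("divide", "multiply"):
            raise ValueError("pq_mode must be 'divide' or 'multiply'")
        if self.ww_dw_source not in ("computed", "fixtures"):
            raise ValueError("ww_dw_source must be 'computed' or 'fixtures'")
        if not self.simulate and self.input_dir is None:
            raise ValueError("input_dir required when simulate=False")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["output_dir"] = None  # hash covers science settings only
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --- input loading ---------------------------------------------------------

def _load_incubations(input_dir: Path) -> list[IncubationSeries]:
    manifest = pd.read_csv(input_dir / "incubations_manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(input_dir / "incubations" / f"{row.incubation_id}.csv")
        out.append(
            IncubationSeries(
                incubation_id=row.incubation_id,
                period=row.period,
                minutes=df["minute"].to_numpy(),
                o2=df["o2_mg_per_l"].to_numpy(),
                temperature=df["temp_c"].to_numpy(),
                dry_weight_g=float(row.dry_weight_g),
                chamber_volume_l=float(row.chamber_volume_l),
                protocol=IncubationProtocol(),
            )
        )
    return out


def _load_growth(input_dir: Path) -> list[GrowthObservation]:
    df = pd.read_csv(input_dir / "growth.csv")
    obs = []
    for _, r in df.iterrows():
        holes = tuple(
            None if pd.isna(r[c]) else float(r[c]) for c in ("hole1_cm", "hole2_cm")
        )
        obs.append(
            GrowthObservation(
                individual_id=str(r.individual_id),
                date=Date.fromisoformat(r.date),
                hole_distances=holes,
                blade_length=float(r.blade_length_cm),
                holes_repunched=bool(r.repunched),
            )
        )
    return obs


def _load_segments(input_dir: Path) -> list[SegmentSample]:
    df = pd.read_csv(input_dir / "segments.csv")
    return [
        SegmentSample(
            individual_id=str(r.individual_id),
            date=Date.fromisoformat(r.date),
            segment_length=float(r.length_cm),
            wet_weight=float(r.ww_g),
            dry_weight=float(r.dw_g),
            carbon_fraction=float(r.c_frac),
            nitrogen_fraction=float(r.n_frac),
        )
        for _, r in df.iterrows()
    ]


def _coefficients_from_segments(
    segments: list[SegmentSample], photoperiods: dict[str, float]
) -> PeriodCoefficientTable:
    """Build the period table from the destructive samplings.

    Each sampling event supplies B_base, WW:DW and C_avg; events map onto
    growth periods by the bracketing rule: the late-May event covers June,
    the early-August event covers July and early August, the September
    event covers late August and September.
    """
    by_event: dict[Date, list[SegmentSample]] = {}
    for s in segments:
        by_event.setdefault(s.date, []).append(s)
    events = sorted(by_event)
    if len(events) != 3:
        raise ValueError(f"expected 3 segment sampling events, got {len(events)}")
    event_periods = {events[0]: ("June",), events[1]: ("July", "early-August"),
                     events[2]: ("late-August", "September")}
    table = {}
    for event, periods in event_periods.items():
        segs = by_event[event]
        b_base, _, _ = estimate_b_base(segs)
        ratio = ww_dw_ratio(segs)
        c_avg = float(pd.Series([s.carbon_fraction for s in segs]).mean())
        for period in periods:
            table[period] = PeriodCoefficients(
                period=period,
                b_base=b_base,
                ww_dw_ratio=ratio,
                c_avg=c_avg,
                photoperiod_h=photoperiods[period],
            )
    return PeriodCoefficientTable(table)


# --- stages ----------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Stage outputs: ``fluxes.csv`` + ``flux_fits.json``, ``growth_rates.csv``
    + ``period_coefficients.json``, ``budget.csv`` + ``fractions.csv``,
    ``attribution.json`` + ``driver_dataset.csv``, ``report.md`` and
    ``manifest.json``.  On a stage failure the completed outputs remain and
    an ``error.json`` is written before the exception propagates.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "inputs"
    try:
        if config.simulate:
            input_dir = config.input_dir or (outdir / "inputs")
            if not (input_dir / "incubations_manifest.csv").exists():
                write_run_inputs(SimulationConfig(seed=config.seed), input_dir)
        else:
            input_dir = config.input_dir

        # flux stage
        stage = "flux"
        series = _load_incubations(input_dir)
        flux_results = [
            compute_fluxes(s, linearity_r2=config.linearity_r2) for s in series
        ]
        fluxes = pd.DataFrame(
            [{
                "incubation_id": r.incubation_id,
                "period": r.period,
                "npp": r.npp,
                "r": r.r,
                "gpp": r.gpp,
                "dry_weight_g": r.dry_weight_g,
                "dark_r2": r.dark_fit.r2,
                "light_r2": r.light_fit.r2,
                "flags": ";".join(r.flags),
            }
            for r in flux_results]
        )
        fluxes.to_csv(outdir / "fluxes.csv", index=False)
        fits = {
            r.incubation_id: {
                "dark": dataclasses.asdict(r.dark_fit),
                "light": dataclasses.asdict(r.light_fit),
            }
            for r in flux_results
        }
        (outdir / "flux_fits.json").write_text(json.dumps(fits, indent=2))
        counts["fluxes"] = len(fluxes)

        # growth stage
        stage = "growth"
        observations = _load_growth(input_dir)
        segments = _load_segments(input_dir)
        if config.ww_dw_source == "computed":
            coeffs = _coefficients_from_segments(segments, config.photoperiods)
        else:
            coeffs = PeriodCoefficientTable(dict(DEFAULT_COEFFICIENTS))
        rates = cohort_rates(observations, coeffs)
        rates.to_csv(outdir / "growth_rates.csv", index=False)
        (outdir / "period_coefficients.json").write_text(
            json.dumps(
                {p: dataclasses.asdict(c) for p, c in coeffs.coefficients.items()},
                indent=2,
            )
        )
        counts["growth_intervals"] = len(rates)

        # budget stage
        stage = "budget"
        bp_by_period = {
            p: sub["bp_mg_dw_per_day"].dropna().tolist()
            for p, sub in rates.dropna(subset=["period"]).groupby("period")
        }
        budget, fractions = carbon.assemble_budget_table(
            flux_results, bp_by_period, coeffs, pq=config.pq, mode=config.pq_mode
        )
        budget.to_csv(outdir / "budget.csv", index=False)
        fractions.to_csv(outdir / "fractions.csv", index=False)
        (outdir / "budget_metadata.json").write_text(
            json.dumps(
                {
                    "pq": config.pq,
                    "pq_mode": config.pq_mode,
                    "photoperiods_h": config.photoperiods,
                    "respiration_scaling": "photoperiod (methodological assumption)",
                    "coefficient_source": config.ww_dw_source,
                },
                indent=2,
            )
        )
        counts["budget_rows"] = len(budget)

        # attribution stage
        stage = "attribution"
        env = EnvSeries.from_csv(input_dir / "environment.csv")
        manifest = pd.read_csv(
            input_dir / "incubations_manifest.csv", parse_dates=["start", "end"]
        )
        windows = {
            r.incubation_id: (r.start, r.end) for r in manifest.itertuples()
        }
        calibration = LuxParCalibration(
            coefficient=config.lux_par_coefficient, n_pairs=10, fit_r2=1.0
        )
        attribution = {}
        driver_frames = []
        for response in ("gpp", "r"):
            ds = assemble_driver_dataset(
                fluxes, env, windows, calibration, response=response
            )
            res = analyze_drivers(ds)
            attribution[response] = {
                "screened_predictors": list(res.screened_predictors),
                "selected_predictors": list(res.selected.subset),
                "coefficients": res.selected.coefficients,
                "selected_r2": res.selected.r2,
                "full_model_r2": res.full_fit.r2,
                "aic_table": [
                    {"subset": list(r.subset), "aic": r.aic, "r2": r.r2}
                    for r in res.aic_table.itertuples()
                ],
                "vif": {k: v for k, v in res.vif_history[0].items()}
                if res.vif_history
                else {},
                "significant_predictors": list(res.significant_predictors),
                "dominance_weights": res.dominance_weights.to_dict(),
                "dominance_pct": res.dominance_pct.to_dict(),
            }
            df = ds.frame.copy()
            df["response"] = response
            driver_frames.append(df)
        (outdir / "attribution.json").write_text(json.dumps(attribution, indent=2))
        pd.concat(driver_frames).to_csv(outdir / "driver_dataset.csv", index=False)
        counts["driver_rows"] = sum(map(len, driver_frames))

        # report + manifest
        stage = "report"
        (outdir / "manifest.json").write_text(
            json.dumps(
                {
                    "config_hash": config.config_hash(),
                    "seed": config.seed,
                    "pq": config.pq,
                    "pq_mode": config.pq_mode,
                    "row_counts": counts,
                },
                indent=2,
            )
        )
        report = render_report(outdir)
        (outdir / "report.md").write_text(report)
    except Exception as exc:
        (outdir / "error.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}, indent=2)
        )
        raise
    return outdir


def _fmt(value, se=None, nd=1) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return "NA"
    if se is None or (isinstance(se, float) and pd.isna(se)):
        return f"{value:.{nd}f}"
    return f"{value:.{nd}f} ± {se:.{nd}f}"


def render_report(run_dir: str | Path) -> str:
    """Deterministic markdown summary of a completed run.

    Budget rows show mean ± SE in mg C/d (one decimal), fractions as
    nearest-integer percentages of GPP; missing cells render as NA.
    """
    run_dir = Path(run_dir)
    needed = ["budget.csv", "fractions.csv", "attribution.json", "manifest.json"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"run directory incomplete; missing {missing}")
    budget = pd.read_csv(run_dir / "budget.csv")
    fractions = pd.read_csv(run_dir / "fractions.csv")
    attribution = json.loads((run_dir / "attribution.json").read_text())
    manifest = json.loads((run_dir / "manifest.json").read_text())

    lines = [
        "# Kelp summer carbon budget",
        "",
        f"Seed {manifest['seed']}, PQ {manifest['pq']} ({manifest['pq_mode']}), "
        f"config {manifest['config_hash']}.",
        "",
        "## Daily carbon rates (mg C / d, mean ± SE)",
        "",
        "| Period | GPP | NPP | R | BP |",
        "|---|---|---|---|---|",
    ]
    for _, r in budget.iterrows():
        lines.append(
            "| {period} | {gpp} | {npp} | {resp} | {bp} |".format(
                period=r["period"],
                gpp=_fmt(r["gpp_mg_c_per_day"], r["gpp_se"]),
                npp=_fmt(r["npp_mg_c_per_day"], r["npp_se"]),
                resp=_fmt(r["r_mg_c_per_day"], r["r_se"]),
                bp=_fmt(r["bp_mg_c_per_day"], r["bp_se"]),
            )
        )
    lines += ["", "## Budget fractions (% of GPP, nearest integer)", ""]
    for _, r in fractions.iterrows():
        lines.append(
            f"- {r['period']}: biomass production bound "
            f"{round(r['bp_over_gpp_pct']) if pd.notna(r['bp_over_gpp_pct']) else 'NA'}% "
            f"of the GPP; respiration consumed {round(r['r_over_gpp_pct'])}%; "
            f"residual (implied dissolved release) "
            f"{round(r['implied_doc_fraction_pct']) if pd.notna(r['implied_doc_fraction_pct']) else 'NA'}%."
        )
    lines += ["", "## Environmental drivers", ""]
    for response, res in attribution.items():
        sel = ", ".join(res["selected_predictors"]) or "none (intercept only)"
        lines.append(
            f"- {response.upper()}: AIC-selected predictors: {sel}; "
            f"selected-model R² = {res['selected_r2']:.2f}, "
            f"full-model R² = {res['full_model_r2']:.2f}."
        )
        for pred, pct in res["dominance_pct"].items():
            lines.append(f"  - {pred}: dominance share {pct:.0f}% of variance")
    lines.append("")
    return "\n".join(lines)
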