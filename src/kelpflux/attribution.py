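"""Relating oxygen fluxes to environmental drivers.

Multiple regression of per-incubation fluxes on daily mean temperature,
daily mean salinity, and incubation-window mean light; collinear predictors
are screened out by variance inflation factor (VIF > 5), the predictor
subset is chosen by AIC over the exhaustive subset lattice, and the selected
model's R-squared is decomposed into per-predictor general dominance
weights by averaging incremental R-squared over all subsets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .environment import EnvSeries, LuxParCalibration, daily_summary, window_mean

__all__ = [
    "DriverDataset",
    "OLSFit",
    "AttributionResult",
    "fit_ols",
    "select_model",
    "vif",
    "vif_screen",
    "dominance_analysis",
    "analyze_drivers",
    "assemble_driver_dataset",
]


@dataclass
class DriverDataset:
    """Response (one flux per incubation) plus predictor columns."""

    frame: pd.DataFrame = field(repr=False)
    response: str = "gpp"
    predictors: tuple[str, ...] = ("temperature", "salinity", "light")

    def __post_init__(self) -> None:
        self.predictors = tuple(self.predictors)
        missing = [c for c in (self.response, *self.predictors) if c not in self.frame]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = self.frame[[self.response, *self.predictors]]
        if sub.isna().any().any():
            raise ValueError("driver dataset contains missing cells")
        if len(sub) <= len(self.predictors) + 1:
            raise ValueError("need n > number of predictors + 1")

    @property
    def n(self) -> int:
        return len(self.frame)

    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    def X(self, subset: Sequence[str] | None = None) -> np.ndarray:
        cols = list(subset if subset is not None else self.predictors)
        return self.frame[cols].to_numpy(dtype=float) if cols else np.empty((self.n, 0))


@dataclass(frozen=True)
class OLSFit:
    """An intercept-including least-squares fit on a predictor subset."""

    subset: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    pvalues: dict[str, float]
    r2: float
    aic: float
    n: int
    rank_deficient: bool = False


def _aic(n: int, rss: float, n_predictors: int) -> float:
    """AIC with the convention n*ln(RSS/n) + 2k, k = predictors + intercept
    + error variance.  Additive constants cancel in subset comparisons."""
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * (n_predictors + 2)


def fit_ols(dataset: DriverDataset, subset: Sequence[str] | None = None) -> OLSFit:
    """Ordinary least squares of the response on a predictor subset."""
    subset = tuple(subset if subset is not None else dataset.predictors)
    X = sm.add_constant(dataset.X(subset), has_constant="add")
    model = sm.OLS(dataset.y(), X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(dataset.X(subset), rowvar=False)
        pairs = [
            (subset[i], subset[j])
            for i in range(len(subset))
            for j in range(i + 1, len(subset))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or subset}")
    res = model.fit()
    names = ("intercept", *subset)
    return OLSFit(
        subset=subset,
        coefficients=dict(zip(names, map(float, res.params))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        r2=float(res.rsquared),
        aic=_aic(dataset.n, float(res.ssr), len(subset)),
        n=dataset.n,
    )


def select_model(dataset: DriverDataset) -> tuple[OLSFit, pd.DataFrame]:
    """Exhaustive AIC search over all predictor subsets (incl. intercept-only).

    Ties are broken toward fewer predictors, then lexicographically, so the
    selection is invariant to predictor ordering.  Returns the winning fit
    and the full AIC table.
    """
    rows = []
    fits = {}
    for r in range(len(dataset.predictors) + 1):
        for subset in itertools.combinations(sorted(dataset.predictors), r):
            fit = fit_ols(dataset, subset)
            fits[subset] = fit
            rows.append({"subset": subset, "k": r, "aic": fit.aic, "r2": fit.r2})
    table = pd.DataFrame(rows).sort_values(
        by=["aic", "k", "subset"], kind="stable"
    ).reset_index(drop=True)
    best = fits[tuple(table.iloc[0]["subset"])]
    return best, table


def _aux_r2(X: np.ndarray, j: int) -> float:
    """R-squared of regressing column j on the remaining columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / tss


def vif(dataset: DriverDataset, predictors: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R2_j).

    R2_j comes from regressing predictor j on the other predictors.  A
    perfectly collinear predictor reports ``inf``.
    """
    preds = tuple(predictors if predictors is not None else dataset.predictors)
    if len(preds) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = dataset.X(preds)
    out = {}
    for j, name in enumerate(preds):
        r2 = _aux_r2(X, j)
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_screen(
    dataset: DriverDataset, threshold: float = 5.0
) -> tuple[tuple[str, ...], list[pd.Series]]:
    """Iteratively drop the highest-VIF predictor above the threshold.

    Returns the retained predictors and the VIF table from each pass.
    """
    kept = list(dataset.predictors)
    history: list[pd.Series] = []
    while len(kept) >= 2:
        v = vif(dataset, kept)
        history.append(v)
        worst = v.idxmax()
        if v[worst] > threshold:
            kept.remove(worst)
        else:
            break
    return tuple(kept), history


def _subset_r2(y: np.ndarray, X: np.ndarray, flag_rank: list[bool]) -> float:
    """Centred R2 of an intercept fit; pseudo-inverse under rank deficiency."""
    design = np.column_stack([np.ones(len(y)), X]) if X.shape[1] else np.ones((len(y), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        beta = np.linalg.pinv(design) @ y
        flag_rank.append(True)
    else:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / tss


def dominance_analysis(
    dataset: DriverDataset, predictors: Sequence[str] | None = None
) -> pd.Series:
    """General dominance weights over all 2^p predictor subsets.

    For predictor j, the incremental R-squared of adding j is averaged over
    every subset not containing j, first within each subset size and then
    across sizes.  The weights sum exactly to the full-model R-squared, so
    each weight reads as the share of explained variance attributable to
    that predictor.
    """
    preds = tuple(predictors if predictors is not None else dataset.predictors)
    p = len(preds)
    if p == 0:
        raise ValueError("no predictors")
    if p > 12:
        raise ValueError("dominance analysis limited to 12 predictors (2^p fits)")
    y = dataset.y()
    flag_rank: list[bool] = []

    r2_cache: dict[frozenset[str], float] = {}
    for r in range(p + 1):
        for subset in itertools.combinations(preds, r):
            r2_cache[frozenset(subset)] = _subset_r2(
                y, dataset.X(subset), flag_rank
            )

    weights = {}
    for j in preds:
        others = [q for q in preds if q != j]
        by_size = []
        for r in range(p):  # size of the base subset
            incs = [
                r2_cache[frozenset(S) | {j}] - r2_cache[frozenset(S)]
                for S in itertools.combinations(others, r)
            ]
            by_size.append(float(np.mean(incs)))
        weights[j] = float(np.mean(by_size))
    out = pd.Series(weights, name="dominance_weight")
    out.attrs["full_model_r2"] = r2_cache[frozenset(preds)]
    out.attrs["rank_deficient_subsets"] = bool(flag_rank)
    return out


@dataclass(frozen=True)
class AttributionResult:
    """Screened, selected and decomposed regression for one flux response."""

    response: str
    screened_predictors: tuple[str, ...]
    vif_history: tuple
    selected: OLSFit
    full_fit: OLSFit
    aic_table: pd.DataFrame
    significant_predictors: tuple[str, ...]
    dominance_weights: pd.Series  # over the selected predictors
    dominance_pct: pd.Series  # weights as percent of variance


def analyze_drivers(dataset: DriverDataset, alpha: float = 0.05) -> AttributionResult:
    """Full attribution pipeline: VIF screen -> AIC selection -> dominance.

    Dominance weights are reported for the "significant" predictors —
    members of the AIC-best model with a coefficient t-test p < alpha —
    computed over the selected model's predictor set.
    """
    kept, history = vif_screen(dataset)
    screened = DriverDataset(dataset.frame, dataset.response, kept)
    full_fit = fit_ols(screened)
    selected, aic_table = select_model(screened)
    significant = tuple(
        name for name in selected.subset if selected.pvalues[name] < alpha
    )
    if selected.subset:
        weights = dominance_analysis(screened, selected.subset)
    else:
        weights = pd.Series(dtype=float, name="dominance_weight")
        weights.attrs["full_model_r2"] = 0.0
    return AttributionResult(
        response=dataset.response,
        screened_predictors=kept,
        vif_history=tuple(history),
        selected=selected,
        full_fit=full_fit,
        aic_table=aic_table,
        significant_predictors=significant,
        dominance_weights=weights,
        dominance_pct=100.0 * weights,
    )


def assemble_driver_dataset(
    fluxes: pd.DataFrame,
    env: EnvSeries,
    incubation_windows: dict[str, tuple],
    calibration: Optional[LuxParCalibration] = None,
    response: str = "gpp",
) -> DriverDataset:
    """Join per-incubation fluxes with their environmental covariates.

    ``fluxes`` needs columns incubation_id and the response; temperature and
    salinity covariates are the daily means of the incubation's calendar day
    (day of the window start) and light is the window mean PAR, converted
    from lux with ``calibration`` when no PAR channel exists.
    """
    rows = []
    missing = []
    for _, rec in fluxes.iterrows():
        iid = rec["incubation_id"]
        if iid not in incubation_windows:
            missing.append(iid)
            continue
        start, end = incubation_windows[iid]
        try:
            daily = daily_summary(env, start)
        except ValueError:
            missing.append(iid)
            continue
        if "irradiance_par" in env.data.columns:
            light = window_mean(env, start, end, "irradiance_par").mean
        else:
            if calibration is None:
                raise ValueError("lux-only light channel requires a calibration")
            light = calibration.convert(
                window_mean(env, start, end, "irradiance_lux").mean
            )
        rows.append(
            {
                "incubation_id": iid,
                response: rec[response],
                "temperature": daily.loc["temperature", "mean"],
                "salinity": daily.loc["salinity", "mean"],
                "light": float(light),
            }
        )
    if missing:
        raise ValueError(f"incubations without matching environment data: {missing}")
    frame = pd.DataFrame(rows)
    return DriverDataset(frame, response=response)
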