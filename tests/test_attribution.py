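"""Regression, VIF screening, AIC selection and dominance analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from kelpflux.attribution import (
    DriverDataset,
    analyze_drivers,
    dominance_analysis,
    fit_ols,
    select_model,
    vif,
    vif_screen,
)
from kelpflux.simulate import SimulationConfig, simulate_driver_scenario


def make_dataset(n=40, seed=0, beta=(1.0, 0.0, 0.0), noise=1.0, corr=None,
                 orthogonalize=False):
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.standard_normal((n, p))
    if corr is not None:
        X = X @ np.linalg.cholesky(corr).T
    if orthogonalize:
        Xc = X - X.mean(axis=0)
        q, _ = np.linalg.qr(Xc)
        X = q  # exactly uncorrelated columns
    y = X @ np.array(beta) + (rng.normal(0, noise, n) if noise else 0.0)
    cols = [f"x{i}" for i in range(p)]
    frame = pd.DataFrame(X, columns=cols)
    frame["y"] = y
    return DriverDataset(frame, response="y", predictors=tuple(cols))


def brute_force_dominance(ds, preds):
    """Independent oracle: statsmodels R2 over explicit subset enumeration."""
    def r2(subset):
        if not subset:
            return 0.0
        X = sm.add_constant(ds.frame[list(subset)])
        return sm.OLS(ds.frame[ds.response], X).fit().rsquared

    weights = {}
    p = len(preds)
    for j in preds:
        others = [q for q in preds if q != j]
        sizes = []
        for r in range(p):
            incs = [
                r2(list(S) + [j]) - r2(list(S))
                for S in itertools.combinations(others, r)
            ]
            sizes.append(np.mean(incs))
        weights[j] = np.mean(sizes)
    return weights


class TestFitOLS:
    def test_response_equal_to_one_predictor(self):
        ds = make_dataset(beta=(1.0, 0.0, 0.0), noise=0.0)
        fit = fit_ols(ds)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients["x0"] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["x1"] == pytest.approx(0.0, abs=1e-8)

    def test_rank_deficient_design_names_columns(self):
        ds = make_dataset(beta=(1.0, 0.0), noise=1.0)
        ds.frame["x1"] = ds.frame["x0"]  # duplicate column
        with pytest.raises(ValueError, match="x0"):
            fit_ols(ds)

    def test_independent_response_matches_brute_force_selection(self):
        # with a pure-noise response the fit explains little, and the chosen
        # subset must agree with an explicit enumeration of all 8 models
        rng = np.random.default_rng(10)
        frame = pd.DataFrame(rng.standard_normal((26, 3)), columns=list("abc"))
        frame["y"] = rng.standard_normal(26)
        ds = DriverDataset(frame, "y", ("a", "b", "c"))
        best, table = select_model(ds)
        assert len(table) == 8  # all subsets enumerated
        assert fit_ols(ds).r2 < 0.3

        def brute_aic(subset):
            X = sm.add_constant(
                ds.frame[list(subset)] if subset else pd.DataFrame(index=ds.frame.index)
            )
            res = sm.OLS(ds.frame["y"], X).fit()
            return 26 * np.log(res.ssr / 26) + 2 * (len(subset) + 2)

        oracle = min(
            (s for r in range(4) for s in itertools.combinations("abc", r)),
            key=lambda s: (brute_aic(s), len(s)),
        )
        assert set(best.subset) == set(oracle)

    def test_aic_selection_order_invariant(self):
        ds1 = make_dataset(seed=4, beta=(0.8, 0.4, 0.0), noise=0.5)
        best1, _ = select_model(ds1)
        ds2 = DriverDataset(ds1.frame, "y", tuple(reversed(ds1.predictors)))
        best2, _ = select_model(ds2)
        assert set(best1.subset) == set(best2.subset)


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        ds = make_dataset(orthogonalize=True)
        assert np.allclose(vif(ds).to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_predictor_is_infinite_and_removed(self):
        ds = make_dataset(beta=(1.0, 0.0), noise=1.0)
        ds.frame["x1"] = ds.frame["x0"]
        v = vif(ds)
        assert np.isinf(v).any()
        kept, _ = vif_screen(ds)
        assert len(kept) == 1

    def test_correlated_design_matches_statsmodels_oracle(self):
        corr = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        ds = make_dataset(n=100, seed=3, beta=(1.0, 0.0, 0.0), corr=corr)
        ours = vif(ds)
        X = sm.add_constant(ds.frame[list(ds.predictors)]).to_numpy()
        for j, name in enumerate(ds.predictors):
            oracle = variance_inflation_factor(X, j + 1)
            assert ours[name] == pytest.approx(oracle, rel=1e-8)

    def test_high_collinearity_triggers_removal(self):
        corr = np.full((2, 2), 0.98)
        np.fill_diagonal(corr, 1.0)
        ds = make_dataset(n=100, seed=6, beta=(1.0, 0.5), corr=corr)
        assert (vif(ds) > 5).all()
        kept, history = vif_screen(ds)
        assert len(kept) == 1 and len(history) >= 1


class TestDominance:
    def test_single_predictor_weight_is_simple_r2(self):
        ds = make_dataset(beta=(0.7,), noise=0.5, seed=2)
        w = dominance_analysis(ds)
        simple = fit_ols(ds, ("x0",)).r2
        assert w["x0"] == pytest.approx(simple, abs=1e-12)

    def test_orthogonal_weights_equal_squared_correlations(self):
        ds = make_dataset(n=60, seed=9, beta=(0.8, 0.5, 0.0), noise=0.7,
                          orthogonalize=True)
        w = dominance_analysis(ds)
        y = ds.frame["y"]
        for name in ds.predictors:
            r = np.corrcoef(ds.frame[name], y)[0, 1]
            assert w[name] == pytest.approx(r**2, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("p", [2, 3])
    def test_agrees_with_brute_force_enumeration(self, seed, p):
        corr = np.full((p, p), 0.4)
        np.fill_diagonal(corr, 1.0)
        ds = make_dataset(n=30, seed=seed, beta=tuple([0.6] * p), corr=corr)
        ours = dominance_analysis(ds)
        oracle = brute_force_dominance(ds, list(ds.predictors))
        for name in ds.predictors:
            assert ours[name] == pytest.approx(oracle[name], abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_weights_sum_to_full_model_r2(self, seed):
        corr = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        ds = make_dataset(n=26, seed=seed, beta=(0.5, 0.3, 0.1), corr=corr)
        w = dominance_analysis(ds)
        full = fit_ols(ds).r2
        assert w.sum() == pytest.approx(full, abs=1e-10)


class TestDriverScenarios:
    def test_zero_noise_recovers_coefficients_exactly(self):
        frame, truth = simulate_driver_scenario(
            SimulationConfig(seed=4), n=30, noise_sd=0.0,
            coefficients={"temperature": 0.4, "salinity": -0.2, "light": 0.7},
        )
        ds = DriverDataset(frame, "flux")
        fit = fit_ols(ds)
        for name, beta in truth["coefficients"].items():
            assert fit.coefficients[name] == pytest.approx(beta, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_light_driven_scenario_selects_light(self):
        # a scenario built so light alone drives the flux at moderate R2
        frame, truth = simulate_driver_scenario(
            SimulationConfig(seed=12), n=26,
            coefficients={"temperature": 0.0, "salinity": 0.0, "light": 0.5},
            target_r2=0.44,
        )
        res = analyze_drivers(DriverDataset(frame, "flux"))
        assert "light" in res.selected.subset
        assert "light" in res.significant_predictors

    def test_mean_fitted_r2_tracks_target_over_replicates(self):
        # adjusted R2 is approximately unbiased for the population R2
        vals = []
        for seed in range(100):
            frame, _ = simulate_driver_scenario(
                SimulationConfig(seed=seed), n=26,
                coefficients={"temperature": 0.4, "salinity": 0.3, "light": 0.0},
                target_r2=0.37,
            )
            ds = DriverDataset(frame, "flux")
            fit = fit_ols(ds)
            k = len(ds.predictors)
            adj = 1 - (1 - fit.r2) * (ds.n - 1) / (ds.n - k - 1)
            vals.append(adj)
        assert np.mean(vals) == pytest.approx(0.37, abs=0.06)

    def test_bad_correlation_matrix_rejected(self):
        with pytest.raises(ValueError):
            simulate_driver_scenario(
                SimulationConfig(seed=1), correlation=np.array([[1.0, 2.0], [2.0, 1.0]]),
                coefficients={"a": 1.0, "b": 1.0},
            )

    def test_dominance_structure_mimics_respiration_scenario(self):
        # two active predictors whose dominance shares add up to the model R2
        frame, _ = simulate_driver_scenario(
            SimulationConfig(seed=21), n=26,
            coefficients={"temperature": 0.45, "salinity": 0.38, "light": 0.0},
            target_r2=0.37,
        )
        res = analyze_drivers(DriverDataset(frame, "flux"))
        w = dominance_analysis(
            DriverDataset(frame, "flux"),
            ("temperature", "salinity", "light"),
        )
        assert w.sum() == pytest.approx(
            fit_ols(DriverDataset(frame, "flux")).r2, abs=1e-10
        )
        assert w["temperature"] + w["salinity"] > w["light"]
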