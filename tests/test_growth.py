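"""Growth rates, erosion bookkeeping, and biomass production."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from kelpflux.growth import (
    GrowthObservation,
    PeriodCoefficients,
    PeriodCoefficientTable,
    SegmentSample,
    biomass_production,
    cohort_rates,
    erosion_rate,
    estimate_b_base,
    linear_growth_rate,
    period_of_date,
    ww_dw_ratio,
)
from kelpflux.simulate import SimulationConfig, simulate_growth_cohort


def obs(iid, d, holes, bl, repunched=False):
    return GrowthObservation(
        individual_id=iid,
        date=d,
        hole_distances=holes,
        blade_length=bl,
        holes_repunched=repunched,
    )


class TestLinearGrowthRate:
    def test_single_hole(self):
        o0 = obs("a", date(2022, 6, 1), (10.0, None), 50.0)
        o1 = obs("a", date(2022, 6, 6), (20.0, None), 55.0)
        r = linear_growth_rate(o0, o1)
        assert r.G == pytest.approx(2.0)
        assert r.elongation_rate == pytest.approx(1.0)
        assert r.erosion_rate == pytest.approx(1.0)

    def test_two_consistent_holes(self):
        o0 = obs("a", date(2022, 6, 1), (10.0, 15.0), 50.0)
        o1 = obs("a", date(2022, 6, 8), (17.0, 22.0), 50.0)
        r = linear_growth_rate(o0, o1)
        assert r.G == pytest.approx(1.0)
        assert r.n_holes_used == 2

    def test_repunched_start_uses_punch_positions(self):
        # visit where holes were renewed: the state carried forward is the
        # punch positions, not the measured (old-hole) distances
        o0 = obs("a", date(2022, 6, 1), (44.0, 49.0), 60.0, repunched=True)
        o1 = obs("a", date(2022, 6, 11), (20.0, 25.0), 60.0)
        r = linear_growth_rate(o0, o1)
        assert r.G == pytest.approx(1.0)  # (20-10)/10 and (25-15)/10

    def test_negative_displacement_excluded_and_flagged(self):
        o0 = obs("a", date(2022, 6, 1), (10.0, 15.0), 50.0)
        o1 = obs("a", date(2022, 6, 6), (20.0, 14.0), 50.0)
        r = linear_growth_rate(o0, o1)
        assert r.G == pytest.approx(2.0)
        assert r.n_holes_used == 1
        assert "negative-hole-displacement" in r.flags

    def test_all_holes_lost_gives_missing_with_reason(self):
        o0 = obs("a", date(2022, 6, 1), (10.0, 15.0), 50.0)
        o1 = obs("a", date(2022, 6, 6), (None, None), 50.0)
        r = linear_growth_rate(o0, o1)
        assert r.G is None and r.reason is not None

    def test_mismatched_individuals_rejected(self):
        o0 = obs("a", date(2022, 6, 1), (10.0,), 50.0)
        o1 = obs("b", date(2022, 6, 6), (20.0,), 50.0)
        with pytest.raises(ValueError):
            linear_growth_rate(o0, o1)

    def test_bookkeeping_identity_holds_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d0, d1 = sorted(rng.uniform(10, 60, 2))
            o0 = obs("a", date(2022, 6, 1), (float(d0),), 80.0)
            o1 = obs("a", date(2022, 6, 9), (float(d1),), float(rng.uniform(60, 90)))
            r = linear_growth_rate(o0, o1)
            assert r.erosion_rate == r.G - r.elongation_rate  # exact identity


class TestSegments:
    def seg(self, length, ww, dw=None, c=0.295, n=0.0155):
        return SegmentSample("s", date(2022, 8, 5), length, ww, dw or ww / 8, c, n)

    def test_b_base_single_segment(self):
        mean, sd, n = estimate_b_base([self.seg(5.0, 4.4)])
        assert mean == pytest.approx(0.88)
        assert sd == 0.0 and n == 1

    def test_b_base_two_segments(self):
        mean, _, _ = estimate_b_base([self.seg(5.0, 4.0), self.seg(5.0, 5.0)])
        assert mean == pytest.approx(0.9)

    def test_ww_dw_ratio(self):
        assert ww_dw_ratio([self.seg(5.0, 10.0, dw=1.0)]) == pytest.approx(10.0)

    def test_ww_dw_ratio_dimensionless(self):
        a = [self.seg(5.0, 8.0, dw=1.0)]
        b = [self.seg(5.0, 8.0 * 3, dw=3.0)]
        assert ww_dw_ratio(a) == pytest.approx(ww_dw_ratio(b))

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            SegmentSample("s", date(2022, 8, 5), 5.0, 4.0, 5.0, 0.3, 0.015)  # DW > WW


class TestBiomassProduction:
    def coeffs(self, b_base=1.0, ratio=10.0):
        return PeriodCoefficients("July", b_base, ratio, 0.295, 15.5)

    def test_round_numbers(self):
        assert biomass_production(1.0, self.coeffs()) == pytest.approx(100.0)

    def test_zero_growth(self):
        assert biomass_production(0.0, self.coeffs()) == 0.0

    def test_hand_arithmetic_july_magnitude(self):
        # 1.38 cm/d * 0.884 g/cm / 7.3 * 1000 = 167.1 mg DW/d
        bp = biomass_production(1.38, self.coeffs(b_base=0.884, ratio=7.3))
        assert bp == pytest.approx(167.1, abs=0.1)

    def test_linearity_and_ratio_scaling(self):
        c = self.coeffs()
        base = biomass_production(1.2, c)
        assert biomass_production(2.4, c) == pytest.approx(2 * base)
        half_ratio = self.coeffs(ratio=5.0)
        assert biomass_production(1.2, half_ratio) == pytest.approx(2 * base)

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            biomass_production(-0.1, self.coeffs())


class TestPeriodAssignment:
    @pytest.mark.parametrize(
        "d,period",
        [
            (date(2022, 6, 15), "June"),
            (date(2022, 7, 20), "July"),
            (date(2022, 8, 3), "early-August"),
            (date(2022, 8, 27), "late-August"),
            (date(2022, 9, 12), "September"),
        ],
    )
    def test_period_mapping(self, d, period):
        assert period_of_date(d) == period

    def test_out_of_season_rejected(self):
        with pytest.raises(ValueError):
            period_of_date(date(2022, 12, 25))

    def test_coefficient_bracketing(self):
        # the late-May sampling covers June; the early-August sampling covers
        # July and early August; the September sampling covers late August
        table = PeriodCoefficientTable.default()
        assert table.for_date(date(2022, 6, 15)).ww_dw_ratio == 10.5
        assert table.for_date(date(2022, 7, 20)).ww_dw_ratio == 7.3
        assert table.for_date(date(2022, 8, 10)).ww_dw_ratio == 7.3
        assert table.for_date(date(2022, 8, 25)).ww_dw_ratio == 9.0


class TestErosion:
    def test_growth_fully_offset_by_erosion(self):
        assert erosion_rate(1.4, 0.0) == pytest.approx(1.4)

    def test_no_erosion(self):
        assert erosion_rate(1.0, 1.0) == 0.0


class TestCohortPipeline:
    def test_zero_noise_unit_growth_blade_lengths_exact(self):
        cfg = SimulationConfig(
            seed=3, growth_mean=1.0, growth_sd=0.0, erosion_mean=0.0,
            erosion_sd=0.0, hole_noise_sd=0.0, blade_noise_sd=0.0,
            tag_loss_probability=0.0, cohort_size=5,
        )
        observations, _, _ = simulate_growth_cohort(cfg)
        rates = cohort_rates(observations)
        assert np.allclose(rates["G_cm_per_day"].astype(float), 1.0)
        assert np.allclose(rates["elongation_cm_per_day"].astype(float), 1.0)
        assert np.allclose(rates["erosion_cm_per_day"].astype(float), 0.0)

    def test_cohort_recovers_generator_means(self):
        cfg = SimulationConfig(seed=7)
        observations, _, truth = simulate_growth_cohort(cfg)
        rates = cohort_rates(observations)
        g = rates["G_cm_per_day"].dropna().astype(float)
        se = g.std() / np.sqrt(len(g))
        assert len(g) >= 15
        assert abs(g.mean() - truth["growth_mean"]) < 3 * se

        ero = rates["erosion_cm_per_day"].dropna().astype(float)
        se_e = ero.std() / np.sqrt(len(ero))
        assert abs(ero.mean() - truth["erosion_mean"]) < 3 * se_e

    def test_erosion_two_cm_per_day_scenario_recovered(self):
        cfg = SimulationConfig(seed=13, erosion_mean=2.0, initial_blade_mean=90.0)
        observations, _, _ = simulate_growth_cohort(cfg)
        rates = cohort_rates(observations)
        ero = rates["erosion_cm_per_day"].dropna().astype(float)
        se = ero.std() / np.sqrt(len(ero))
        assert abs(ero.mean() - 2.0) < 3 * se

    def test_total_tag_loss_leaves_no_measurable_interval(self):
        cfg = SimulationConfig(seed=1, tag_loss_probability=1.0, cohort_size=10)
        observations, _, _ = simulate_growth_cohort(cfg)
        rates = cohort_rates(observations)
        assert rates.empty or rates["G_cm_per_day"].isna().all()

    def test_interval_identity_holds_for_every_row(self):
        observations, _, _ = simulate_growth_cohort(SimulationConfig(seed=2))
        rates = cohort_rates(observations)
        valid = rates.dropna(subset=["G_cm_per_day"])
        resid = (
            valid["G_cm_per_day"]
            - valid["elongation_cm_per_day"]
            - valid["erosion_cm_per_day"]
        )
        assert np.allclose(resid.astype(float), 0.0, atol=1e-12)
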