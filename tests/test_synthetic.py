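"""Generators: determinism, gel round-trip, pre-incubation model, ODE oracle."""

import numpy as np
import pytest

from oggkit import (
    BurstParams,
    eval_burst,
    fit_burst,
    gen_gel_lanes,
    gen_melt,
    gen_preincubated_time_course,
    gen_study,
    gen_time_course,
    quantify_lanes,
    simulate_mechanism,
)
from oggkit.models import DomainError, PreincubationCondition, VariantSpec
from oggkit.synthetic import (
    DEFAULT_TIMES,
    DEFAULT_VARIANTS,
    SUBSTRATE_TOTAL,
    active_fraction,
)


class TestGenTimeCourse:
    def test_zero_noise_reproduces_model_exactly(self, wt_spec):
        tc = gen_time_course(wt_spec, noise_sd=0.0, n_reps=1)[0]
        expect = eval_burst(wt_spec.burst, tc.time)
        assert np.allclose(tc.product, expect, atol=0)

    def test_same_seed_identical_different_seed_distinct(self, wt_spec):
        a = gen_time_course(wt_spec, seed=5)[0]
        b = gen_time_course(wt_spec, seed=5)[0]
        c = gen_time_course(wt_spec, seed=6)[0]
        assert np.array_equal(a.product, b.product)
        assert not np.array_equal(a.product, c.product)

    def test_truncation_to_substrate_total(self):
        spec = VariantSpec("hot", BurstParams(19.9, 5.0, 0.5), tm=42.0)
        for seed in range(20):
            for tc in gen_time_course(spec, noise_sd=2.0, n_reps=3, seed=seed):
                assert tc.product.max() <= SUBSTRATE_TOTAL
                assert tc.product.min() >= 0.0


class TestGelRoundTrip:
    def test_quantification_inverts_generation_at_zero_noise(self, wt_spec):
        tc = gen_time_course(wt_spec, noise_sd=0.3, n_reps=1, seed=3)[0]
        lanes = gen_gel_lanes(tc, noise_cv=0.0)
        back = quantify_lanes(lanes)
        assert np.allclose(back.product, tc.product, atol=1e-10)

    def test_band_fractions_before_noise(self, wt_spec):
        tc = gen_time_course(wt_spec, noise_sd=0.0, n_reps=1)[0]
        lanes = gen_gel_lanes(tc, total_intensity=5000.0)
        frac = lanes.i_product / (lanes.i_product + lanes.i_substrate)
        assert np.allclose(frac, tc.product / tc.substrate_total)

    def test_shared_lane_factor_cancels(self, wt_spec):
        tc = gen_time_course(wt_spec, noise_sd=0.0, n_reps=1)[0]
        lanes = gen_gel_lanes(tc, noise_cv=0.0)
        lanes.i_product *= 2.0
        lanes.i_substrate *= 2.0
        back = quantify_lanes(lanes)
        assert np.allclose(back.product, tc.product, atol=1e-10)

    def test_loading_noise_leaves_quantification_exact(self, wt_spec):
        tc = gen_time_course(wt_spec, noise_sd=0.0, n_reps=1)[0]
        lanes = gen_gel_lanes(tc, noise_cv=0.3, seed=4)
        back = quantify_lanes(lanes)
        assert np.allclose(back.product, tc.product, atol=1e-9)

    def test_dead_lane_dropped_with_warning(self, wt_spec):
        tc = gen_time_course(wt_spec, noise_sd=0.0, n_reps=1)[0]
        lanes = gen_gel_lanes(tc)
        lanes.i_product[2] = 0.0
        lanes.i_substrate[2] = 0.0
        with pytest.warns(UserWarning, match="no signal"):
            back = quantify_lanes(lanes)
        assert back.n_points == tc.n_points - 1


class TestGenMelt:
    def test_zero_noise_midpoint_at_spec_tm(self, wt_spec):
        from oggkit.thermal import two_state_theta

        # grid step chosen so the midpoint temperature is sampled exactly
        grid = np.arange(10.0, 95.0 + 1e-9, 0.2)
        curve = gen_melt(wt_spec, t_grid=grid, noise_sd=0.0, n_reps=1)[0]
        theta_mid = two_state_theta(
            np.array([wt_spec.tm]), wt_spec.tm, wt_spec.dh_vh,
            (-12000.0, 20.0), (-2000.0, 5.0),
        )[0]
        i = np.argmin(np.abs(curve.temperature - wt_spec.tm))
        assert curve.temperature[i] == pytest.approx(wt_spec.tm, abs=1e-9)
        assert curve.theta222[i] == pytest.approx(theta_mid, rel=1e-9)

    def test_fraction_denatured_half_at_midpoint_before_noise(self, wt_spec):
        from oggkit.thermal import fraction_folded

        assert 1.0 - fraction_folded(wt_spec.tm, wt_spec.tm, wt_spec.dh_vh) == pytest.approx(0.5)

    def test_grid_outside_physical_range_rejected(self, wt_spec):
        with pytest.raises(DomainError):
            gen_melt(wt_spec, t_grid=np.linspace(-5, 50, 100))


class TestPreincubation:
    def test_cold_control_is_lossless(self, variants):
        for spec in variants.values():
            f = active_fraction(spec, PreincubationCondition(4.0))
            assert f == pytest.approx(1.0, abs=1e-6)

    def test_unstable_variant_near_zero_after_warm_challenge(self, variants):
        spec = variants["R46Q"]
        f = active_fraction(spec, PreincubationCondition(37.0))
        assert f < 0.1
        tcs = gen_preincubated_time_course(
            spec, PreincubationCondition(37.0), noise_sd=0.0, n_reps=1
        )
        assert tcs[0].product.max() < 0.15 * spec.burst.A0

    def test_full_protection_factor_zero_matches_control(self, variants):
        spec_dict = variants["R46Q"].__dict__ | {"dna_protection": 0.0}
        spec = VariantSpec(**spec_dict)
        cond = PreincubationCondition(
            37.0, competitor_dna=True, competitor_stoichiometry=1.0
        )
        challenged = gen_preincubated_time_course(spec, cond, noise_sd=0.0, n_reps=1)[0]
        control = gen_preincubated_time_course(
            spec, PreincubationCondition(4.0), noise_sd=0.0, n_reps=1
        )[0]
        assert np.allclose(challenged.product, control.product, atol=1e-9)

    def test_k1_unchanged_by_challenge(self, variants):
        spec = variants["S232T"]
        tc = gen_preincubated_time_course(
            spec, PreincubationCondition(37.0), noise_sd=0.0, n_reps=1
        )[0]
        fit = fit_burst(tc)
        assert fit.k1 == pytest.approx(spec.burst.k1, rel=1e-3)
        assert fit.A0 == pytest.approx(
            active_fraction(spec, PreincubationCondition(37.0)) * spec.burst.A0,
            rel=1e-3,
        )


class TestMechanism:
    REGIME = dict(k_on=100.0, k_off=0.01, k_chem=1.4, k_rel=0.005)

    def test_no_chemistry_no_product(self):
        res = simulate_mechanism(k_on=10.0, k_off=1.0, k_chem=0.0, k_rel=0.1)
        assert np.allclose(res.observable, 0.0, atol=1e-9)

    def test_mass_conservation(self):
        res = simulate_mechanism(**self.REGIME, t_grid=np.linspace(0.01, 30, 50))
        assert np.max(np.abs(res.total_dna() - 20.0)) / 20.0 <= 1e-8
        assert np.max(np.abs(res.total_enzyme() - 100.0)) / 100.0 <= 1e-8

    def test_fast_binding_slow_release_matches_closed_form(self):
        """With binding much faster than chemistry and release much slower,
        the mechanistic observable [EP]+[P] follows the closed-form burst
        with A0 = bound substrate (all of it, enzyme in excess),
        k1 = the chemistry rate and a vanishing linear term."""
        t = np.array(DEFAULT_TIMES)
        res = simulate_mechanism(**self.REGIME, t_grid=t)
        closed = eval_burst(BurstParams(20.0, 1.4, 1e-9), t)
        assert np.max(np.abs(res.observable - closed)) <= 0.02 * 20.0

    def test_fit_on_ode_output_recovers_mechanistic_rates(self):
        from oggkit.models import TimeCourse

        t = np.array(DEFAULT_TIMES)
        res = simulate_mechanism(**self.REGIME, t_grid=t)
        tc = TimeCourse(
            variant="ode", condition="std", substrate_total=20.0,
            time=t, product=np.clip(res.observable, 0, 20.0),
            replicate=np.array(["r1"] * t.size),
        )
        fit = fit_burst(tc)
        assert fit.model == "burst"
        assert fit.k1 == pytest.approx(self.REGIME["k_chem"], rel=0.05)
        assert fit.A0 == pytest.approx(20.0, rel=0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            simulate_mechanism(k_on=-1.0, k_off=0.0, k_chem=1.0, k_rel=0.0)


class TestGenStudy:
    def test_bundle_complete_and_deterministic(self):
        a = gen_study(seed=7)
        b = gen_study(seed=7)
        assert sorted(a.kinetics) == sorted(v.name for v in DEFAULT_VARIANTS)
        assert len(a.panel) == 5 * 4
        for name in a.kinetics:
            for ta, tb in zip(a.kinetics[name], b.kinetics[name]):
                assert np.array_equal(ta.product, tb.product)
            for ma, mb in zip(a.melts[name], b.melts[name]):
                assert np.array_equal(ma.theta222, mb.theta222)

    def test_different_seeds_differ_but_recover_same_truth(self, variants):
        a = gen_study(seed=8)
        b = gen_study(seed=9)
        assert not np.array_equal(
            a.kinetics["Wild-type"][0].product, b.kinetics["Wild-type"][0].product
        )
        for bundle in (a, b):
            from oggkit import aggregate_replicates

            fit = fit_burst(aggregate_replicates(bundle.kinetics["Wild-type"]))
            assert fit.A0 == pytest.approx(14.2, abs=1.0)
            assert fit.k1 == pytest.approx(1.4, abs=0.4)

    def test_duplicate_variant_names_rejected(self, wt_spec):
        with pytest.raises(ValueError):
            gen_study(specs=(wt_spec, wt_spec), seed=0)
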