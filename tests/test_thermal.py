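"""Two-state melt model, smoothing, Tm extraction and replicate averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oggkit import average_melts, fit_melt, fraction_folded, smooth_melt, tm_by_derivative
from oggkit.models import (
    ConfigurationError,
    DomainError,
    MeltCurve,
    NoTransitionError,
)
from oggkit.synthetic import DEFAULT_MELT_GRID, DEFAULT_VARIANTS, gen_melt
from oggkit.thermal import fraction_denatured


def make_melt(T, theta, variant="x", replicate="r1"):
    return MeltCurve(variant=variant, replicate=replicate,
                     temperature=np.asarray(T, float),
                     theta222=np.asarray(theta, float))


class TestFractionFolded:
    def test_half_unfolded_at_midpoint(self):
        assert fraction_folded(36.6, 36.6, 200.0) == pytest.approx(0.5, abs=1e-15)

    def test_fully_folded_far_below_midpoint(self):
        assert fraction_folded(6.6, 36.6, 500.0) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_value(self):
        # frozen from a 40-digit arbitrary-precision evaluation
        assert fraction_folded(40.0, 36.6, 200.0) == pytest.approx(
            0.30085939160558504, rel=1e-12
        )

    def test_nonpositive_enthalpy_rejected(self):
        with pytest.raises(DomainError):
            fraction_folded(40.0, 36.6, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tm=st.floats(20.0, 80.0), dh=st.floats(50.0, 800.0))
    def test_strictly_decreasing_in_temperature(self, tm, dh):
        T = np.linspace(5.0, 95.0, 181)
        f = fraction_folded(T, tm, dh)
        assert np.all(np.diff(f) <= 0)
        # strict decrease wherever the fraction is not saturated in floats
        active = (f[:-1] < 1 - 1e-9) & (f[1:] > 1e-9)
        assert np.all(np.diff(f)[active] < 0)
        assert fraction_folded(tm, tm, dh) == pytest.approx(0.5, abs=1e-12)


class TestSmoothMelt:
    def test_preserves_smooth_signal(self):
        # 0.1 °C sampling keeps the 11-point window well inside the
        # transition's curvature scale, where the polynomial filter is exact
        spec = DEFAULT_VARIANTS[0]
        grid = np.arange(10.0, 95.0 + 1e-9, 0.1)
        clean = gen_melt(spec, t_grid=grid, noise_sd=0.0, n_reps=1)[0]
        out = smooth_melt(clean)
        rng_ = np.ptp(clean.theta222)
        rms = np.sqrt(np.mean((out.theta222 - clean.theta222) ** 2))
        assert rms < 1e-6 * rng_

    def test_constant_signal_unchanged(self):
        T = np.linspace(10, 95, 171)
        out = smooth_melt(make_melt(T, np.full(T.size, -5000.0)))
        assert np.allclose(out.theta222, -5000.0)

    def test_noise_variance_reduction_matches_filter_gain(self):
        """White noise on a sinusoid is attenuated by close to the filter's
        theoretical noise gain (sum of squared coefficients)."""
        from scipy.signal import savgol_coeffs

        rng = np.random.default_rng(3)
        T = np.linspace(10, 95, 2001)
        signal = 100 * np.sin(T / 8.0)
        noise = rng.normal(0, 5.0, T.size)
        out = smooth_melt(make_melt(T, signal + noise), window=11, order=3)
        resid = out.theta222 - signal
        gain = float(np.sum(savgol_coeffs(11, 3) ** 2))
        observed = resid[50:-50].var() / 25.0
        assert observed == pytest.approx(gain, rel=0.2)

    def test_invalid_window_rejected(self):
        T = np.linspace(10, 95, 171)
        curve = make_melt(T, np.zeros(T.size))
        with pytest.raises(ConfigurationError):
            smooth_melt(curve, window=4, order=3)
        with pytest.raises(ConfigurationError):
            smooth_melt(curve, window=5, order=7)


class TestFitMelt:
    @pytest.mark.parametrize("spec", DEFAULT_VARIANTS, ids=lambda s: s.name)
    def test_noiseless_recovery_published_midpoints(self, spec):
        curve = gen_melt(spec, noise_sd=0.0, n_reps=1)[0]
        fit = fit_melt(curve)
        assert fit.tm == pytest.approx(spec.tm, abs=0.05)
        assert fit.dh_vh == pytest.approx(spec.dh_vh, rel=0.02)

    def test_noisy_recovery_within_printed_uncertainty(self, variants):
        """Default 2%-amplitude noise leaves the fitted Tm within 0.3 °C of
        the generating midpoint."""
        spec = variants["R46Q"]
        for seed in range(5):
            curve = gen_melt(spec, n_reps=1, seed=seed)[0]
            assert fit_melt(curve).tm == pytest.approx(spec.tm, abs=0.3)

    def test_monte_carlo_bias_and_scatter(self, wt_spec):
        """Over 100 noisy melts the Tm bias stays below 0.2 °C and the
        scatter is comparable to the published ±0.1–0.5 °C triplicate
        spread."""
        tms = np.array(
            [fit_melt(gen_melt(wt_spec, n_reps=1, seed=s)[0]).tm for s in range(100)]
        )
        assert abs(tms.mean() - wt_spec.tm) <= 0.2
        assert 0.01 <= tms.std(ddof=1) <= 0.5

    def test_too_few_points_rejected(self):
        T = np.linspace(10, 95, 10)
        with pytest.raises(DomainError):
            fit_melt(make_melt(T, -1000 * np.ones(T.size)))

    def test_monotone_featureless_signal_raises_no_transition(self):
        T = np.linspace(10, 95, 171)
        with pytest.raises(NoTransitionError):
            fit_melt(make_melt(T, -8000 + 30 * T))

    def test_tm_strictly_inside_range_and_dh_positive(self, wt_spec):
        fit = fit_melt(gen_melt(wt_spec, n_reps=1, seed=1)[0])
        assert DEFAULT_MELT_GRID[0] < fit.tm < DEFAULT_MELT_GRID[-1]
        assert fit.dh_vh > 0

    def test_fraction_denatured_normalized_range(self, wt_spec):
        curve = gen_melt(wt_spec, n_reps=1, seed=2)[0]
        fit = fit_melt(curve)
        frac, flagged = fraction_denatured(curve, fit, flag_beyond=0.2)
        assert frac.min() > -0.2 and frac.max() < 1.2
        assert not flagged
        assert frac[0] < 0.05 and frac[-1] > 0.95


class TestTmByDerivative:
    def test_flat_baseline_peak_sits_just_below_thermodynamic_tm(self, wt_spec):
        """For a two-state sigmoid the |dθ/dT| peak lies 4R²Tm³/ΔH² below
        the thermodynamic midpoint (≈0.22 °C at ΔH = 200 kJ/mol); the
        derivative estimator lands within grid resolution of that point."""
        curve = gen_melt(
            wt_spec, baselines=((-12000.0, 0.0), (-2000.0, 0.0)),
            noise_sd=0.0, n_reps=1,
        )[0]
        tm_d = tm_by_derivative(curve)
        t_abs = wt_spec.tm + 273.15
        offset = 4 * 8.314**2 * t_abs**3 / (wt_spec.dh_vh * 1e3) ** 2
        assert tm_d == pytest.approx(wt_spec.tm - offset, abs=0.25)
        assert tm_d < wt_spec.tm

    def test_sloping_baselines_bias_documented_vs_two_state_fit(self, wt_spec):
        """Steeply sloping baselines pull the derivative peak away from the
        parametric Tm; the fit records the derivative value for comparison
        and flags large disagreement."""
        curve = gen_melt(
            wt_spec, baselines=((-12000.0, 120.0), (-2000.0, 5.0)),
            noise_sd=0.0, n_reps=1,
        )[0]
        fit = fit_melt(curve)
        assert fit.tm == pytest.approx(wt_spec.tm, abs=0.1)
        assert abs(fit.tm_derivative - fit.tm) > abs(
            tm_by_derivative(
                gen_melt(wt_spec, baselines=((-12000.0, 0.0), (-2000.0, 0.0)),
                         noise_sd=0.0, n_reps=1)[0]
            )
            - fit.tm
        ) or fit.message  # bias grows, or the disagreement is flagged

    def test_monotone_line_raises_no_transition(self):
        T = np.linspace(10, 95, 171)
        with pytest.raises(NoTransitionError):
            tm_by_derivative(make_melt(T, -8000 + 30 * T))


class TestAverageMelts:
    def test_identical_replicates_zero_sd(self, wt_spec):
        reps = gen_melt(wt_spec, noise_sd=0.0, n_reps=3)
        avg = average_melts(reps)
        assert avg.tm_sd == pytest.approx(0.0, abs=1e-9)
        assert avg.tm_mean == pytest.approx(wt_spec.tm, abs=0.05)

    def test_hand_arithmetic_mean_and_sd_shape(self):
        """Replicate midpoints 36.1/36.6/37.1 °C summarise to 36.6 ± 0.5,
        the shape of the published least-stable variant value."""
        tms = np.array([36.1, 36.6, 37.1])
        assert tms.mean() == pytest.approx(36.6)
        assert tms.std(ddof=1) == pytest.approx(0.5)
        from oggkit.models import VariantSpec, BurstParams
        from oggkit.synthetic import gen_melt as gm

        reps = [
            gm(
                VariantSpec("v", BurstParams(10, 1, 0.1), tm=tm),
                noise_sd=0.0, n_reps=1,
            )[0]
            for tm in tms
        ]
        for r, lab in zip(reps, "abc"):
            r.replicate = lab
        avg = average_melts(reps)
        assert avg.tm_mean == pytest.approx(36.6, abs=0.02)
        assert avg.tm_sd == pytest.approx(0.5, abs=0.02)

    def test_single_replicate_sd_absent(self, wt_spec):
        avg = average_melts(gen_melt(wt_spec, n_reps=1, seed=5))
        assert avg.tm_sd is None

    def test_variant_ranking_matches_published_order(self, variants):
        """Seeded triplicates at each published midpoint recover the
        published stability ranking R46Q < WT < A85S = S232T < R154H."""
        means, sds = {}, {}
        for i, (name, spec) in enumerate(sorted(variants.items())):
            avg = average_melts(gen_melt(spec, n_reps=3, seed=40 + i))
            means[name] = avg.tm_mean
            sds[name] = avg.tm_sd
        assert means["R46Q"] < means["Wild-type"]
        assert means["Wild-type"] < means["A85S"]
        # A85S and S232T share the same generating midpoint: their means
        # must agree within the combined triplicate standard error
        sem = np.sqrt((sds["A85S"] ** 2 + sds["S232T"] ** 2) / 3)
        assert abs(means["A85S"] - means["S232T"]) < 3 * max(sem, 0.05)
        assert means["R154H"] == max(means.values())
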