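"""Reference pathway transfer functions, balanced truncation, impulse
timing, fixed-order estimation and the nested chi-square comparison."""

import numpy as np
import pytest

from nvugrey import (
    RationalTF,
    balanced_truncate,
    chi2_goodness_of_fit,
    impulse_peak_time,
    nested_tf_comparison,
    reference_tf,
    tf_estimate,
)
from nvugrey.errors import InstabilityError, ValidationError
from nvugrey.reduction import EXPECTED_COUNTS, TFFit
from nvugrey.synth import generate_tf_dataset
from nvugrey.tdcs_input import StimulusWaveform


def _random_stable_system(rng, n):
    A = rng.standard_normal((n, n))
    A -= (np.max(np.linalg.eigvals(A).real) + 0.5 + rng.uniform()) * np.eye(n)
    B = rng.standard_normal((n, 1))
    C = rng.standard_normal((1, n))
    return A, B, C, np.zeros((1, 1))


class TestReferenceTFs:
    @pytest.mark.parametrize("pathway,counts", sorted(EXPECTED_COUNTS.items()))
    def test_pole_zero_counts(self, pathway, counts):
        tf = reference_tf(pathway)
        assert (tf.n_poles, tf.n_zeros) == counts

    def test_input_filter_cascade_adds_one_pole(self):
        tf = reference_tf(3, include_input_filter=True)
        assert (tf.n_poles, tf.n_zeros) == (9, 2)
        assert np.min(np.abs(tf.poles + 50.0)) < 1e-9   # pole at -1/tau

    @pytest.mark.parametrize("pathway", [1, 2, 3, 4])
    def test_all_poles_stable_including_complex_pair(self, pathway):
        tf = reference_tf(pathway)
        assert np.all(tf.poles.real < 0.0)
        cplx = tf.poles[np.abs(tf.poles.imag) > 0]
        assert len(cplx) == 2   # the conjugate pair of s^2 + 9.804 s + 95.24
        imag = np.sqrt(95.24 - (9.804 / 2.0) ** 2)
        np.testing.assert_allclose(np.sort(cplx.imag), [-imag, imag],
                                   rtol=1e-9)
        np.testing.assert_allclose(cplx.real, -9.804 / 2.0, rtol=1e-9)

    def test_nesting_pathway3_poles_inside_pathway2(self):
        p2 = reference_tf(2).poles
        for p in reference_tf(3).poles:
            assert np.min(np.abs(p2 - p)) < 1e-9 * max(1.0, abs(p))

    def test_unit_peak_normalization(self):
        tf = reference_tf(4, unit_peak=True)
        t = np.arange(0.0, 30.0, 1e-3)
        assert np.max(np.abs(tf.impulse_response(t))) == pytest.approx(1.0,
                                                                       rel=1e-9)


class TestImpulsePeak:
    def test_double_pole_closed_form(self):
        # 1/(s+a)^2 peaks at t = 1/a
        tf = RationalTF.from_pzk([], [-1.0, -1.0], 1.0)
        assert impulse_peak_time(tf, horizon=10.0) == pytest.approx(1.0,
                                                                    abs=1e-3)

    def test_smc_pathway_peaks_near_0p4_seconds(self):
        t = impulse_peak_time(reference_tf(4), horizon=30.0)
        assert t == pytest.approx(0.4, rel=0.25)

    def test_synaptic_pathway_peaks_near_5_seconds(self):
        t = impulse_peak_time(reference_tf(1), horizon=60.0)
        assert t == pytest.approx(5.0, rel=0.25)

    def test_peak_time_ordering_follows_nesting(self):
        t4 = impulse_peak_time(reference_tf(4), horizon=30.0)
        t3 = impulse_peak_time(reference_tf(3), horizon=60.0)
        t2 = impulse_peak_time(reference_tf(2), horizon=60.0)
        t1 = impulse_peak_time(reference_tf(1), horizon=60.0)
        assert t4 < t3 <= t2 < t1

    def test_short_horizon_warns_boundary_peak(self):
        tf = RationalTF.from_pzk([], [-0.01], 0.01)
        with pytest.warns(RuntimeWarning, match="boundary"):
            impulse_peak_time(tf, horizon=0.5)

    def test_unstable_tf_rejected(self):
        with pytest.raises(InstabilityError):
            impulse_peak_time(RationalTF.from_pzk([], [0.1], 1.0))

    def test_impulse_integral_equals_dc_gain(self):
        tf = reference_tf(4)
        t = np.arange(0.0, 60.0, 1e-3)
        h = tf.impulse_response(t)
        assert np.trapezoid(h, t) == pytest.approx(tf.dc_gain(), rel=1e-3)


class TestRationalTF:
    def test_coefficients_consistent_with_roots(self):
        tf = RationalTF.from_pzk([-2.0], [-1.0, -3.0, -5.0], 4.0)
        np.testing.assert_allclose(np.sort(np.roots(tf.num)), [-2.0],
                                   atol=1e-8)
        np.testing.assert_allclose(np.sort(np.roots(tf.den)),
                                   [-5.0, -3.0, -1.0], atol=1e-8)

    def test_improper_tf_rejected(self):
        with pytest.raises(Exception):
            RationalTF.from_pzk([-1.0, -2.0], [-1.0], 1.0)

    def test_serialization_round_trip(self):
        tf = reference_tf(2)
        back = RationalTF.from_dict(tf.to_dict())
        np.testing.assert_allclose(np.sort_complex(back.poles),
                                   np.sort_complex(tf.poles))
        assert back.gain == tf.gain


class TestBalancedTruncation:
    def test_full_order_reduction_is_exact(self):
        rng = np.random.default_rng(0)
        A, B, C, D = _random_stable_system(rng, 6)
        red, rep = balanced_truncate((A, B, C, D), order=6)
        w = np.logspace(-2, 2, 30)
        from nvugrey.linearize import LinearModel
        full = LinearModel(A=A, B=B, C=C, D=D,
                           state_labels=tuple(map(str, range(6))))
        np.testing.assert_allclose(np.abs(red.frequency_response(w)),
                                   np.abs(full.frequency_response(w)),
                                   rtol=1e-7)

    def test_error_bound_holds_on_random_systems(self):
        rng = np.random.default_rng(1)
        w = np.logspace(-3, 3, 200)
        for _ in range(20):
            A, B, C, D = _random_stable_system(rng, 10)
            red, rep = balanced_truncate((A, B, C, D), order=4)
            from nvugrey.linearize import LinearModel
            full = LinearModel(A=A, B=B, C=C, D=D,
                               state_labels=tuple(map(str, range(10))))
            err = np.max(np.abs(full.frequency_response(w)
                                - red.frequency_response(w)))
            assert err <= rep.error_bound * (1 + 1e-6)

    def test_negligible_state_dropped_cleanly(self):
        # two-state system, one nearly unreachable state
        A = np.diag([-1.0, -50.0])
        B = np.array([[1.0], [1e-5]])
        C = np.array([[1.0, 1e-5]])
        red, rep = balanced_truncate((A, B, C, np.zeros((1, 1))), order=1)
        assert red.order == 1
        assert rep.dc_gain_error < 1e-6
        assert rep.hankel_singular_values[1] < 1e-9

    def test_hankel_values_sorted_nonnegative(self, pathway_models):
        red, rep = balanced_truncate(pathway_models[3], order=6)
        hsv = rep.hankel_singular_values
        assert np.all(np.diff(hsv) <= 1e-12)
        assert np.all(hsv >= -1e-12)

    def test_unstable_system_needs_modal_split(self):
        A = np.diag([1.0, -2.0, -3.0])
        B = np.ones((3, 1))
        C = np.ones((1, 3))
        with pytest.raises(InstabilityError):
            balanced_truncate((A, B, C, np.zeros((1, 1))), order=2,
                              allow_modal_split=False)
        red, rep = balanced_truncate((A, B, C, np.zeros((1, 1))), order=2)
        assert rep.stable_split
        assert np.max(np.linalg.eigvals(red.A).real) == pytest.approx(1.0)

    def test_tolerance_driven_order_selection(self, pathway_models):
        red, rep = balanced_truncate(pathway_models[3], tolerance=1e-2)
        tail = 2.0 * np.sum(rep.hankel_singular_values[rep.retained_order:])
        assert tail <= 1e-2
        assert red.order < 17


class TestTfEstimate:
    def test_noiseless_recovery_from_true_initialization(self):
        true = RationalTF.from_pzk([-2.0], [-0.2, -1.0, -5.0], 3.0)
        stim = StimulusWaveform(1.0, 30.0, 120.0, 0.0)
        ds = generate_tf_dataset(true, stim, np.inf, 0, t_end=150.0)
        fit = tf_estimate(ds.u, ds.y, 3, 1, dt=ds.dt, init=true)
        assert fit.mse < 1e-12
        np.testing.assert_allclose(np.sort(fit.tf.poles.real),
                                   [-5.0, -1.0, -0.2], rtol=1e-6)
        np.testing.assert_allclose(fit.tf.zeros.real, [-2.0], rtol=1e-6)

    def test_mse_never_increases_with_order_when_warm_started(self):
        true = reference_tf(3, include_input_filter=True)
        stim = StimulusWaveform(1.0, 30.0, 120.0, 0.0)
        ds = generate_tf_dataset(true, stim, 10.0, 3, t_end=150.0)
        prev_mse = np.inf
        prev_tf = None
        for n_p, n_z in [(7, 1), (9, 2), (11, 3)]:
            init = prev_tf if prev_tf is not None else reference_tf(
                4, include_input_filter=True)
            fit = tf_estimate(ds.u, ds.y, n_p, n_z, dt=ds.dt, init=init,
                              max_nfev=120)
            # nested least squares: non-increase up to optimizer tolerance
            assert fit.mse <= prev_mse * 1.05
            prev_mse, prev_tf = fit.mse, fit.tf

    def test_invalid_order_rejected(self):
        with pytest.raises(ValidationError):
            tf_estimate(np.ones(100), np.ones(100), 2, 2)


class TestChi2:
    def test_perfect_fit_scores_zero(self):
        y = np.sin(np.linspace(0, 5, 100))
        assert chi2_goodness_of_fit(y, y) == 0.0

    def test_mean_prediction_scores_one(self):
        y = np.sin(np.linspace(0, 5, 100))
        assert chi2_goodness_of_fit(y, np.full_like(y, y.mean())) == \
            pytest.approx(1.0)

    def test_constant_output_rejected(self):
        with pytest.raises(ValidationError):
            chi2_goodness_of_fit(np.ones(50), np.ones(50))

    def test_nested_difference_test_prefers_parsimony_when_tied(self):
        def fake(n_p, chi2):
            tf = RationalTF.from_pzk([], list(-np.arange(1, n_p + 1)), 1.0)
            return TFFit(tf=tf, mse=chi2, chi2=chi2, n_free=n_p + 1,
                         converged=True)
        fits = [fake(7, 0.0101), fake(9, 0.0100), fake(11, 0.0099)]
        out = nested_tf_comparison(fits, n_samples=1500)
        assert out["selected_order"] == 7

    def test_nested_difference_test_detects_real_improvement(self):
        def fake(n_p, chi2):
            tf = RationalTF.from_pzk([], list(-np.arange(1, n_p + 1)), 1.0)
            return TFFit(tf=tf, mse=chi2, chi2=chi2, n_free=n_p + 1,
                         converged=True)
        fits = [fake(7, 0.20), fake(9, 0.010), fake(11, 0.0099)]
        out = nested_tf_comparison(fits, n_samples=1500)
        assert out["selected_order"] == 9
        assert out["trace"][0]["larger_preferred"]

    def test_nested_selection_recovery_on_perivascular_data(self):
        """Data from the composed perivascular TF: the difference test never
        prefers the over-parameterized orders (11/3, 12/3) over 9/2, and
        9/2 ties-or-beats 7/1 on raw chi-square."""
        true = reference_tf(3, include_input_filter=True)
        stim = StimulusWaveform(1.0, 30.0, 120.0, 0.0)
        inits = {7: reference_tf(4, include_input_filter=True),
                 9: reference_tf(3, include_input_filter=True),
                 11: reference_tf(2, include_input_filter=True),
                 12: reference_tf(1, include_input_filter=True)}
        orders = [(7, 1), (9, 2), (11, 3), (12, 3)]
        ok_over = 0
        ok_under = 0
        n_rep = 10
        for seed in range(n_rep):
            ds = generate_tf_dataset(true, stim, 10.0, seed, t_end=150.0)
            fits = []
            prev = None
            for n_p, n_z in orders:
                init = prev if prev is not None else inits[n_p]
                f = tf_estimate(ds.u, ds.y, n_p, n_z, dt=ds.dt, init=init,
                                max_nfev=100)
                fits.append(f)
                prev = f.tf
            out = nested_tf_comparison(fits, n_samples=len(ds.y))
            ok_over += int(out["selected_order"] <= 9)
            ok_under += int(fits[1].chi2 <= fits[0].chi2 * 1.05)
        assert ok_over >= int(0.8 * n_rep)
        assert ok_under >= int(0.8 * n_rep)
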