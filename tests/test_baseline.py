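"""Baseline estimators vs dense/normal-equation oracles and invariants."""

import numpy as np
import pytest

import oracles
from voltkit import (AlsParams, FitError, InputError, Mode, ParameterError,
                     ValidationError, Voltammogram, als_baseline,
                     poly_baseline, segmented_linear_baseline, split_sweeps,
                     subtract_baseline)
from voltkit.synthetic import DpvSpec, simulate_dpv


class TestPolyBaseline:
    def test_exact_quadratic_fully_removed(self):
        x = np.linspace(-0.2, 0.8, 60)
        y = 1.5 - 2.0 * x + 4.0 * x ** 2
        est = poly_baseline(x, y, degree=2)
        np.testing.assert_allclose(est.corrected, 0.0, atol=1e-9)

    def test_degree_zero_is_mean(self, rng):
        x = np.linspace(0, 1, 25)
        y = rng.normal(size=25)
        est = poly_baseline(x, y, degree=0)
        np.testing.assert_allclose(est.baseline, np.mean(y), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.sort(rng.uniform(-0.3, 0.9, 80))
        y = rng.normal(scale=3.0, size=80)
        est = poly_baseline(x, y, degree=2)
        expected = oracles.normal_equations_polyfit(x, y, 2)
        np.testing.assert_allclose(est.baseline, expected, rtol=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            poly_baseline([0, 1, 2], [0, 1, 2], degree=-1)
        with pytest.raises(FitError):
            poly_baseline(np.ones(10), np.arange(10.0), degree=2)
        with pytest.raises(InputError):
            poly_baseline([0.0, 1.0], [0.0, 1.0], degree=3)


def _cv_linear_trace(m=2.0, q=1.0, peak_amp=0.0):
    fwd = np.linspace(-0.2, 0.8, 101)
    pot = np.concatenate([fwd, fwd[::-1][1:]])
    cur = q + m * pot
    if peak_amp:
        cur = cur + np.concatenate([
            peak_amp * np.exp(-((fwd - 0.3) ** 2) / (2 * 0.08 ** 2)),
            np.zeros(100),
        ])
    return Voltammogram(pot, cur, Mode.CV)


class TestSegmentedLinearBaseline:
    def test_linear_sweep_fully_removed(self):
        v = _cv_linear_trace()
        est = segmented_linear_baseline(v, split_sweeps(v), 0.2)
        np.testing.assert_allclose(est.corrected, 0.0, atol=1e-9)

    def test_recovers_background_slope_under_peak(self):
        m = 2.0
        v = _cv_linear_trace(m=m, peak_amp=5.0)
        seg = split_sweeps(v)
        est = segmented_linear_baseline(v, seg, 0.2)
        lo, hi = seg.forward
        slope = np.polyfit(v.potentials[lo:hi], est.baseline[lo:hi], 1)[0]
        assert slope == pytest.approx(m, rel=0.02)

    def test_half_fraction_equals_poly_degree_one_per_sweep(self):
        v = _cv_linear_trace(m=-1.3, q=0.4)
        seg = split_sweeps(v)
        est = segmented_linear_baseline(v, seg, 0.5)
        lo, hi = seg.forward
        # on a peak-free linear sweep the half-window line is the same
        # straight line a global degree-1 fit of that sweep finds
        ref = poly_baseline(v.potentials[lo:hi], v.currents[lo:hi], 1)
        np.testing.assert_allclose(est.baseline[lo:hi], ref.baseline,
                                   atol=1e-8)

    def test_monotone_trace_forward_only_with_warning(self):
        pot = np.linspace(0, 1, 30)
        v = Voltammogram(pot, 1 + 2 * pot, Mode.CV)
        est = segmented_linear_baseline(v, split_sweeps(v), 0.3)
        assert est.diagnostics["warnings"]
        np.testing.assert_allclose(est.corrected, 0.0, atol=1e-9)

    def test_bad_edge_fraction(self, cv_trace):
        trace, _ = cv_trace
        seg = split_sweeps(trace)
        for frac in (0.0, 0.6, -0.1):
            with pytest.raises(ParameterError):
                segmented_linear_baseline(trace, seg, frac)


class TestAlsBaseline:
    def test_constant_signal_is_its_own_baseline(self):
        y = np.full(30, 2.5)
        est = als_baseline(y, AlsParams(lam=100.0))
        np.testing.assert_allclose(est.baseline, y, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle_every_iteration(self, seed):
        r = np.random.default_rng(seed)
        y = r.normal(size=50) + np.linspace(0, 3, 50)
        lam, p = 100.0, 0.05
        expected = oracles.dense_als_iterations(y, lam, p, max_iter=8)
        for k, z in enumerate(expected, start=1):
            est = als_baseline(y, AlsParams(lam=lam, p=p, max_iter=k))
            np.testing.assert_allclose(est.baseline, z, rtol=1e-8)
            assert est.diagnostics["iterations"] == k

    def test_first_iteration_is_symmetric_whittaker(self, rng):
        y = rng.normal(size=50)
        est = als_baseline(y, AlsParams(lam=500.0, max_iter=1))
        np.testing.assert_allclose(est.baseline,
                                   oracles.whittaker_dense(y, 500.0),
                                   rtol=1e-8)

    def test_huge_lambda_flattens_second_differences(self, rng):
        y = rng.normal(scale=2.0, size=120) + 5 * np.sin(np.linspace(0, 6, 120))
        est = als_baseline(y, AlsParams(lam=1e12, max_iter=1))
        assert np.max(np.abs(np.diff(est.baseline, n=2))) < 1e-6 * np.ptp(y)

    def test_recovers_drift_under_peak(self):
        spec = DpvSpec(seed=3, bg_decay_amplitude=0.0, noise_sigma=0.1)
        trace, truth = simulate_dpv(spec)
        est = als_baseline(trace.currents)
        outside = np.abs(trace.potentials - spec.peak_center) > 3 * spec.peak_width
        err = np.abs(est.baseline - truth.background)[outside]
        assert np.max(err) < 3 * spec.noise_sigma

    def test_asymmetry_pushes_baseline_below_signal(self, rng):
        y = rng.normal(size=150) + np.linspace(0, 2, 150)
        above = []
        for p in (0.5, 0.1, 0.01, 0.001):
            est = als_baseline(y, AlsParams(lam=1e4, p=p))
            above.append(np.mean(est.baseline > y + 1e-9))
        assert all(a >= b - 1e-12 for a, b in zip(above, above[1:]))
        assert above[-1] < 0.05

    def test_parameter_validation(self):
        for bad in (dict(lam=0), dict(lam=-5), dict(p=0.0), dict(p=1.0),
                    dict(max_iter=0), dict(tol=-1)):
            with pytest.raises(ParameterError):
                AlsParams(**bad)
        with pytest.raises(ValidationError):
            als_baseline(np.array([1.0, np.nan, 2.0, 3.0]))
        with pytest.raises(InputError):
            als_baseline(np.array([1.0, 2.0, 3.0]))


@pytest.mark.parametrize("method", ["poly", "segmented", "als"])
def test_translation_equivariance(method, rng):
    """Shifting the current by a constant shifts the baseline identically."""
    shift = 7.5
    if method == "poly":
        x = np.linspace(0, 1, 60)
        y = rng.normal(size=60)
        b0 = poly_baseline(x, y, 2).baseline
        b1 = poly_baseline(x, y + shift, 2).baseline
    elif method == "segmented":
        v = _cv_linear_trace(peak_amp=5.0)
        noisy = v.with_currents(v.currents + rng.normal(0, 0.1, len(v)))
        seg = split_sweeps(noisy)
        b0 = segmented_linear_baseline(noisy, seg, 0.2).baseline
        b1 = segmented_linear_baseline(
            noisy.with_currents(noisy.currents + shift), seg, 0.2).baseline
    else:
        y = rng.normal(size=80) + np.linspace(0, 4, 80)
        b0 = als_baseline(y, AlsParams(lam=1e4)).baseline
        b1 = als_baseline(y + shift, AlsParams(lam=1e4)).baseline
    np.testing.assert_allclose(b1 - b0, shift, atol=1e-6)


class TestSubtractBaseline:
    def test_signal_equal_to_baseline_gives_zero(self):
        y = np.linspace(1, 2, 30)
        est = als_baseline(y, AlsParams(lam=10.0, max_iter=1))
        np.testing.assert_allclose(subtract_baseline(y, est)
                                   + est.baseline, y, atol=0)

    def test_reconstruction_is_bitwise(self, dpv_trace):
        trace, _ = dpv_trace
        est = als_baseline(trace.currents)
        assert np.array_equal(est.baseline + est.corrected, trace.currents)

    def test_length_mismatch(self, dpv_trace):
        trace, _ = dpv_trace
        est = als_baseline(trace.currents)
        with pytest.raises(InputError):
            subtract_baseline(trace.currents[:-1], est)
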