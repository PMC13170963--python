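"""Smoothing, transient trimming, sweep segmentation, scan selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from voltkit import (InputError, Mode, ParameterError, SmoothingParams,
                     Voltammogram, savitzky_golay_smooth, select_stable_scan,
                     split_sweeps, trim_initial)


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        y = np.full(21, 3.7)
        out = savitzky_golay_smooth(y, SmoothingParams(5, 2))
        np.testing.assert_allclose(out, y, atol=1e-12)

    def test_linear_series_reproduced(self):
        x = np.arange(30, dtype=float)
        y = 2 * x + 1
        out = savitzky_golay_smooth(y, SmoothingParams(7, 2))
        np.testing.assert_allclose(out, y, atol=1e-10)

    @pytest.mark.parametrize("window,order", [(5, 2), (11, 3), (9, 4)])
    def test_polynomial_reproduction_including_edges(self, window, order):
        x = np.linspace(-1, 1, 40)
        y = sum(c * x ** k for k, c in enumerate([0.5, -1.2, 3.0, 0.7, -0.3][: order + 1]))
        out = savitzky_golay_smooth(y, SmoothingParams(window, order))
        np.testing.assert_allclose(out, y, atol=1e-10)

    def test_interior_matches_window_regression_oracle(self, rng):
        y = rng.normal(size=60)
        out = savitzky_golay_smooth(y, SmoothingParams(5, 2))
        for i in range(2, 58):
            assert out[i] == pytest.approx(
                oracles.savgol_window_value(y, i, 5, 2), abs=1e-9)

    @pytest.mark.parametrize("window,order", [(4, 2), (2, 0), (5, 5)])
    def test_bad_params_rejected(self, window, order):
        with pytest.raises(ParameterError):
            SmoothingParams(window, order)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ParameterError):
            savitzky_golay_smooth(np.zeros(5), SmoothingParams(7, 2))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000),
           a=st.floats(-5, 5, allow_nan=False),
           b=st.floats(-5, 5, allow_nan=False))
    def test_linearity(self, seed, a, b):
        r = np.random.default_rng(seed)
        y1, y2 = r.normal(size=25), r.normal(size=25)
        p = SmoothingParams(7, 2)
        lhs = savitzky_golay_smooth(a * y1 + b * y2, p)
        rhs = a * savitzky_golay_smooth(y1, p) + b * savitzky_golay_smooth(y2, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestTrimInitial:
    def test_zero_fraction_is_identity(self, dpv_trace):
        trace, _ = dpv_trace
        out = trim_initial(trace, 0.0)
        np.testing.assert_array_equal(out.currents, trace.currents)
        assert out.meta["trimmed_points"] == 0

    def test_floor_arithmetic(self):
        v = Voltammogram(np.linspace(0, 1, 10), np.zeros(10), Mode.DPV)
        assert len(trim_initial(v, 0.3)) == 7

    def test_default_fraction(self):
        n = 121
        v = Voltammogram(np.linspace(0, 1, n), np.zeros(n), Mode.DPV)
        out = trim_initial(v)
        assert len(out) == n - int(np.floor(0.05 * n))
        assert out.meta["trim_fraction"] == 0.05

    @pytest.mark.parametrize("fraction", [-0.1, 0.5, 0.9])
    def test_out_of_range_fraction(self, fraction, dpv_trace):
        with pytest.raises(ParameterError):
            trim_initial(dpv_trace[0], fraction)

    def test_zero_trim_idempotent(self, dpv_trace):
        trace, _ = dpv_trace
        once = trim_initial(trace, 0.0)
        twice = trim_initial(once, 0.0)
        np.testing.assert_array_equal(once.currents, twice.currents)


class TestSplitSweeps:
    def test_triangular_turning_index(self):
        pot = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        v = Voltammogram(pot, np.zeros(21), Mode.CV)
        seg = split_sweeps(v)
        assert seg.turning_index == 10
        assert seg.forward == (0, 11)
        assert seg.reverse == (11, 21)

    def test_noisy_sweep_matches_sign_change_oracle(self):
        r = np.random.default_rng(42)
        fwd = np.linspace(-0.2, 0.8, 101)
        pot = np.concatenate([fwd, fwd[::-1][1:]])
        pot = pot + r.normal(0, 0.0005, len(pot))  # readback jitter << step
        v = Voltammogram(pot, np.zeros(len(pot)), Mode.CV)
        seg = split_sweeps(v)
        assert seg.turning_index == oracles.sign_change_turning_index(pot)

    def test_monotone_ramp_empty_reverse(self):
        v = Voltammogram(np.linspace(0, 1, 10), np.zeros(10), Mode.CV)
        seg = split_sweeps(v)
        assert seg.reverse == (10, 10)
        assert seg.warnings

    def test_cathodic_first_sweep(self):
        pot = np.concatenate([np.linspace(1, 0, 11), np.linspace(0, 1, 11)[1:]])
        v = Voltammogram(pot, np.zeros(21), Mode.CV)
        assert split_sweeps(v).turning_index == 10

    def test_partition_property(self, cv_trace):
        trace, _ = cv_trace
        seg = split_sweeps(trace)
        assert seg.forward[0] == 0
        assert seg.forward[1] == seg.reverse[0]
        assert seg.reverse[1] == len(trace)

    def test_too_short(self):
        v = Voltammogram([0.0, 1.0], [0.0, 0.0], Mode.CV)
        with pytest.raises(InputError):
            split_sweeps(v)

    def test_dpv_rejected(self, dpv_trace):
        with pytest.raises(ParameterError):
            split_sweeps(dpv_trace[0])


class TestSelectStableScan:
    @staticmethod
    def _scan(currents, idx):
        n = len(currents)
        return Voltammogram(np.linspace(0, 1, n), currents, Mode.CV,
                            scan_index=idx)

    def test_single_scan_returned(self, cv_trace):
        trace, _ = cv_trace
        assert select_stable_scan([trace]) is trace

    def test_identical_pair_wins(self, rng):
        base = rng.normal(size=50)
        scans = [self._scan(base + 1.0, 0), self._scan(base, 1),
                 self._scan(base.copy(), 2)]
        assert select_stable_scan(scans).scan_index == 1

    def test_matches_exhaustive_criterion(self, rng):
        scans = [self._scan(rng.normal(size=40), i) for i in range(5)]
        scores = []
        for i in range(5):
            other = scans[i + 1] if i < 4 else scans[i - 1]
            scores.append(np.mean(np.abs(scans[i].currents - other.currents)))
        assert (select_stable_scan(scans).scan_index
                == int(np.argmin(scores)))

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            select_stable_scan([])
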