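import numpy as np
import pytest
from hypothesis import given, strategies as st

import catrace as ct
from catrace.core import (ConstantTraceError, NonpositiveBaselineError,
                          StageError, TraceMatrix)
from catrace.traces import (BaselineParams, decay_factor, inverse_filter,
                            rolling_quantile)


def brute_force_baseline(x, params):
    """Loop-and-quantile re-implementation of the sliding baseline."""
    n = len(x)
    w = min(params.window_frames, n)
    half = w // 2

    def roll_q(q):
        return np.array([np.quantile(x[max(0, t - half):min(n, t - half + w)], q)
                         for t in range(n)])

    provisional = roll_q(0.5)
    resid = x - provisional
    robust_sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    active = np.mean(x > provisional + params.activity_probe_sd * robust_sd)
    q = min(max(params.q_max - active, params.q_min), params.q_max)
    return roll_q(q)


class TestSlidingBaseline:
    def test_constant_trace_baseline_is_the_constant(self):
        raw = TraceMatrix(np.full((700, 2), 5.0), 10.0)
        f0 = ct.sliding_baseline(raw)
        assert np.all(f0.values == 5.0)

    def test_silent_neuron_uses_the_median(self):
        """Near-zero activity fraction clamps the quantile at the median."""
        x = 5.0 + 0.01 * (-1.0) ** np.arange(1000)
        raw = TraceMatrix(x, 10.0)
        f0 = ct.sliding_baseline(raw, BaselineParams(window_frames=500))
        med = rolling_quantile(x, 500, 0.5)
        assert np.allclose(f0.values[:, 0], med)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        params = BaselineParams(window_frames=500)
        for n in (300, 1200, 2000):
            x = 100.0 + 10.0 * rng.standard_normal(n) \
                + 30.0 * (rng.random(n) < 0.05)
            got = ct.sliding_baseline(TraceMatrix(x, 10.0), params)
            assert np.allclose(got.values[:, 0], brute_force_baseline(x, params))

    def test_ramp_interior_window_quantile(self):
        """An interior frame's baseline is the quantile of its own window."""
        x = np.arange(1.0, 1001.0)
        f0 = ct.sliding_baseline(TraceMatrix(x, 10.0),
                                 BaselineParams(window_frames=500))
        t = 500
        window = x[t - 250:t + 250]
        # a clean ramp has activity fraction ~0.5 -> q clamps to q_min = 0.10
        assert f0.values[t, 0] == pytest.approx(np.quantile(window, 0.10))

    def test_nonpositive_baseline_rejected(self):
        x = np.concatenate([np.full(300, -1.0), np.full(300, 2.0)])
        with pytest.raises(NonpositiveBaselineError):
            ct.sliding_baseline(TraceMatrix(x, 10.0))

    def test_accuracy_on_drifting_synthetic_session(self):
        """Median relative baseline error < 5% with drift and sparse events."""
        cfg = ct.SimConfig(n_neurons=10, duration_s=600.0, seed=8,
                           drift_amplitude=0.2)
        s = ct.simulate_session(cfg)
        f0 = ct.sliding_baseline(s.traces)
        # away from events the trace itself is baseline*(1+drift) plus small
        # noise, so it serves as the ground-truth baseline there
        rel_err = []
        for j in range(10):
            quiet = np.ones(s.traces.n_frames, dtype=bool)
            fs = cfg.frame_rate_hz
            for t0 in s.truth.event_times[j]:
                k0 = int(t0 * fs)
                quiet[max(0, k0 - 1):k0 + 40] = False
            true_f0 = s.traces.values[quiet, j]
            est = f0.values[quiet, j]
            rel_err.append(np.median(np.abs(est - true_f0) / true_f0))
        assert np.median(rel_err) < 0.05

    def test_dff_of_constant_trace_is_zero(self):
        raw = TraceMatrix(np.full((800, 1), 7.0), 10.0)
        dff = ct.compute_dff(raw, ct.sliding_baseline(raw))
        assert np.all(dff.values == 0.0)


class TestDff:
    @pytest.mark.parametrize("f, f0, expected", [(6.0, 5.0, 0.2),
                                                 (5.0, 5.0, 0.0),
                                                 (2.5, 5.0, -0.5)])
    def test_formula(self, f, f0, expected):
        trace = TraceMatrix(np.full((10, 1), f), 10.0)
        base = TraceMatrix(np.full((10, 1), f0), 10.0)
        assert ct.compute_dff(trace, base).values[0, 0] == pytest.approx(expected)

    def test_rejects_nonpositive_baseline(self):
        trace = TraceMatrix(np.ones((10, 1)), 10.0)
        base = TraceMatrix(np.zeros((10, 1)) - 1.0, 10.0)
        with pytest.raises(NonpositiveBaselineError):
            ct.compute_dff(trace, base)


class TestStandardize:
    def test_three_point_example(self):
        dff = TraceMatrix(np.array([1.0, 2.0, 3.0]), 10.0, stage="dff")
        assert np.allclose(ct.standardize(dff).values[:, 0], [-1.0, 0.0, 1.0])

    def test_output_median_zero(self):
        rng = np.random.default_rng(0)
        dff = TraceMatrix(rng.random((501, 4)), 10.0, stage="dff")
        out = ct.standardize(dff)
        assert np.allclose(np.median(out.values, axis=0), 0.0)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        base = ct.standardize(TraceMatrix(x, 10.0, stage="dff"))
        scaled = ct.standardize(TraceMatrix(a * x + b, 10.0, stage="dff"))
        assert np.allclose(base.values, scaled.values, atol=1e-8)

    def test_constant_trace_rejected(self):
        dff = TraceMatrix(np.full((10, 1), 2.0), 10.0, stage="dff")
        with pytest.raises(ConstantTraceError):
            ct.standardize(dff)

    def test_stage_checked(self):
        with pytest.raises(StageError):
            ct.standardize(TraceMatrix(np.arange(10.0), 10.0, stage="raw"))


class TestDeconvolve:
    def test_zero_in_zero_out(self):
        z = TraceMatrix(np.zeros((50, 2)), 10.0, stage="standardized")
        assert np.all(ct.deconvolve_standin(z).values == 0.0)

    def test_single_kernel_collapses_to_single_frame(self):
        lam = decay_factor(0.2, 10.0)
        x = np.zeros(100)
        x[20:] = lam ** np.arange(80)
        out = ct.deconvolve_standin(
            TraceMatrix(x, 10.0, stage="standardized"), t_half_s=0.2)
        support = np.flatnonzero(out.values[:, 0] > 1e-12)
        assert list(support) == [20]

    def test_reconvolution_identity(self):
        """The unrectified inverse filter is exactly invertible."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal((400, 3))
        lam = decay_factor(0.2, 10.0)
        y = inverse_filter(x, lam)
        recon = np.empty_like(y)
        acc = np.zeros(x.shape[1])
        for t in range(len(y)):
            acc = y[t] + lam * acc
            recon[t] = acc
        assert np.max(np.abs(recon - x)) < 1e-6


class TestZscoreMasked:
    def test_noise_trace_centered(self):
        rng = np.random.default_rng(6)
        x = 2.0 + 0.5 * rng.standard_normal(10_000)
        z = ct.zscore_activity_masked(TraceMatrix(x, 10.0, stage="deconvolved"))
        assert abs(z.values[:, 0].mean()) < 0.05

    def test_constant_trace_rejected(self):
        with pytest.raises(ConstantTraceError):
            ct.zscore_activity_masked(
                TraceMatrix(np.full((100, 1), 3.0), 10.0, stage="deconvolved"))

    def test_baseline_immune_to_spike_height(self):
        """Masked frames keep transients out of the baseline statistics."""
        rng = np.random.default_rng(7)
        base = rng.standard_normal(5000)
        zs = []
        for spike in (50.0, 5000.0):
            x = base.copy()
            x[1000:1010] += spike
            z = ct.zscore_activity_masked(
                TraceMatrix(x, 10.0, stage="deconvolved"))
            zs.append(z.values[:, 0])
        # baseline frames are z-scored identically regardless of spike size
        quiet = np.ones(5000, dtype=bool)
        quiet[1000:1010] = False
        assert np.allclose(zs[0][quiet], zs[1][quiet])
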