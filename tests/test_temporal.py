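"""Temporal analysis: traces, cross-correlations, ACF + correlation
time, intracellular projection maps and their 2-D Fourier spectra."""

import math

import numpy as np
import pandas as pd
import pytest

from virtustain import simgen, temporal
from virtustain.errors import (
    FitFailureError,
    UndefinedStatisticError,
    ValidationError,
)


def make_trace(values, dt=2.0, marker="M"):
    return temporal.TimelapseTrace(
        cell_id="c0", marker=marker, values=np.asarray(values, float),
        frame_interval=dt,
    )


class TestTraceExpression:
    def test_constant_stack(self):
        stack = np.full((5, 8, 8), 2.0)
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        tr = temporal.trace_expression(stack, mask)
        np.testing.assert_allclose(tr.values, 2.0 * 4)

    def test_linear_ramp(self):
        mask = np.zeros((6, 6), bool)
        mask[1:4, 1:3] = True
        stack = np.stack([t * mask.astype(float) for t in range(4)])
        tr = temporal.trace_expression(stack, mask)
        np.testing.assert_allclose(tr.values, np.arange(4) * mask.sum())

    def test_ou_timelapse_trace_mean(self):
        """Rendered OU time-lapse: mean total intensity tracks the
        product of the stationary mean and the cell's intensity mass."""
        scene = simgen.generate_scene(1, field_size=(48, 48), seed=3,
                                      size_scale=0.35)
        ou = simgen.OUProcessParams(mean_level=1.0, stationary_sd=0.15,
                                    duration=400.0)
        stacks = simgen.generate_timelapse(scene, {"CD105": ou}, seed=0)
        frames = [p.ground_truth for p in stacks["CD105"]]
        mask = scene.cell_mask(0)
        tr = temporal.trace_expression(frames, mask)
        expr = simgen.true_traces(stacks["CD105"])["cell_0000"]
        # total intensity is affine in expression: I(t) = a + b*e(t)
        e1 = simgen.render_pair(scene, "CD105",
                                expressions={"cell_0000": 1.0}).ground_truth
        e2 = simgen.render_pair(scene, "CD105",
                                expressions={"cell_0000": 2.0}).ground_truth
        b = (e2 - e1)[mask].sum()
        a = e1[mask].sum() - b
        np.testing.assert_allclose(tr.values, a + b * expr, rtol=1e-10)
        se = tr.values.std(ddof=1) / math.sqrt(tr.values.size)
        assert abs(tr.values.mean() - (a + b)) < 6 * se

    def test_frame_mask_mismatch(self):
        with pytest.raises(ValidationError):
            temporal.trace_expression(
                np.ones((4, 8, 8)), [np.ones((8, 8), bool)] * 3
            )


class TestOverallCorrelation:
    def test_proportional_markers(self):
        df = pd.DataFrame(
            {"mean_A": [1.0, 2.0, 3.0, 4.0], "mean_B": [2.0, 4.0, 6.0, 8.0]}
        )
        m = temporal.overall_correlation(df)
        assert m.loc["A", "B"] == pytest.approx(1.0)
        assert m.loc["A", "A"] == 1.0 and m.loc["B", "B"] == 1.0

    def test_shared_size_factor(self):
        """Two markers sharing a cell-size factor plus independent noise:
        expected correlation var(f)/(var(f)+var(eps)) from the variance
        decomposition."""
        rng = np.random.default_rng(0)
        n = 4000
        f = rng.normal(1.0, 0.5, n)
        sd_eps = 0.25
        df = pd.DataFrame(
            {
                "mean_A": f + rng.normal(0, sd_eps, n),
                "mean_B": f + rng.normal(0, sd_eps, n),
            }
        )
        expected = 0.5**2 / (0.5**2 + sd_eps**2)
        m = temporal.overall_correlation(df)
        assert m.loc["A", "B"] == pytest.approx(expected, abs=0.03)

    def test_constant_marker_rejected(self):
        df = pd.DataFrame({"mean_A": [1.0, 2.0, 3.0], "mean_B": [1.0, 1.0, 1.0]})
        with pytest.raises(UndefinedStatisticError):
            temporal.overall_correlation(df)


class TestFluctuationCorrelation:
    def test_self_correlation_is_one(self, rng):
        tr = make_trace(rng.random(100))
        m = temporal.fluctuation_correlation({"A": tr, "B": tr})
        assert m.loc["A", "B"] == pytest.approx(1.0)

    def test_independent_ou_traces_near_zero(self):
        """Independent processes: correlation within the null band implied
        by the effective number of independent samples of the process."""
        rng = np.random.default_rng(7)
        ou = simgen.OUProcessParams(correlation_time=40.0, frame_interval=2.0,
                                    duration=2880.0)
        vals = []
        for _ in range(30):
            a = make_trace(simgen._ou_trace(ou, rng))
            b = make_trace(simgen._ou_trace(ou, rng))
            m = temporal.fluctuation_correlation({"A": a, "B": b})
            vals.append(m.loc["A", "B"])
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            temporal.fluctuation_correlation(
                {"A": make_trace(rng.random(50)), "B": make_trace(rng.random(60))}
            )


class TestACF:
    def test_lag_zero_is_one(self, rng):
        acf = temporal.autocorrelation(make_trace(rng.random(200)), max_lag=20)
        assert acf.acf[0] == pytest.approx(1.0)

    def test_white_noise_acf_near_zero(self):
        rng = np.random.default_rng(11)
        n = 2000
        acf = temporal.autocorrelation(make_trace(rng.normal(size=n)), max_lag=10)
        assert np.all(np.abs(acf.acf[1:]) < 3.0 / math.sqrt(n))

    def test_ou_ensemble_matches_exponential(self):
        """Ensemble ACF of exact-discretized OU matches exp(-k dt/tau)
        within 3 standard errors for the first 10 lags."""
        rng = np.random.default_rng(5)
        ou = simgen.OUProcessParams(correlation_time=40.0, frame_interval=2.0,
                                    duration=2880.0)
        acfs = np.array([
            temporal.autocorrelation(make_trace(simgen._ou_trace(ou, rng)),
                                     max_lag=12).acf
            for _ in range(200)
        ])
        mean_acf = acfs.mean(axis=0)
        se = acfs.std(axis=0, ddof=1) / math.sqrt(acfs.shape[0])
        # estimating the mean on the same finite record biases the ACF
        # down by ~2 tau / T (the finite-duration effect that also
        # produces the anticorrelated tail)
        bias = 2.0 * 40.0 / 2880.0
        for k in range(1, 11):
            expected = math.exp(-2.0 * k / 40.0)
            assert abs(mean_acf[k] - expected) < 3 * se[k] + bias

    def test_constant_trace_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            temporal.autocorrelation(make_trace(np.ones(100)), max_lag=5)


class TestCorrelationTimeFit:
    def test_exact_exponential_recovered(self):
        lags = np.arange(30) * 2.0
        acf = temporal.ACFResult(lags=lags, acf=np.exp(-lags / 40.0),
                                 frame_interval=2.0)
        tau = temporal.fit_correlation_time(acf)
        assert tau == pytest.approx(40.0, abs=1e-6)

    @pytest.mark.parametrize("tau_over_dt", [5, 20, 50])
    def test_ou_ensemble_recovery(self, tau_over_dt):
        """Median fitted tau within 20% of the simulated value across
        ensemble repetitions."""
        dt = 2.0
        tau_true = tau_over_dt * dt
        rng = np.random.default_rng(tau_over_dt)
        ou = simgen.OUProcessParams(correlation_time=tau_true, frame_interval=dt,
                                    duration=2880.0)
        taus = []
        for _ in range(20):
            acfs = [
                temporal.autocorrelation(
                    make_trace(simgen._ou_trace(ou, rng), dt=dt), max_lag=200
                )
                for _ in range(25)
            ]
            mean = temporal.average_acf(acfs)
            taus.append(temporal.fit_correlation_time(mean))
        assert np.median(taus) == pytest.approx(tau_true, rel=0.20)

    def test_white_noise_head_degenerate(self):
        rng = np.random.default_rng(2)
        acf = temporal.autocorrelation(make_trace(rng.normal(size=500)), max_lag=50)
        try:
            tau = temporal.fit_correlation_time(acf)
        except FitFailureError:
            return  # zero crossing at lag 1: no fittable head
        assert tau <= 2.0 * acf.frame_interval  # degenerate, flagged by magnitude


class TestProjection:
    def test_uniform_cell_gives_constant_columns(self):
        mask = np.zeros((20, 30), bool)
        mask[5:15, 8:25] = True
        stack = [np.where(mask, 3.0, 0.0)] * 4
        m = temporal.project_intracellular(stack, mask)
        assert np.allclose(m.matrix, 3.0)

    def test_step_profile_position(self):
        mask = np.zeros((20, 40), bool)
        mask[5:15, 10:30] = True
        img = np.zeros((20, 40))
        img[:, :20] = 2.0
        img[:, 20:] = 1.0
        m = temporal.project_intracellular([img, img], mask, n_positions=100)
        # mask spans columns 10..29; the step at column 20 is halfway
        profile = m.matrix[:, 0]
        step_bin = np.argmax(np.abs(np.diff(profile)))
        assert abs(step_bin - 50) <= 1
        assert profile[10] == pytest.approx(2.0)
        assert profile[90] == pytest.approx(1.0)

    def test_conserves_total_expression(self):
        rng = np.random.default_rng(8)
        mask = np.zeros((30, 40), bool)
        mask[4:26, 6:36] = True
        img = rng.random((30, 40))
        m = temporal.project_intracellular([img, img], mask, n_positions=100)
        tr = temporal.trace_expression([img, img], mask)
        approx_total = float((m.matrix[:, 0] * m.occupancy[:, 0]).sum())
        assert approx_total == pytest.approx(tr.values[0], rel=0.02)

    def test_vanishing_mask_rejected(self):
        with pytest.raises(ValidationError):
            temporal.project_intracellular(
                [np.ones((8, 8)), np.ones((8, 8))],
                [np.ones((8, 8), bool), np.zeros((8, 8), bool)],
            )


class TestFFT2:
    def _map(self, matrix, pitch=1.0, dt=1.0):
        return temporal.SpatioTemporalMap(
            matrix=matrix, pixel_pitch=pitch, frame_interval=dt
        )

    def test_constant_map_zero_spectrum(self):
        spec, fs, ft = temporal.fft2_map(self._map(np.full((16, 16), 5.0)))
        assert np.allclose(spec, 0.0, atol=1e-9)

    def test_pure_spatial_sinusoid_peak(self):
        pos = np.arange(64)
        mat = np.tile(np.sin(2 * np.pi * pos / 8.0)[:, None], (1, 32))
        spec, fs, ft = temporal.fft2_map(self._map(mat))
        i, j = np.unravel_index(np.argmax(spec), spec.shape)
        assert abs(fs[i]) == pytest.approx(1.0 / 8.0)
        assert ft[j] == 0.0
        # symmetric partner peak
        spec[i, j] = 0.0
        i2, j2 = np.unravel_index(np.argmax(spec), spec.shape)
        assert fs[i2] == pytest.approx(-fs[i])

    def test_separable_spacetime_product_four_peaks(self):
        pos, t = np.arange(64), np.arange(64)
        mat = np.outer(np.sin(2 * np.pi * pos / 8.0), np.sin(2 * np.pi * t / 16.0))
        spec, fs, ft = temporal.fft2_map(self._map(mat))
        order = np.argsort(spec.ravel())[::-1][:4]
        peaks = {
            (round(abs(fs[i]), 6), round(abs(ft[j]), 6))
            for i, j in (np.unravel_index(o, spec.shape) for o in order)
        }
        assert peaks == {(round(1 / 8, 6), round(1 / 16, 6))}

    def test_parseval_identity(self, rng):
        mat = rng.random((32, 48))
        m = self._map(mat)
        spec, _, _ = temporal.fft2_map(m, window=False)
        x = mat - mat.mean()
        lhs = (spec**2).sum() / mat.size
        rhs = (x**2).sum()
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_physical_frequency_axes(self):
        mat = np.zeros((10, 20))
        m = self._map(mat + np.arange(20)[None, :], pitch=0.5, dt=2.0)
        spec, fs, ft = temporal.fft2_map(m)
        assert fs.max() <= 1.0 / (2 * 0.5) + 1e-9  # Nyquist in cycles/um
        assert ft.max() <= 1.0 / (2 * 2.0) + 1e-9  # Nyquist in cycles/min

    def test_non_finite_rejected(self):
        mat = np.ones((8, 8))
        mat[0, 0] = np.nan
        with pytest.raises(ValidationError):
            temporal.fft2_map(self._map(mat))
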