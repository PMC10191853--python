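"""Global lifetime analysis: model evaluation, variable projection, DAS."""

import numpy as np
import pytest

from flashkin.dataset import WavenumberGrid
from flashkin.exceptions import ValidationError
from flashkin.globalfit import (
    ExponentialFitModel,
    evaluate_model,
    extract_das,
    global_fit,
    steady_state_spectrum,
)


def make_model(seed=0, taus=(340.0, 2500.0), n_wn=20, scale=30e-6):
    rng = np.random.default_rng(seed)
    taus = np.asarray(taus, float)
    amps = rng.normal(0.0, scale, size=(n_wn, taus.size))
    offs = rng.normal(0.0, scale / 5, size=n_wn)
    return ExponentialFitModel(taus, amps, offs)


class TestEvaluateModel:
    def test_t0_equals_offsets(self):
        m = make_model()
        np.testing.assert_allclose(evaluate_model(m, [0.0])[0], m.offsets)

    def test_single_component_closed_form(self):
        m = ExponentialFitModel([340.0], [[1.0]], [0.0])
        val = evaluate_model(m, [340.0])[0, 0]
        assert val == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)

    def test_asymptote_is_amplitude_sum_plus_offset(self):
        m = make_model()
        limit = evaluate_model(m, [1e9])[0]
        np.testing.assert_allclose(limit, m.amplitudes.sum(axis=1) + m.offsets,
                                   atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_model(make_model(), [-1.0])

    def test_model_invariants(self):
        with pytest.raises(ValidationError):
            ExponentialFitModel([500.0, 100.0], np.zeros((3, 2)), np.zeros(3))
        with pytest.raises(ValidationError):
            ExponentialFitModel([-5.0], np.zeros((3, 1)), np.zeros(3))


class TestGlobalFit:
    times = np.arange(0.0, 100_000.0, 25.0)

    @pytest.mark.parametrize("taus", [(340.0, 2500.0), (33.0, 300.0, 3000.0)])
    def test_simulate_then_fit_identity(self, taus):
        """Noise-free recovery: taus to <=0.1%, amplitudes to <=1e-6."""
        m = make_model(seed=1, taus=taus)
        data = evaluate_model(m, self.times)
        init = np.asarray(taus) * 3.0
        res = global_fit(data, self.times, init_taus=init)
        np.testing.assert_allclose(res.taus, m.taus, rtol=1e-3)
        np.testing.assert_allclose(res.model.amplitudes, m.amplitudes,
                                   rtol=1e-6, atol=1e-12)

    def test_flat_traces_give_zero_amplitudes(self):
        data = np.full((len(self.times), 5), 3.7e-5)
        res = global_fit(data, self.times, init_taus=[500.0])
        np.testing.assert_allclose(res.model.amplitudes, 0.0, atol=1e-9)
        np.testing.assert_allclose(res.model.offsets, 3.7e-5, atol=1e-9)

    def test_variable_projection_consistency(self):
        """Re-solving the linear subproblem at the returned taus is stable."""
        m = make_model(seed=2)
        data = evaluate_model(m, self.times)
        res = global_fit(data, self.times, init_taus=[200.0, 5000.0])
        from flashkin.globalfit import design_matrix
        mask = self.times >= res.model.fit_start
        phi = design_matrix(res.taus, self.times[mask])
        coef, *_ = np.linalg.lstsq(phi, data[mask], rcond=None)
        np.testing.assert_allclose(coef[:2].T, res.model.amplitudes,
                                   rtol=1e-10, atol=1e-16)

    def test_residual_monotone_in_component_count(self):
        m = make_model(seed=3, taus=(100.0, 1500.0, 9000.0))
        data = evaluate_model(m, self.times)
        data = data + np.random.default_rng(0).normal(0, 2e-6, data.shape)
        residuals = []
        for k, init in [(1, [500.0]), (2, [100.0, 5000.0]),
                        (3, [80.0, 1000.0, 10000.0])]:
            res = global_fit(data, self.times, init_taus=init)
            residuals.append(res.residual_norm)
        assert residuals[0] >= residuals[1] >= residuals[2]

    def test_wavenumber_permutation_invariance(self):
        m = make_model(seed=4)
        data = evaluate_model(m, self.times)
        perm = np.random.default_rng(1).permutation(data.shape[1])
        res1 = global_fit(data, self.times, init_taus=[200.0, 5000.0])
        res2 = global_fit(data[:, perm], self.times,
                          init_taus=[200.0, 5000.0])
        np.testing.assert_allclose(res1.taus, res2.taus, rtol=1e-9)
        np.testing.assert_allclose(res1.model.amplitudes[perm],
                                   res2.model.amplitudes, rtol=1e-7)

    def test_uniform_rescaling_leaves_taus(self):
        m = make_model(seed=5)
        data = evaluate_model(m, self.times)
        res1 = global_fit(data, self.times, init_taus=[200.0, 5000.0])
        res2 = global_fit(1e3 * data, self.times, init_taus=[200.0, 5000.0])
        np.testing.assert_allclose(res1.taus, res2.taus, rtol=1e-9)
        np.testing.assert_allclose(res2.model.amplitudes,
                                   1e3 * res1.model.amplitudes, rtol=1e-9)

    @pytest.mark.parametrize("noise", [0.10, 0.01, 0.001])
    def test_tau_error_shrinks_with_noise(self, noise):
        """Estimates are consistent: error decreases as sigma -> 0."""
        m = make_model(seed=6)
        clean = evaluate_model(m, self.times)
        peak = np.abs(clean).max()
        data = clean + np.random.default_rng(7).normal(
            0, noise * peak, clean.shape)
        res = global_fit(data, self.times, init_taus=[200.0, 5000.0])
        err = np.abs(res.taus / m.taus - 1).max()
        # generous per-level caps; the trend check is the parametrization
        assert err < {0.10: 0.10, 0.01: 0.01, 0.001: 0.001}[noise] * 5

    def test_degenerate_taus_flagged(self):
        m = make_model(seed=8, taus=(1000.0, 1030.0))
        data = evaluate_model(m, self.times)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = global_fit(data, self.times, init_taus=[990.0, 1040.0])
        assert res.degenerate_pairs

    def test_config_errors(self):
        data = np.zeros((len(self.times), 3))
        with pytest.raises(ValidationError):
            global_fit(data, self.times)  # no init, no multi-start
        with pytest.raises(ValidationError):
            global_fit(data, self.times, init_taus=[100.0], n_components=2)


class TestDASAccess:
    def test_extract_by_label_and_index(self):
        grid = WavenumberGrid(np.linspace(1300, 1700, 10))
        m = make_model(seed=9, n_wn=10)
        data = evaluate_model(m, np.arange(0, 50_000, 25.0))
        res = global_fit(data, np.arange(0, 50_000, 25.0),
                         init_taus=[300.0, 3000.0], wavenumbers=grid)
        res.label({"t_H+": 340.0, "t_O2": 2500.0})
        das = extract_das(res, "t_O2")
        np.testing.assert_allclose(das.values, res.model.amplitudes[:, 1],
                                   atol=1e-15)
        with pytest.raises(KeyError, match="t_H\\+"):
            extract_das(res, "nonexistent")
        with pytest.raises(KeyError):
            extract_das(res, 5)

    def test_single_exponential_das_is_generating_spectrum(self):
        spectrum = np.sin(np.linspace(0, 3, 15)) * 1e-5
        m = ExponentialFitModel([800.0], spectrum[:, None], np.zeros(15))
        t = np.arange(0, 20_000, 20.0)
        res = global_fit(evaluate_model(m, t), t, init_taus=[2000.0])
        np.testing.assert_allclose(res.model.amplitudes[:, 0], spectrum,
                                   rtol=1e-8, atol=1e-14)


class TestSteadyState:
    def test_constant_signal(self):
        t = np.arange(0, 1_200_000.0, 1000.0)
        data = np.full((t.size, 4), 2.5e-5)
        np.testing.assert_allclose(
            steady_state_spectrum(data, t), 2.5e-5, atol=1e-15)

    def test_window_mean_matches_model_asymptote(self):
        """With all taus <= 25 ms, the 300 ms..1 s mean is sum(A) + B."""
        m = make_model(seed=10, taus=(340.0, 25_000.0))
        t = np.arange(0, 1_050_000.0, 500.0)
        data = evaluate_model(m, t)
        spec = steady_state_spectrum(data, t)
        np.testing.assert_allclose(
            spec, m.amplitudes.sum(axis=1) + m.offsets, rtol=2e-5, atol=1e-12)

    def test_empty_window_rejected(self):
        t = np.arange(0, 1000.0, 10.0)
        with pytest.raises(ValidationError):
            steady_state_spectrum(np.zeros((t.size, 2)), t)
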