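"""Kok S-state bookkeeping: Markov propagation, weights, deconvolution."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flashkin.dataset import TRANSITIONS, FlashSeriesDataset, TimeGrid
from flashkin.exceptions import DeconvolutionError, ValidationError
from flashkin.kok import (
    KokParameters,
    deconvolve_transitions,
    o2_yield_pattern,
    propagate_states,
    transition_matrix,
    transition_weights,
)


def enumerate_outcomes(params: KokParameters, n_flashes: int) -> np.ndarray:
    """Brute-force oracle: expand all 3^n miss/advance/double paths."""
    a = params.misses
    b = params.double_hit
    pops = np.zeros(4)
    for state, p0 in enumerate(params.initial_populations):
        if p0 == 0.0:
            continue
        for path in itertools.product((0, 1, 2), repeat=n_flashes):
            prob = p0
            s = state
            for move in path:
                prob *= (a[s], 1.0 - a[s] - b, b)[move]
                s = (s + move) % 4
            pops[s] += prob
    return pops


class TestTransitionMatrix:
    def test_no_miss_is_cyclic_permutation(self):
        m = transition_matrix(KokParameters(miss=0.0))
        expected = np.zeros((4, 4))
        for j in range(4):
            expected[(j + 1) % 4, j] = 1.0
        np.testing.assert_allclose(m, expected)

    def test_column_stochastic_with_double_hits(self):
        m = transition_matrix(KokParameters(miss=0.07, double_hit=0.03))
        np.testing.assert_allclose(m.sum(axis=0), np.ones(4), atol=1e-14)
        assert np.all(m >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            KokParameters(miss=0.8, double_hit=0.3)
        with pytest.raises(ValidationError):
            KokParameters(initial_populations=(0.5, 0.5, 0.5, 0.0))


class TestPropagation:
    def test_single_flash_pure_s1(self):
        pops = propagate_states(KokParameters(miss=0.0), 1)
        np.testing.assert_allclose(pops[1], [0, 0, 1, 0], atol=1e-15)

    def test_three_flashes_with_miss(self):
        pops = propagate_states(KokParameters(miss=0.1), 3)
        assert pops[3][0] == pytest.approx(0.729, abs=1e-12)

    def test_entry_zero_is_initial_populations(self):
        params = KokParameters(initial_populations=(0.25, 0.25, 0.25, 0.25))
        pops = propagate_states(params, 2)
        np.testing.assert_allclose(pops[0], [0.25] * 4)

    @given(
        miss=st.floats(0.0, 0.5),
        double=st.floats(0.0, 0.3),
        n=st.integers(0, 6),
    )
    @settings(max_examples=40, deadline=None)
    def test_matrix_power_equals_outcome_tree(self, miss, double, n):
        """Matrix propagation agrees with exhaustive path enumeration."""
        params = KokParameters(miss=miss, double_hit=double)
        pops = propagate_states(params, n)[n]
        oracle = enumerate_outcomes(params, n)
        np.testing.assert_allclose(pops, oracle, atol=1e-12)
        assert abs(pops.sum() - 1.0) < 1e-12


class TestTransitionWeights:
    def test_no_miss_identity_rows(self):
        w = transition_weights(KokParameters(miss=0.0), 4)
        # flash 1 drives S1->S2 (index 1), flash 3 drives S3->S0 (index 3)
        np.testing.assert_allclose(w[0], [0, 1, 0, 0], atol=1e-15)
        np.testing.assert_allclose(w[2], [0, 0, 0, 1], atol=1e-15)

    def test_flash3_weights_with_miss(self):
        w = transition_weights(KokParameters(miss=0.1), 3)
        np.testing.assert_allclose(
            w[2], [0.0, 0.009, 0.162, 0.729], atol=1e-12
        )

    def test_s3_to_s0_dominates_flash3(self):
        for miss in (0.05, 0.1, 0.2):
            w = transition_weights(KokParameters(miss=miss), 3)
            assert np.argmax(w[2]) == 3


class TestO2Yields:
    def test_period_four_no_miss(self):
        y = o2_yield_pattern(KokParameters(miss=0.0), 8)
        np.testing.assert_allclose(y, [0, 0, 1, 0, 0, 0, 1, 0], atol=1e-15)

    def test_long_run_mean_with_miss(self):
        y = o2_yield_pattern(KokParameters(miss=0.1), 4000)
        assert y[-1] == pytest.approx(0.225, abs=1e-6)
        normalized = o2_yield_pattern(KokParameters(miss=0.1), 4000,
                                      normalized=True)
        assert normalized[-1] == pytest.approx(1.0, abs=1e-5)

    def test_period4_oscillation_damps(self):
        """Oscillation amplitude around steady state is non-increasing."""
        y = o2_yield_pattern(KokParameters(miss=0.1), 80)
        amp = np.array([np.ptp(y[i:i + 4]) for i in range(0, 80, 4)])
        assert np.all(np.diff(amp) <= 1e-12)


class TestDeconvolution:
    @staticmethod
    def _mixture(weights, time, wn_grid, seed=0):
        rng = np.random.default_rng(seed)
        truth = rng.normal(0, 1e-5, size=(4, time.n_samples, len(wn_grid)))
        data = np.einsum("nj,jtw->ntw", weights, truth)
        ds = FlashSeriesDataset(data=data, time=time, wavenumbers=wn_grid)
        return ds, truth

    def test_identity_weights_return_flashes(self, wn_grid):
        time = TimeGrid(dt=50.0, n_samples=30, t0_index=3)
        w = transition_weights(KokParameters(miss=0.0), 4)
        ds, truth = self._mixture(w, time, wn_grid)
        series = deconvolve_transitions(ds, w)
        # with alpha=beta=0, flashes 1..4 are the pure transitions
        np.testing.assert_allclose(series.data, truth, atol=1e-18)

    def test_exact_recovery_with_miss(self, wn_grid):
        time = TimeGrid(dt=50.0, n_samples=30, t0_index=3)
        w = transition_weights(KokParameters(miss=0.08), 10)
        ds, truth = self._mixture(w, time, wn_grid, seed=1)
        series = deconvolve_transitions(ds, w)
        err = np.abs(series.data - truth).max() / np.abs(truth).max()
        assert err < 1e-10
        assert series.residual_norm < 1e-12

    def test_noise_leaves_sigma_level_residual(self, wn_grid):
        time = TimeGrid(dt=50.0, n_samples=30, t0_index=3)
        sigma = 2e-6
        w = transition_weights(KokParameters(miss=0.1), 10)
        ds, truth = self._mixture(w, time, wn_grid, seed=2)
        noisy = FlashSeriesDataset(
            data=ds.data + np.random.default_rng(3).normal(0, sigma,
                                                           ds.data.shape),
            time=time, wavenumbers=wn_grid)
        series = deconvolve_transitions(noisy, w)
        n_cells = np.prod(noisy.data.shape)
        # residual absorbs the noise orthogonal to the 4D weight column space
        expected = sigma * np.sqrt(n_cells * (1 - 4 / 10))
        assert series.residual_norm == pytest.approx(expected, rel=0.1)

    def test_rank_deficient_weights_rejected(self, tiny_dataset):
        w = np.ones((4, 4)) * 0.25
        with pytest.raises(DeconvolutionError):
            deconvolve_transitions(tiny_dataset, w)

    def test_too_few_flashes_rejected(self, wn_grid):
        time = TimeGrid(dt=50.0, n_samples=10, t0_index=1)
        ds = FlashSeriesDataset(
            data=np.zeros((3, 10, len(wn_grid))), time=time,
            wavenumbers=wn_grid)
        with pytest.raises(DeconvolutionError):
            deconvolve_transitions(ds, np.eye(4)[:3])

    def test_transition_accessor(self, tiny_dataset):
        w = transition_weights(KokParameters(miss=0.05), 4)
        series = deconvolve_transitions(tiny_dataset, w)
        for name in TRANSITIONS:
            assert series.transition(name).shape == tiny_dataset.data.shape[1:]
        with pytest.raises(KeyError):
            series.transition("S4->S5")
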