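"""1D reaction-diffusion polarography: solver, filter, tau_ox extraction."""

import numpy as np
import pytest

from flashkin.exceptions import StabilityError, ValidationError
from flashkin.kok import KokParameters, o2_yield_pattern
from flashkin.polarography import (
    PolarographyModel,
    apply_highpass,
    fit_tau_ox,
    simulate_transients,
)
from flashkin.synthetic import generate_polarography


def small_model(**kwargs):
    """Reduced geometry for fast tests (25x smaller domain than default)."""
    defaults = dict(domain_length=100.0, n_grid=101, dt_sim=100.0, tau_ox=2.0)
    defaults.update(kwargs)
    return PolarographyModel(**defaults)


class TestSimulator:
    def test_zero_yields_zero_current(self):
        res = simulate_transients(small_model(), 2, yields=[0.0, 0.0],
                                  pre_ms=5, post_ms=50)
        np.testing.assert_array_equal(res.raw_flux, 0.0)
        np.testing.assert_array_equal(res.filtered, 0.0)

    def test_mass_conserved_with_reflecting_boundaries(self):
        res = simulate_transients(small_model(electrode="reflecting"), 1,
                                  yields=[1.0], pre_ms=0, post_ms=400)
        assert abs(res.mass_remaining / res.produced_total - 1) < 1e-3
        np.testing.assert_allclose(res.raw_flux, 0.0, atol=1e-12)

    def test_integrated_flux_equals_total_o2(self):
        """Mass balance: absorbing electrode eventually collects everything."""
        m = small_model(domain_length=25.0, n_grid=126)
        t_diff = m.domain_length ** 2 / m.d_um2_ms
        res = simulate_transients(m, 1, yields=[1.0], pre_ms=0,
                                  post_ms=100 * t_diff)
        integral = np.sum(res.raw_flux) * m.dt_record
        assert integral == pytest.approx(res.produced_total, rel=0.01)

    def test_linearity_in_yield(self):
        r1 = simulate_transients(small_model(), 1, yields=[1.0],
                                 pre_ms=5, post_ms=100)
        r2 = simulate_transients(small_model(), 1, yields=[2.0],
                                 pre_ms=5, post_ms=100)
        np.testing.assert_allclose(r2.raw_flux, 2.0 * r1.raw_flux, rtol=1e-12)

    def test_grid_convergence_small_model(self):
        m = small_model()
        f = small_model(n_grid=2 * m.n_grid - 1, dt_sim=m.dt_sim / 2)
        rb = simulate_transients(m, 1, yields=[1.0], pre_ms=5, post_ms=200)
        rf = simulate_transients(f, 1, yields=[1.0], pre_ms=5, post_ms=200)
        diff = np.abs(rb.filtered - rf.filtered).max()
        assert diff / np.abs(rf.filtered).max() < 0.005

    def test_transient_windows(self):
        res = simulate_transients(small_model(flash_spacing=100.0), 3,
                                  yields=[1.0, 0.5, 0.25],
                                  pre_ms=10, post_ms=80)
        assert len(res.transients) == 3
        for tr in res.transients:
            assert tr.times[0] == pytest.approx(-9.5)
            assert tr.times[-1] == pytest.approx(79.5)

    def test_validation(self):
        with pytest.raises(StabilityError):
            PolarographyModel(tau_ox=0.1, dt_sim=100.0)
        with pytest.raises(ValidationError):
            PolarographyModel(layer_thickness=600.0)
        with pytest.raises(ValidationError):
            PolarographyModel(electrode="magic")
        with pytest.raises(ValidationError):
            simulate_transients(small_model(), 2, yields=[1.0])

    def test_robin_electrode_slower_than_absorbing(self):
        """A finite reduction rate collects O2 more slowly than the
        diffusion-limited electrode."""
        ra = simulate_transients(small_model(), 1, yields=[1.0],
                                 pre_ms=0, post_ms=100)
        rr = simulate_transients(small_model(electrode="robin",
                                             robin_rate=0.5), 1,
                                 yields=[1.0], pre_ms=0, post_ms=100)
        assert np.sum(rr.raw_flux) < np.sum(ra.raw_flux)


class TestHighpass:
    def test_zero_input_zero_output(self):
        np.testing.assert_array_equal(
            apply_highpass(np.zeros(100), 1.0, 100.0), 0.0)

    def test_step_response_decays_with_filter_tau(self):
        dt, tau = 0.5, 100.0
        y = apply_highpass(np.ones(4000), dt, tau)
        # log-linear decay at rate 1/tau (within the discretization error)
        rate = -np.polyfit(dt * np.arange(2000), np.log(y[:2000]), 1)[0]
        assert rate == pytest.approx(1.0 / tau, rel=0.01)

    def test_passband_gain_near_unity(self):
        """|H| = wt/sqrt(1+w^2t^2): 0.99995 at w*tau = 100."""
        dt, tau = 0.05, 100.0
        omega = 100.0 / tau
        t = np.arange(0, 2000.0, dt)
        y = apply_highpass(np.sin(omega * t), dt, tau)
        gain = np.abs(y[y.size // 2:]).max()
        analytic = 100.0 / np.sqrt(1.0 + 100.0 ** 2)
        assert gain == pytest.approx(analytic, rel=0.01)

    def test_dc_fully_rejected_on_long_windows(self):
        m = small_model(domain_length=25.0, n_grid=101)
        res = simulate_transients(m, 1, yields=[1.0], pre_ms=0, post_ms=5000)
        raw_integral = np.sum(res.raw_flux) * m.dt_record
        filt_integral = np.sum(res.filtered) * m.dt_record
        assert raw_integral == pytest.approx(1.0, rel=0.02)
        assert abs(filt_integral) < 0.01 * raw_integral


class TestTauOxFit:
    def test_self_consistency_noise_free(self):
        tmpl = small_model()
        obs = simulate_transients(tmpl, 1, yields=[1.0])
        tau, scale, diag = fit_tau_ox(obs.transients, tmpl, tau_init=5.0)
        assert tau == pytest.approx(2.0, rel=0.01)
        assert scale == pytest.approx(1.0, rel=0.01)

    def test_recovery_with_noise(self):
        tmpl = small_model()
        noisy, truth, _ = generate_polarography(
            tmpl, n_flashes=1, yields=[1.0],
            noise_sigma=0.05 * np.abs(
                simulate_transients(tmpl, 1, [1.0]).filtered).max(),
            seed=11)
        tau, scale, diag = fit_tau_ox(noisy, tmpl, tau_init=4.0)
        assert tau == pytest.approx(2.0, rel=0.10)

    def test_objective_minimum_at_generating_value(self):
        """Identifiability: scanning tau over a 10x range brackets the truth."""
        tmpl = small_model()
        obs = simulate_transients(tmpl, 1, yields=[1.0])
        t_obs = obs.transients[0]
        mask = t_obs.times >= 0

        def sse(tau):
            sim = simulate_transients(small_model(tau_ox=tau), 1, [1.0])
            cur = sim.transients[0].current[mask[:sim.transients[0].times.size]]
            return np.sum((cur - t_obs.current[mask]) ** 2)

        taus = np.geomspace(0.7, 7.0, 9)
        costs = [sse(t) for t in taus]
        assert taus[int(np.argmin(costs))] == pytest.approx(2.0, rel=0.15)


class TestKokCoupling:
    def test_period4_yield_pattern_in_transients(self):
        """An 80-flash train shows the damped period-4 O2 oscillation."""
        yields = o2_yield_pattern(KokParameters(miss=0.1), 80)
        assert np.argmax(yields) == 2  # flash 3
        peaks = yields[2::4]
        assert np.all(np.diff(peaks[:5]) < 0)
        # a short train through the simulator preserves the ordering
        m = small_model(flash_spacing=100.0)
        res = simulate_transients(m, 8, yields=yields[:8],
                                  pre_ms=10, post_ms=80)
        amp = [tr.current.max() for tr in res.transients]
        assert np.argmax(amp) == 2
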