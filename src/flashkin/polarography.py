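"""Flash-induced O2 amperometry: 1D reaction-diffusion forward model.

A pellet of PSII-containing membranes of thickness ``layer_thickness`` rests
on a polarized platinum electrode at x = 0.  Each saturating flash n releases
an amount Y_n of O2 (the period-4 Kok yield) inside the layer with first-order
kinetics, source rate Y_n/tau_ox * exp(-t'/tau_ox).  O2 diffuses in one
dimension; the electrode reduces it diffusion-limited (absorbing boundary,
c = 0), the far end of the buffer column is closed (zero flux).  The recorded
current is proportional to the diffusive O2 flux into the electrode, passed
through the amplifier's first-order high-pass filter (100 ms default) that
suppresses slow drift.

Numerics: finite volumes on a grid geometrically refined towards the
electrode (the flux onset after a flash has a sqrt(t) boundary layer),
Crank-Nicolson time stepping (unconditionally stable) with backward-Euler
sub-steps right after each flash, and the flash source deposited
mass-exactly by Strang splitting.  The recorded sample is the flux averaged
over each recording interval ``dt_record`` (integrating detector), which
the discrete mass bookkeeping reproduces exactly.  Internal units:
micrometres and milliseconds (D in m^2/s is converted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import least_squares

from .exceptions import FitError, StabilityError, ValidationError


@dataclass
class PolarographyModel:
    """Geometry, kinetics and filter of the polarography experiment.

    ``D`` is the O2 diffusion coefficient in m^2 s^-1 (typical aqueous value
    2.0e-9); lengths in micrometres; ``dt_sim`` in microseconds; ``tau_ox``
    and ``filter_tau`` and ``flash_spacing`` in milliseconds.
    ``electrode`` is "absorbing" (diffusion-limited reduction), "robin"
    (finite reduction rate ``robin_rate`` in um/ms) or "reflecting" (no
    electrode sink; used for conservation checks).
    """

    D: float = 2.0e-9
    layer_thickness: float = 10.0
    domain_length: float = 500.0
    n_grid: int = 400
    dt_sim: float = 50.0
    tau_ox: float = 2.5
    filter_tau: float = 100.0
    flash_spacing: float = 900.0
    yields: np.ndarray | None = None
    electrode: str = "absorbing"
    robin_rate: float = 10.0
    grading: float = 6.0
    dt_record: float = 1.0

    def __post_init__(self):
        for name in ("D", "layer_thickness", "domain_length", "dt_sim",
                     "tau_ox", "filter_tau", "flash_spacing", "dt_record"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_grid < 5:
            raise ValidationError("n_grid must be >= 5")
        if self.grading < 0:
            raise ValidationError("grading must be >= 0")
        if self.layer_thickness >= self.domain_length:
            raise ValidationError("PSII layer must be thinner than the domain")
        if self.electrode not in ("absorbing", "robin", "reflecting"):
            raise ValidationError(f"unknown electrode mode {self.electrode!r}")
        if self.tau_ox < 4 * self.dt_ms:
            raise StabilityError(
                f"time step {self.dt_ms} ms does not resolve the source "
                f"time constant {self.tau_ox} ms (need tau_ox >= 4*dt)"
            )

    @property
    def dt_ms(self) -> float:
        return self.dt_sim / 1e3

    @property
    def d_um2_ms(self) -> float:
        """Diffusion coefficient in um^2/ms (1 m^2/s = 1e9 um^2/ms)."""
        return self.D * 1e9

    @property
    def grid(self) -> np.ndarray:
        """Node positions (um), geometrically refined towards the electrode.

        The electrode flux carries a sqrt(t) onset whose spatial boundary
        layer a uniform grid cannot resolve; an exponential stretching
        (``grading`` > 0, larger = finer near x = 0; 0 = uniform) puts the
        resolution where the gradient lives.
        """
        xi = np.linspace(0.0, 1.0, self.n_grid)
        if self.grading == 0.0:
            return self.domain_length * xi
        g = np.expm1(self.grading * xi) / np.expm1(self.grading)
        return self.domain_length * g


@dataclass
class CurrentTransient:
    """Post-filter current of one flash, uniform sampling, 0 at the flash."""

    times: np.ndarray   # ms
    current: np.ndarray
    flash_index: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.current, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValidationError("times and current must be matching 1D arrays")
        if t.size > 1 and not np.allclose(np.diff(t), t[1] - t[0], rtol=1e-9):
            raise ValidationError("transient sampling must be uniform")
        if not np.all(np.isfinite(c)):
            raise ValidationError("transient contains non-finite values")
        self.times, self.current = t, c


@dataclass
class SimulationResult:
    """Full-train simulation output (also used for diagnostics/tests)."""

    times: np.ndarray        # ms, recording-bin midpoints, flash 0 at t = 0
    raw_flux: np.ndarray     # mean flux into the electrode per bin (a.u.)
    filtered: np.ndarray     # raw_flux after the high-pass filter
    produced_total: float    # total O2 amount released by sources
    mass_remaining: float    # O2 left in the domain at the end
    transients: list = field(default_factory=list)


def apply_highpass(signal: np.ndarray, dt_ms: float, filter_tau: float = 100.0):
    """Discrete first-order (single-pole RC) high-pass filter.

    y[n] = a*(y[n-1] + x[n] - x[n-1]) with a = tau/(tau + dt); DC is rejected
    asymptotically and frequencies well above 1/tau pass with unit gain.
    """
    x = np.asarray(signal, dtype=float)
    if dt_ms <= 0 or filter_tau <= 0:
        raise ValidationError("dt and filter_tau must be positive")
    a = filter_tau / (filter_tau + dt_ms)
    y = np.empty_like(x)
    prev_x = 0.0
    prev_y = 0.0
    for i in range(x.size):
        prev_y = a * (prev_y + x[i] - prev_x)
        prev_x = x[i]
        y[i] = prev_y
    return y


def _discretize(model: PolarographyModel):
    """Finite-volume operators on the (possibly graded) grid.

    Returns ``(make_step, cell_measure, inst_flux)``: ``make_step(dt,
    theta)`` builds a theta-scheme step ``step(c, source_half)`` with the
    half-source deposited before and after the diffusion solve (Strang
    splitting); ``cell_measure`` are the node weights such that
    mass = sum(cell_measure * c) (= trapezoid rule); ``inst_flux(c)`` is
    the instantaneous electrode flux (diagnostics).
    """
    x = model.grid
    n = model.n_grid
    dt = model.dt_ms
    d_coef = model.d_um2_ms
    h = np.diff(x)                      # n-1 face spacings
    m = np.empty(n)                     # cell measures (trapezoid weights)
    m[0] = h[0] / 2
    m[-1] = h[-1] / 2
    m[1:-1] = (h[:-1] + h[1:]) / 2

    # tridiagonal diffusion operator A with m_j * dc_j/dt = (A c)_j
    lower = np.zeros(n)                 # A[j, j-1]
    diag = np.zeros(n)
    upper = np.zeros(n)                 # A[j, j+1]
    for j in range(1, n - 1):
        lower[j] = d_coef / h[j - 1]
        upper[j] = d_coef / h[j]
        diag[j] = -(lower[j] + upper[j])
    # far boundary: zero flux, only the left face contributes
    lower[n - 1] = d_coef / h[-1]
    diag[n - 1] = -lower[n - 1]
    if model.electrode == "absorbing":
        diag[0] = 1.0  # placeholder; row is overwritten as Dirichlet below
    elif model.electrode == "reflecting":
        upper[0] = d_coef / h[0]
        diag[0] = -upper[0]
    else:  # robin: electrode consumes at rate robin_rate * c0
        upper[0] = d_coef / h[0]
        diag[0] = -(upper[0] + model.robin_rate)

    def apply_a(c):
        out = np.empty_like(c)
        out[0] = diag[0] * c[0] + upper[0] * c[1]
        out[1:-1] = (lower[1:-1] * c[:-2] + diag[1:-1] * c[1:-1]
                     + upper[1:-1] * c[2:])
        out[-1] = lower[-1] * c[-2] + diag[-1] * c[-1]
        return out

    def make_step(step_dt: float, theta: float = 0.5):
        """theta = 0.5: Crank-Nicolson; theta = 1: backward Euler."""
        ab = np.zeros((3, n))
        ab[0, 1:] = -theta * step_dt * upper[:-1]
        ab[1, :] = m - theta * step_dt * diag
        ab[2, :-1] = -theta * step_dt * lower[1:]
        if model.electrode == "absorbing":
            ab[1, 0] = 1.0
            ab[0, 1] = 0.0
        explicit = (1.0 - theta) * step_dt

        def step(c, source_half):
            c = c + source_half
            rhs = m * c + explicit * apply_a(c)
            if model.electrode == "absorbing":
                rhs[0] = 0.0
            c_new = solve_banded((1, 1), ab, rhs)
            return c_new + source_half

        return step

    def inst_flux(c):
        """Instantaneous diffusive flux into the electrode."""
        if model.electrode == "absorbing":
            return d_coef * (c[1] - c[0]) / h[0]
        if model.electrode == "robin":
            return model.robin_rate * c[0]
        return 0.0

    return make_step, m, inst_flux


def _source_profile(model: PolarographyModel, cell_measure: np.ndarray):
    """Per-node concentration increment for unit released amount.

    Uniform release across the PSII layer: each cell receives mass in
    proportion to its overlap with [0, layer_thickness]; the Dirichlet node
    of an absorbing electrode cannot hold mass.
    """
    x = model.grid
    n = model.n_grid
    d = model.layer_thickness
    faces = np.empty(n + 1)
    faces[0] = x[0]
    faces[-1] = x[-1]
    faces[1:-1] = 0.5 * (x[:-1] + x[1:])
    overlap = np.clip(np.minimum(faces[1:], d) - np.minimum(faces[:-1], d),
                      0.0, None)
    if model.electrode == "absorbing":
        overlap[0] = 0.0
    total = overlap.sum()
    if total <= 0:
        raise ValidationError("PSII layer does not cover any grid cell")
    with np.errstate(divide="ignore", invalid="ignore"):
        profile = np.where(cell_measure > 0, overlap / cell_measure, 0.0)
    return profile / total


def simulate_transients(
    model: PolarographyModel,
    n_flashes: int = 1,
    yields=None,
    pre_ms: float = 20.0,
    post_ms: float = 480.0,
) -> SimulationResult:
    """Evolve the O2 field over a flash train and record filtered transients.

    ``yields`` (default: model.yields, else unit yield on every flash) is the
    per-flash O2 amount; the recorded window of flash n spans
    [-pre_ms, +post_ms] around that flash on the global clock.
    """
    if n_flashes < 1:
        raise ValidationError("n_flashes must be >= 1")
    if yields is None:
        yields = model.yields if model.yields is not None else np.ones(n_flashes)
    yields = np.asarray(yields, dtype=float)
    if yields.shape != (n_flashes,):
        raise ValidationError(f"need one yield per flash, got {yields.shape}")
    dt = model.dt_ms
    spacing = model.flash_spacing
    # the recorded current integrates the flux over each sampling interval
    # (integrating ADC); the solver step subdivides it
    n_sub = max(1, int(round(model.dt_record / dt)))
    dt_rec = n_sub * dt
    t_end = (n_flashes - 1) * spacing + post_ms
    n_bins = int(round((t_end + pre_ms) / dt_rec))
    n_steps = n_bins * n_sub
    times = -pre_ms + dt * np.arange(n_steps + 1)
    times_rec = -pre_ms + dt_rec * (np.arange(n_bins) + 0.5)
    flash_times = spacing * np.arange(n_flashes)

    make_step, cell_measure, inst_flux = _discretize(model)
    step_cn = make_step(dt, theta=0.5)
    # the flash switches the source on discontinuously (sqrt(t) flux onset);
    # damped sub-steps right after each flash keep the Crank-Nicolson
    # scheme's accuracy (Rannacher-style startup)
    onset_steps = 8
    sub_dt = dt / 16
    step_onset = make_step(sub_dt, theta=1.0)
    profile = _source_profile(model, cell_measure)
    c = np.zeros(model.n_grid)
    rates = np.zeros(n_steps)  # mass-loss rate per step (midpoint value)

    def released(t0, t1):
        """O2 amount released by all flashes within the interval [t0, t1]."""
        amount = 0.0
        for tf, y in zip(flash_times, yields):
            if y == 0.0 or t1 <= tf:
                continue
            a = max(t0, tf)
            amount += y * (
                np.exp(-(a - tf) / model.tau_ox)
                - np.exp(-(t1 - tf) / model.tau_ox)
            )
        return amount

    def mass(c):
        return float(np.dot(cell_measure, c))

    # raw signal = O2 flux into the electrode as the scheme's exact
    # per-step mass-loss rate (mass conservative by construction and
    # insensitive to stiff-mode ringing); node-time values are the average
    # of adjacent step rates
    m_prev = mass(c)
    onset_len = onset_steps * dt
    for i in range(n_steps):
        t0, t1 = times[i], times[i + 1]
        in_onset = any(
            t0 < tf + onset_len and t1 > tf - dt / 2
            for tf, y in zip(flash_times, yields) if y != 0.0
        )
        q = released(t0, t1)
        if in_onset:
            for k in range(16):
                qk = released(t0 + k * sub_dt, t0 + (k + 1) * sub_dt)
                c = step_onset(c, 0.5 * qk * profile)
        else:
            c = step_cn(c, 0.5 * q * profile)
        m_new = mass(c)
        rates[i] = (m_prev + q - m_new) / dt
        m_prev = m_new
    # bin-average the per-step mass-loss rates into recording samples;
    # each sample is the exact mean flux over its interval
    raw = rates.reshape(n_bins, n_sub).mean(axis=1)

    filtered = apply_highpass(raw, dt_rec, model.filter_tau)
    produced = released(times[0], times[-1])
    mass_left = mass(c)

    transients = []
    for n, tf in enumerate(flash_times):
        sel = (times_rec > tf - pre_ms) & (times_rec < tf + post_ms)
        transients.append(
            CurrentTransient(times=times_rec[sel] - tf, current=filtered[sel],
                             flash_index=n)
        )
    return SimulationResult(
        times=times_rec,
        raw_flux=raw,
        filtered=filtered,
        produced_total=float(produced),
        mass_remaining=mass_left,
        transients=transients,
    )


def _average_transients(transients) -> CurrentTransient:
    n = min(t.times.size for t in transients)
    stack = np.stack([t.current[:n] for t in transients])
    return CurrentTransient(times=transients[0].times[:n],
                            current=stack.mean(axis=0))


def fit_tau_ox(
    observed,
    model_template: PolarographyModel,
    tau_init: float | None = None,
    scale_init: float = 1.0,
    max_nfev: int = 100,
):
    """Extract tau_ox by least squares against the forward model.

    ``observed`` is a list of CurrentTransient recorded under the template's
    geometry/filter/protocol; tau_ox and an overall amplitude scale are free.
    Transients are averaged and the post-flash window (t >= 0) is fitted.
    Returns ``(tau_ox_ms, scale, result_dict)``.
    """
    if isinstance(observed, CurrentTransient):
        observed = [observed]
    avg = _average_transients(list(observed))
    mask = avg.times >= 0
    t_obs = avg.times[mask]
    y_obs = avg.current[mask]
    n_flashes = len(observed)
    yields = (model_template.yields if model_template.yields is not None
              else np.ones(n_flashes))
    # observed samples are recording-bin midpoints; recover the window
    # edges so the re-simulation bins align with the flash
    dt_rec = float(avg.times[1] - avg.times[0]) if avg.times.size > 1 \
        else model_template.dt_record
    pre = float(dt_rec / 2 - avg.times[0])
    post = float(t_obs[-1] + dt_rec / 2)

    def simulated(tau, scale):
        m = replace(model_template, tau_ox=float(tau), yields=None)
        res = simulate_transients(m, n_flashes=n_flashes, yields=yields,
                                  pre_ms=pre, post_ms=post)
        sim = _average_transients(res.transients)
        sel = sim.times >= 0
        return scale * np.interp(t_obs, sim.times[sel], sim.current[sel])

    def residuals(theta):
        return simulated(np.exp(theta[0]), np.exp(theta[1])) - y_obs

    tau0 = tau_init if tau_init is not None else model_template.tau_ox
    x0 = np.log([tau0, scale_init])
    # keep tau_ox resolvable by the template's time step during the search
    lo_tau = np.log(4.0 * model_template.dt_ms * 1.001)
    sol = least_squares(residuals, x0, method="trf", max_nfev=max_nfev,
                        bounds=([lo_tau, -np.inf], [np.inf, np.inf]))
    if not (sol.success or sol.status > 0):
        raise FitError("tau_ox fit did not converge",
                       best={"tau_ox": float(np.exp(sol.x[0]))})
    tau_fit = float(np.exp(sol.x[0]))
    scale_fit = float(np.exp(sol.x[1]))
    diagnostics = {
        "residual_norm": float(np.linalg.norm(sol.fun)),
        "n_evaluations": int(sol.nfev),
        "success": bool(sol.success),
    }
    return tau_fit, scale_fit, diagnostics
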