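"""Global multiexponential lifetime analysis and decay-associated spectra.

The flash-induced absorbance change at wavenumber nu is modelled as a sum of
exponential rise components sharing time constants across all wavenumbers:

    F_nu(t) = sum_i A_nu,i * (1 - exp(-t / tau_i)) + B_nu

The per-component amplitude spectra A_nu,i are the decay-associated spectra
(DAS); B_nu collects changes faster than the instrument response.  The fit is
a variable projection: the nonlinear search runs over log(tau) only, while at
every tau evaluation the amplitudes and offsets are the exact solution of the
linear least-squares subproblem for all wavenumbers simultaneously.  This is
what makes a simultaneous fit of thousands of transients tractable and keeps
tau > 0 by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dataset import SpectrumVector, WavenumberGrid
from .exceptions import FitError, ValidationError

log = logging.getLogger(__name__)

#: Default fit window start: 9 us after the flash (instrument response limit).
DEFAULT_FIT_START_US = 9.0


@dataclass
class ExponentialFitModel:
    """Parameters of the shared-lifetime exponential model.

    ``taus`` are in microseconds, strictly ascending; ``amplitudes`` has
    shape (n_wavenumbers, n_components); ``offsets`` has shape
    (n_wavenumbers,).
    """

    taus: np.ndarray
    amplitudes: np.ndarray
    offsets: np.ndarray
    fit_start: float = DEFAULT_FIT_START_US

    def __post_init__(self):
        taus = np.atleast_1d(np.asarray(self.taus, dtype=float))
        amps = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        offs = np.atleast_1d(np.asarray(self.offsets, dtype=float))
        if np.any(taus <= 0):
            raise ValidationError("all time constants must be positive")
        if taus.size > 1 and not np.all(np.diff(taus) > 0):
            raise ValidationError("time constants must be strictly ascending")
        if amps.shape != (offs.size, taus.size):
            raise ValidationError(
                f"amplitudes shape {amps.shape} != "
                f"(n_wavenumbers={offs.size}, n_components={taus.size})"
            )
        self.taus, self.amplitudes, self.offsets = taus, amps, offs

    @property
    def n_components(self) -> int:
        return self.taus.size


def design_matrix(taus_us: np.ndarray, times_us: np.ndarray) -> np.ndarray:
    """Columns (1 - exp(-t/tau_i)) plus a constant column for the offset."""
    t = np.asarray(times_us, dtype=float)[:, None]
    phi = 1.0 - np.exp(-t / np.asarray(taus_us, dtype=float)[None, :])
    return np.hstack([phi, np.ones((t.shape[0], 1))])


def evaluate_model(model: ExponentialFitModel, times_us) -> np.ndarray:
    """Evaluate F_nu(t) on ``times_us`` (>= 0); returns (n_times, n_wn)."""
    t = np.asarray(times_us, dtype=float)
    if np.any(t < 0):
        raise ValidationError("model is defined for t >= 0 (post-flash) only")
    phi = design_matrix(model.taus, t)
    coef = np.vstack([model.amplitudes.T, model.offsets[None, :]])
    return phi @ coef


@dataclass
class DASResult:
    """Result of a global fit: model, DAS per component, diagnostics."""

    model: ExponentialFitModel
    wavenumbers: WavenumberGrid | None
    residual_norm: float
    per_wavenumber_residual: np.ndarray
    n_iterations: int
    condition_number: float
    success: bool
    degenerate_pairs: list = field(default_factory=list)
    labels: dict = field(default_factory=dict)

    @property
    def taus(self) -> np.ndarray:
        return self.model.taus

    @property
    def das(self) -> list:
        """One spectrum (A_nu,i column) per time constant, ascending in tau."""
        return [self._spectrum(self.model.amplitudes[:, i])
                for i in range(self.model.n_components)]

    @property
    def offset_spectrum(self):
        return self._spectrum(self.model.offsets)

    def _spectrum(self, values):
        if self.wavenumbers is not None:
            return SpectrumVector(self.wavenumbers, values)
        return np.asarray(values)

    def label(self, mapping: dict):
        """Attach names to components by nearest tau, e.g. {'t_O2': 2500.0}."""
        for name, tau in mapping.items():
            self.labels[name] = int(np.argmin(np.abs(self.model.taus - tau)))
        return self


def extract_das(result: DASResult, component) -> SpectrumVector:
    """DAS of one component, addressed by index or by label (e.g. 't_O2')."""
    if isinstance(component, str):
        if component not in result.labels:
            raise KeyError(
                f"unknown component label {component!r}; known labels: "
                f"{sorted(result.labels)}"
            )
        component = result.labels[component]
    n = result.model.n_components
    if not -n <= component < n:
        raise KeyError(f"component index {component} out of range for {n} components")
    return result.das[component]


def _solve_linear(phi: np.ndarray, data: np.ndarray):
    coef, *_ = np.linalg.lstsq(phi, data, rcond=None)
    return coef


def global_fit(
    data: np.ndarray,
    times_us: np.ndarray,
    init_taus=None,
    n_components: int | None = None,
    fit_start: float = DEFAULT_FIT_START_US,
    wavenumbers: WavenumberGrid | None = None,
    multi_start: int = 0,
    seed: int | None = None,
    max_nfev: int = 400,
) -> DASResult:
    """Variable-projection global fit of (n_times, n_wavenumbers) data.

    ``init_taus`` (microseconds) seeds the nonlinear search; with
    ``multi_start > 0`` additional log-uniform random starts are drawn
    (seed-controlled) and the best final residual wins.  Samples earlier than
    ``fit_start`` after the flash are excluded from the objective.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    times_us = np.asarray(times_us, dtype=float)
    if data.shape[0] != times_us.size:
        raise ValidationError(
            f"data has {data.shape[0]} time samples but time axis has "
            f"{times_us.size}"
        )
    if init_taus is None and multi_start <= 0:
        raise ValidationError("provide init_taus and/or multi_start > 0")
    if init_taus is not None:
        init_taus = np.sort(np.atleast_1d(np.asarray(init_taus, dtype=float)))
        if np.any(init_taus <= 0):
            raise ValidationError("initial time constants must be positive")
        if n_components is None:
            n_components = init_taus.size
        elif n_components != init_taus.size:
            raise ValidationError(
                f"n_components={n_components} but {init_taus.size} initial "
                "time constants given"
            )
    if n_components is None or n_components < 1:
        raise ValidationError("n_components must be >= 1")

    mask = times_us >= fit_start
    if mask.sum() <= n_components + 1:
        raise ValidationError("too few samples after fit_start for the model")
    t_fit = times_us[mask]
    y_raw = data[mask]
    # normalize to unit scale: fitted taus are invariant to uniform
    # amplitude rescaling, and the optimizer tolerances become meaningful
    # for micro-OD data
    y_scale = np.max(np.abs(y_raw))
    if y_scale == 0.0:
        y_scale = 1.0
    y_fit = y_raw / y_scale
    span = t_fit[-1] - t_fit[0]
    if init_taus is not None and span < 10.0 * init_taus[-1]:
        log.warning(
            "data span %.3g us covers less than 10x the largest initial tau "
            "(%.3g us); slow components may be poorly determined",
            span, init_taus[-1],
        )

    def residuals(log_taus):
        phi = design_matrix(np.exp(log_taus), t_fit)
        coef = _solve_linear(phi, y_fit)
        return (phi @ coef - y_fit).ravel()

    starts = []
    if init_taus is not None:
        starts.append(np.log(init_taus))
    if multi_start > 0:
        rng = np.random.default_rng(seed)
        lo = np.log(max(t_fit[0], 1e-3))
        hi = np.log(span)
        for _ in range(multi_start):
            starts.append(np.sort(rng.uniform(lo, hi, size=n_components)))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, method="trf", max_nfev=max_nfev,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # numerical failure from a bad start
            log.debug("fit start %s failed: %s", np.exp(x0), exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all fit starts failed", best=None)
    if not best.success:
        warnings.warn(
            "global fit did not formally converge; returning best-so-far",
            RuntimeWarning,
        )

    taus = np.exp(best.x)
    order = np.argsort(taus)
    taus = taus[order]
    # re-solve the linear subproblem exactly at the returned taus
    phi = design_matrix(taus, t_fit)
    cond = float(np.linalg.cond(phi))
    coef = _solve_linear(phi, y_raw)
    amplitudes = coef[:n_components].T
    offsets = coef[n_components]
    resid = phi @ coef - y_raw

    degenerate = []
    for i in range(n_components - 1):
        if taus[i + 1] / taus[i] < 1.05:
            degenerate.append((i, i + 1))
    if degenerate:
        warnings.warn(
            f"time constants nearly degenerate (within 5%): "
            f"{[(taus[i], taus[j]) for i, j in degenerate]}",
            RuntimeWarning,
        )
    log.info(
        "global fit: %d components, %d evaluations, residual %.6g, "
        "design-matrix condition number %.3g",
        n_components, best.nfev, float(np.linalg.norm(resid)), cond,
    )
    model = ExponentialFitModel(taus, amplitudes, offsets, fit_start=fit_start)
    return DASResult(
        model=model,
        wavenumbers=wavenumbers,
        residual_norm=float(np.linalg.norm(resid)),
        per_wavenumber_residual=np.linalg.norm(resid, axis=0),
        n_iterations=int(best.nfev),
        condition_number=cond,
        success=bool(best.success),
        degenerate_pairs=degenerate,
    )


def steady_state_spectrum(
    data: np.ndarray,
    times_us: np.ndarray,
    wavenumbers: WavenumberGrid | None = None,
    window_us: tuple = (300_000.0, 1_000_000.0),
):
    """Per-wavenumber mean over a late post-flash window.

    The default window (300 ms to 1 s) reproduces the conventional
    steady-state difference spectrum; for the exponential model it converges
    to sum_i A_nu,i + B_nu once the window start exceeds all lifetimes.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    times_us = np.asarray(times_us, dtype=float)
    lo, hi = window_us
    mask = (times_us >= lo) & (times_us <= hi)
    if not mask.any():
        raise ValidationError(
            f"no samples inside the steady-state window [{lo}, {hi}] us "
            f"(data cover [{times_us[0]}, {times_us[-1]}] us)"
        )
    values = data[mask].mean(axis=0)
    if wavenumbers is not None:
        return SpectrumVector(wavenumbers, values)
    return values
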