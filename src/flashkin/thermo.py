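"""Arrhenius regression and Eyring transition-state decomposition.

The temperature dependence of the O2-formation time constant tau_ox gives the
activation energy E_act as the slope of the unweighted regression of
ln(tau_ox) against (k_B*T)^-1.  Transition-state theory then decomposes the
free energy of activation at a reference temperature T0,

    k = kappa * (k_B*T/h) * exp(-dG/(k_B*T)),        kappa = 1,

into an enthalpic part H_act and an entropic part T0*S_act = H_act - dG.
A strongly negative activation entropy slows the reaction by the Boltzmann
factor exp(|T0*S_act| / (k_B*T0)) relative to a purely enthalpic barrier.

Units: temperatures in K, time constants in ms (converted to s for rate
constants), energies reported in meV and kcal mol^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import KB_EV, attempt_frequency, kbt_ev, mev_to_kcal_mol
from .exceptions import ValidationError

CONVENTIONS = ("condensed", "identity")


@dataclass
class ArrheniusDataset:
    """Per-temperature replicate time constants.

    ``temperatures`` in K (distinct); ``tau_ox`` is a list/array of replicate
    values in ms per temperature (ragged allowed).
    """

    temperatures: np.ndarray
    tau_ox: list

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 2 or np.unique(t).size != t.size:
            raise ValidationError("need >= 2 distinct temperatures")
        taus = [np.atleast_1d(np.asarray(x, dtype=float)) for x in self.tau_ox]
        if len(taus) != t.size:
            raise ValidationError("one tau_ox group per temperature required")
        for group in taus:
            if np.any(group <= 0):
                raise ValidationError("all time constants must be positive")
        self.temperatures = t
        self.tau_ox = taus

    @property
    def mean_tau(self) -> np.ndarray:
        return np.array([g.mean() for g in self.tau_ox])

    @property
    def n_per_point(self) -> np.ndarray:
        return np.array([g.size for g in self.tau_ox])


@dataclass
class ArrheniusFit:
    """Slope/intercept of ln(tau) vs (k_B*T)^-1 with 1-sigma slope CI."""

    e_act_mev: float
    prefactor_per_s: float
    slope_sigma_mev: float  # NaN when only two temperatures
    intercept: float        # ln(tau/s) extrapolated to (k_B*T)^-1 = 0
    r_squared: float

    @property
    def e_act_kcal_mol(self) -> float:
        return mev_to_kcal_mol(self.e_act_mev)

    def tau_at(self, temperature_k: float) -> float:
        """Regression-line time constant at a temperature, in ms."""
        x = 1.0 / kbt_ev(temperature_k)
        return float(np.exp(self.intercept + self.e_act_mev / 1e3 * x)) * 1e3


def arrhenius_fit(data: ArrheniusDataset) -> ArrheniusFit:
    """Unweighted OLS of per-temperature mean ln(tau) on (k_B*T)^-1.

    The slope is E_act; the 1-sigma confidence interval of the slope is the
    reported uncertainty.  With exactly two temperatures the line
    interpolates and the CI is undefined (NaN).
    """
    x = 1.0 / (KB_EV * data.temperatures)          # (eV)^-1
    y = np.log(data.mean_tau / 1e3)                # ln(tau in s)
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        sigma = np.nan
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        sigma = res.stderr
        r2 = res.rvalue ** 2
    # ln(tau) = E/(kB T) - ln A  =>  intercept = -ln A
    return ArrheniusFit(
        e_act_mev=float(slope * 1e3),
        prefactor_per_s=float(np.exp(-intercept)),
        slope_sigma_mev=float(sigma * 1e3) if np.isfinite(sigma) else np.nan,
        intercept=float(intercept),
        r_squared=float(r2),
    )


@dataclass
class ActivationResult:
    """Eyring decomposition of a rate at a reference temperature."""

    e_act_mev: float
    prefactor_per_s: float
    slope_sigma_mev: float
    delta_g_mev: float       # free energy of activation at T0
    h_act_mev: float
    ts_act_mev: float        # T0 * S_act, negative for entropic slowdown
    s_act_mev_per_k: float
    t0: float
    kappa: float
    slowdown: float          # exp((dG - H)/kB T0), > 1 for entropic slowdown
    convention: str
    h_act_sigma_mev: float = np.nan       # relative-uncertainty propagation
    ts_act_sigma_mev: float = np.nan
    h_act_sigma_abs_mev: float = np.nan   # equal-absolute-uncertainty variant
    ts_act_sigma_abs_mev: float = np.nan

    @property
    def e_act_kcal_mol(self) -> float:
        return mev_to_kcal_mol(self.e_act_mev)

    def rate_from_free_energy(self) -> float:
        """Reconstruct k (s^-1) from (dG, T0); inverts the decomposition."""
        nu = attempt_frequency(self.t0, self.kappa)
        return nu * np.exp(-self.delta_g_mev / 1e3 / kbt_ev(self.t0))


def eyring_decompose(
    tau_ms: float,
    temperature_k: float,
    e_act_mev: float,
    kappa: float = 1.0,
    convention: str = "condensed",
    slope_sigma_mev: float = np.nan,
    prefactor_per_s: float = np.nan,
) -> ActivationResult:
    """Decompose a rate 1/tau into enthalpic and entropic activation terms.

    ``convention`` selects how the Arrhenius activation energy maps to the
    activation enthalpy: "condensed" (condensed-phase unimolecular,
    H_act = E_act - k_B*T) or "identity" (H_act = E_act).
    """
    if tau_ms <= 0 or temperature_k <= 0:
        raise ValidationError("tau and T must be positive")
    if convention not in CONVENTIONS:
        raise ValidationError(
            f"convention must be one of {CONVENTIONS}, got {convention!r}"
        )
    k = 1.0 / (tau_ms / 1e3)                      # s^-1
    nu = attempt_frequency(temperature_k, kappa)  # s^-1
    if k >= nu:
        raise ValidationError(
            f"rate {k:.3g}/s is at or above the attempt frequency "
            f"{nu:.3g}/s; no positive activation free energy exists"
        )
    kbt = kbt_ev(temperature_k)                   # eV
    dg_mev = kbt * np.log(nu / k) * 1e3
    if convention == "condensed":
        h_mev = e_act_mev - kbt * 1e3
    else:
        h_mev = e_act_mev
    ts_mev = h_mev - dg_mev
    slowdown = float(np.exp((dg_mev - h_mev) / 1e3 / kbt))
    if np.isfinite(slope_sigma_mev) and e_act_mev != 0:
        rel = abs(slope_sigma_mev / e_act_mev)
        h_sig, ts_sig = abs(h_mev) * rel, abs(ts_mev) * rel
    else:
        h_sig = ts_sig = np.nan
    return ActivationResult(
        e_act_mev=float(e_act_mev),
        prefactor_per_s=float(prefactor_per_s),
        slope_sigma_mev=float(slope_sigma_mev),
        delta_g_mev=float(dg_mev),
        h_act_mev=float(h_mev),
        ts_act_mev=float(ts_mev),
        s_act_mev_per_k=float(ts_mev / temperature_k),
        t0=float(temperature_k),
        kappa=float(kappa),
        slowdown=slowdown,
        convention=convention,
        h_act_sigma_mev=float(h_sig),
        ts_act_sigma_mev=float(ts_sig),
        h_act_sigma_abs_mev=float(slope_sigma_mev),
        ts_act_sigma_abs_mev=float(slope_sigma_mev),
    )


def activation_from_arrhenius(
    fit: ArrheniusFit,
    t0: float = 293.15,
    kappa: float = 1.0,
    convention: str = "condensed",
) -> ActivationResult:
    """Full chain: Arrhenius fit -> Eyring decomposition at T0.

    The time constant at T0 is taken from the regression line.
    """
    return eyring_decompose(
        tau_ms=fit.tau_at(t0),
        temperature_k=t0,
        e_act_mev=fit.e_act_mev,
        kappa=kappa,
        convention=convention,
        slope_sigma_mev=fit.slope_sigma_mev,
        prefactor_per_s=fit.prefactor_per_s,
    )


def enthalpic_limit_tau(
    delta_g_mev: float, temperature_k: float, kappa: float = 1.0
) -> float:
    """Eyring time constant (s) for a given activation free energy.

    tau = h / (kappa * k_B * T) * exp(dG / (k_B * T)).  With dG equal to a
    purely enthalpic barrier of ~310 meV at 293.15 K this is below 1 us —
    orders of magnitude faster than the observed millisecond kinetics.
    """
    if temperature_k <= 0 or kappa <= 0:
        raise ValidationError("temperature and kappa must be positive")
    kbt = kbt_ev(temperature_k)
    return float(
        np.exp(delta_g_mev / 1e3 / kbt) / attempt_frequency(temperature_k, kappa)
    )


def entropic_slowdown(entropic_contribution_mev: float, temperature_k: float) -> float:
    """Boltzmann slowdown factor exp(E_s / (k_B * T)) of an entropic barrier."""
    if temperature_k <= 0:
        raise ValidationError("temperature must be positive")
    return float(np.exp(entropic_contribution_mev / 1e3 / kbt_ev(temperature_k)))
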