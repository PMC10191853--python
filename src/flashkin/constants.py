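"""Physical constants and unit conversions (CODATA via scipy.constants).

Energies are handled in eV internally; user-facing activation quantities are
reported in meV and kcal mol^-1. Times follow the module they live in:
microseconds for IR kinetics, milliseconds for polarography, seconds for rate
constants.
"""

from scipy import constants as _c

#: Boltzmann constant, J K^-1
KB_J = _c.k
#: Planck constant, J s
H_J = _c.h
#: Boltzmann constant, eV K^-1 (~8.617e-5)
KB_EV = _c.k / _c.e
#: 1 kcal mol^-1 in meV (~43.364)
MEV_PER_KCAL_MOL = 4184.0 / (_c.N_A * _c.e) * 1e3


def kbt_ev(temperature_k: float) -> float:
    """Thermal energy k_B*T in eV."""
    return KB_EV * temperature_k


def kbt_mev(temperature_k: float) -> float:
    """Thermal energy k_B*T in meV (~25.26 meV at 293.15 K)."""
    return KB_EV * temperature_k * 1e3


def attempt_frequency(temperature_k: float, kappa: float = 1.0) -> float:
    """Transition-state-theory prefactor kappa*k_B*T/h in s^-1."""
    return kappa * KB_J * temperature_k / H_J


def kcal_mol_to_mev(value: float) -> float:
    return value * MEV_PER_KCAL_MOL


def mev_to_kcal_mol(value: float) -> float:
    return value / MEV_PER_KCAL_MOL
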