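#!/usr/bin/env python
"""Activation thermodynamics of the O2-formation step.

Simulates the temperature series of tau_ox (Arrhenius law at 310 meV, 5%
lognormal noise, 7 temperatures, 3 replicates), refits the activation
energy by the unweighted ln(tau_ox) vs (kB*T)^-1 regression, decomposes the
free energy of activation at T0 = 293.15 K with the Eyring equation, and
evaluates the enthalpic-limit time constant and the entropic slowdown.
Writes the activation table to results/.
"""

import json
from pathlib import Path

from flashkin import protocols
from flashkin.synthetic import generate_arrhenius_series
from flashkin.thermo import activation_from_arrhenius, arrhenius_fit

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main():
    data = generate_arrhenius_series(e_act_mev=protocols.E_ACT_MEV,
                                     tau_ref_ms=2.5,
                                     t_ref=protocols.T0_K, seed=SEED)
    fit = arrhenius_fit(data)
    act = activation_from_arrhenius(fit, t0=protocols.T0_K)

    tau_limit_us = protocols.enthalpic_limit_microseconds()
    slowdown = protocols.entropic_slowdown_factor()

    table = {
        "E_act_meV": round(act.e_act_mev, 1),
        "E_act_1sigma_meV": round(act.slope_sigma_mev, 1),
        "E_act_kcal_mol": round(act.e_act_kcal_mol, 2),
        "deltaG_meV_at_T0": round(act.delta_g_mev, 1),
        "H_act_meV": round(act.h_act_mev, 1),
        "T0_S_act_meV": round(act.ts_act_mev, 1),
        "slowdown_from_fit": round(act.slowdown, 0),
        "convention": act.convention,
        "T0_K": act.t0,
        "enthalpic_limit_tau_us_at_310meV": tau_limit_us,
        "slowdown_at_285meV": slowdown,
        "seed": SEED,
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "05_activation.json").write_text(json.dumps(table, indent=1))

    print(f"refit E_act = {act.e_act_mev:.1f} +/- {act.slope_sigma_mev:.1f} "
          f"meV (generator: 310 meV)")
    print(f"dG(T0) = {act.delta_g_mev:.0f} meV; H_act = {act.h_act_mev:.0f} "
          f"meV; T0*S_act = {act.ts_act_mev:.0f} meV")
    print(f"a purely enthalpic 310 meV barrier would give tau = "
          f"{tau_limit_us:.3g} us (< 1 us), i.e. the observed millisecond "
          f"kinetics imply an entropic slowdown; 285 meV of entropic "
          f"contribution corresponds to a factor {slowdown:.3g} (> 10,000)")


if __name__ == "__main__":
    main()
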