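# flashkin

Analysis chain for time-resolved flash spectroscopy of photosynthetic
oxygen evolution in photosystem II (PSII), plus the forward model of
flash-induced O₂ polarography.

## The problem

The oxygen-evolving Mn₄CaO₅ cluster of PSII cycles through the Kok S-states
S0→S1→S2→S3→S0; O₂ is released on the S3→S0 step. Saturating laser flashes
applied to dark-adapted (pure-S1) samples advance the cycle one step per
flash, up to a *miss* probability α and a *double-hit* probability β, so the
O₂ yield oscillates with period four (maximal on flash 3) and flash-indexed
data are a known linear mixture of the four pure transitions. Time-resolved
IR difference spectra of the S3→S0 transition resolve an obligatory proton
release phase (t_H⁺ = 340 µs) preceding the rate-determining O₂ formation
step (t_O₂ = 2.5 ms); the temperature dependence of t_O₂ gives a moderate
activation energy whose Eyring decomposition reveals a large entropic
slowdown. This package implements every computational step of that chain,
with a ground-truth synthetic-data generator in place of the spectrometer.

## The models

* **Kok deconvolution** (`flashkin.kok`). Single-flash advancement matrix
  (stay α, advance 1−α−β, double-advance β, cyclic mod 4); expected
  transition weights W[n, j] per flash; per-cell ordinary least squares
  `data[n] ≈ Σ_j W[n,j]·transition_j` through one shared pseudo-inverse.
* **Global lifetime analysis** (`flashkin.globalfit`). Shared-lifetime
  exponential model `F_ν(t) = Σ_i A_ν,i (1 − e^(−t/τ_i)) + B_ν`; the
  amplitude spectra A_ν,i are the decay-associated spectra (DAS). Fitted by
  variable projection: nonlinear search over log τ only, exact linear solve
  for all amplitudes at each step, fit window starting 9 µs after the flash.
* **Spectral corrections** (`flashkin.corrections`). The millisecond DAS of
  S3→S0 contains an acceptor-side (quinone) contribution that oscillates
  with flash parity; the 3.1 ms DAS of S1→S2 is subtracted pointwise without
  further scaling. Heat artifacts are removed as a flash-synchronized,
  time-independent additive spectrum.
* **Activation thermodynamics** (`flashkin.thermo`). Unweighted regression
  of ln τ_ox on (k_B T)⁻¹ gives E_act with a 1σ slope CI; the Eyring
  equation k = κ(k_BT/h)·e^(−ΔG‡/k_BT) (κ = 1) decomposes ΔG‡ at
  T₀ = 293.15 K into H_act and T₀S_act = H_act − ΔG‡.
* **O₂ polarography** (`flashkin.polarography`). 1D diffusion of O₂ from a
  PSII layer (first-order release, time constant τ_ox, period-4 yields)
  to an absorbing electrode, finite volumes on a graded mesh with
  Crank–Nicolson stepping, recorded through a first-order 100 ms high-pass
  filter; τ_ox is refit by least squares against the forward model.
* **Synthetic data** (`flashkin.synthetic`). Generates flash series from
  known per-transition kinetics (S3→S0: 340 µs, 2.5 ms; S1→S2: 33 µs,
  91 µs, 25 ms plus the parity-locked 3.1 ms acceptor component),
  heat artifact and Gaussian noise — always together with the exact ground
  truth.

## Worked example

The numbered drivers under `analysis/` run the chain on synthetic data
(64 wavenumbers, 12 µs sampling — reduced from the instrument's 2,582
wavenumbers at 6 µs) and write tables under `results/`:

```
$ python analysis/01_simulate.py
dataset: 10 flashes x 11001 samples x 64 wavenumbers, noise sigma 5e-07 OD
O2 yield maximal on flash 3 (period-4 pattern, damped by the 0.1 miss factor)

$ python analysis/02_deconvolve.py
transition weights on flash 3: {'S0->S1': 0.0, 'S1->S2': 0.009, 'S2->S3': 0.162, 'S3->S0': 0.729}

$ python analysis/03_fit_das.py
S3->S0 phases: 334 us (proton release) and 2.60 ms (O2 formation; ...)
S1->S2 phases (us): [33.7, 85.4, 3064.8, 25051.3]

$ python analysis/04_correct.py
ms-DAS deviation from the true O2 spectrum: 53.5% before correction, 12.7% after

$ python analysis/05_thermo.py
refit E_act = 317.8 +/- 3.8 meV (generator: 310 meV)
dG(T0) = 592 meV; H_act = 293 meV; T0*S_act = -300 meV
a purely enthalpic 310 meV barrier would give tau = 0.035 us (< 1 us) ...

$ python analysis/06_polarography.py
per-flash O2 yields (miss 0.1): [0.0, 0.0, 0.729, 0.219, 0.044, 0.007, 0.479, 0.335]
tau_ox refit from 8 averaged noisy transients: 2.506 ms (true 2.5 ms, scale 1.015)
```

Reading the numbers: flash 3 carries 72.9% S3→S0 character at miss factor
0.1, and the global fit of the deconvolved S3→S0 series returns the two
donor-side phases near their generating values (334 µs, 2.60 ms — the ms
phase is biased upward by the folded-in 3.1 ms acceptor component, which
the unscaled subtraction then largely removes). A purely enthalpic 310 meV
barrier would imply a sub-microsecond time constant; the observed
millisecond kinetics correspond to ~300 meV of entropic contribution, a
slowdown factor near 10⁵.

The same stages are available as CLI subcommands
(`flashkin simulate|deconvolve|fit-das|correct|thermo|polaro|run`).

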