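# Methods

This note documents the models, parameter choices and numerical decisions
behind `flashkin`, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Kok model and deconvolution

The S-state cycle is a 4-state Markov chain over (S0, S1, S2, S3). Per
flash a centre stays with probability α (miss), advances one step with
1−α−β and advances two with β (double hit), indices cyclic so S3 advances
to S0 with O₂ release. Defaults α = 0.1, β = 0, pure-S1 start — the
conventional literature values for dark-adapted samples under saturating
nanosecond flashes (β ≈ 0 because a 5 ns flash cannot turn over a centre
twice); both are exposed in every interface because deconvolution quality
is sensitive to them. An optional per-state miss vector generalizes α.

The expected fraction of centres executing transition j on flash n is
`W[n,j] = p_j(1−α_j) + p_{j−1}·β` with p the populations before the flash;
a double hit executes two transitions and both legs are credited. No
S2/S3 deactivation is modelled between flashes: at 700–900 ms spacing the
back-reaction losses are small against the dark-stable S-state lifetimes.

Deconvolution solves `data[n] ≈ Σ_j W[n,j]·X_j` independently per
(time, wavenumber) cell through one shared pseudo-inverse, which makes it
exact on data synthesized from the same weights; the weight matrix is
rejected if rank-deficient or with condition number above 1e8 (at which
point the unmixing would amplify noise beyond use). The tests verify
matrix propagation against exhaustive enumeration of all 3ⁿ per-flash
outcome paths (n ≤ 6, tolerance 1e−12), population conservation, damping
of the period-4 yield oscillation, and exact unmix-after-mix recovery.

## Global lifetime analysis (DAS)

All wavenumbers share the time constants; amplitudes and offsets are
linear. The fit is a variable projection: `scipy.optimize.least_squares`
searches over log τ (which enforces τ > 0 and equalizes step scales across
decades), and at every evaluation the amplitude matrix is the exact
least-squares solution for all wavenumbers simultaneously. The data are
normalized to unit peak before fitting — fitted taus are invariant to
uniform rescaling, and micro-OD signals would otherwise sit below the
optimizer's termination tolerances (set to 1e−12).

Choices: the fit window starts 9 µs after the flash (instrument response);
returned components are sorted ascending in τ; components within 5% of
each other are flagged as degenerate, not merged; initialization is
user-supplied, with an optional seeded log-uniform multi-start (best final
residual wins) for when no good guess exists. The rise form
`A(1 − e^(−t/τ))` is used throughout; decays are negative amplitudes. The
number of components is a user decision, not automated model selection.

Property tests: noise-free simulate-then-fit identity (τ to ≤0.1%,
amplitudes to ≤1e−6 for components separated by ≥3×), invariance to
wavenumber permutation and amplitude rescaling, residual monotonicity in
component count, and consistency (τ error shrinking with noise at
σ ∈ {10%, 1%, 0.1%} of peak).

A caution established while validating: with components at 2.5 ms and
3.1 ms (ratio 1.24) under noise at 10% of peak, the global minimum of the
objective is genuinely displaced from the generating values (the fitted
pair straddles them); the DAS shapes, not the taus alone, identify which
component is the O₂-formation phase. The recovery protocol therefore
matches fitted DAS against the generating O₂ spectrum by cosine
similarity.

## Corrections

Acceptor-side: the two-electron quinone chemistry at the PSII acceptor
side alternates with flash parity, not with S-state period 4, so its
millisecond signature appears in both the S1→S2 (flash 1) and S3→S0
(flash 3) millisecond DAS. The correction subtracts the 3.1 ms DAS of
S1→S2 from the millisecond DAS of S3→S0 pointwise with scaling fixed at 1.
On synthetic data this removal is exact only when the deconvolution leaks
the parity component equally into both transitions (true at α = 0; at
α = 0.1 the leak coefficients are ≈1.35 and ≈1.57, leaving a small
residual — the analysis drivers report before/after errors against ground
truth).

Heat artifact: modelled as a flash-synchronized, time-independent additive
spectrum with optional per-flash scales, supplied as data (never
hard-coded). Whether the real artifact has time structure is unknown to
this implementation; the time-independent form is a declared assumption.

## Activation thermodynamics

E_act is the slope of the unweighted ordinary least-squares regression of
per-temperature mean ln τ_ox on (k_B T)⁻¹; its 1σ slope confidence
interval is the reported uncertainty (undefined with only two
temperatures). The Eyring decomposition at T₀ = 293.15 K uses κ = 1:
ΔG‡ = k_B T ln(k_B T/(h·k)) with k = 1/τ. Two conventions for the
enthalpy are exposed because the mapping from Arrhenius E_act to H_act is
convention-dependent: "condensed" (default, condensed-phase unimolecular,
H_act = E_act − k_BT) and "identity" (H_act = E_act). T₀S_act =
H_act − ΔG‡ (negative for entropic slowdown); the slowdown factor is
exp((ΔG‡ − H_act)/k_BT₀). Uncertainties on H_act and T₀S_act are
propagated with the same relative uncertainty as E_act, with the
equal-absolute-uncertainty variant also carried. Constants are CODATA via
`scipy.constants`; 1 kcal mol⁻¹ = 43.364 meV.

Statistical note: with 7 temperatures the band slope ± stderr has
theoretical coverage P(|t₅| ≤ 1) = 63.7%, and the Monte-Carlo coverage
test asserts the corresponding 3σ binomial band (49–78 hits of 100
seeds), measured 63/100 on seeds 0–99.

## Polarography forward model

Geometry: a PSII layer of thickness 10 µm on the electrode at x = 0,
1D aqueous column of 500 µm (far boundary closed), D = 2.0×10⁻⁹ m² s⁻¹
(typical aqueous O₂ diffusivity; all geometry is configuration, none of it
measured here). Each flash releases its Kok yield uniformly in the layer
with rate Y/τ_ox·e^(−t/τ_ox). The electrode is an absorbing boundary
(diffusion-limited O₂ reduction); a finite-rate Robin boundary and a
reflecting variant (for conservation checks) are options.

Numerics, chosen for the flux's √t onset after each flash (an effectively
singular boundary layer that a uniform grid cannot resolve):

* finite volumes on a geometrically graded mesh (default stretching 6,
  first cell ≈ 0.02 µm; grading 0 recovers a uniform grid);
* Crank–Nicolson stepping (unconditionally stable), with backward-Euler
  sub-steps (16 per step for the first 8 steps after each flash) damping
  the onset transient, Rannacher-style;
* the source deposited mass-exactly per step by Strang splitting, with the
  per-step amount integrated in closed form;
* the recorded sample defined as the flux averaged over each recording
  interval (`dt_record`, default 1 ms — integrating-ADC semantics),
  computed exactly from the scheme's discrete mass bookkeeping. This makes
  mass conservation and the flux integral machine-exact and the recorded
  transient insensitive to sub-sample discretization detail: halving dx
  and dt changes it by ~0.3% (max-norm) at default settings.

The recorded current passes a discrete single-pole high-pass
(τ = 100 ms), matching the drift-suppression filter of the amperometric
amplifier; gain agrees with the analytic transfer function within 1% at
ωτ = 100, and DC is rejected exactly in the long-window limit. τ_ox is
extracted by least squares (free amplitude scale, since the current
calibration is instrument-specific) over the post-flash window of the
averaged transients; noise-free self-consistency recovers τ_ox within 1%.

## Synthetic data generator

The generator emulates: Kok mixing over 10 flashes (700 ms spacing),
per-transition rise kinetics with the protocol time constants (S3→S0:
340 µs and 2.5 ms; S1→S2: 33 µs, 91 µs and 25 ms), a parity-locked
acceptor component at 3.1 ms (odd flashes — this is what surfaces as the
3.1 ms phase of S1→S2), a broad heat-artifact spectrum, and i.i.d.
Gaussian noise; time axis 6 µs sampling from −6 ms to +130 ms, wavenumber
window 1,200–1,800 cm⁻¹. DAS fixtures are Gaussian bands at the
characteristic carboxylate/quinone positions (1,384; 1,478; 1,571–1,605;
1,707; 1,723; 1,744 cm⁻¹) with invented amplitudes of tens of µOD chosen
so the proton-release and O₂-formation DAS are mutually inverted in the
carboxylic region; the fast phase half-rises before the slow one by
construction. Every generated artifact ships with its serialized ground
truth, and a seed is mandatory for any stochastic output.

Not emulated: 1/f detector noise, baseline drift, physical IR lineshapes
(Voigt), isotope effects, interferogram-level processing. Passing tests
therefore demonstrate that the analysis chain is correct and
self-consistent under its stated statistical model — not that the model
captures every artifact of a real spectrometer.

## Problem sizes

The analysis drivers use 64 wavenumbers at 12 µs sampling (the full
protocol's 2,582 wavenumbers at 6 µs behave identically; the chain is
linear in wavenumbers), demo noise 5×10⁻⁷ OD reflecting heavily averaged
step-scan data. The phase-recovery protocol uses 50 wavenumbers at 6 µs
over 130 ms with noise at 10% of peak; the polarography tests use a
100–200 µm domain (the far boundary is irrelevant on 500 ms windows).

## Known limitations

* Kok parameters are taken as given, never estimated from the data.
* No deactivation or redox heterogeneity (Tyr_D) in the Kok chain.
* Acceptor-side correction is the unscaled subtraction used experimentally; it is
  approximate whenever the deconvolution leaks the parity component
  unequally (any α > 0).
* No lifetime-density or target analysis; no bootstrap error bars on DAS.
* The polarography model is 1D with an idealized electrode: no
  double-layer electrochemistry, no 2D edge effects, no temperature field.
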