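# Methods

## Scope and model structure

`aprepair` couples four components: a single-cell ventricular AP/Ca²⁺
model, a Hill-type drug-effect model with multiplicative combination, a
beat-biomarker panel, and a bounded incremental dose optimiser. The
contract between them is the density/flux factorisation of every membrane
current, I_i = ρ_i·J_i:

* ρ_i (channels per unit membrane capacitance, dimensionless after
  folding area and specific capacitance) is the only thing that differs
  between the hiPSC-CM, rabbit and adult-human parameterisations;
* J_i = g₀·o·(v − E) is the only thing the mutation or a drug touches.

Two invariants follow and are enforced by property tests: the
maturation/translation ratio of any current is independent of genotype,
and the mutant/wild-type ratio is independent of cell type. A practical
consequence is that drug parameters estimated in one cell type (e.g.
hiPSC-CMs) transfer unchanged to another: the per-current factors commute
with ρ-scaling.

## The surrogate cell model

The shipped parameter set (`data/surrogate_model.yaml`) is synthetic. It
is a compact Hodgkin–Huxley-style model — eight currents (I_Na, I_NaL,
I_CaL, I_Kr, I_Ks, I_K1, I_f, I_b), eight Boltzmann/Gaussian-bell gates,
and a two-parameter phenomenological Ca²⁺ subsystem — sized to produce an
adult ventricular AP with RMP ≈ −86 mV, APA ≈ 141 mV, dv/dt_max ≈
260 mV/ms, APD90 ≈ 230 ms at 1 Hz, and a sub-micromolar Ca²⁺ transient.
It is **not** a published cell line, and no quantitative AP-level claim is
made from it; quantitative checks in this package are restricted to the
closed-form drug arithmetic. Design choices that matter:

* **I_Kr inactivation is instantaneous** (hERG inactivation is fast
  relative to activation), so the mutation enters purely through the
  x_Kr2,∞ curve. With the +62 mV midpoint shift and 1.85× slope widening,
  the mutant channel is ~25× less inactivated at plateau voltages; the
  surrogate's WT I_Kr is therefore kept small at the plateau so that the
  mutant's gain shortens APD90 by ~25% instead of collapsing the AP.
* **Ca²⁺ release follows the L-type open fraction** (d·f·g·factor) at a
  fixed 60 mV effective driving force, with first-order removal
  (τ = 300 ms) toward a 0.1 μM diastolic target. Using the instantaneous
  ohmic I_CaL instead couples release to the driving force (v − E_Ca),
  which *rises* as the mutant AP falls to lower plateau voltages and
  inverts the expected contrast; gating the release on open fraction makes
  the transient amplitude track plateau open *time*, so the SQT1 model
  shows the depressed Ca²⁺ transient expected from shortened
  repolarisation.
* **I_NaL is small** (g₀ = 0.002 A/F/mV, ~0.1 A/F at the plateau). This
  keeps the late-Na agonist genuinely partial: even at its saturation-cap
  dose veratridine cannot fully restore the mutant plateau, so single-drug
  repair saturates at a sizeable residual and combinations win — the
  qualitative structure the optimiser is meant to exhibit. The agonist's
  single-drug optimum consequently sits at its dose cap.
* **Cell-type ρ profiles** are plausibility-level: hiPSC-CMs get reduced
  I_Na/I_K1/I_Kr/I_Ks and 4× I_f (slower upstroke, longer APD, less
  stable resting potential); rabbit gets stronger I_Kr/I_K1 and weaker
  I_Ks. They exist to exercise the translation machinery, not to model
  those cells quantitatively.

What the surrogate does *not* represent: ion-concentration homeostasis
(Na⁺/K⁺ are fixed in the reversal potentials), SR Ca²⁺ dynamics and
release refractoriness, I_to and the phase-1 notch, rate dependence
beyond the 1 Hz protocol, and any tissue-level quantity (conduction
velocity, QT interval). Tests passing on this model therefore demonstrate
the correctness of the *pipeline* — factor application, biomarker
extraction, cost evaluation, search — and the qualitative SQT1 contrasts,
not predictions for real myocytes.

## Drug model

η(D) = (εD)^H/((εD)^H + 1)·E per current, with (εD)^H computed as
exp(H·log εD) and the D = 0 branch returned exactly (Hill coefficients in
the library are non-integer). Parameters are validated at load time:
EC₅₀ > 0, H > 0, E ≥ −1 (a current cannot lose more than 100%), E ≠ 0.
Combination is an exact product over drugs, taken in sorted-name order so
permutation invariance holds bitwise. Empty drug/current cells in the
library mean "no characterised effect" (factor 1); a drug acting on a
current absent from the model contributes factor 1 with a warning, so one
library can serve reduced models. Percent tables are rounded only at
presentation time, one decimal, ties away from zero.

## Pacing and integration

Default protocol: cycle length 1000 ms, rectangular stimulus 60 A/F ×
1 ms (≈1.5× the surrogate's diastolic threshold of ~40 A/F; a bisection
helper `diastolic_threshold` is provided for other parameter sets), up to
100 conditioning beats with early stopping when every beat-summary
statistic changes by < 0.1% between consecutive beats.

The integrator is a fixed-step exponential scheme: Rush–Larsen updates
for the gates (exact for the locally linearised gate ODEs, hence stable
for stiff gates), forward Euler for v and Ca²⁺, dt = 0.025 ms, recorded
on a 0.05 ms grid. The kernel is numba-compiled; one paced beat costs
~10 ms, which is what makes the incremental search (∼10⁴ beat
simulations) desk-scale. Two independent checks guard the scheme: halving
dt changes APD90 by < 0.01 ms, and a SciPy LSODA integration of the same
right-hand side (`simulate_reference`, rtol 10⁻⁶, split at the stimulus
edge) agrees with the kernel to ~0.1 ms on APD90. A non-finite state
aborts with the failing time attached.

Drug runs start from the drug-free paced steady state of the mutant and
apply three conditioning beats under the drug factors before the analysed
beat; this approximates the treated steady state at a fraction of the
cost and matches the "drug applied to the patient's mutant myocyte"
framing.

## Biomarkers

Eighteen per beat. Conventions, since figure-style definitions leave them
open: durations start at the instant of maximal upstroke velocity
(central differences on the recorded grid, search starting at stimulus
end to exclude the artifact); repolarisation thresholds are percentages
of the amplitude, peak-referenced; crossings are linearly interpolated.
CaD_p defaults to "p% decay from the peak", mirroring APD_p; the
alternative "width at p% of amplitude above rest" reading is available as
`cad_convention="width"`. A threshold not re-crossed within the beat
yields the beat-end value with a censoring flag, which the cost function
uses as-is (censoring pushes the cost up, which is the desired pressure
away from such doses). Synthetic waveforms with closed-form biomarkers
(quadratic-ease-in upstroke so the maximal-slope instant is unambiguous;
linear or exponential decay) verify recovery to two grid steps for
durations and 10⁻⁶ relative for amplitudes.

## Cost and optimisation

C(D) = Σ w_j |R_j^M(D) − R_j^W|/|R_j^W|, weights 1 with 5 on APD80,
APD90 and dv/dt_max. Wild-type references must be nonzero for weighted
terms (they are, by construction of the panel).

Dose bounds per drug: `saturation-cap` (default; the dose at which the
most affected current — largest |E|, ties to smallest EC₅₀ — reaches 95%
of |E|, i.e. EC₅₀·19^(1/H)), `min-EC50`, `half-min-EC50`, or explicit.
The 95% figure makes the cap coincide with the reported maximal
veratridine dose (1.86 μM).

The local solver is bounded Nelder–Mead in per-axis normalised dose space
(dose/bound ∈ [0,1]); normalisation matters because bounds span four
orders of magnitude and a shared absolute tolerance would otherwise
freeze the narrow axes. Convergence: simplex spread < 0.1% of each bound
and cost spread < 10⁻⁴. `optimize_single` and `pairwise_scan` use a
deterministic 5-point-per-dimension multistart lattice; the incremental
search extends the best n-drug solution with each remaining drug at dose
zero and re-solves from that single continuation start, so its cost
sequence is non-increasing by construction (asserted, with a clip at the
solver tolerance). Among near-ties (< 10⁻⁴ cost) the smaller total
normalised dose wins, including a final polish that zeroes any drug whose
removal costs < 10⁻⁴ — this pins ineffective drugs to dose 0 rather than
letting the simplex drift along a flat axis. Evaluations are memoised on
dose vectors rounded to 6 significant digits. No randomness anywhere: the
whole pipeline is deterministic.

Problem sizes used in the shipped test suite: the nine-drug incremental
search to n = 5 under both EC₅₀-based dose restrictions, the nine
single-drug optimisations and the best-pair search under the saturation
cap, on the adult-human surrogate at 1 Hz — about 3·10³ cached cost
evaluations in total.

## Known limitations

* The multiplicative combination rule assumes strictly independent
  binding; competitive or allosteric interactions and state-dependent
  (Markov) drug binding are out of scope.
* EC₅₀ values in the literature vary substantially between protocols; the
  shipped library is a single consistent snapshot, not a consensus.
* The optimiser is a deterministic local search with continuation — it
  matches brute-force scans on the tested landscapes but carries no
  global-optimality guarantee.
* Single representative cell: no population variability in channel
  densities; robustness of a dose vector across a cohort is a
  configuration-level extension, not implemented.
* Biomarker censoring at the beat end biases durations low for doses that
  push repolarisation past the cycle length; such doses are heavily
  penalised anyway.
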