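# Methods

This note documents the models implemented in `acetalnet`, the choices made
where the design was open, and what the synthetic data do and do not
emulate.

## Free-energy bookkeeping

Every network state is a labelled thermodynamic species (no molecular
structure is represented).  Formation free energies are referenced to four
isolated reference species — the sugar tautomer chosen as reference
(α-D-xylopyranose by default, configurable), the aldehyde (HCHO), water and
hydronium — through

    G_i = (E + ZPE − T·S)_i − a·g_sugar − b·g_HCHO − c·g_H2O − d·g_H3O+

where `(a, b, c, d)` is the integer composition of state *i* in reference
units (an acetal is sugar + aldehyde − water, so `c` may be negative) and
`g_X = E_X + ZPE_X − T·S_X`.  On this common zero, a proton-addition step
A + H3O+ → B + H2O has ΔG = G_B − G_A, because both reservoir species sit
at zero; the general form ΔG = G_B + G_H2O − G_A − G_H3O+ is retained for
energies on other references.  Only hydronium carries charge, so the charge
of any state equals its `d` entry — one of the validated invariants.

Units are kJ/mol internally (1 eV = 96.4853 kJ/mol, 1 kcal = 4.184 kJ/mol,
1 Hartree = 2625.4996 kJ/mol); files must declare `kJ/mol` or `eV`
explicitly.  All thermodynamics default to T = 333.15 K (the 60 °C reaction
temperature).  R = 8.314462618 J/(mol K).

Activation free energies `g_a` are stored per directed step, measured from
the reactant state plus any consumed co-reagents.  `g_a = 0` (barrierless)
is distinct from `g_a` absent (not computed).  The reverse of a step shares
its transition state: ΔG′ = −ΔG and g_a′ = g_a − ΔG, which is rejected as
inconsistent input if it would be negative.  The validator tolerates
g_a ≥ ΔG − 0.5 kJ/mol because published values are rounded to 0.1.

A uniform solvation shift (one increment per solvated network state)
cancels exactly in any step that converts one state into one state — this
is why a ~−0.5 eV implicit-solvent correction leaves the network's reaction
energetics unchanged, and it is tested as an invariant.

## Apparent barriers (energetic spans)

A pathway profile accumulates step ΔG over an ordered state sequence and
inserts each computed transition state at `G_intermediate + g_a`.  The
apparent barrier is the energetic span

    span = max over pairs (i before j) of  G(state_j) − G(intermediate_i)

with the low state restricted to intermediates.  No catalytic-cycle
wrap-around term is applied: the transformation is a one-way conversion,
not a closed cycle.  A monotone downhill profile has span 0.  Route
enumeration uses simple paths (networkx) capped at 25 states — the physical
pathways have ≤ 12 — and ranks deterministically by (span, path length,
labels).

On the packaged network the three pathway spans are 153.4, 152.5 and
145.0 kJ/mol, and the strained β-anomer route to the furanose 1,2-O-acetal
is 186.2 kJ/mol, each realized by the published low/high state pair.

One property worth recording: the span of a reversed profile is *not*
`span(forward) − G(last)` in general (a 5-state counterexample:
0, 30, −100, 10, −150 has forward span 110 but reversed span 180, not 260).
The correct dual relation — the reversed span equals the forward profile's
largest descent onto a later intermediate — is what the test suite asserts
by brute force.

## Microkinetics

Forward rate constants follow transition-state theory,
k = (k_B T/h)·exp(−G_a/RT), transmission coefficient 1; reverse rates come
from detailed balance, so every reversible pair satisfies
k_f/k_b = exp(−ΔG/RT) exactly.  Water, hydronium and the aldehyde are
reservoirs in excess whose activities are folded into the rate constants
(pseudo-first-order reduction), which keeps the master equation linear in
the sugar-derived mole fractions; the sugar moiety is the conserved
quantity and the fractions sum to 1.

Anomerization steps with no computed barrier are treated as fast
equilibrated steps: k = 10³ s⁻¹ downhill with the detailed-balance
Boltzmann factor uphill.  A step lacking both a barrier and the
equilibrated interpretation is an error.

**Reservoir re-referencing.**  The isolated (gas-phase) hydronium reference
overstabilises protonated adducts relative to solution by hundreds of
kJ/mol, which would make the cation pools the global free-energy minima.
The rate model therefore accepts chemical-potential offsets per reservoir:
a state consuming `d` hydronium units is destabilised by `−d·Δµ(H3O+)`.
Offsets default to zero (the referencing of the input data); the packaged
example recommends Δµ(H3O+) = −60 kJ/mol — the same order as the uniform
−0.5 eV solvation correction — which restores the experimentally observed
phenomenology (neutral acetals as resting states, diacetal dominant at long
time).  The offset shifts effective barriers of proton-consuming steps
consistently, so detailed balance is preserved exactly.

**Integration.**  The default integrator is scipy's BDF with rtol 1e-8 and
atol 1e-12, which is accurate for horizons up to ~10⁸ times the fastest
rate.  The packaged network spans ~29 decades of rates (proton transfers at
10¹² s⁻¹ against span-limited conversions at 10⁻¹² s⁻¹), where implicit
steppers stall on Newton-matrix conditioning.  For such runs
`method="expm"` propagates through binary powers of the exact propagator
P = expm(K·t_base): products of column-stochastic non-negative matrices
involve no cancellation, and each power is re-projected onto the stochastic
manifold (clip at 0, renormalise columns) because an eps-sized column-sum
excess would otherwise compound doubly exponentially through repeated
squaring.  Each requested time is reached via the binary expansion of
t/t_base plus one short remainder exponential, so the result is exact to
working precision at every sample; mass is conserved to ~1e-15 over 20+
decades of time.  An optional rate cap rescales both directions of a
too-fast reversible pair by a common factor, which leaves every equilibrium
constant (hence the stationary distribution) intact while removing
irrelevant fast-equilibrium stiffness.

**Timescales.**  Absolute simulated times on the packaged network are not
comparable to the 10-hour experiment: solution-phase prefactors and the
lumped reservoir activities are unknown, and the published barriers are
acknowledged overestimates (single explicit water).  Only shapes and
orderings are asserted: pyranose monoacetals rise and decay (unimodal), the
diacetal trajectory is non-decreasing and dominates at long time, and
closed subnetworks relax to the Boltzmann distribution of their effective
free energies (tested to 1e-4 relative).

## Van't Hoff thermodynamics

For a tautomer pair, ln K against 1/T is fitted by unweighted ordinary
least squares (no weighting scheme is defined for the source data;
statsmodels provides the regression): slope = −ΔH°/R, intercept = ΔS°/R,
with standard errors propagated by the same factors.  Two points determine
the parameters exactly but carry no uncertainty, so `fit()` refuses n < 3
and a separate `two_point_solve` handles the determined case.
ΔG°(T) = ΔH° − T·ΔS°, and Boltzmann weights give tautomer fractions.  The
aggregate pyranose→furanose constant is (α-fur + β-fur)/(α-pyr + β-pyr);
the open-chain form (< 1 % of the pool) is excluded from both sides of the
ratio.  Temperatures are stored in K; Celsius input is accepted with an
explicit flag or column name.

## Electrophilicity descriptors

From frontier-orbital energies: µ = (ε_HOMO + ε_LUMO)/2,
η = (ε_LUMO − ε_HOMO)/2, EI = µ²/2η.  EI_-CHO multiplies EI by the Mulliken
spin density at the carbonyl carbon of the radical state (the spin-density
scheme is assumed Mulliken, consistent with the Fukui definition used);
the condensed Fukui index is q_radical − q_neutral.  EI is reported in
kcal/mol for comparison with the empirical 28–29 kcal/mol accessibility
band: above it an aldehyde is electrophilic enough to stabilise the
strained trans-fused pyranose acetals (formaldehyde-like), below it only
furanose acetals form (benzaldehyde-like); the band itself, inclusive on
both ends, is classified `boundary` because the threshold is reported as a
range, not a point.

## The packaged network

The topology, pathway membership and all published energies (tautomer and
key-intermediate formation energies, step ΔG values, and the activation
energies along Pathways 1–3) are transcribed as printed.  The remaining
energies are synthetic placeholders chosen once under three constraints:
(i) every step satisfies g_a ≥ max(0, ΔG); (ii) the four published apparent
barriers and their realizing low/high states are reproduced exactly, and no
alternative simple path undercuts them (e.g. the unpublished β-anomer
ring-rearrangement deprotonation is set at 180 kJ/mol and the direct
α-furanose 3,5-O-closure deprotonation at 148 kJ/mol so the published
routes remain minimal); (iii) the side chains to the pyranose monoacetals
have their neutral acetals as resting states, matching the operando
observation that those intermediates — not their cations — accumulate and
then decay.  Published tautomer values do not close a thermodynamic cycle
(9.7 + 6.8 − 7.7 ≠ 9.7); the network keeps the two tautomerization ΔG
values 9.7 (α) and 6.8 (β), which fixes β-fur → α-fur at −6.8 rather than
the printed −7.7.  Because step ΔG values are generated from the species
potential table, every loop closes exactly.  Species energy terms
(E, ZPE, S) are synthetic, constructed to reproduce each formation free
energy exactly through the referencing formula at 333.15 K; they stand in
for unpublished quantum-chemistry output and are labelled as such in the
builder.

## Synthetic data

* **Equilibrium series**: K(T) = exp(−ΔH/RT + ΔS/R) on the experimental
  grid (20–140 °C, 10 °C steps) with multiplicative lognormal noise on K —
  peak-area ratios are ratio data, so noise multiplies.  The default
  σ_lnK = 0.02 is a calibration choice making the recovered-parameter
  scatter comparable to the published ±1.0 kJ/mol / ±2.7 J/(K mol)
  uncertainties; it is not a measured value.
* **Kinetic observations**: simulated traces sampled every 6 min over 10 h
  (the operando protocol), additive truncated-at-zero Gaussian noise,
  renormalised per time point.
* **Descriptor tables**: EI_-CHO targets spread across a range straddling
  the 28–29 kcal/mol band, with orbital energies reverse-engineered so the
  conceptual-DFT pipeline reproduces the targets exactly.
* **Toy networks**: random connected graphs whose step ΔG values are
  differences of latent per-species potentials (loop closure exact by
  construction) with barriers max(0, ΔG) plus a positive offset, stored
  with explicit reverses — they validate clean for every seed.

All generators are pure functions of (config, seed).  What passing tests on
synthetic data show is that the estimators and simulators are correct under
the stated noise models; they do not validate the noise models against real
NMR data, nor the network energies against new electronic-structure
calculations.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice: 200
replicate series (13 points each) for the recovery experiment, 500 for the
coverage calibration, 1000 random profiles for the span oracle, and one
wide-horizon kinetic run on the 70-species network (200 log-spaced samples).

## Known limitations

* Species are labelled states; there is no structure handling, no SMILES,
  and no automatic network generation from reaction templates.
* No barrier estimation for steps lacking g_a (no BEP relations); such
  steps are either fast-equilibrated or an error.
* Rate constants are pseudo-first-order; fitting them to measured traces is
  out of scope.
* EI values per real aldehyde are inputs, not predictions; the package only
  post-processes electronic-structure descriptors.
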