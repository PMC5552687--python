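# Methods

This note documents the models, estimators and numerical choices behind
`mlqmmm`, and what the shipped synthetic systems do and do not probe.

## System composition and embedding

A system is a QM solute plus an MM bath of rigid waters.  The energy is
composed additively, `V = V_qm + V_qm/mm + V_mm`, with `V_qm` the solute's
internal (gas-phase-expression) energy at the requested theory tier, `V_mm`
the water–water energy (O–O Lennard-Jones + all-site Coulomb, SPC/E
constants: q_O = −0.8476 e, q_H = +0.4238 e, σ_OO = 3.166 Å,
ε_OO = 0.1553 kcal·mol⁻¹, rigid r_OH = 1.0 Å, ∠HOH = 109.47°), and
`V_qm/mm` the coupling.  Coupling is electrostatic embedding with a hard
distance cutoff (default 15 Å): waters whose oxygen lies strictly inside the
cutoff of the nearest QM atom couple through full Coulomb plus Lennard-Jones
terms (solute LJ parameters from an Amber-style element table,
Lorentz–Berthelot combination with the water oxygen); waters outside couple
through Coulomb only, against the solute's unscaled ESP charges.  The cutoff
is group-based — a water is wholly in or out, judged by its oxygen — so
molecules are never split across the boundary; the tie-break at exactly the
cutoff is "outside".  The default treatment is a non-periodic droplet held by
the hard walls of its generation box; no Ewald summation, no switching
function.  The Coulomb constant is pinned at 332.0637 kcal·Å·mol⁻¹·e⁻² for
bit-reproducibility.

There are no covalent QM–MM boundary terms: the solute is a closed molecule,
and the short-range "bonded" solute–solvent repulsion is carried by the
Lennard-Jones term.

## The surrogate solute and its theory tiers

The reactive solute is a seven-atom model of the purine fragment whose
C8–N9 bond breaks (sites N7, C8, N9, C4, O10, H8, H10).  The reactive pair
interacts through a Morse well (D_e = 60 kcal·mol⁻¹, a = 2.0 Å⁻¹,
r₀ = 1.47 Å) plus an attractive Gaussian "product well" (depth 46, centre
2.90 Å, width 0.30 Å), yielding a double-well profile in the bond length r
with a single barrier (~33 kcal·mol⁻¹ forward, ~7 kcal·mol⁻¹ endothermic at
the LOW tier — the same order as the studied reaction).  The rest of the
skeleton is held by harmonic bonds and angles whose equilibria do not depend
on r; a soft C8···C4 distance restraint stands in for the ring's angular
stiffness, and no explicit dihedral terms are needed at this size.  The
endpoint geometries are produced by L-BFGS minimization on the LOW surface;
the reactant sits at r ≈ 1.47 Å and the product at r ≈ 2.87 Å, echoing the
1.466 → 2.812 Å evolution of the real lesion.

The three theory tiers emulate the multi-level scheme:

* **ESP** — charges only; the internal energy is frozen at 0 by convention.
  ESP charges interpolate linearly between a reactant-state and a
  product-state charge set as a function of r (clamped outside
  [1.47, 2.90] Å), standing in for conformation-dependent fitted charges.
* **LOW** — the full internal force field above (the "cheap wavefunction"
  tier).
* **HIGH** — LOW plus a bounded, differentiable Gaussian bump along r
  (amplitude 2.5 kcal·mol⁻¹, centre 2.30 Å, width 0.25 Å), so the
  HIGH−LOW barrier change is of the same order as the 28.8 → 31.6 kcal·mol⁻¹
  tier change in the study.  HIGH and LOW coincide wherever the bump
  vanishes.

Each tier additionally applies a small uniform polish to the solute point
charges (scale 1.00 / 1.03 / 1.05 for ESP / LOW / HIGH).  This makes the
tier-switching energy *configuration-dependent* in solvent — as it is when a
real wavefunction polarizes in the MM field — so the level-shift free
energies are nontrivial and their estimator can be meaningfully validated.
The interpolation scheme for ESP charges is a stand-in: no published charge
trajectory exists for the real system.

## Path optimization

The reaction path is a nudged elastic band of N beads (default 10, matching
the ten snapshots the study plots) between fixed endpoints.  Tangents use the
energy-weighted upwinding estimate; spring forces (default
1.0 kcal·mol⁻¹·Å⁻²) act along the tangent; the optimizer is FIRE-style
projected-velocity damped dynamics with a per-component step cap.  After 50
iterations the highest bead switches to climbing mode (spring dropped,
parallel force inverted) and converges onto the saddle.  Convergence is the
max-norm of the per-bead NEB force (default 0.05 kcal·mol⁻¹·Å⁻¹), including
the spring component so bead spacing equalizes.  Solution-phase paths follow
the frozen-solvent convention: path optimization never samples solvent
degrees of freedom, so the band is a minimum-energy path, not a free-energy
path.

Transition states are verified by a central-difference Hessian (step
0.005 Å), mass-weighted, with rigid-body translations/rotations projected out
before counting imaginary modes; 2-D analytic benchmark surfaces use unit
masses without projection.  A first-order saddle must show exactly one
imaginary mode.

## Solvent sampling and free-energy estimators

Solvent ensembles are canonical Metropolis Monte Carlo over rigid waters at
298.15 K (the study states no temperature; 298.15 K is the conventional
default): single-molecule moves combining a uniform translation (half-width
0.18 Å) and a rotation about the oxygen (up to 22°), tuned to ≈ 30–40 %
acceptance.  Moves leaving the box are rejected (hard-wall droplet).  A
whole-molecule relocation ("teleport") move type exists for sub-liquid
densities but is off by default — at liquid density its acceptance is
essentially zero.  All randomness derives from one master seed through a
documented SeedSequence fan-out keyed by (bead, tier, window, chain), so
every trajectory is bit-reproducible.

Starting configurations are prepared in two stages.  A rejection-sampled box
starts far from liquid equilibrium, so one global pre-relaxation (default
4000 sweeps at the reactant bead) comes first.  Production sampling then uses
*sequential path walks*: the solvent is re-relaxed at each bead (600 sweeps,
at the tier's own coupling) starting from the previous bead's relaxed
configuration, so chains launched at product-like beads do not inherit a
reactant-shaped solvent shell — without the walk, that common under-
relaxation biases bead-to-bead free-energy differences systematically.

Every ensemble is sampled as several independent chains (default 3; each
chain 600 equilibration + 1500 production sweeps, samples stored at stride
10), and *each chain runs its own path walk*, so the chains share no history
beyond the globally pre-relaxed box.  Free-energy differences use the
one-sided Zwanzig estimator ΔW = −kT·ln⟨exp(−ΔU/kT)⟩ pooled over the chains,
with the standard error estimated *between* the chains' exponential means.
Between-chain errors see slow solvent correlations (shell rearrangements
with correlation times beyond any realistic block length) that within-chain
block averaging is blind to — during development, block-averaged errors on
single chains understated the route-to-route spread of the composed/direct
comparison severalfold, which is why the chain scheme is the default.  A
variance guard rejects any perturbation whose exponent variance exceeds
25 kT² (the remedy is finer spacing, not a larger average).

The PMF increment between adjacent beads perturbs the frozen solute A→B
inside A's ensemble; because a bead-to-bead geometry change is a large
perturbation for one-sided averaging, each segment is stratified into
sub-windows (default 4) along the linear A→B interpolation, each window
sampled at its own start geometry.  The solute's configuration-independent
internal energy change telescopes out of the exponentials and is added
analytically — hence with zero coupling the sampled profile reduces
*exactly* to the gas profile, which fixes the composition convention (the
ESP profile includes the solute's internal ESP energy change; for the
charges-only ESP tier that term is identically zero).

The high-tier profile is composed per the level-shift identity (difference of
per-bead fixed-configuration shifts relative to the reactant bead, added to
the ESP profile), with ESP→LOW shifts evaluated in the ESP ensembles and
LOW→HIGH shifts in LOW ensembles.  The identity is exact in the
infinite-sampling limit; the package verifies it operationally by comparing
the composed barrier against a PMF sampled directly at the HIGH tier with the
same machinery, requiring agreement within three combined standard errors.
Block-averaged errors on correlated chains are approximate, which is why the
default sampling lengths above are chosen generously relative to the observed
route-to-route discrepancies.

## Decomposition, cycle and rates

The solvent decomposition is bookkeeping on three per-bead profiles: the
gas-phase profile (solute internal energy at the path beads, no solvent
terms), the internal QM/MM profile (gas plus ensemble-averaged coupling —
everything except the MM–MM energy), and the ESP-tier PMF (the
solvent-energy contribution).  Polarization is internal minus gas; net
contributions subtract the reactant value; the identity
`aqueous = solvent + net polarization` holds exactly by construction.

The thermodynamic cycle composes solution-phase values as
ΔW‡ = ΔE‡(gas) + ΔG_solv(TS) − ΔG_solv(RC) (and likewise for the reaction
energy with the product).  Solvation free energies are *inputs* (continuum
values; computing them is out of scope).

TST rates use k = A·exp(−ΔW‡/RT) with A = (k_B·T/h)·(RT/P) per molecule,
reported in cm³·molecule⁻¹·s⁻¹ — the prefactor deliberately carries the
bimolecular standard-state volume factor because that is the convention in
which the reference estimates are printed, even though the ring opening is
unimolecular.  Constants are CODATA-2018; defaults T = 298.15 K, P = 1 atm.
"Nearest power of ten" means round(log₁₀ k); the order-of-magnitude
conclusions are insensitive to any temperature choice in 273–310 K (verified
as a property test).

## Synthetic data

Water boxes are generated by rejection sampling of oxygen positions under a
minimum O–O distance, with uniform random orientations of the rigid template.
The reference conditions are 1752 waters in a 37.5 Å cube (0.994 g·cm⁻³);
tests and the demo pipeline use 64 waters in a 12.4 Å cube at the same
density so the full pipeline runs in minutes.  The minimum O–O distance
defaults to 2.4 Å: random sequential placement cannot reach liquid density
with 2.85 Å spheres (it exceeds the RSA jamming fraction), and 2.4 Å is
enough to avoid catastrophic Lennard-Jones overlaps given the subsequent
Monte-Carlo pre-equilibration.

What the synthetic systems do **not** emulate: real electronic structure
(polarization enters only through the uniform charge polish), periodic
boundary conditions and long-range electrostatics, solvent exchange on long
time scales, and the real lesion's full dimensionality (the surrogate
reaction coordinate is essentially one-dimensional).  Passing tests therefore
validate the *machinery* — path optimization, embedding bookkeeping,
estimators, composition identities, cycle and rate arithmetic — not the
chemistry of any real solute.  The printed study values enter only as fixture
inputs to the arithmetic surfaces (cycle, decomposition, geometry statistics,
rate orders); the package makes no claim to reproduce the study's absolute
QM barriers, which require real CCSD(T)/DFT.

## Numerical choices and limitations

* Hydrogen bonds: geometric criterion, H···A ≤ 3.0 Å and D–H···A ≥ 120°
  (configurable); chosen because the study's reported hydrogen bonds span
  1.77–2.81 Å but its criterion is unstated.  Connectivity is inferred from
  covalent radii × 1.2.
* Dihedrals follow the IUPAC sign convention, range (−180°, 180°];
  differences of periodic quantities always use the minimal wrapped distance.
* The water-box hard wall slightly structures the outermost solvent layer;
  since all free energies are *differences* between beads in the same
  container, the wall bias largely cancels.
* One-sided (forward) exponential averaging carries finite-sample bias of
  order β·Var(ΔU)/2n; the window stratification keeps Var(ΔU) ≲ a few kT²
  per window.  Bidirectional estimators (BAR) are not implemented.
* `RunConfig` exposes every knob (bead count, window count, sweep counts,
  cutoff, temperature, solvation inputs) in one YAML file; the run summary
  records seed, config hash and package version.
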