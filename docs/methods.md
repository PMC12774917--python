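# Methods

## Scope and data flow

The package starts where an electronic-structure code stops. Its inputs are
per-structure calculation summaries (frontier-orbital energies, total
energies, dipole moments, counterpoise corrections, optionally geometries)
and volumetric electron densities in Gaussian-cube format. From these it
derives conceptual-DFT reactivity descriptors, BSSE-corrected adsorption
energetics, chemiresistive figures of merit, NCI/RDG interaction maps and
QTAIM bond-critical-point reports. Nothing in the package performs or
approximates a self-consistent-field calculation.

Units are fixed per quantity and never mixed silently: orbital energies in
eV, total energies in hartree, adsorption energies in kJ/mol, cohesive
energies in kcal/mol per atom, densities and derived field quantities in
atomic units, grid coordinates in bohr, geometries in Å. All conversions
pivot through hartree (1 hartree = 27.211386 eV = 2625.4996 kJ/mol =
627.5095 kcal/mol), which makes every conversion cycle exactly consistent.

## Reactivity descriptors

For a structure with frontier energies E_HOMO ≤ E_LUMO:

- HLG = |E_HOMO − E_LUMO|; η = HLG/2; µ = (E_HOMO + E_LUMO)/2;
  S = 1/(2η); ΔNmax = −µ/η.
- A vanishing gap makes S and ΔNmax undefined; the package raises a
  degenerate-gap error instead of returning infinities.
- ECT is reported as ΔNmax(sensor) − ΔNmax(complex). The opposite
  subtraction order is algebraically equivalent up to sign; the chosen
  convention is the one whose sign directly encodes charge flow from the
  analyte into the sensor, which matches the reference dataset's sign on
  all three complexes. The convention is named in output metadata.

The NBO second-order stabilization E(2) = q·F(i,j)²/ΔE (hartree in,
kcal/mol out) exposes the occupancy q explicitly with default 1: the σ- and
π-type reference rows are consistent with q = 1, while textbook donor
occupancies are ≈ 2. Lone-pair rows in the reference data follow neither
choice and are treated as non-reproducible inputs.

Density-of-states curves are sums of unit-area Gaussians at the orbital
levels. Default grid: the level span extended by ±5 broadenings, 2001
points — wide and dense enough that the curve integrates to the level count
within 0.1%.

## Energetics

E_ads = E_complex − (E_sensor + E_analyte) + E_BSSE, with the raw
complexation term converted hartree → kJ/mol and the counterpoise
correction (always ≥ 0 here) supplied in kJ/mol. Binding means E_ads < 0.

Cohesive energy per atom supports two sign conventions: ``equation``
returns −(E_tot − Σᵢ nᵢEᵢ)/n literally (positive for a bound system) and
``reported`` its negation (negative for bound systems, the form usually
plotted). ``reported`` is the reporting default; every result carries
its convention tag. Isolated-atom reference energies are caller inputs —
they cannot be derived at desk scale — so cohesive values in the bundled
fixture are carried constants, not recomputable targets.

Dipole analysis reports Δµ = µ_complex − µ_bare and the ratio
µ_complex/µ_bare, with the ratio undefined (None, not infinite) for apolar
baselines such as pristine C60.

## Sensor metrics

- τ = v₀⁻¹ · exp(|E_ads| / k_B T), with k_B = 8.617×10⁻⁵ eV/K,
  v₀ = 10¹² s⁻¹ and T = 298 K by default (all overridable). The magnitude
  of E_ads is used deliberately: a literal reading of the formula with a
  negative binding energy yields the same exponent, and the magnitude form
  keeps the physically required monotonicity — stronger binding, longer
  recovery — explicit for any sign convention of the input.
- σ = A·T^{3/2}·exp(−HLG/2k_B T) with the Richardson constant
  A = 6×10⁵ A·m⁻²·K⁻². The expression is dimensionally loose (the
  prefactor is not an S/m quantity), so outputs are labelled "nominal S/m";
  the modulation ratio σ_complex/σ_bare, which is what the assessment uses,
  is dimensionless and well-defined.
- Recomputed σ agrees with the six reference values within 2% relative and
  τ within 10%; the residual few-percent gaps trace to the reference
  values having been produced with rounded constants, and are treated as
  tolerance rather than fitted away with alternative constants.

The recommendation rule (all thresholds configurable): *adsorbent* if
E_ads ≤ −40 kJ/mol; *sensor* if the modulation ratio ≥ 100 and
τ ≤ 10⁻⁶ s; *dual* if both; *weak* otherwise. With the defaults the three
reference complexes classify as adsorbent (BC59), sensor (NC59) and weak
(C60) — the boron-doped cage binds strongest and recovers slowest, while
the nitrogen-doped cage pairs a five-orders-of-magnitude conductivity
response with sub-microsecond recovery.

## Density fields

Two interchangeable backends implement value/gradient/Hessian evaluation:

- **Promolecular**: a sum of atom-centered isotropic Gaussians
  ρ(r) = Σ aᵢ·exp(−αᵢ|r−cᵢ|²), with analytic first and second derivatives.
  Gaussians rather than exponential atomic tails are used so the field is
  cusp-free and the finite-difference oracle below is clean. This is a
  synthetic stand-in: it reproduces the *topology* of a non-covalent
  contact (a (3,−1) saddle between fragments, smooth decay) but not the
  magnitudes, shell structure or anisotropy of a molecular density, so
  tests passing on it validate the numerics, not chemical accuracy.
- **Grid**: a cube-backed field. Values are interpolated trilinearly;
  gradients and Hessians are precomputed on the grid with second-order
  central differences (one-sided second-order stencils at boundaries),
  mixed partials averaged to enforce Hessian symmetry, and each component
  interpolated trilinearly at probe points. Axes must be mutually
  orthogonal (any rotation is fine; sheared grids are out of scope).
  Probes outside the box clamp to the nearest face with a warning.
  Derivatives converge with order 2 (error ratio ≈ 4 when the spacing
  halves), verified against the promolecular closed form; at 0.1 bohr
  spacing the worst gradient error on a unit Gaussian is below 2% of the
  peak gradient. Between nodes, trilinear interpolation adds an O(h²)
  smoothing error of similar size.

## NCI/RDG

Each retained point maps to (sign(λ₂)·ρ, RDG) with λ₂ the middle Hessian
eigenvalue (ascending sort; degeneracies share the value, so the product is
unaffected) and RDG = |∇ρ|/(2(3π²)^{1/3}ρ^{4/3}). Defaults, all
configurable and recorded in every output: density floor 10⁻⁸ a.u. (vacuum
cut), ceiling 0.05 a.u. (intramolecular cut), attractive/repulsive cutoffs
at s = ∓0.01 a.u. — conventional NCI practice; the reference plots span
roughly ±0.04 a.u. Bins are exhaustive and exclusive. Note that even an
overlap-free Gaussian dimer exhibits small positive-λ₂ zones flanking the
axis, so a nonzero repulsive bin is not by itself evidence of steric
clash; the diagnostic feature is the low-RDG attractive trough at
s = −ρ(midpoint).

## QTAIM

Critical points are refined by damped Newton iteration on ∇ρ = 0 (step
length capped at 0.5 bohr, at most 100 steps, convergence at
|∇ρ| < 10⁻⁸ a.u.), deduplicated within 10⁻³ bohr. Non-convergent seeds
warn and are dropped; so are rank-deficient points (an eigenvalue within
10⁻⁶ a.u. of zero), which also covers the trivial zeros found when a seed
starts in numerical vacuum. All rank-3 points are reported with their
(rank, signature) label; (3,−1) points are the bond critical points.
Default seeds are midpoints of inter-fragment atom pairs within 8 bohr,
since sensor–analyte contacts are the bond paths of interest.

Energy densities use the Abramov closed-shell estimate
G = (3/10)(3π²)^{2/3}ρ^{5/3} + ∇²ρ/6 and the local virial relation
V = ∇²ρ/4 − 2G, hence H_b = G + V = ∇²ρ/4 − G. These estimates are valid
in the low-density closed-shell regions typical of non-covalent contacts
and are labelled as estimates in reports; wavefunction-exact G and V are
out of scope, and the wavefunction-derived G/V pairs in the bundled fixture
are used only as inputs to H_b and classification, never as targets for
the estimator. In the ∇²ρ = 0 limit the closed forms reduce to V = −2G,
H_b = −G.

Bond classification follows the sign pattern of (H_b, ∇²ρ). The default
variant is strong (−,−), moderate (+,−), weak (+,+), matching the source
dataset's usage; a ``literature`` switch provides the original ordering
with moderate at (−,+). Reports name the variant used.

## Synthetic data

`make_mock_record(hlg, mu)` inverts the descriptor definitions exactly
(HOMO = µ − HLG/2, LUMO = µ + HLG/2), so descriptor round trips are exact
to machine precision. `make_dimer(separation, ...)` builds a symmetric
Gaussian pair on the z-axis and samples it on a cube extending 4/√α beyond
each center (boundary density < 10⁻⁶ of the peak); node values are exact
analytic samples. Both generators are deterministic given their arguments;
the seed parameter is reserved for future noise injection. The dimer's
midpoint critical point has closed-form properties — density 2a·e^{−αd²/4}
at separation d — and for the canonical unit dimer at separation 2 it is a
(3,−1) point with ρ = 2/e and eigenvalues (−4/e, −4/e, +4/e). Separations below √2 (unit
exponent) merge the saddle and the two maxima into one maximum — tests and
demonstrations stay above that bifurcation.

## Reproduction tolerances

The reference tables truncate rather than round in places, so the
reproduction reports apply: one unit in the last printed digit for
descriptor and H_b cells (tolerance derived per cell from the printed
string), 2% relative for conductivities, 10% relative for recovery times.
Cells that cannot be recomputed (adsorption energies, cohesive energies,
dipoles, wavefunction-derived G/V) are reported as "given". Known anomalies
are stored as fixture data and surface as "flag" status: the softness cell
of the NC59 complex (printed 1.36, recomputed 1.370) and the
abstract-vs-table exponent conflict in the NC59-complex conductivity
(10⁻³ vs 10³; the conduction formula supports 10³, which is adopted).

## Problem sizes

Everything runs at desk scale by design: the descriptor and sensor
pipelines are closed-form arithmetic on six structures; field tests use
single-Gaussian and dimer scenes on grids of ≤ 61³ points (0.1–0.5 bohr
spacing), chosen because the convergence-order checks need only two
spacings of a smooth field. The full test suite completes in well under a
minute on one CPU.

## Known limitations

- Promolecular Gaussians carry no shell structure, cusps or anisotropy;
  NCI/QTAIM results on them validate numerics only.
- The grid backend requires orthogonal axes and a single scalar block;
  multi-orbital cubes keep only their first block.
- The conductivity expression is a ratio-quality, not absolute-quality,
  figure of merit (see above).
- No Poincaré–Hopf completeness audit, bond paths, basin integration or
  ring/cage enumeration; the critical-point search finds what its seeds
  reach.
- The recommendation thresholds encode one screening convention; they are
  configuration, not physics.
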