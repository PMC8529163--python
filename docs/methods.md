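# Methods

## Scope and model

`cdftprof` implements the desk-side analysis layer of a ligand-screening
workflow. It deliberately does **not** run electronic-structure theory,
docking, or ADMET predictors: it consumes their outputs (orbital and total
energies, cube densities, score tables) or synthetic stand-ins with known
properties, and computes everything derivable from them.

### Global conceptual-DFT descriptors

All global descriptors are closed-form functions of the vertical ionization
energy *I* and electron affinity *A* (eV):

| descriptor | formula | units |
|---|---|---|
| electronegativity χ | (I+A)/2 | eV |
| hardness η | I−A | eV |
| electrophilicity ω | χ²/(2η) | eV |
| softness S | 1/η | eV⁻¹ |
| nucleophilicity N | ε_HOMO − ε_HOMO(ref) | eV |
| electrodonating power ω⁻ | (3I+A)²/(16η) | eV |
| electroaccepting power ω⁺ | (I+3A)²/(16η) | eV |
| net electrophilicity Δω± | ω⁻+ω⁺ | eV |

Softness is defined as 1/η (not 1/2η); this is the convention consistent
with the reference panel the package ships (1/5.6238 = 0.1778). Two
algebraic identities, ω⁻ − ω⁺ = χ and Δω± = ω⁻ + ω⁺, hold exactly and are
enforced by property tests.

*I* and *A* come either from frontier orbitals (Koopmans-type,
*I* = −ε_HOMO, *A* = −ε_LUMO) or from ΔSCF total-energy differences
(*I* = E(N−1) − E(N), *A* = E(N) − E(N+1)). The KID ("Koopmans in DFT")
diagnostic quantifies their agreement:
J_I = |ε_HOMO + E(N−1) − E(N)|, J_A = |ε_LUMO + E(N) − E(N+1)|,
J_HL = √(J_I² + J_A²); a check "passes" when J_I and J_A are both within a
tolerance, default **0.05 eV** (configurable) — tight enough to catch an
inconsistent functional, loose enough for SCF noise.

The nucleophilicity reference is tetracyanoethylene with
ε_HOMO = **−8.7924 eV** by default (flag `--tce-homo`). This value was
back-derived from the shipped descriptor panel, where it is consistent
across four of the five ligands; the panel's fifth nucleophilicity cell
(chloramphenicol monoglucuronide, 2.8369) is inconsistent with any single
reference (the consistent value would be ≈1.465) and is therefore excluded
from reproduction checks.

Electrophilicity classes follow the Domingo scale: strong above 1.5 eV,
moderate above 0.8 eV, marginal below. The published inequalities are
strict on both sides and leave the two boundary values unassigned; the
package assigns each boundary to the weaker class (1.5 → moderate,
0.8 → marginal), a conservative choice covered by tests.

### Local descriptors

Fukui functions use the integer finite-difference definition only
(ΔN = 1), matching the N, N±1 species convention; no fractional-occupation
variants. Grid quadrature is a plain Riemann sum (values × voxel volume):
cube grids are uniform and the stated tolerances absorb discretization
error. Normalization deviations (∫f± ≠ 1) **warn** with the measured
integral rather than abort, because truncated real-world cubes legitimately
under-integrate. The condensed scheme is population-analysis-agnostic: it
accepts any atomic charges whose totals differ by exactly ±1 between charge
states, and its column sums (1, 1, 0) are then exact algebra. The dual
descriptor's sign regions are reported symmetrically (counts, volumes and
integrated mass for Δf > +t and Δf < −t) without privileging either sign.

### Pharmacokinetics rules

Bioactivity classes: active for score > 0, moderately active on
[−0.50, 0] — read as inclusive at both boundaries — inactive below. The
ADMET rulebook is a JSON document (property, comparator, threshold, verdict
text), so the shipped thresholds (Caco-2 > 0.90 high; intestinal absorption
< 30% poor; log Kp > −2.5 low skin permeability; log BB > −0.3 readily
crosses the BBB, < −1 poorly distributed; *T. pyriformis* > −0.5 toxic) are
data, not code. CNS permeability has no published cutoff, so the default
rulebook reports the value without a verdict, and the report layer never
emits a verdict the rulebook cannot justify. Ligand/protein label matching
is case-sensitive and exact; the fixtures keep the source tables' original
spellings (including "Rutine" and "Chloramphenicol Monoglucoronide", and
the per-table variation in ligand capitalisation). Two transcription notes:
the *T. pyriformis* cells printed as "0.2.85" for two ligands were
transcribed as 0.285, matching the other three; the docking table is kept
exactly as printed even where the source's prose summary ("6 to 11 hydrogen
bonds") disagrees with its own rows (2–11).

### Assay analysis

Percent inhibition is (1 − A_sample/A_control)·100; the printed form of
this equation is ambiguous about precedence, and this reading is forced by
the boundary conditions (0% at the control point, 100% at zero absorbance).
IC50 estimation fits the four-parameter logistic
y = bottom + (top−bottom)/(1 + (IC50/x)^hill) with free Hill slope by
bounded least squares (scipy `curve_fit`, trust-region reflective);
initialisation bottom = min(y), top = max(y), IC50 = geometric median dose,
hill = 1. The method name is carried in the output record because the
analysis behind the wet-lab IC50s it emulates is unstated; those wet-lab
values (22.39, 206.31, 96.43 µg/mL) serve only as generator parameters,
never as reproduction targets. Non-convergence returns `converged=False`
with diagnostics rather than a silent bad fit. The Scherrer utility
computes D = kλ/(β cos θ) and converts Å → nm (the source's "36 mm" is an
evident nm typo; it is not a target because the peak width is unpublished).

## Synthetic data: what it emulates and what it does not

The generators define the test conditions; all are pure functions of their
arguments and a seed, and bit-reproducible.

* **Species triplets** satisfy E(N−1) = E(N) + I and E(N+1) = E(N) − A with
  ε_HOMO = −I, ε_LUMO = −A, so KID deviations are exactly zero; a
  controlled shift on either ion's total energy injects a known J_I or J_A.
  The default ligand set reproduces the five phytoligands' implied (I, A)
  pairs, so the shipped demo regenerates the published descriptor panel.
* **Density triplets** are sums of atom-centered isotropic Gaussians, each
  normalized to its assigned electron count, on a 16-bohr cubic box; the
  N±1 species move exactly one electron between atoms per the spec. The
  default test geometry uses two centers (6 e⁻ + 4 e⁻) with σ = 0.55 bohr —
  chosen so a 16³ grid is visibly under-resolved while 32³ meets the 10⁻²
  normalization tolerance, making refinement convergence observable at
  16³ → 32³ → 64³ — and ≥5σ wall padding (enforced; the generator refuses
  tighter boxes). These densities have no nuclear cusps, shell structure or
  relaxation effects, so passing tests demonstrate correct finite-difference
  and quadrature machinery, **not** fidelity to real molecular densities.
* **ADMET tables** draw numeric properties uniformly from ranges straddling
  each default threshold (e.g. Caco-2 from 0.5–1.3) so both verdict
  branches occur; booleans are fair coin flips. No inter-property
  correlation structure is emulated.
* **Dose-response curves** are exact 4PL evaluations plus additive Gaussian
  noise (default conditions: IC50 = 22.39 µg/mL, hill = 1, 0–100%
  window, eight log-spaced doses over ±1.5 decades around the IC50, 2%
  absolute noise for the recovery studies). Real assays have
  heteroscedastic, replicate-correlated noise; recovery results bound
  estimator behaviour only under this idealised model.

## Numerical choices

* Hartree → eV constant 27.211386245988 (CODATA 2018); conversion happens
  only at I/O boundaries and the canonical internal unit is eV.
* Cube dialect: positive atom counts ⇒ bohr, z-fastest ordering, six
  values per line at 7 significant figures on write (round-trips to 1e-6
  relative).
* Descriptor reproduction tolerance against the shipped panel: absolute
  0.005 eV, the rounding radius of its 4-decimal χ and η inputs.
* Hardness-ranking ties break lexicographically by ligand id; docking
  best-per-protein ties break by more hydrogen bonds, then ligand name.
* Degenerate inputs fail loudly: I ≤ A raises (hardness would be
  non-positive), as do zero-volume voxels, mismatched grid geometries and
  inconsistent charge totals.

## Problem sizes

The test suite and acceptance script run on the five-ligand panel, the
25-complex docking table, 32³ (up to 64³ for the refinement check) density
grids, and 100–200 seeded dose-response replicates — sizes chosen so the
whole suite completes in seconds on one CPU while every statistical claim
still has comfortable margin.

## Known limitations

* No Gaussian log/fchk or Molden parsing; users export energies to the
  species table themselves.
* No spin-resolved or fractional-charge descriptors, no grand-canonical
  temperature dependence, no isosurface rendering, no grid resampling
  between mismatched geometries.
* The species table's free-text `source` field exists because the
  solvation state behind any given orbital-energy set is not always
  recoverable; the package records rather than guesses it.
* The rule engine implements stated thresholds only; where a source
  narrative conflicts with its own rules (e.g. a Caco-2 value of 0.737
  described as considerable under a > 0.90 rule), the threshold wins and
  the narrative claim is not asserted.
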