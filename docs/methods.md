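# Methods

This note records the models implemented by `cosolvkb`, the defaults and
their rationale, what the synthetic generators do and do not emulate, and
the numerical choices that affect results.

## Data model and geometry

Configurations are stored as a `Trajectory`: a topology of atoms (name,
species role, residue, mass, charge, van der Waals radius) shared by an
ordered list of frames (positions in nm, orthorhombic box edge lengths).
Only orthorhombic periodicity is supported — the systems this package
targets are cubic bulk boxes and rectangular interfacial slabs — and
triclinic input is rejected rather than silently truncated. All pair
geometry uses the minimum-image convention; PDB input is converted from Å
to nm at the boundary, and GRO/extended-XYZ are read and written natively
(multi-frame concatenated GRO, `box=Lx Ly Lz` on the XYZ comment line).

Species roles (protein / water / tba / excipient / ion) are inferred from
residue names via a packaged map (SOL/HOH → water, TBA → tba, CL/NA → ion,
amino acids → protein, everything else → excipient), overridable per call.
Element-based masses and Bondi-style radii are guessed from atom names;
inside amino-acid residues the two-letter-symbol rule is suppressed so
that CA is an α-carbon, not calcium.

Analyses operate on a trailing window of frames (default: last 80%),
mirroring the usual practice of discarding the equilibration head of a
production run.

## Lennard-Jones conventions and the TBAff table

The same 12-6 potential is parameterised either as (σ, ε) or as
(C6, C12) = (4εσ⁶, 4εσ¹²). The packaged TBAff set for *tert*-butyl alcohol
carries both published columns verbatim: a C6/C12 column paired with
geometric combination on C6/C12 ("rule 1", for SPC/E water) and a σ/ε
column paired with Lorentz–Berthelot ("rule 2", for CHARMM TIP3P water),
plus carbon–oxygen and methyl–oxygen pair overrides that deliberately
follow neither combination rule (they were refit against experimental
Kirkwood–Buff data) and therefore always take precedence. The hydroxyl
hydrogen carries all-zero LJ parameters.

The two published representations of each self term agree under
C6 = 4εσ⁶ / C12 = 4εσ¹² only to about a part in 10³, which is exactly the
agreement achievable from 4-significant-figure σ/ε values; the package's
consistency check therefore uses a relative tolerance of 1e-3, not
tighter.

Formulation arithmetic uses packaged molar masses (TBA 74.12 g/mol, water
18.015 g/mol). Molecule counts for a box assume a reference density of the
final mixture (default 1.0 g/cm³, configurable); one fixed protein copy
subtracts its mass from the box budget before the bulk mass fractions are
distributed, and counterions (count = |net charge| / |valence|, erroring
on non-integer ratios) are treated purely as neutralizers, outside the
solute/solvent fraction bookkeeping.

## RDF normalisation and the finite-size correction

`compute_rdf` histograms minimum-image pair distances into uniform bins
and normalises shell counts by the exact shell volume
(4π/3)(r₊³ − r₋³) — not 4πr²Δr — so an ideal uniform mixture gives
⟨g⟩ = 1 in every bin with no small-r bias. Two density conventions are
offered: the closed-system density (N_j − δ_ij)/V (default; ideal-gas
g ≡ 1 exactly) and the open convention N_j/V, under which a closed ideal
gas shows the familiar g = (N−1)/N depletion. Self-pairs are excluded and
same-species pairs counted once. Pair search is either a brute-force
double loop or a periodic KD-tree; both produce identical integer counts,
and the tree is selected automatically above ~2.5×10⁵ pair comparisons.

The finite-size correction multiplies g(r) by
N_j(1 − v(r)/V) / [N_j(1 − v(r)/V) − ΔN_j(r) − δ_ij], where v(r) is the
sphere volume at the bin's upper edge and ΔN_j(r) the running excess
implied by the uncorrected curve (accumulated over the same shells, with
ρ_j = N_j/V). Evaluating v(r) and ΔN_j(r) at the same cumulative grid
makes the correction exact for the ideal gas: g = (N−1)/N maps to
g ≡ 1 bin-wise, and the running KBI plateau moves from −(4/3)πR³/N to 0.
The correction is formulated against the open normalisation; the
pipeline's KBI stage therefore computes open-normalised rdfs and corrects
them. A non-positive denominator (badly under-sampled selection) raises
rather than returning a distorted curve.

`kbi_running` integrates (g − 1)4πr² by the trapezoidal rule on the grid
{0, bin centers}; the integrand vanishes identically at r = 0, so the
first panel is exact. Quadrature error is O(Δr²); the validation suites
use Δr between 5×10⁻⁴ and 10⁻⁴ nm where closed forms are asserted at
10⁻⁴ relative / 10⁻⁶ absolute. The plateau estimate is the mean of G over
a window (default 1.5 nm to r_max) and is always reported with the window
standard deviation so unconverged curves are visible. Default bin width
for measured rdfs is 0.002 nm and r_max is half the smallest box edge.

Note on sign conventions: accumulation corresponds to G > 0 and exclusion
to G < 0 (the integral of g − 1 changes sign at zero); descriptions that
place the threshold at 1 conflate G with g.

## β-parameter profile

β(r) = [n_solute(r)·n_solvent(∞)] / [n_solvent(r)·n_solute(∞)] with n(r)
the *cumulative* frame-averaged count of molecules whose centre of mass
lies within surface distance r; under this grouping β(∞) = 1 exactly,
which is the property that makes the inclusion/exclusion reading
(β > 1 included, β < 1 excluded) well calibrated. Shell-local (rather
than cumulative) counts would not normalise to 1 and are not used.
Surface distance is the minimum over protein atoms of the minimum-image
distance to the molecule's centre of mass; whole molecules are
reconstructed across the periodic boundary before the centre of mass is
taken. Bins where no solvent has yet appeared are reported as NaN
(undefined), not zero; an empty solute numerator with nonzero solvent
gives β = 0. Default bin width 0.02 nm, fine enough to resolve
sub-0.1 nm features near the surface.

## Contacts and residue classes

The contact statistic is per residue: the fraction of frames in which at
least one cosolvent centre of mass lies within the cutoff (default
0.3 nm) of any atom of the residue. The criterion is solute-COM to
residue-atom centre; an alternative reading (average over solute
molecules rather than "any solute") would scale occupancies down without
changing the ranking, and is not implemented. Class means are unweighted
means over member residues with the standard assignment: positive
{LYS, ARG, HIS}, negative {ASP, GLU}, polar {SER, THR, ASN, GLN, TYR,
CYS}, apolar {ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP, GLY}; unclassified
names raise with the offending names listed.

## Density profiles and descriptors

The dimensionless density along an axis divides each slab's
frame-averaged count by the whole-box mean count per slab, vacuum slabs
included, so a homogeneous system sits at 1, a slab occupying a fraction
f of the axis sits at 1/f, and the plain bin average is identically 1.
The default axis is z, the slab normal of interfacial boxes. The bin
width must divide the box edge so no partial slab distorts the
normalisation.

Radius of gyration is the mass-weighted RMS distance from the centre of
mass after making the selection whole by minimum-image displacement from
its first atom; this unwrapping fails only for objects extending beyond
half the box, which the compact protein selections here never do.

SASA follows the Shrake–Rupley construction with a deterministic
golden-spiral point set (default 960 points) on each expanded sphere
(vdW radius + 0.14 nm probe); a point is accessible when outside every
other selected atom's expanded sphere, and the per-atom area is the
accessible fraction of the expanded-sphere area. Periodic images are
ignored (the protein is assumed compact and isolated). At 960 points an
isolated sphere is reproduced to well under 1%. The hydrophobic fraction
is atom-based by default — carbon and sulfur hydrophobic, N/O/H polar — a
residue-level classification can be supplied via the mask argument.

## Synthetic generators and what they show

The generators provide *structure*, not chemistry: they are null models
and constructions with known answers, so a passing suite demonstrates
correctness of the estimators, not fidelity of any force field.

- `gen_ideal_mixture`: uncorrelated uniform positions; exact null for
  g = 1, β = 1, density = 1, and the source of the closed ideal-gas
  finite-size benchmark.
- `gen_lj_fluid`: single-particle Metropolis sampling of the truncated
  (2.5σ) Lennard-Jones fluid from a simple-cubic start, reduced units
  mapped to nm via σ = 0.34 nm. It provides a correlated liquid whose
  first rdf peak (near 1.05σ, height well above 1.5 at ρ* = 0.8,
  T* = 0.9) exercises the rdf/KBI pipeline on nontrivial structure. The
  energy series and acceptance rate are recorded for equilibration
  checks; it makes no claim of matching TBA/water thermodynamics.
- `gen_shell_protein`: a rigid bead protein (residue names cycling
  LYS/ARG/ASP/ALA/SER) on a 0.4 nm sphere, with solute placed radially
  outward from randomly chosen beads at exact shell distances — so
  surface distances, cumulative counts and occupancies are known by
  construction — plus uniform bulk molecules outside the core. A
  per-residue-name bias reproduces enrichment near chosen residue types
  (e.g. lysine). The expected-profile oracle combines exact shell step
  functions with a Monte-Carlo estimate (independent seeded stream,
  2×10⁵ samples, ≈0.2% accuracy) of the uniform-background
  surface-distance CDF. Because the toy protein is rigid, descriptor
  baselines (constant Rg and SASA) are exact.
- `gen_slab`: uniform positions confined to [0, f·Lz]; occupied bins sit
  at 1/f and vacuum bins at exactly 0.

What these do *not* emulate: molecular flexibility, realistic water
structure, electrostatics, genuine adsorption thermodynamics at the
interface, or excipient chemistry. Agreement on these fixtures validates
the estimators' arithmetic and statistics only.

A deliberate numerical point for fixture design: placing particles at a
distance exactly equal to a bin edge makes the bin assignment depend on
the last floating-point ulp; constructions therefore put shells strictly
inside bins (e.g. a 0.25 nm shell with 0.1 nm bins).

## Validation problem sizes

The statistical suites run at sizes chosen to keep 3-standard-error bands
decisive on a single CPU: the ideal-gas KBI benchmark uses 512 particles
and 200 frames in a 5 nm cube (plateau window 1.5–2.0 nm); β construction
oracles use a 20-residue toy protein with ~430 molecules over 30 frames;
the LJ liquid uses 125 particles and 260 sweeps. Brute-force O(N²)
references cap fixtures at ~10³ particles, where integer pair-count
equality with the accelerated path is asserted exactly.

## Pipeline

`validate_config` performs aggregated validation (all problems reported
at once, unknown keys rejected) and applies the defaults above (contact
cutoff 0.3 nm, probe 0.14 nm, analysis window 0.8). `run_pipeline`
executes rdf/KBI, β, contacts, density and descriptor stages
independently — one failing stage is marked failed and the rest still
run — writes per-stage TSV files plus a `report.json` whose summary
scalars are taken from the same objects that produced the TSVs (no
recomputation drift), and includes a provenance block (config hash,
package version, seed). Reports contain no timestamps, so identical
configs yield identical reports.

## Known limitations

- Orthorhombic boxes only; constant box across frames is assumed for rdf
  normalisation (the frame-average volume is used).
- Rg/SASA unwrapping assumes the selection spans less than half the box.
- The β profile and contact analysis treat single-atom molecules'
  positions as their centres of mass exactly; for multi-atom molecules
  the COM uses the topology masses, falling back to the geometric centre
  when masses are absent.
- The parameter-file dialect is this package's own documented text
  format; it is not byte-compatible with any simulation engine's include
  files.
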