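# Methods

This note documents the models, conventions and numerical choices
behind `lipdyn`, in the spirit of a package manual's methods chapter.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structures, numbering, categories

Atoms are kept in file order with **author residue numbering**
preserved exactly; nothing is ever renumbered. This matters because the
biological labels the metrics are defined on — catalytic triad
Ser113/Asp317/His358, lid termini Asp175/Arg230, metal ligands such as
Glu360 or Asp238 — are author numbers. Each atom carries a category
(`protein`, `water`, `organic_solvent`, `ion`, `other`) assigned from a
fixed residue-name table (`constants.py`); waters and ions are matched
before the amino-acid set so a calcium HETATM named `CA` is never
confused with an alpha-carbon. Organic co-solvent residue names are not
standardized across MD packages, so the built-in mapping (MOH/EOH/POH/
BOH/PNL) can be extended per run via `RunConfig.organic_resnames`.
Elements missing from a PDB's element column are inferred from the atom
name under PDB v3 alignment rules and logged. Frame times default to
30 ps spacing when the file carries none — the snapshot interval of the
simulations this package models.

## Superposition and fluctuation metrics

Rigid-body superposition is the Kabsch algorithm via SVD with an
explicit determinant correction, so a reflection is never returned;
degenerate (collinear, < 3 atoms) inputs raise. RMSD between
conformations is √(Σ|rᵢ|²/n) with no implicit fitting; the
deviation-from-reference time series fits each frame first, the
standard (usually unstated) prerequisite for deviation-from-crystal
curves.

RMSF uses the trajectory-**mean** conformation as reference, refined by
two fit passes (fit to running mean, recompute mean, fit again); the
first frame is available as an alternative reference since published
analyses do not always say which they used. After fitting, per-atom
RMSF is the square root of the summed per-Cartesian-component
population variances. Superposition absorbs six rigid-body degrees of
freedom, so on an isotropic Gaussian trajectory with per-axis variance
v the measured mean RMSF falls slightly below the no-fit expectation
√(3v) — by roughly √(1 − 6/(3A)) for A atoms (≈ 2 % at A = 48). The
acceptance band (5 %) accommodates this; the B-factor conversion
B = (8π²/3)·RMSF² is exact by construction. The "backbone" atom set is
{N, CA, C, O}. The radius of gyration is mass-weighted over the
selection, hydrogens included when present.

## Accessible surface area

SASA is Shrake–Rupley: each atom's van der Waals sphere is inflated by
the probe radius (default 1.4 Å, the water probe) and sampled with a
**deterministic golden-spiral lattice** (default 960 points) rather
than random sampling, so results are bit-reproducible and
rotation-invariant to ≤ 0.5 %. The radii are a fixed Bondi-style table
written into every run manifest, because absolute SASA depends on them
and different packages ship different radii; an element without a
tabulated radius raises rather than defaulting. The isolated-atom
closed form 4π(r+1.4)² is reproduced within 1 % at 960 points.

Per-residue **hydrophobic** SASA counts the surface of carbons typed
hydrophobic (see below) plus their attached hydrogens, with the whole
structure still occluding. A residue under 20 Å² of hydrophobic surface
is classified buried, at or above it exposed; the threshold is strict
(`< 20` buried) and configurable.

## Interaction criteria

**Hydrogen bonds.** Two modes, and every report records which produced
a count. *Distance mode* (the fallback for hydrogen-less crystal
structures, applied automatically when a structure has no hydrogens):
a donor heavy atom (N/O bearing hydrogen, explicit or by residue
template) within 3.5 Å of an acceptor (any O, or an N with no
hydrogen), excluding same-residue and covalent-distance pairs.
*Energy mode*: E = 25·(2.6 − max(d_HA, 2.1))/0.5·Scale_DHA·Scale_HAX
kJ/mol, clamped at 0 beyond d_HA = 2.6 Å, maximum 25 at ideal geometry.
The two angular factors are linear ramps, Scale_DHA =
clamp((θ_DHA−100°)/80°, 0, 1) and Scale_HAX = clamp((θ_HAX−80°)/100°,
0, 1) — the published model states only that two angular scale factors
exist with a 25 kJ/mol maximum, so the ramp shape is a package
convention, chosen to be continuous, bounded in [0, 1] and testable,
and both ramps are configurable. A bond is counted when E exceeds
6.25 kJ/mol (25 % of maximum; configurable). When an acceptor has
several heavy neighbours, the one giving the widest H–A–X angle (hence
the largest scale) defines X. One bond is counted per donor–acceptor
pair.

**Salt bridges.** Lys NZ under 4.0 Å, or Arg NE/NH1/NH2 under 3.5 Å,
from an Asp OD1/OD2 or Glu OE1/OE2 oxygen; strict `<`; several
qualifying atom pairs between one basic and one acidic residue count
once (residue-pair deduplication — the magnitude a per-structure count
of ~14–17 bridges implies).

**Hydrophobic typing and contacts.** Carbons are typed 1 (≥ 3 bound H,
–CH₃), 2 (two H, or one H plus three bound carbons) or 3 (aromatic
ring carbons whose bonded partners are only C and H: the Phe ring, Tyr
ring minus CZ, the benzo carbons of Trp; His ring carbons all touch
ring nitrogens and are excluded). Connectivity comes from distance
inference (X–H < 1.25 Å, heavy–heavy < 1.7 Å, 1.95 Å with sulfur);
hydrogen counts come from explicit hydrogens when the structure has
any, else from standard-residue templates; unresolvable carbons are
left untyped with a warning. A contact is an unordered pair of typed
atoms under 5.0 Å — cross-residue within the protein, or protein atom
versus any non-protein molecule in "hetgroup" mode (all solvent treated
as one group). Only the contact *census* is implemented; the
knowledge-based interaction energy the census originally accompanied is
out of scope.

**Metal coordination and the active site.** Coordination is reported as
plain ion-to-shell-atom distances in shell order. The triad geometry is
the Cα angle Ser–Asp–His with the vertex at the Asp, plus the
Asp-OD2 ↔ His-ND1 and Ser-OG ↔ His-NE2 distances, each flagged as a
hydrogen bond under the 3.5 Å rule. The serine side is taken at the
hydroxyl oxygen (OG): a CB-attached hydrogen would be chemically inert
as a donor, so the hydroxyl is the only meaningful interpretation.

**Lid metrics.** Per frame: the Cα(175)–Cα(230) distance, and the
backbone RMSD of lid residues after superposing the frame on the
reference over all *non-lid* backbone atoms, so the lid's own motion
does not bias the fit.

## Secondary structure

Backbone hydrogen bonds use the Kabsch–Sander electrostatic model
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the
−0.5 kcal/mol bond threshold. Missing amide hydrogens are synthesized
1.0 Å from N, anti to the preceding carbonyl (the standard convention;
prolines and segment-start residues get none). Chains split into
segments at chain-ID changes or C–N links over 2.5 Å; no pattern
crosses a break. Assignment: α-helix (H) from two consecutive i→i+4
turns, 3₁₀ (G) from i→i+3, sheet (E) from parallel/antiparallel bridge
patterns, turn (T) from isolated n-turn interiors, else coil (C), with
priority H > E > G > T. The eight-class DSSP alphabet is collapsed to
these five (π-helix→H, isolated bridge→E, bend→C) to match the
five-class content plots this layout reproduces. Content fractions are
a probability vector per frame.

## Cross-correlation maps

DCCMᵢⱼ = ⟨dᵢ·dⱼ⟩/√(⟨dᵢ²⟩⟨dⱼ²⟩) over 3-D displacement vectors about the
window-mean positions. The default selection is one Cα per protein
residue; the default window is the trailing 25 % of frames (the
equilibrated tail, mirroring a last-10-of-40-ns analysis). Frames are
superposed onto the window mean before displacements are taken —
without fitting, global tumbling dominates the map; the fit selection
defaults to the analysis selection. Zero-variance atoms yield rows and
columns of 0 with an explicit flag rather than NaNs; the diagonal is
set to exactly +1 for every moving atom and the matrix is symmetrized
to the bit. Region-pair block means are plain means over the submatrix
(diagonal included for a region against itself).

## Solvent arithmetic and penetration

A 50 % (v/v) box replaces a reference count of waters with the number
of co-solvent molecules occupying the same volume at the solvent's
experimental density: n_s = round_half_up(n_w·(ρ_s/M_s)/(ρ_w/M_w)).
Molar masses are the 2-decimal handbook values (18.015, 32.04, 46.07,
60.09, 74.12, 88.15 g/mol); with these and the experimental densities
the methanol/ethanol/propanol/butanol counts match the published box
compositions exactly (2144/1491/1165/949 from a 4,829-water reference).
Pentanol's published count (806) exceeds the density-based arithmetic
(803) by three molecules whatever plausible mass/density pair is used;
it is therefore excluded from exact checks.

"Penetration" of a solvent molecule is operationalized by molecular
burial, since the qualitative notion (migration into the core) needs a
geometric criterion: a molecule *contacts* the protein when any heavy
atom is within 5 Å of a protein atom, and has *penetrated* when its
total SASA, computed in the protein-plus-that-molecule complex (other
solvent removed), falls below 5 Å². Both cutoffs are config-exposed and
reported. By construction n_penetrating ≤ n_contact ≤ n_molecules.

## Synthetic data

The generator provides the study conditions in miniature, without MD:

* **Toy peptides** are N/CA/C/O backbones built by internal-coordinate
  chaining at ideal bond geometry and fixed dihedrals (α-helix −57/−47;
  extended −139/135; "lid_like" = helix–loop–helix, conventionally
  numbered from 175). They exercise assignment, fitting and lid
  metrics, not side-chain chemistry.
* **Gaussian trajectories** add zero-mean normal displacements with a
  prescribed per-axis atom covariance: per-atom variances on the
  diagonal, correlation blocks (member set, ρ) off it; the three axes
  are independent and identically distributed. The implied covariance
  is validated for positive semi-definiteness and **never repaired** —
  an impossible prescription (e.g. three atoms pairwise at ρ = −0.9) is
  an error, keeping prescriptions honest. Closed forms: isotropic
  variance v gives expected RMSF √(3v); a block at ρ appears in the
  correlation map as entries converging to ρ. Defaults (0.25 Ų/axis,
  2000 frames, 30 ps spacing, three replicate seeds) are the conditions
  the recovery checks run under.
* **Solvated boxes** place idealized rigid solvent molecules (correct
  atom counts and typeable carbons; simplified internal geometry) at
  random non-clashing poses (2.2 Å heavy-atom floor, bounded retries)
  around a centered protein. They exercise counting, categorization and
  contact censuses — not liquid structure, which only MD can provide.
* **Interaction fixtures** instantiate each census criterion at exact
  requested geometry (H-bond at chosen d_HA and angles, salt bridge at
  a chosen N–O distance, CH₃ pair, metal shell at chosen distances),
  including a synthetic catalytic-triad stand-in that places marker
  atoms at the crystal-reference angle and distances. These fixtures
  validate measurement paths; they are labelled synthetic and are not
  crystal coordinates.

All generators are bit-reproducible from (prescription, seed), using
one documented NumPy generator per call.

What passing on synthetic data does **not** show: correctness of
force-field physics, realistic solvent shells, side-chain packing, or
the absolute values of surface areas and census counts on real
proteins — those depend on the input coordinates. What it does show:
every metric computes its defining formula correctly, respects its
stated cutoffs strictly, and is invariant where it should be (rigid
motion, replicate permutation, atom reordering).

## Pipeline, aggregation, determinism

A run is driven by a YAML config collecting every threshold above
(unknown keys rejected; files checked at load). Per replicate it writes
per-metric time series, per-atom RMSF/B-factor profiles, first- and
last-frame interaction censuses, per-frame secondary-structure
fractions and a correlation matrix; across replicates it writes the
element-wise mean matrix and a summary table with, per metric, the
across-replicate mean, sample standard deviation (n−1) and standard
error s.d./√n of the per-replicate time means — the layout of a
simulation-property table; snapshot censuses use the last structure.
A manifest records the config, package version, input SHA-256 digests
and the vdW radii table. Outputs use fixed 6-significant-digit
formatting and contain no timestamps, so identical inputs produce
byte-identical files; any stage failure removes partial outputs and
reports the stage name.

## Known limitations

* Multi-model PDB is the native trajectory format; DCD/XTC require the
  optional MDAnalysis dependency.
* The SASA algorithm and radii are documented but deliberately not a
  reverse-engineering of any specific MD package's surface code, so
  per-residue areas on real structures should be compared qualitatively
  (buried/exposed classes), not digit-for-digit.
* Hydrophobic-contact counting is atom-pair based by default; a
  published count of unknown convention (atom-pair vs residue-pair)
  can differ by a constant factor.
* DSSP here is a faithful but compact re-implementation; rare edge
  motifs (bulges, π-helices) collapse into the five-class alphabet.
* The energy-mode hydrogen-bond count requires explicit hydrogens;
  hydrogen-less structures silently use the distance rule (and say so
  in the logs and reports).
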