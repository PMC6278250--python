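# Methods

## The contact model

A methyl tetrel bond is detected purely geometrically. For a sulfonium
S–CH3 donor (sulfur atom `SD`, methyl carbon `CE` in the SAM component) and
a candidate acceptor atom X, the package measures

- `r = |X − C|`, the C···X distance in Å, and
- `theta`, the S–C···X angle at the methyl carbon in degrees,

and applies two inclusive criteria: `theta_min ≤ theta ≤ theta_max`
(defaults 160° and 180°) and `r ≤ r_vdW(C) + r_vdW(X)`. The radius table
pins C = 1.75 Å, O = 1.50 Å and Cl = 1.75 Å — the values that define the
survey cutoffs R(C···O) ≤ 3.25 Å and R(C···Cl) ≤ 3.50 Å — and falls back to
Bondi radii for additional elements (N, S, F, Br, I) that can be enabled by
configuration; every entry carries a provenance label and can be overridden.
Both boundaries are inclusive: a contact at exactly the van der Waals sum,
or at exactly 160°, passes. Near-miss contacts inside the search radius
(default 3.6 Å) are retained with pass flags set to false so reports can
show near-threshold geometry.

Acceptor candidates are atoms of the configured elements (default {O, Cl})
within the search radius of the methyl carbon, excluding the donor
residue's own atoms, hydrogens, and atoms below a configurable occupancy
floor (default 0, i.e. no filter). Protein (polymer) atoms are scanned and
flagged by donor class rather than skipped, so the empirical observation
that no protein-residue acceptor passes in real methyltransferase
structures is checkable from the output rather than baked in.

## Structure handling

PDB and mmCIF files are read with gemmi into a minimal hierarchy (model →
residue → atom) carrying coordinates, elements, altlocs, occupancies and
header resolution. Only the first model is kept: the survey concerns
crystal structures. When the element field is absent it is inferred from
the atom name using fixed-column conventions, mapping two-letter symbols
only where unambiguous (Cl, Br, Mg, Zn, Fe, Si) or where the residue is a
known monoatomic ion. Residues classify as water (name in {HOH, WAT, DOD}),
ion (configurable set including Mg, Na, K, Cl, Zn, Ca and the small
inorganic anions SO4/PO4), polymer (tabulated amino acids/nucleotides) or
ligand (everything else). Altloc policy: by default the highest-occupancy
alternate (ties broken toward altloc "A") represents each atom, matching
the single reported value per contact in published survey tables; a config
switch (`altloc_mode: all`) evaluates every alternate instead.

Deposited hydrogens are kept in the model but never used by detection,
since X-ray structures at survey resolutions lack reliable H positions.
Crystallographic symmetry is not expanded; only the asymmetric unit is
scanned. This mirrors the deposited-coordinate reading of the survey and is
a documented limitation, not an option.

## Hydrogen-bond competition

Because the deposited structures have no usable hydrogens, the three methyl
hydrogens are constructed with ideal geometry: C–H = 1.09 Å, S–C–H at the
tetrahedral angle arccos(−1/3) ≈ 109.471°, three-fold about the S–C axis.
The methyl torsion is free; the default `closest-approach` mode rotates it
(closed form, verified against a dense torsion grid in the tests) to
minimize d(H···X) toward the contact's acceptor, which gives the most
conservative — i.e. most hydrogen-bond-favorable — geometry. For each
hydrogen the report lists d(H···X) and the C–H···X angle.

For an acceptor on the S–C axis at 3.0 Å all three C–H···X angles come out
near 88°, i.e. acute: an axial sigma-hole contact is geometrically
incompatible with a conventional (or trifurcated) hydrogen bond. As the
acceptor tilts off-axis the closest hydrogen's C–H···X angle grows
monotonically until the acceptor aligns with one C–H bond near
θ(S–C···X) ≈ 109.5°, below which it decreases again; the monotonicity
property in the tests is therefore asserted on the sampled interval
[110°, 180°]. The `hbond_label` column ("tetrel-consistent" when θ ≥ 160°
and every C–H···X angle < 120°) is a package convention for triage, not a
physical claim.

## Survey pipeline

The survey runs over a user-curated manifest because corpus assembly —
which PDB entries constitute "all structures of this methyltransferase" —
is biological curation no parser can do. Enzyme identity and wild-type
status come from the manifest; resolution comes from the manifest when
given, else the file header. Entries are screened at ≤ 2.50 Å (inclusive);
unparseable files and entries without a resolution are excluded with
reasons and the run continues. Passing contacts are grouped per structure
by acceptor-residue component across chains (the strongest — shortest —
passing contact represents each chain), giving one record per
structure/donor pair with per-chain (r, θ).

The redundancy rule keys records by (enzyme, donor descriptor), where the
descriptor is the ligand component code for ligand donors and the donor
class for water/ion donors (all waters of one enzyme compete as a single
donor kind). Within a key, mutant records are dropped whenever a wild-type
record exists; the survivor is the record with numerically smallest
resolution, ties broken by lexicographic entry id. The operation is
idempotent and attains the per-group minimum, which the tests check against
a brute-force oracle.

The printed report rounds r to 2 decimals and θ to whole degrees, half away
from zero, rendering multi-chain cells as `3.14 (A), 3.17 (B)`; a companion
TSV keeps full precision (Python `repr`, exact round-trip).

## Synthetic fixtures

The generator builds a sulfonium fragment with standard internal geometry —
S–C = 1.81 Å, C–S–C = 100°, S–C–C = 109.471°, heavy atoms only, SAM atom
naming — and places a probe acceptor at exact (r, θ, azimuth) about the
S–CH3 axis (recovered to 1e-9 before serialization; fixed-column PDB
rounding degrades this to ≤ 1.5e-3 Å and ≤ 0.05°). Batches mix planted
passes (r uniform in [2.4 Å, cutoff], θ in [160°, 180°]) with decoys
cycling through the three violation modes — distance only, angle only,
both — in equal proportion so each criterion is exercised independently.
Oxygen probes are water-named and chlorine probes chloride-named so residue
classification runs on realistic component codes. Everything is
deterministic under a seed, byte-identical on disk.

What the fixtures deliberately omit: protein environment, crystallographic
noise, B-factor variation, altloc disorder, symmetry mates. Passing the
planted-truth suite therefore demonstrates the correctness of the
measurement, criteria and bookkeeping — not robustness to modelling errors
in real depositions, which the survey's manual curation steps (electron-
density inspection, remodeling) address outside this package.

## Fragment export

`truncate_to_surrogate` keeps atoms within `keep_depth` bond steps of the
anchor sulfur (bonds inferred by covalent-radius distance, tolerance
0.45 Å). Depth 2 keeps the methyl carbon and both two-carbon arms: the
MeS⁺(Et)₂ surrogate, total charge +1. Kept heavy atoms never move. Broken
bonds from kept carbons are capped with hydrogen along the former bond
vector, and carbon valence is then completed to four with ideal tetrahedral
hydrogens (C–H 1.09 Å; N–H 1.01 Å and O–H 0.96 Å where caps land on other
elements). Hydrogen completion is required because X-ray inputs carry no
hydrogens at all; on the heavy-atom-only synthetic fragment, depth 2 yields
the C5H13S⁺ composition. Added hydrogens are ideal-geometry placements, not
optimized positions — external QM engines are expected to refine them.

Pair systems take the whole acceptor residue by default (whole chemical
moieties — a water, an oxindole, a dichlorobenzene ring — are the natural
interaction partners), with a bond-depth-limited mode for very large
ligands. Substitution variants operate rigidly: replacing a group by H
places the hydrogen along the former bond at standard length; nitro→methyl
keeps the aryl bond direction and builds an ideal methyl (C–C 1.51 Å); the
neutral-thioether variant removes the methyl and sets the charge to 0; the
phenoxide-O→H variant leaves the total charge to the caller, since the
protonation bookkeeping of that substitution is a modelling decision.
Extended multi-residue active-site models (metal ions, side-chain mimics)
are supported only as explicit user selections — there is no automatic
side-chain-to-mimic substitution, because that mapping is
chemistry-specific. Outputs are standard XYZ (6 decimals) with the label
and total charge on the comment line.

## Numerical choices and problem sizes

- Angle cosines are clamped to [−1, 1] before arccos; collinear probes
  return exactly 180°.
- Neighbor search uses a k-d tree (`scipy.spatial.cKDTree`) with the
  all-pairs scan retained as an oracle; the tests require set equality.
- Donor sites whose S–C distance falls outside [1.6, 2.0] Å are dropped
  with a warning as corrupt geometry.
- The acceptance script uses batches of 100 planted hits + 100 decoys, 50
  neighbor-search instances, 200 random angle triples and 80 random survey
  records — sizes chosen so the full run completes in seconds while every
  code path is exercised; the tests use comparable sizes.

## Known limitations

- Donor identification is name-based (residue SAM, atoms SD/CE) with a
  config escape hatch for other component codes; generic
  connectivity-based sulfonium detection is not implemented.
- No symmetry expansion: a contact formed across a crystallographic
  interface would be missed, consistent with asymmetric-unit-only reading.
- Reconstructed validation geometries exercise the measurement, rounding
  and reporting path; they are not re-measurements of deposited
  coordinates, which would require fetching the entries.
- The package computes geometry only. Interaction energies, charge
  transfer, NMR/IR signatures and electrostatic-potential surfaces belong
  to external QM tools consuming the exported XYZ systems.
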