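# tetrelscan

Geometric detection and survey of **methyl tetrel bonds** in macromolecular
crystal structures, aimed at S-adenosylmethionine (AdoMet/SAM)-dependent
methyltransferases.

A tetrel bond is a sigma-hole interaction: a Lewis base X donates lone-pair
density into the sigma* orbital of a Group-IV atom. At a sulfonium methyl
group the sigma-hole sits on the extension of the S–CH3 bond, so the
geometry of a bona fide contact is tightly constrained. `tetrelscan` screens
every candidate acceptor atom X near the AdoMet methyl carbon (atom CE,
bonded to sulfur SD) against two criteria:

1. **angle**: θ(S–C···X) ∈ [160°, 180°], both ends inclusive, measured at
   the methyl carbon;
2. **distance**: R(C···X) ≤ r_vdW(C) + r_vdW(X), with r_vdW(C) = 1.75 Å,
   r_vdW(O) = 1.50 Å, r_vdW(Cl) = 1.75 Å, i.e. R(C···O) ≤ 3.25 Å and
   R(C···Cl) ≤ 3.50 Å.

This geometry is also the near-attack arrangement of the SN2 methyl-transfer
reaction these enzymes catalyze, which is what makes the contact
mechanistically interesting. The package additionally

- places **ideal methyl hydrogens** (C–H = 1.09 Å, tetrahedral, torsion
  optimized for closest approach) and reports the competing C–H···X
  hydrogen-bond geometry, quantifying why an axial contact cannot be a
  conventional hydrogen bond (all three C–H···X angles are acute);
- runs a **survey pipeline** over a manifest of structures with a
  resolution screen (≤ 2.50 Å) and a redundancy rule (per enzyme/donor
  pair, keep the highest-resolution wild-type structure), emitting a
  survey table with per-chain R and θ;
- generates **ground-truth synthetic fixtures** (sulfonium fragments with
  probes planted at exact r, θ, azimuth, plus decoys) so every stage is
  testable without downloading structures;
- **exports QM-ready model systems**: the cofactor truncated to the
  MeS⁺(Et)₂ sulfonium surrogate (everything within two bonds of the
  sulfur, hydrogen-completed), paired with the acceptor moiety at
  unchanged crystal coordinates, with substitution variants
  (nitro→methyl, methyl→H, neutral thioether, phenoxide-O→H) written as
  XYZ files. No quantum chemistry is performed here.

## Worked example

```sh
# build fixtures: 4 planted contacts, 2 decoys
tetrelscan synth --seed 3 --n-pass 4 --n-fail 2 --outdir fixtures/

# scan one structure
tetrelscan scan fixtures/synth0000.pdb --out contacts.tsv
```

which prints, for example,

```
synth0000: 1 candidate contacts, 1 passing -> contacts.tsv
```

`contacts.tsv` holds one row per candidate acceptor with the measured
geometry, pass flags and hydrogen-bond competition columns, e.g. a water
oxygen at `r = 2.71`, `theta = 172.7`, `cutoff = 3.25`,
`normalized_r = 0.834`, `passes = True`, `d_HX_min = 2.42`,
`hbond_label = tetrel-consistent`: a contact half an angstrom inside the
van der Waals sum, nearly on the S–C axis, whose closest ideal hydrogen is
too bent (C–H···X ≈ 93°) to read as a hydrogen bond.

A survey over a manifest (TSV: `path`, `entry_id`, `enzyme`, `wild_type`,
`ligand_map`) and a QM-fragment export:

```sh
tetrelscan survey manifest.tsv --out report.tsv --full-precision full.tsv
tetrelscan carve fixtures/synth0000.pdb --variant drop-methyl-neutral --out system.xyz
```

The numbered scripts under `analysis/` run the same steps as a narrative:
`01_generate_fixtures.py` builds a synthetic corpus (including
reconstructions of published contact geometries such as R = 2.712 Å,
θ = 172.7° for a catechol-inhibitor complex), `02_scan_survey.py` surveys
it (printing, for that entry, the survey row `2.71 / 173`),
`03_hbond_geometry.py` sweeps the hydrogen-bond competition across θ, and
`04_export_fragments.py` writes the surrogate model systems. Outputs land
under `results/`.

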