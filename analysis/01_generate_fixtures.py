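#!/usr/bin/env python
"""Build the synthetic structure corpus for the downstream analyses.

Generates (a) a labeled batch of sulfonium-fragment fixtures with probe
acceptors planted inside and outside the tetrel-bond criteria, and (b) a
small survey corpus reconstructing known methyltransferase contact
geometries, including redundant duplicates of one enzyme so the redundancy
rule has work to do.  PDB files go under scratch/fixtures/; the manifest and
truth tables go under results/.
"""

from pathlib import Path

from tetrelscan.structure_io import write_pdb
from tetrelscan.synthetic import PlacementSpec, build_sulfonium_fragment, generate_batch, place_probe

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"

SEED = 20180913

# Reconstructed survey corpus: (entry, enzyme, element, probe residue, r,
# theta, resolution, wild_type, ligand_map).  The extra G9A-like entries
# duplicate the water donor at worse resolution / as a mutant, to exercise
# deduplication.
CORPUS = [
    ("comt_dnc", "COMT-like", "O", "DNC", 2.712, 172.7, 1.5, True,
     "DNC=3,5-Dinitrocatechol"),
    ("smyd2_cl", "SMYD2-like", "CL", "BAY", 3.431, 175.0, 1.99, True,
     "BAY=Inhibitor chlorine"),
    ("smyd3_oxindole", "SMYD3-like", "O", "OXI", 2.885, 164.3, 1.5, True,
     "OXI=Oxindole-like inhibitor"),
    ("g9a_water", "G9A-like", "O", "HOH", 3.145, 165.6, 1.4, True, ""),
    ("g9a_water_lowres", "G9A-like", "O", "HOH", 3.11, 166.0, 2.1, True, ""),
    ("g9a_water_mutant", "G9A-like", "O", "HOH", 3.09, 167.0, 1.2, False, ""),
    ("too_low_res", "OTHER", "O", "HOH", 3.0, 170.0, 2.7, True, ""),
    ("no_contact", "OTHER2", "O", "HOH", 3.0, 120.0, 1.8, True, ""),
]


def main() -> None:
    FIXTURES.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    batch = generate_batch(SEED, n_pass=50, n_fail=50, outdir=FIXTURES / "batch")
    print(f"planted batch: {len(batch.models)} models -> {FIXTURES / 'batch'}")

    fragment = build_sulfonium_fragment()
    manifest_rows = ["path\tentry_id\tenzyme\twild_type\tligand_map"]
    for entry_id, enzyme, element, probe_res, r, theta, resolution, wt, ligmap in CORPUS:
        model = place_probe(
            fragment,
            PlacementSpec(r=r, theta=theta, azimuth=25.0, probe_element=element,
                          probe_residue_name=probe_res),
            entry_id=entry_id,
            resolution=resolution,
        )
        path = FIXTURES / f"{entry_id}.pdb"
        write_pdb(model, path)
        manifest_rows.append(f"{path}\t{entry_id}\t{enzyme}\t{str(wt).lower()}\t{ligmap}")
    manifest = RESULTS / "survey_manifest.tsv"
    manifest.write_text("\n".join(manifest_rows) + "\n")
    print(f"survey corpus: {len(CORPUS)} structures, manifest -> {manifest}")


if __name__ == "__main__":
    main()
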