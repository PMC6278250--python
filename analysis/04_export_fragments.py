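#!/usr/bin/env python
"""Export QM-ready model systems for the strongest surveyed contact.

Takes the reconstructed short C...O contact from the synthetic corpus,
truncates the cofactor to the MeS+(Et)2 sulfonium surrogate, pairs it with
the acceptor residue at unchanged crystal positions, and writes the base
system plus the substitution variants used to dissect tetrel- from
hydrogen-bonding contributions.  Run analysis/01_generate_fixtures.py first.
"""

from pathlib import Path

from tetrelscan.detect import scan_structure
from tetrelscan.fragments import apply_variant, build_pair_system, write_xyz
from tetrelscan.structure_io import parse_structure

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results" / "fragments"

VARIANTS = ["none", "methyl-to-H", "drop-methyl-neutral"]


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    model = parse_structure(FIXTURES / "comt_dnc.pdb")
    contact = next(c for c in scan_structure(model) if c.passes)
    print(
        f"carving {model.entry_id}: R(C...{contact.acceptor.element}) = "
        f"{contact.geometry.r:.3f} A, theta = {contact.geometry.theta:.1f} deg"
    )
    base = build_pair_system(contact, model)
    for variant in VARIANTS:
        system = apply_variant(base, variant)
        name = "base" if variant == "none" else variant.replace("-", "_")
        out = RESULTS / f"{model.entry_id}_{name}.xyz"
        write_xyz(system, out)
        counts = system.element_counts()
        formula = "".join(f"{el}{n}" for el, n in sorted(counts.items()))
        print(f"  {variant:<22} {formula:<14} charge {system.total_charge:+d} -> {out.name}")


if __name__ == "__main__":
    main()
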