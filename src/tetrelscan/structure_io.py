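"""Reading and writing macromolecular structures.

PDB and mmCIF files are parsed with gemmi into a small uniform hierarchy
(:class:`StructureModel` -> :class:`ResidueRecord` -> :class:`AtomRecord`)
that carries exactly what contact detection needs: coordinates, elements,
altlocs, occupancies and the header resolution.  Only the first model of
multi-model files is kept, since the survey concerns crystal structures.

Residues are classified into {polymer, water, ion, ligand}; water and ion
name sets are configurable because deposition dialects vary.  Deposited
hydrogens are retained here and excluded later, at detection time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "ClassificationConfig",
    "StructureParseError",
    "PdbSerializationError",
    "parse_structure",
    "classify_residue",
    "write_pdb",
    "infer_element",
]

Category = Literal["polymer", "water", "ion", "ligand"]

DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})
# Monoatomic ions commonly deposited in methyltransferase structures, plus
# small inorganic anions (SO4, PO4) that the survey treats as ions.
DEFAULT_ION_NAMES = frozenset(
    {"MG", "NA", "K", "CL", "ZN", "CA", "MN", "FE", "CD", "NI", "CO", "CU", "SO4", "PO4"}
)

# Two-letter element symbols recognized when inferring from atom names.
_TWO_LETTER_ELEMENTS = frozenset(
    {"CL", "BR", "MG", "NA", "ZN", "CA", "MN", "FE", "CD", "NI", "CO", "CU", "SE", "SI"}
)
# Symbols that never collide with single-letter atom-name conventions.
_TWO_LETTER_UNAMBIGUOUS = frozenset({"CL", "BR", "MG", "ZN", "FE", "SI"})


class StructureParseError(ValueError):
    """A structure file could not be parsed."""


class PdbSerializationError(ValueError):
    """A model cannot be written in fixed-column PDB format."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    parent_residue: "ResidueRecord | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class ResidueRecord:
    name: str
    chain_id: str
    seq_id: int
    insertion_code: str = ""
    category: Category = "ligand"
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        for atom in self.atoms:
            atom.parent_residue = self

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.seq_id, self.insertion_code, self.name)

    def find_atom(self, name: str) -> AtomRecord | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class StructureModel:
    entry_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    resolution: float | None = None
    model_number: int = 1

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys within model")

    def atoms(self) -> Iterator[AtomRecord]:
        for residue in self.residues:
            yield from residue.atoms

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass(frozen=True)
class ClassificationConfig:
    water_names: frozenset[str] = DEFAULT_WATER_NAMES
    ion_names: frozenset[str] = DEFAULT_ION_NAMES


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer the element symbol from a PDB atom name.

    Follows fixed-column conventions: the leading non-digit characters carry
    the element; two-letter symbols (Cl, Mg, Fe...) are recognized from a
    fixed table, with monoatomic-ion residues given priority (so atom "CA" in
    residue "CA" is calcium, while "CA" in an amino acid is an alpha carbon).
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    rest = stripped[2:]
    if two in _TWO_LETTER_ELEMENTS and (rest == "" or rest.isdigit()):
        # Atom names like CA/CE/SD in polymers and ligands denote single-letter
        # elements; only unambiguous symbols (or a matching ion residue) map to
        # two-letter elements.
        if residue_name.strip().upper() in DEFAULT_ION_NAMES or two in _TWO_LETTER_UNAMBIGUOUS:
            return two.capitalize()
    return stripped[0].upper()


def classify_residue(residue: ResidueRecord | str, config: ClassificationConfig | None = None) -> Category:
    """Classify a residue as polymer, water, ion or ligand.

    Total and deterministic: every name falls into exactly one category for a
    given configuration.
    """
    if config is None:
        config = ClassificationConfig()
    name = (residue if isinstance(residue, str) else residue.name).strip().upper()
    if name in config.water_names:
        return "water"
    if name in config.ion_names:
        return "ion"
    info = gemmi.find_tabulated_residue(name)
    if info is not None and (info.is_amino_acid() or info.is_nucleic_acid()):
        return "polymer"
    return "ligand"


def parse_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    config: ClassificationConfig | None = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Returns the first model only.  Coordinates are in Angstrom; altlocs and
    occupancies are preserved; the resolution is taken from header metadata
    when present (None otherwise).  Atom counts are conserved: nothing is
    silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise StructureParseError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models in {path}")
    st.setup_entities()

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    model = st[0]
    residues: list[ResidueRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            atoms: list[AtomRecord] = []
            for atom in res:
                serial += 1
                element = atom.element.name
                if element in ("", "X"):
                    element = infer_element(atom.name, res.name)
                atoms.append(
                    AtomRecord(
                        serial=atom.serial if atom.serial else serial,
                        name=atom.name,
                        element=element,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=float(atom.occ),
                        altloc=atom.altloc if atom.altloc != "\0" else "",
                        b_factor=float(atom.b_iso),
                    )
                )
            record = ResidueRecord(
                name=res.name,
                chain_id=chain.name,
                seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                atoms=atoms,
            )
            record.category = classify_residue(record, config)
            residues.append(record)
    entry_id = st.name.strip() if st.name.strip() else path.stem
    return StructureModel(
        entry_id=entry_id,
        residues=residues,
        resolution=resolution,
        model_number=getattr(model, "num", 1) or 1,
    )


def _format_atom_name(name: str, element: str) -> str:
    """Align an atom name in PDB columns 13-16."""
    if len(name) > 4:
        raise PdbSerializationError(f"atom name too long for PDB columns: {name!r}")
    if len(name) == 4 or len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-column PDB ATOM/HETATM records (coordinates to 3 decimals).

    Output is parseable by :func:`parse_structure`; polymer residues get ATOM
    records, everything else HETATM.
    """
    path = Path(path)
    lines: list[str] = []
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.")
    serial = 0
    for res in model.residues:
        if len(res.name) > 3:
            raise PdbSerializationError(f"residue name too long for PDB columns: {res.name!r}")
        record = "ATOM  " if res.category == "polymer" else "HETATM"
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.position
            for coord in (x, y, z):
                if abs(coord) >= 10000:
                    raise PdbSerializationError(f"coordinate out of PDB range: {coord}")
            lines.append(
                f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                f"{atom.altloc or ' '}{res.name:>3s} {res.chain_id[:1] or 'A'}"
                f"{res.seq_id:4d}{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
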