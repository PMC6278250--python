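"""Carving QM-ready model fragments from crystal structures.

The cofactor is reduced to a small sulfonium surrogate — MeS+(Et)2, i.e.
everything within two bond steps of the sulfur — and paired with the intact
acceptor moiety from the crystal.  Crystal heavy-atom positions are never
moved; hydrogens absent from the X-ray model are added with ideal geometry
(caps along broken bonds, valence completion on carbons), and chemical
substitution variants used to dissect the interaction (nitro-to-methyl,
methyl-to-H, neutral thioether, phenoxide-O-to-H) are applied with simple
rigid geometry rules.  Systems are written in XYZ format for external QM
engines; no quantum chemistry happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .detect import TetrelContact
from .structure_io import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "FragmentAtom",
    "FragmentSystem",
    "TruncationRule",
    "infer_bonds",
    "truncate_to_surrogate",
    "build_pair_system",
    "apply_variant",
    "write_xyz",
    "read_xyz",
]

# Cordero et al. single-bond covalent radii (A).
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "NA": 1.66, "MG": 1.41, "P": 1.07, "S": 1.05, "CL": 1.02, "K": 2.03,
    "CA": 1.76, "ZN": 1.22, "FE": 1.32, "BR": 1.20, "I": 1.39,
}

# Ideal X-H bond lengths for added hydrogens (A).
CAP_LENGTHS = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

_VALENCE = {"C": 4}  # only carbons get hydrogen completion


@dataclass(frozen=True)
class FragmentAtom:
    element: str
    position: np.ndarray
    source: str = "kept"  # "kept" (crystal position) or "cap" (added H)
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class FragmentSystem:
    atoms: list[FragmentAtom]
    bonds: set[tuple[int, int]]  # (i, j) with i < j
    total_charge: int = 0
    label: str = ""

    def __post_init__(self):
        self.bonds = {tuple(sorted(b)) for b in self.bonds}
        for i, j in self.bonds:
            if i == j:
                raise ValueError("self-loop in bond list")
        for idx, atom in enumerate(self.atoms):
            if atom.source == "cap":
                if atom.element.upper() != "H":
                    raise ValueError("cap atoms must be hydrogen")
                partners = [b for b in self.bonds if idx in b]
                if len(partners) != 1:
                    raise ValueError("cap atom must bond exactly one kept atom")

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return sorted(out)

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.atoms:
            counts[atom.element.capitalize()] = counts.get(atom.element.capitalize(), 0) + 1
        return counts


@dataclass(frozen=True)
class TruncationRule:
    anchor_atom: str = "SD"
    keep_depth: int = 2
    cap_length: float = 1.09

    def __post_init__(self):
        if self.keep_depth < 1:
            raise ValueError("keep_depth must be >= 1")


def _covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no covalent radius for element {element!r}") from None


def infer_bonds(residue: ResidueRecord, tolerance: float = 0.45) -> set[tuple[int, int]]:
    """Distance-based bond inference over a residue's atoms.

    Atoms i < j are bonded iff their distance is at most the sum of covalent
    radii plus the tolerance; H-H pairs are never bonded.  Indices refer to
    positions in ``residue.atoms``.
    """
    atoms = residue.atoms
    bonds: set[tuple[int, int]] = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ei, ej = atoms[i].element.upper(), atoms[j].element.upper()
            if ei == "H" and ej == "H":
                continue
            limit = _covalent_radius(ei) + _covalent_radius(ej) + tolerance
            if np.linalg.norm(atoms[i].position - atoms[j].position) <= limit:
                bonds.add((i, j))
    return bonds


def _bfs_depths(n_atoms: int, bonds: set[tuple[int, int]], start: int) -> dict[int, int]:
    adjacency: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    depths = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adjacency[node]:
                if nb not in depths:
                    depths[nb] = depths[node] + 1
                    nxt.append(nb)
        frontier = nxt
    return depths


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(axis, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def _completion_directions(existing: list[np.ndarray], n_needed: int) -> list[np.ndarray]:
    """Ideal directions for hydrogens completing a tetrahedral carbon.

    ``existing`` are unit vectors along the carbon's current bonds.
    """
    if n_needed <= 0:
        return []
    k = len(existing)
    if k == 0:
        raise ValueError("cannot orient hydrogens on an unbonded atom")
    if k == 1:
        u = -existing[0]  # cone opposite the single bond
        e1, e2 = _orthonormal_frame(u)
        cos_a, sin_a = 1.0 / 3.0, math.sqrt(8.0) / 3.0
        dirs = []
        for m in range(3):
            phi = 2.0 * math.pi * m / 3.0
            dirs.append(cos_a * u + sin_a * (math.cos(phi) * e1 + math.sin(phi) * e2))
        return dirs[:n_needed]
    if k == 2:
        bisector = -(existing[0] + existing[1])
        bisector /= np.linalg.norm(bisector)
        perp = np.cross(existing[0], existing[1])
        perp /= np.linalg.norm(perp)
        half = math.radians(109.471 / 2.0)
        dirs = [
            math.cos(half) * bisector + math.sin(half) * perp,
            math.cos(half) * bisector - math.sin(half) * perp,
        ]
        return dirs[:n_needed]
    # k >= 3: single hydrogen opposite the bond-vector sum
    s = -sum(existing)
    s /= np.linalg.norm(s)
    return [s][:n_needed]


def _carve_residue(
    residue: ResidueRecord,
    anchor_index: int,
    keep_depth: int | None,
    complete_carbons: bool,
    tolerance: float = 0.45,
) -> tuple[list[FragmentAtom], set[tuple[int, int]]]:
    """Keep atoms within keep_depth bonds of the anchor (None keeps all),
    cap broken bonds with H and optionally fill carbon valence with ideal H."""
    bonds = infer_bonds(residue, tolerance)
    depths = _bfs_depths(len(residue.atoms), bonds, anchor_index)
    if keep_depth is None:
        kept_idx = sorted(depths)  # connected component only
    else:
        kept_idx = sorted(i for i, d in depths.items() if d <= keep_depth)
    index_map = {old: new for new, old in enumerate(kept_idx)}

    atoms: list[FragmentAtom] = [
        FragmentAtom(
            element=residue.atoms[i].element.capitalize(),
            position=residue.atoms[i].position.copy(),
            source="kept",
            name=residue.atoms[i].name,
        )
        for i in kept_idx
    ]
    new_bonds = {
        (index_map[i], index_map[j])
        for i, j in bonds
        if i in index_map and j in index_map
    }

    # cap broken bonds, then complete carbon valence
    for old_i in kept_idx:
        atom = residue.atoms[old_i]
        element = atom.element.upper()
        cap_len = CAP_LENGTHS.get(element.capitalize(), 1.09)
        broken = [
            other
            for i, j in bonds
            for here, other in ((i, j), (j, i))
            if here == old_i and other not in index_map
        ]
        for other in broken:
            direction = residue.atoms[other].position - atom.position
            direction /= np.linalg.norm(direction)
            cap_pos = atom.position + cap_len * direction
            atoms.append(FragmentAtom(element="H", position=cap_pos, source="cap"))
            new_bonds.add((index_map[old_i], len(atoms) - 1))

    if complete_carbons:
        # recompute neighbor directions including caps
        def current_dirs(idx_new: int) -> list[np.ndarray]:
            dirs = []
            for i, j in new_bonds:
                other = j if i == idx_new else i if j == idx_new else None
                if other is not None:
                    v = atoms[other].position - atoms[idx_new].position
                    dirs.append(v / np.linalg.norm(v))
            return dirs

        for old_i in kept_idx:
            idx_new = index_map[old_i]
            element = atoms[idx_new].element.upper()
            target = _VALENCE.get(element)
            if target is None:
                continue
            dirs = current_dirs(idx_new)
            needed = target - len(dirs)
            if needed <= 0:
                continue
            for d in _completion_directions(dirs, needed):
                pos = atoms[idx_new].position + CAP_LENGTHS["C"] * d
                atoms.append(FragmentAtom(element="H", position=pos, source="cap"))
                new_bonds.add((idx_new, len(atoms) - 1))

    return atoms, new_bonds


def truncate_to_surrogate(
    residue: ResidueRecord,
    rule: TruncationRule | None = None,
    total_charge: int = 1,
) -> FragmentSystem:
    """Truncate a cofactor residue to its sulfonium surrogate.

    Keeps atoms within ``keep_depth`` bond steps of the anchor sulfur (depth 2
    keeps the methyl and both two-carbon arms: the MeS+(Et)2 model), caps
    every broken carbon bond with hydrogen along the former bond vector, and
    completes carbon valence with ideal tetrahedral hydrogens.  Kept heavy
    atoms are never moved.
    """
    rule = rule or TruncationRule()
    anchor_index = next(
        (i for i, a in enumerate(residue.atoms) if a.name == rule.anchor_atom), None
    )
    if anchor_index is None:
        raise ValueError(f"anchor atom {rule.anchor_atom!r} not found in residue {residue.name}")
    atoms, bonds = _carve_residue(residue, anchor_index, rule.keep_depth, complete_carbons=True)
    return FragmentSystem(
        atoms=atoms,
        bonds=bonds,
        total_charge=total_charge,
        label=f"surrogate:{residue.name}",
    )


def build_pair_system(
    contact: TetrelContact,
    model: StructureModel,
    rule: TruncationRule | None = None,
    acceptor_scope: str | int = "whole-residue",
    total_charge: int = 1,
) -> FragmentSystem:
    """Surrogate plus the acceptor moiety, at unchanged crystal positions.

    ``acceptor_scope`` is "whole-residue" (the full water/ligand residue) or
    an integer bond depth around the acceptor atom for very large ligands.
    Cut acceptor bonds are capped with hydrogen.
    """
    rule = rule or TruncationRule()
    surrogate = truncate_to_surrogate(contact.site.residue, rule, total_charge)

    acc_res = contact.acceptor_residue
    acc_index = next(
        i for i, a in enumerate(acc_res.atoms) if a is contact.acceptor
        or (a.name == contact.acceptor.name and a.altloc == contact.acceptor.altloc)
    )
    depth = None if acceptor_scope == "whole-residue" else int(acceptor_scope)
    acc_atoms, acc_bonds = _carve_residue(acc_res, acc_index, depth, complete_carbons=False)

    offset = len(surrogate.atoms)
    atoms = surrogate.atoms + acc_atoms
    bonds = set(surrogate.bonds) | {(i + offset, j + offset) for i, j in acc_bonds}
    label = (
        f"{model.entry_id}:{contact.site.residue.name}{contact.site.residue.seq_id}"
        f"({contact.site.chain_id})...{acc_res.name}{acc_res.seq_id}/{contact.acceptor.name}"
    )
    return FragmentSystem(atoms=atoms, bonds=bonds, total_charge=total_charge, label=label)


def _find_methyl_carbon(system: FragmentSystem) -> int:
    """The surrogate methyl carbon: named CE, or a terminal carbon on sulfur."""
    for i, atom in enumerate(system.atoms):
        if atom.name == "CE":
            return i
    for i, atom in enumerate(system.atoms):
        if atom.element.upper() != "C":
            continue
        heavy = [
            j for j in system.neighbors(i) if system.atoms[j].element.upper() != "H"
        ]
        if len(heavy) == 1 and system.atoms[heavy[0]].element.upper() == "S":
            return i
    raise ValueError("no methyl carbon found in system")


def _find_nitro_group(system: FragmentSystem) -> tuple[int, int, int, int]:
    """(N, O, O, aryl C) of a nitro group: N bonded to two terminal O and one C."""
    for i, atom in enumerate(system.atoms):
        if atom.element.upper() != "N":
            continue
        nbrs = system.neighbors(i)
        oxygens = [
            j for j in nbrs
            if system.atoms[j].element.upper() == "O" and system.neighbors(j) == [i]
        ]
        carbons = [j for j in nbrs if system.atoms[j].element.upper() == "C"]
        if len(oxygens) == 2 and len(carbons) == 1 and len(nbrs) == 3:
            return i, oxygens[0], oxygens[1], carbons[0]
    raise ValueError("no nitro group found in system")


def _rebuild(
    system: FragmentSystem,
    drop: set[int],
    extra_atoms: list[FragmentAtom],
    extra_bonds: list[tuple[int, int]],
    total_charge: int,
    label_suffix: str,
) -> FragmentSystem:
    """New system without ``drop`` atoms, plus new atoms bonded by old indices
    (negative extra-bond indices -n refer to extra atom n-1)."""
    keep = [i for i in range(len(system.atoms)) if i not in drop]
    index_map = {old: new for new, old in enumerate(keep)}
    atoms = [system.atoms[i] for i in keep]
    bonds = {
        (index_map[i], index_map[j])
        for i, j in system.bonds
        if i in index_map and j in index_map
    }
    for atom in extra_atoms:
        atoms.append(atom)
    for i, j in extra_bonds:
        ni = index_map[i] if i >= 0 else len(keep) + (-i - 1)
        nj = index_map[j] if j >= 0 else len(keep) + (-j - 1)
        bonds.add(tuple(sorted((ni, nj))))
    return FragmentSystem(
        atoms=atoms,
        bonds=bonds,
        total_charge=total_charge,
        label=system.label + label_suffix,
    )


def apply_variant(system: FragmentSystem, variant: str) -> FragmentSystem:
    """Chemical substitution variants on an exported pair system.

    - ``none``: identity (copy).
    - ``methyl-to-H``: the sulfonium methyl (CH3) becomes H on sulfur,
      giving the HS+(Et)2 cation; net atom count -3.
    - ``drop-methyl-neutral``: the methyl is removed outright and the charge
      set to 0, giving the neutral thioether S(Et)2 (the demethylated
      product analog).
    - ``nitro-to-methyl``: an NO2 group is replaced by an ideal methyl along
      the unchanged aryl bond direction (removes a possible CH...O hydrogen
      bond while keeping the tetrel acceptor).
    - ``phenoxideO-to-H``: a terminal oxygen on carbon becomes H at ideal
      length (removes the tetrel acceptor); the total charge is left for the
      caller to adjust, since the protonation bookkeeping is a modelling
      choice.
    """
    if variant == "none":
        return FragmentSystem(
            atoms=list(system.atoms),
            bonds=set(system.bonds),
            total_charge=system.total_charge,
            label=system.label,
        )

    if variant in ("methyl-to-H", "drop-methyl-neutral"):
        ce = _find_methyl_carbon(system)
        methyl_h = [
            j for j in system.neighbors(ce) if system.atoms[j].element.upper() == "H"
        ]
        sulfur = next(
            j for j in system.neighbors(ce) if system.atoms[j].element.upper() == "S"
        )
        drop = {ce, *methyl_h}
        if variant == "drop-methyl-neutral":
            return _rebuild(system, drop, [], [], total_charge=0, label_suffix="|S(Et)2")
        s_pos = system.atoms[sulfur].position
        direction = system.atoms[ce].position - s_pos
        direction /= np.linalg.norm(direction)
        new_h = FragmentAtom(
            element="H", position=s_pos + CAP_LENGTHS["S"] * direction, source="cap"
        )
        return _rebuild(
            system, drop, [new_h], [(sulfur, -1)],
            total_charge=system.total_charge, label_suffix="|HS+(Et)2",
        )

    if variant == "nitro-to-methyl":
        n_idx, o1, o2, aryl = _find_nitro_group(system)
        aryl_pos = system.atoms[aryl].position
        direction = system.atoms[n_idx].position - aryl_pos
        direction /= np.linalg.norm(direction)
        c_pos = aryl_pos + 1.51 * direction
        new_c = FragmentAtom(element="C", position=c_pos, source="kept", name="CM")
        h_atoms = []
        for d in _completion_directions([-direction], 3):
            h_atoms.append(
                FragmentAtom(element="H", position=c_pos + CAP_LENGTHS["C"] * d, source="cap")
            )
        extra_bonds = [(aryl, -1), (-1, -2), (-1, -3), (-1, -4)]
        return _rebuild(
            system, {n_idx, o1, o2}, [new_c] + h_atoms, extra_bonds,
            total_charge=system.total_charge, label_suffix="|NO2->CH3",
        )

    if variant == "phenoxideO-to-H":
        candidates = []
        for i, atom in enumerate(system.atoms):
            if atom.element.upper() != "O":
                continue
            nbrs = system.neighbors(i)
            # nitro oxygens bond to N, not C, so they never match this rule
            if len(nbrs) == 1 and system.atoms[nbrs[0]].element.upper() == "C":
                candidates.append((i, nbrs[0]))
        if not candidates:
            raise ValueError("no terminal C-O oxygen found in system")
        o_idx, c_idx = candidates[0]
        c_pos = system.atoms[c_idx].position
        direction = system.atoms[o_idx].position - c_pos
        direction /= np.linalg.norm(direction)
        new_h = FragmentAtom(
            element="H", position=c_pos + CAP_LENGTHS["C"] * direction, source="cap"
        )
        return _rebuild(
            system, {o_idx}, [new_h], [(c_idx, -1)],
            total_charge=system.total_charge, label_suffix="|O->H",
        )

    raise ValueError(f"unknown variant {variant!r}")


def write_xyz(system: FragmentSystem, path: str | Path) -> None:
    """Standard XYZ: atom count, a comment with label and charge, then
    element and coordinates (A, 6 decimals) per line."""
    charge = system.total_charge
    charge_text = f"+{charge}" if charge > 0 else str(charge)
    lines = [str(len(system.atoms)), f"{system.label} charge={charge_text}"]
    for atom in system.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.element.capitalize():2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray, str]:
    """Read back an XYZ file: (elements, Nx3 coordinates, comment line)."""
    lines = Path(path).read_text().splitlines()
    count = int(lines[0])
    comment = lines[1]
    elements = []
    coords = []
    for line in lines[2 : 2 + count]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return elements, np.array(coords), comment
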