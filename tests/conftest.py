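import numpy as np
import pytest

from tetrelscan.detect import DetectionParams
from tetrelscan.structure_io import AtomRecord, ResidueRecord, StructureModel
from tetrelscan.synthetic import PlacementSpec, build_sulfonium_fragment, place_probe


@pytest.fixture
def fragment():
    return build_sulfonium_fragment()


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture
def probe_model(fragment):
    """Factory: fragment + one probe at controlled geometry."""

    def make(r=3.10, theta=180.0, azimuth=0.0, element="O", residue_name=None, **kwargs):
        spec = PlacementSpec(
            r=r, theta=theta, azimuth=azimuth, probe_element=element,
            probe_residue_name=residue_name,
        )
        return place_probe(fragment, spec, **kwargs)

    return make


def make_residue(name, chain, seq, atom_specs, category=None):
    """atom_specs: list of (atom_name, element, xyz[, occupancy, altloc])."""
    atoms = []
    for i, spec in enumerate(atom_specs):
        atom_name, element, xyz = spec[:3]
        occ = spec[3] if len(spec) > 3 else 1.0
        alt = spec[4] if len(spec) > 4 else ""
        atoms.append(
            AtomRecord(
                serial=i + 1, name=atom_name, element=element,
                position=np.asarray(xyz, float), occupancy=occ, altloc=alt,
            )
        )
    res = ResidueRecord(name=name, chain_id=chain, seq_id=seq, atoms=atoms)
    if category is not None:
        res.category = category
    return res


@pytest.fixture
def nitrophenoxide_residue():
    """Toy catecholate-like acceptor: phenoxide O, two ring carbons, a nitro
    group.  Planar zig-zag with standard bond lengths; the phenoxide oxygen
    sits at the origin so callers can translate it onto a contact position."""
    import math

    o1 = np.array([0.0, 0.0, 0.0])
    c1 = o1 + np.array([1.30, 0.0, 0.0])
    # 120 degree internal angles, zig-zagging in the xy plane
    c2 = c1 + 1.40 * np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
    n = c2 + 1.47 * np.array([1.0, 0.0, 0.0])
    no_dir1 = np.array([math.cos(math.radians(60)), -math.sin(math.radians(60)), 0.0])
    no_dir2 = np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
    o2 = n + 1.22 * no_dir1
    o3 = n + 1.22 * no_dir2
    return make_residue(
        "DNC", "A", 201,
        [
            ("O1", "O", o1),
            ("C1", "C", c1),
            ("C2", "C", c2),
            ("N1", "N", n),
            ("O2", "O", o2),
            ("O3", "O", o3),
        ],
        category="ligand",
    )
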