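import numpy as np
import pytest

from tests.conftest import make_residue
from tetrelscan.detect import (
    DetectionParams,
    enumerate_candidates,
    evaluate_contact,
    find_methyl_donor_sites,
    scan_structure,
)
from tetrelscan.geometry import distance, vertex_angle
from tetrelscan.structure_io import StructureModel
from tetrelscan.synthetic import (
    PlacementSpec,
    build_sulfonium_fragment,
    generate_batch,
    place_probe,
)


class TestFindDonorSites:
    def test_no_donor_residue(self):
        model = StructureModel(
            entry_id="x",
            residues=[make_residue("HOH", "A", 1, [("O", "O", (0, 0, 0))], "water")],
        )
        assert find_methyl_donor_sites(model) == []

    def test_single_site(self, fragment):
        model = StructureModel(entry_id="x", residues=[fragment])
        sites = find_methyl_donor_sites(model)
        assert len(sites) == 1
        assert sites[0].sulfur.name == "SD"
        assert sites[0].methyl_carbon.name == "CE"
        assert sites[0].sc_bond_length == pytest.approx(1.81, abs=1e-9)

    def test_two_chains_two_sites(self, fragment):
        other = build_sulfonium_fragment()
        other.chain_id = "B"
        for atom in other.atoms:
            atom.position = atom.position + np.array([50.0, 0.0, 0.0])
        model = StructureModel(entry_id="x", residues=[fragment, other])
        sites = find_methyl_donor_sites(model)
        assert [s.chain_id for s in sites] == ["A", "B"]

    def test_implausible_sc_bond_dropped(self):
        res = make_residue(
            "SAM", "A", 1,
            [("SD", "S", (0, 0, 0)), ("CE", "C", (3.5, 0, 0))],
            "ligand",
        )
        model = StructureModel(entry_id="x", residues=[res])
        assert find_methyl_donor_sites(model) == []

    def test_configurable_donor_names(self, fragment):
        fragment.name = "SAH"
        model = StructureModel(entry_id="x", residues=[fragment])
        assert find_methyl_donor_sites(model) == []
        params = DetectionParams(donor_residue_names=frozenset({"SAH"}))
        assert len(find_methyl_donor_sites(model, params)) == 1

    def test_altloc_selects_highest_occupancy(self):
        res = make_residue(
            "SAM", "A", 1,
            [
                ("SD", "S", (0, 0, 0)),
                ("CE", "C", (1.81, 0, 0), 0.7, "A"),
                ("CE", "C", (1.85, 0.1, 0), 0.3, "B"),
            ],
            "ligand",
        )
        model = StructureModel(entry_id="x", residues=[res])
        sites = find_methyl_donor_sites(model)
        assert len(sites) == 1
        assert sites[0].methyl_carbon.altloc == "A"


class TestEnumerateCandidates:
    def test_nearby_water_found(self, fragment):
        model = place_probe(fragment, PlacementSpec(r=3.0, theta=170.0, azimuth=0.0))
        site = find_methyl_donor_sites(model)[0]
        candidates = enumerate_candidates(model, site)
        assert [a.element.upper() for a in candidates] == ["O"]

    def test_self_exclusion(self, fragment):
        """Oxygen belonging to the donor residue itself is never a candidate."""
        donor = make_residue(
            "SAM", "A", 1,
            [
                ("SD", "S", (0, 0, 0)),
                ("CE", "C", (1.81, 0, 0)),
                ("O2'", "O", (3.5, 0.5, 0)),  # within reach, same residue
            ],
            "ligand",
        )
        model = StructureModel(entry_id="x", residues=[donor])
        site = find_methyl_donor_sites(model)[0]
        assert enumerate_candidates(model, site) == []

    def test_brute_force_oracle(self, params):
        """Candidate set equals a direct filter over all atoms."""
        rng = np.random.default_rng(5)
        fragment = build_sulfonium_fragment()
        residues = [fragment]
        for i in range(60):
            element = rng.choice(["O", "N", "C", "CL"])
            name = {"O": "O", "N": "N1", "C": "C1", "CL": "CL1"}[str(element)]
            residues.append(
                make_residue(
                    "LIG", "A", 300 + i,
                    [(name, str(element).capitalize(), rng.uniform(-6, 6, 3))],
                    "ligand",
                )
            )
        model = StructureModel(entry_id="x", residues=residues)
        site = find_methyl_donor_sites(model, params)[0]
        got = {id(a) for a in enumerate_candidates(model, site, params)}
        expected = {
            id(a)
            for res in residues[1:]
            for a in res.atoms
            if a.element.upper() in params.acceptor_elements
            and distance(site.methyl_carbon.position, a.position) <= params.max_search_radius
        }
        assert got == expected

    def test_occupancy_filter(self, fragment):
        model = place_probe(fragment, PlacementSpec(r=3.0, theta=170.0, azimuth=0.0))
        model.residues[1].atoms[0].occupancy = 0.4
        site = find_methyl_donor_sites(model)[0]
        assert len(enumerate_candidates(model, site)) == 1
        params = DetectionParams(min_occupancy=0.5)
        assert enumerate_candidates(model, site, params) == []

    def test_polymer_atoms_scanned_not_skipped(self, fragment):
        """Protein oxygens are candidates, flagged by donor class downstream."""
        backbone_o = make_residue(
            "GLY", "A", 10, [("O", "O", (4.8, 0.0, 0.0))], "polymer"
        )
        model = StructureModel(entry_id="x", residues=[fragment, backbone_o])
        site = find_methyl_donor_sites(model)[0]
        candidates = enumerate_candidates(model, site)
        assert len(candidates) == 1
        contact = evaluate_contact(site, candidates[0])
        assert contact.donor_class == "polymer"
        assert contact.passes  # r = 2.99, theta = 180


class TestEvaluateContact:
    def test_collinear_pass(self, fragment):
        model = place_probe(fragment, PlacementSpec(r=3.10, theta=180.0, azimuth=0.0))
        site = find_methyl_donor_sites(model)[0]
        contact = evaluate_contact(site, model.residues[1].atoms[0])
        assert contact.geometry.r == pytest.approx(3.10, abs=1e-9)
        assert contact.geometry.theta == pytest.approx(180.0, abs=1e-6)
        assert contact.passes_distance and contact.passes_angle and contact.passes

    def test_angle_below_window_fails(self, fragment):
        model = place_probe(fragment, PlacementSpec(r=3.0, theta=159.0, azimuth=0.0))
        site = find_methyl_donor_sites(model)[0]
        contact = evaluate_contact(site, model.residues[1].atoms[0])
        assert contact.passes_distance
        assert not contact.passes_angle
        assert not contact.passes

    def test_chlorine_contact_passes_at_343(self, fragment):
        """A Cl acceptor at 3.43 A / 175 deg is inside the 3.5 A Cl cutoff."""
        model = place_probe(
            fragment, PlacementSpec(r=3.43, theta=175.0, azimuth=0.0, probe_element="CL")
        )
        site = find_methyl_donor_sites(model)[0]
        contact = evaluate_contact(site, model.residues[1].atoms[0])
        assert contact.geometry.cutoff == pytest.approx(3.5, abs=1e-12)
        assert contact.passes

    def test_boundaries_inclusive(self, fragment):
        model = place_probe(fragment, PlacementSpec(r=3.25, theta=160.0, azimuth=0.0))
        site = find_methyl_donor_sites(model)[0]
        contact = evaluate_contact(site, model.residues[1].atoms[0])
        assert contact.passes

    def test_flags_consistent_with_geometry(self, fragment, params):
        """Recomputing r and theta from raw coordinates reproduces the
        stored values exactly, and the pass flags follow the invariants."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            spec = PlacementSpec(
                r=float(rng.uniform(2.0, 3.6)),
                theta=float(rng.uniform(90.0, 180.0)),
                azimuth=float(rng.uniform(0, 360)),
            )
            model = place_probe(build_sulfonium_fragment(), spec)
            site = find_methyl_donor_sites(model)[0]
            acceptor = model.residues[1].atoms[0]
            contact = evaluate_contact(site, acceptor)
            r = distance(site.methyl_carbon.position, acceptor.position)
            theta = vertex_angle(
                site.sulfur.position, site.methyl_carbon.position, acceptor.position
            )
            assert contact.geometry.r == r
            assert contact.geometry.theta == theta
            assert contact.passes_distance == (r <= contact.geometry.cutoff)
            assert contact.passes_angle == (params.theta_min <= theta <= params.theta_max)
            assert contact.passes == (contact.passes_distance and contact.passes_angle)
            assert contact.geometry.normalized_r == r / contact.geometry.cutoff


class TestScanStructure:
    def test_pass_and_decoy(self, fragment):
        model = place_probe(fragment, PlacementSpec(r=3.0, theta=170.0, azimuth=0.0))
        decoy_model = place_probe(
            fragment, PlacementSpec(r=3.0, theta=120.0, azimuth=0.0), probe_seq_id=102
        )
        model.residues.append(decoy_model.residues[1])
        contacts = scan_structure(model)
        assert len(contacts) == 2
        passing = [c for c in contacts if c.passes]
        assert len(passing) == 1
        assert passing[0].geometry.theta == pytest.approx(170.0, abs=1e-6)
        # passing contacts sort before near-misses
        assert contacts[0].passes

    def test_planted_truth_recovery(self):
        """Detector output matches generator labels exactly on a seeded batch."""
        batch = generate_batch(seed=123, n_pass=50, n_fail=50)
        for model, spec, label in zip(batch.models, batch.specs, batch.truth):
            contacts = scan_structure(model)
            passing = [c for c in contacts if c.passes]
            if label == "planted-pass":
                assert len(passing) == 1
                assert passing[0].geometry.r == pytest.approx(spec.r, abs=1e-9)
                assert passing[0].geometry.theta == pytest.approx(spec.theta, abs=1e-9)
            else:
                assert passing == []

    def test_monotone_in_distance_and_angle(self, fragment):
        """Decreasing r never loses passes_distance; moving theta toward 180
        never loses passes_angle."""
        for theta in (150.0, 160.0, 170.0, 180.0):
            prev_angle_pass = False
            for model_theta in np.linspace(theta, 180.0, 5):
                model = place_probe(
                    build_sulfonium_fragment(),
                    PlacementSpec(r=3.0, theta=float(model_theta), azimuth=0.0),
                )
                site = find_methyl_donor_sites(model)[0]
                c = evaluate_contact(site, model.residues[1].atoms[0])
                assert c.passes_angle or not prev_angle_pass
                prev_angle_pass = c.passes_angle
        for r_start in (3.6, 3.25, 2.8):
            prev_dist_pass = False
            for r in np.linspace(r_start, 2.4, 5):
                model = place_probe(
                    build_sulfonium_fragment(),
                    PlacementSpec(r=float(r), theta=175.0, azimuth=0.0),
                )
                site = find_methyl_donor_sites(model)[0]
                c = evaluate_contact(site, model.residues[1].atoms[0])
                assert c.passes_distance or not prev_dist_pass
                prev_dist_pass = c.passes_distance

    def test_never_reports_own_residue(self):
        batch = generate_batch(seed=9, n_pass=10, n_fail=10)
        for model in batch.models:
            for contact in scan_structure(model):
                assert contact.acceptor_residue is not contact.site.residue


class TestDetectionParams:
    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            DetectionParams(theta_min=170, theta_max=160)

    def test_rejects_small_search_radius(self):
        with pytest.raises(ValueError):
            DetectionParams(max_search_radius=3.0)
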