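import numpy as np
import pytest

from ptpkit import interactions as ni
from ptpkit import synth
from ptpkit.io import Atom, StructureModel, Trajectory


def _res(chain, num, name, atom_positions):
    return [
        Atom(chain, num, name, atom_name, atom_name[0], np.asarray(pos, float))
        for atom_name, pos in atom_positions.items()
    ]


def _leu(num, origin, chain="A"):
    o = np.asarray(origin, float)
    return _res(chain, num, "LEU", {
        "N": o + (0, 0, 1.5), "CA": o + (0, 0, 0), "C": o + (1.4, 0, 0),
        "O": o + (1.9, 1.0, 0), "CB": o + (0, 1.5, 0), "CG": o + (0, 2.8, 0.5),
        "CD1": o + (0.8, 3.9, 0), "CD2": o + (-1.2, 3.4, 0.9),
    })


def _gly(num, origin, chain="A"):
    o = np.asarray(origin, float)
    return _res(chain, num, "GLY", {
        "N": o + (0, 0, 1.5), "CA": o + (0, 0, 0), "C": o + (1.4, 0, 0),
        "O": o + (1.9, 1.0, 0),
    })


class TestHydrophobicContacts:
    def _fixture(self, gap):
        """LEU 1 ... GLY 2, GLY 3 ... LEU 4, closest side-chain carbons
        (LEU1 CD1 to LEU4 CB) exactly `gap` apart."""
        atoms = []
        atoms += _leu(1, (0, 0, 0))
        atoms += _gly(2, (6, -8, 0))
        atoms += _gly(3, (10, -8, 0))
        atoms += _leu(4, (0.8, 2.4 + gap, 0))
        return StructureModel(atoms)

    def test_pair_within_cutoff_engages_half_the_residues(self):
        model = self._fixture(gap=4.0)
        pairs, pct = ni.hydrophobic_contacts(model)
        assert len(pairs) == 1
        assert {p.number for pair in pairs for p in pair} == {1, 4}
        assert pct == pytest.approx(50.0)  # 2 of 4 residues

    def test_separated_side_chains_no_pairs(self):
        pairs, pct = ni.hydrophobic_contacts(self._fixture(gap=5.5))
        assert pairs == [] and pct == 0.0

    def test_sequence_neighbors_excluded(self):
        atoms = _leu(1, (0, 0, 0)) + _leu(2, (0, 1.0, 0))
        pairs, _ = ni.hydrophobic_contacts(StructureModel(atoms))
        assert pairs == []


class TestSaltBridges:
    def _fixture(self, d):
        atoms = _res("A", 10, "LYS", {
            "N": (0, 0, 1.5), "CA": (0, 0, 0), "C": (1.4, 0, 0), "O": (1.9, 1, 0),
            "NZ": (0, 4.0, 0),
        })
        atoms += _res("A", 40, "GLU", {
            "N": (8, 0, 1.5), "CA": (8, 0, 0), "C": (9.4, 0, 0), "O": (9.9, 1, 0),
            "OE1": (0, 4.0 + d, 0), "OE2": (2.5, 9.0, 0),
        })
        return StructureModel(atoms)

    def test_bridge_within_cutoff(self):
        pairs, pct = ni.salt_bridges(self._fixture(3.5))
        assert len(pairs) == 1 and pct == pytest.approx(100.0)

    def test_boundary_inclusive(self):
        pairs, _ = ni.salt_bridges(self._fixture(4.0))
        assert len(pairs) == 1

    def test_beyond_cutoff_empty(self):
        pairs, _ = ni.salt_bridges(self._fixture(4.01))
        assert pairs == []


class TestSidechainHbonds:
    def _fixture(self, d, with_h_at_angle=None):
        ser = {
            "N": (0, 0, 1.5), "CA": (0, 0, 0), "C": (1.4, 0, 0), "O": (1.9, 1, 0),
            "OG": (0, 2.0, 0),
        }
        if with_h_at_angle is not None:
            theta = np.radians(180.0 - with_h_at_angle)
            # acceptor direction is +y; place H so the D-H...A angle is as asked
            ser["HG"] = (np.sin(theta), 2.0 + np.cos(theta), 0)
        asn = {
            "N": (6, 0, 1.5), "CA": (6, 0, 0), "C": (7.4, 0, 0), "O": (7.9, 1, 0),
            "OD1": (0, 2.0 + d, 0), "ND2": (6, 3.5, 1.0),
        }
        if with_h_at_angle is not None:
            # give the acceptor residue explicit hydrogens too, so neither
            # of its heavy atoms silently becomes a fallback donor
            asn["HD21"] = (6.9, 3.9, 1.0)
            asn["HD22"] = (5.3, 4.3, 1.3)
        return StructureModel(
            _res("A", 5, "SER", ser) + _res("A", 50, "ASN", asn)
        )

    def test_heavy_atom_fallback_counts(self):
        pairs, pct = ni.sidechain_hbonds(self._fixture(3.0))
        assert len(pairs) == 1 and pct == pytest.approx(100.0)

    def test_explicit_hydrogen_with_bad_angle_rejected(self):
        pairs, _ = ni.sidechain_hbonds(self._fixture(3.0, with_h_at_angle=90.0))
        assert pairs == []

    def test_explicit_hydrogen_with_good_angle_kept(self):
        pairs, _ = ni.sidechain_hbonds(self._fixture(3.0, with_h_at_angle=165.0))
        assert len(pairs) == 1

    def test_salt_bridge_pairs_excluded(self):
        atoms = _res("A", 10, "LYS", {
            "N": (0, 0, 1.5), "CA": (0, 0, 0), "C": (1.4, 0, 0), "O": (1.9, 1, 0),
            "NZ": (0, 4.0, 0),
        })
        atoms += _res("A", 40, "GLU", {
            "N": (8, 0, 1.5), "CA": (8, 0, 0), "C": (9.4, 0, 0), "O": (9.9, 1, 0),
            "OE1": (0, 7.0, 0), "OE2": (2.5, 9.0, 0),
        })
        model = StructureModel(atoms)
        assert len(ni.salt_bridges(model)[0]) == 1
        assert ni.sidechain_hbonds(model)[0] == []


class TestCationPi:
    def _fixture(self, d):
        ring_center = np.array([0.0, d, 0.0])
        ring = {}
        for i, name in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
            ang = np.radians(60 * i)
            ring[name] = ring_center + 1.4 * np.array([np.cos(ang), 0, np.sin(ang)])
        phe = {"N": (0, -1.5, 1.5), "CA": (0, -1.5, 0), "C": (1.4, -1.5, 0),
               "O": (1.9, -0.5, 0), **ring}
        arg = {
            "N": (0, 0, 6.5), "CA": (0, 0, 5), "C": (1.4, 0, 5), "O": (1.9, 1, 5),
            "NE": (0, 0.5, 0.5), "CZ": (0, 0, 0), "NH1": (0.8, -0.8, 0),
            "NH2": (-0.8, -0.8, -0.5),
        }
        # guanidinium centroid sits at mean of CZ/NH1/NH2/NE
        return StructureModel(_res("A", 14, "PHE", phe) + _res("A", 127, "ARG", arg))

    def test_pair_within_cutoff(self):
        model = self._fixture(5.0)
        arg_centroid = np.mean([
            model.atom("A", 127, n).position for n in ("CZ", "NH1", "NH2", "NE")
        ], axis=0)
        ring_centroid = np.mean([
            model.atom("A", 14, n).position
            for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        ], axis=0)
        d = np.linalg.norm(arg_centroid - ring_centroid)
        pairs = ni.cation_pi(model)[0]
        assert (len(pairs) == 1) == (d <= 6.0)
        assert len(pairs) == 1

    def test_far_ring_no_pair(self):
        assert ni.cation_pi(self._fixture(12.0))[0] == []


class TestHelixContent:
    def test_ideal_helix_fully_helical(self):
        assert ni.helix_content([(-60.0, -45.0)] * 10) == pytest.approx(100.0)

    def test_alternating_angles_break_runs(self):
        pairs = [(-60.0, -45.0), (-120.0, 130.0)] * 5
        assert ni.helix_content(pairs) == 0.0

    def test_run_length_rule(self):
        pairs = [(-60.0, -45.0)] * 6 + [(-120.0, 130.0)] * 4
        assert ni.helix_content(pairs) == pytest.approx(60.0)
        short = [(-60.0, -45.0)] * 3 + [(-120.0, 130.0)] * 7
        assert ni.helix_content(short) == 0.0

    def test_helix_content_from_backbone_structure(self):
        model = synth.build_backbone(np.array([(-60.0, -45.0)] * 8))
        # terminal flank residues have no defined phi/psi; the 8-residue
        # core is one helical run
        content = ni.helix_content_of_model(model)
        assert content == pytest.approx(100.0, abs=1e-6)


def brute_force_pairs(model, detector, cutoff):
    """Exhaustive all-pairs oracle for the distance-based detectors."""
    residues = ni.protein_residues(model)
    found = set()
    for i, a in enumerate(residues):
        for b in residues[i + 1:]:
            if detector == "hydrophobic":
                if a.name not in ni.HYDROPHOBIC_RESIDUES:
                    continue
                if b.name not in ni.HYDROPHOBIC_RESIDUES:
                    continue
                if a.chain == b.chain and abs(a.number - b.number) < 2:
                    continue
                pa = [p for n, p in a.sidechain_atoms().items() if n.startswith("C")]
                pb = [p for n, p in b.sidechain_atoms().items() if n.startswith("C")]
                if any(np.linalg.norm(x - y) <= cutoff for x in pa for y in pb):
                    found.add((a.key, b.key))
            else:  # salt
                for basic, acid in ((a, b), (b, a)):
                    if basic.name not in ni.BASIC_NITROGENS:
                        continue
                    if acid.name not in ni.ACIDIC_OXYGENS:
                        continue
                    pn = [basic.atoms[n] for n in ni.BASIC_NITROGENS[basic.name]
                          if n in basic.atoms]
                    po = [acid.atoms[n] for n in ni.ACIDIC_OXYGENS[acid.name]
                          if n in acid.atoms]
                    if any(np.linalg.norm(x - y) <= cutoff for x in pn for y in po):
                        found.add((a.key, b.key))
    return found


def random_interaction_model(rng, n=14):
    atoms = []
    names = ["LEU", "LYS", "GLU", "ALA", "ASP", "ARG", "GLY"]
    templates = {
        "LEU": lambda o: _leu(0, o),
        "GLY": lambda o: _gly(0, o),
        "ALA": lambda o: _res("A", 0, "ALA", {
            "N": o + (0, 0, 1.5), "CA": o, "C": o + (1.4, 0, 0),
            "O": o + (1.9, 1, 0), "CB": o + (0, 1.5, 0)}),
        "LYS": lambda o: _res("A", 0, "LYS", {
            "N": o + (0, 0, 1.5), "CA": o, "C": o + (1.4, 0, 0),
            "O": o + (1.9, 1, 0), "NZ": o + (0, 3.9, 0)}),
        "ARG": lambda o: _res("A", 0, "ARG", {
            "N": o + (0, 0, 1.5), "CA": o, "C": o + (1.4, 0, 0),
            "O": o + (1.9, 1, 0), "NE": o + (0, 3.0, 0.3),
            "CZ": o + (0, 4.2, 0), "NH1": o + (0.9, 5.0, 0),
            "NH2": o + (-0.9, 5.0, 0)}),
        "GLU": lambda o: _res("A", 0, "GLU", {
            "N": o + (0, 0, 1.5), "CA": o, "C": o + (1.4, 0, 0),
            "O": o + (1.9, 1, 0), "OE1": o + (0.5, 3.8, 0),
            "OE2": o + (-0.5, 4.2, 0)}),
        "ASP": lambda o: _res("A", 0, "ASP", {
            "N": o + (0, 0, 1.5), "CA": o, "C": o + (1.4, 0, 0),
            "O": o + (1.9, 1, 0), "OD1": o + (0.5, 2.8, 0),
            "OD2": o + (-0.5, 3.1, 0)}),
    }
    for i in range(1, n + 1):
        name = names[rng.integers(len(names))]
        origin = rng.uniform(-9, 9, 3)
        for atom in templates[name](origin):
            atoms.append(Atom("A", i, name, atom.atom_name, atom.element,
                              atom.position))
    return StructureModel(atoms)


class TestBruteForceAgreement:
    @pytest.mark.parametrize("detector,cutoff", [("hydrophobic", 4.5), ("salt", 4.0)])
    def test_detectors_equal_exhaustive_scan(self, rng, detector, cutoff):
        for _ in range(15):
            model = random_interaction_model(rng)
            if detector == "hydrophobic":
                pairs, _ = ni.hydrophobic_contacts(model, cutoff)
            else:
                pairs, _ = ni.salt_bridges(model, cutoff)
            ours = {tuple(sorted((a.key, b.key))) for a, b in pairs}
            brute = {tuple(sorted(p)) for p in brute_force_pairs(model, detector, cutoff)}
            assert ours == brute

    def test_engaged_percentage_monotone_in_cutoff(self, rng):
        model = random_interaction_model(rng)
        pcts = [ni.hydrophobic_contacts(model, c)[1] for c in (3.0, 4.5, 6.0, 9.0)]
        assert pcts == sorted(pcts)

    def test_salt_and_hbond_pairs_disjoint(self, rng):
        for _ in range(10):
            model = random_interaction_model(rng)
            salt = {frozenset((a.key, b.key)) for a, b in ni.salt_bridges(model)[0]}
            hb = {frozenset((a.key, b.key)) for a, b in ni.sidechain_hbonds(model)[0]}
            assert salt.isdisjoint(hb)


class TestCensusTimeseries:
    def test_static_trajectory_constant_series(self, rng):
        model = random_interaction_model(rng)
        traj = Trajectory([StructureModel(model.atoms, model_id=i + 1)
                           for i in range(4)])
        census = ni.census_timeseries(traj)
        for col in ("hydrophobic_pct", "salt_bridge_pct", "sidechain_hbond_pct"):
            assert census.per_frame[col].nunique() == 1

    def test_toggling_salt_bridge_alternates(self):
        def lys_glu(d, model_id):
            atoms = _res("A", 10, "LYS", {
                "N": (0, 0, 1.5), "CA": (0, 0, 0), "C": (1.4, 0, 0),
                "O": (1.9, 1, 0), "NZ": (0, 4.0, 0)})
            atoms += _res("A", 40, "GLU", {
                "N": (8, 0, 1.5), "CA": (8, 0, 0), "C": (9.4, 0, 0),
                "O": (9.9, 1, 0), "OE1": (0, 4.0 + d, 0), "OE2": (2.5, 9.0, 0)})
            return StructureModel(atoms, model_id=model_id)

        traj = Trajectory([lys_glu(d, i + 1) for i, d in enumerate((3.0, 6.0) * 3)])
        census = ni.census_timeseries(traj)
        assert list(census.per_frame["salt_bridge_pct"]) == [100.0, 0.0] * 3

    def test_means_equal_framewise_average(self, rng):
        models = [random_interaction_model(rng) for _ in range(3)]
        traj = Trajectory([StructureModel(m.atoms, model_id=i + 1)
                           for i, m in enumerate([models[0]] * 3)])
        census = ni.census_timeseries(traj)
        means = census.means()
        np.testing.assert_allclose(
            means["hydrophobic_pct"], census.per_frame["hydrophobic_pct"].mean()
        )
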