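"""Contact detection vs brute force, strength scoring, dynamic maps and
substate clustering."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from yreflank.contacts import (AtomAnnotation, ContactStrengthMap, RoleTable,
                               cluster_substates, contact_strength,
                               detect_all, detect_apolar, detect_hbonds,
                               detect_salt_bridges, dynamic_contact_map,
                               residue_fingerprints)
from yreflank.io_formats import StructureEnsemble
from yreflank.synthetic import (ProbeContact, StructureSpec,
                                gen_structure_ensemble)


def build_frame(atoms, n_frames=1):
    """Ensemble from (chain, resnum, resname, atom_name, element, xyz)."""
    return StructureEnsemble(
        serial=np.arange(1, len(atoms) + 1),
        name=np.array([a[3] for a in atoms]),
        element=np.array([a[4] for a in atoms]),
        residue_name=np.array([a[2] for a in atoms]),
        residue_number=np.array([a[1] for a in atoms]),
        chain_id=np.array([a[0] for a in atoms]),
        coords=np.tile(np.array([a[5] for a in atoms], dtype=float),
                       (n_frames, 1, 1)),
    )


@pytest.fixture(scope="module")
def role_table():
    return RoleTable.default()


def annotate(ens, role_table):
    return AtomAnnotation.annotate(ens, role_table)


class TestHbonds:
    def _frame(self, o_x):
        return build_frame([
            ("A", 1, "ASN", "ND2", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "ASN", "HD21", "H", (1.0, 0.0, 0.0)),
            ("B", 1, "DA", "N7", "N", (o_x, 0.0, 0.0)),
        ])

    def test_collinear_geometry_detected(self, role_table):
        ens = self._frame(3.2)
        recs = detect_hbonds(ens, 0, annotate(ens, role_table))
        assert len(recs) == 1
        assert recs[0].type == "hbond"
        assert recs[0].specific  # side chain to base

    def test_beyond_cutoff_not_detected(self, role_table):
        ens = self._frame(5.0)
        assert detect_hbonds(ens, 0, annotate(ens, role_table)) == []

    def test_boundary_inclusive(self, role_table):
        ens = self._frame(3.5)
        assert len(detect_hbonds(ens, 0, annotate(ens, role_table))) == 1

    def test_bad_angle_rejected(self, role_table):
        ens = build_frame([
            ("A", 1, "ASN", "ND2", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "ASN", "HD21", "H", (-1.0, 0.0, 0.0)),  # points away
            ("B", 1, "DA", "N7", "N", (3.2, 0.0, 0.0)),
        ])
        assert detect_hbonds(ens, 0, annotate(ens, role_table)) == []

    def test_distance_only_without_hydrogens(self, role_table):
        ens = build_frame([
            ("A", 1, "ASN", "ND2", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "DA", "N7", "N", (3.2, 0.0, 0.0)),
        ])
        assert len(detect_hbonds(ens, 0, annotate(ens, role_table))) == 1


class TestSaltBridges:
    def _frame(self, d):
        return build_frame([
            ("A", 1, "ARG", "NH1", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "DA", "OP1", "O", (d, 0.0, 0.0)),
        ])

    def test_within_cutoff(self, role_table):
        recs = detect_salt_bridges(self._frame(3.8), 0,
                                   annotate(self._frame(3.8), role_table))
        assert len(recs) == 1
        assert not recs[0].specific  # phosphate is backbone

    def test_beyond_cutoff(self, role_table):
        ens = self._frame(4.5)
        assert detect_salt_bridges(ens, 0, annotate(ens, role_table)) == []


def random_protein_dna_frame(rng, n_protein=25, n_dna=25):
    """A randomized frame mixing donors, acceptors, charges and apolars."""
    protein_pool = [("ARG", "NH1", "N"), ("ARG", "CB", "C"),
                    ("LYS", "NZ", "N"), ("ASN", "ND2", "N"),
                    ("ASN", "OD1", "O"), ("ALA", "CB", "C"),
                    ("GLU", "OE1", "O"), ("SER", "OG", "O")]
    dna_pool = [("DA", "N7", "N"), ("DA", "N6", "N"), ("DG", "O6", "O"),
                ("DT", "O4", "O"), ("DT", "C7", "C"), ("DC", "O2", "O"),
                ("DA", "OP1", "O"), ("DA", "C1'", "C")]
    atoms = []
    for i in range(n_protein):
        res, name, el = protein_pool[rng.integers(len(protein_pool))]
        atoms.append(("A", i + 1, res, name, el,
                      tuple(rng.uniform(0, 15, 3))))
    for i in range(n_dna):
        res, name, el = dna_pool[rng.integers(len(dna_pool))]
        atoms.append(("B", i + 1, res, name, el,
                      tuple(rng.uniform(0, 15, 3))))
    return build_frame(atoms)


def brute_force_contacts(ens, role_table, hb_d=3.5, sb_d=4.0, ap_d=4.5):
    """All-pairs reference filter (no spatial index, no angle term needed:
    the randomized frames carry no hydrogens)."""
    ann = annotate(ens, role_table)
    coords = ens.frame(0)
    out = {"hbond": set(), "salt_bridge": set(), "apolar": set()}
    for i in range(ens.n_atoms):
        for j in range(ens.n_atoms):
            if not (ann.is_protein[i] and ann.is_dna[j]):
                continue
            ri, rj = ann.roles[i], ann.roles[j]
            if ri is None or rj is None:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d <= hb_d and ((ri.donor and rj.acceptor)
                              or (ri.acceptor and rj.donor)):
                out["hbond"].add((i, j))
            if d <= sb_d and {ri.charge, rj.charge} == {"cationic",
                                                        "anionic"}:
                out["salt_bridge"].add((i, j))
            if d <= ap_d and ri.apolar and rj.apolar:
                out["apolar"].add((i, j))
    return out


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_detectors_match_all_pairs_filter(self, seed, role_table):
        rng = np.random.default_rng(seed)
        ens = random_protein_dna_frame(rng)
        ann = annotate(ens, role_table)
        want = brute_force_contacts(ens, role_table)
        name_of = {i: (str(ens.chain_id[i]), int(ens.residue_number[i]),
                       str(ens.name[i])) for i in range(ens.n_atoms)}

        def got(records):
            return {(r.protein.chain, r.protein.number, r.protein_atom,
                     r.dna.chain, r.dna.number, r.dna_atom)
                    for r in records}

        def expect(pairs):
            return {name_of[i] + name_of[j] for i, j in pairs}

        # note: a donor-acceptor pair that is also a charge pair appears in
        # both sets, exactly as the independent filter produces it
        assert got(detect_hbonds(ens, 0, ann)) == expect(want["hbond"])
        assert got(detect_salt_bridges(ens, 0, ann)) == \
            expect(want["salt_bridge"])
        assert got(detect_apolar(ens, 0, ann)) == expect(want["apolar"])

    def test_rigid_motion_invariance(self, role_table):
        rng = np.random.default_rng(42)
        ens = random_protein_dna_frame(rng)
        rot = Rotation.random(random_state=7).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved = StructureEnsemble(
            ens.serial, ens.name, ens.element, ens.residue_name,
            ens.residue_number, ens.chain_id,
            ens.coords @ rot.T + shift,
        )
        before = detect_all(ens, 0, annotate(ens, role_table))
        after = detect_all(moved, 0, annotate(moved, role_table))
        key = lambda r: (r.type, str(r.protein), r.protein_atom,
                         str(r.dna), r.dna_atom)
        assert sorted(map(key, before)) == sorted(map(key, after))

    def test_specific_implies_sidechain_and_base(self, role_table):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            ens = random_protein_dna_frame(rng)
            ann = annotate(ens, role_table)
            for r in detect_all(ens, 0, ann):
                if r.specific:
                    assert ann.roles[
                        list(ens.name).index(r.protein_atom)] is not None
                    # re-derive from the role table directly
                    prot_role = role_table.resolve(r.protein.name,
                                                   r.protein_atom, "X")
                    dna_role = role_table.resolve(r.dna.name, r.dna_atom, "X")
                    assert prot_role.role == "protein_sidechain"
                    assert dna_role.role == "base"


class TestStrengthAndMaps:
    def test_unit_weight_sum(self, role_table):
        ens = build_frame([
            ("A", 1, "ARG", "NH1", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "ARG", "NH2", "N", (0.0, 2.0, 0.0)),
            ("B", 1, "DG", "O6", "O", (3.0, 0.0, 0.0)),
            ("B", 1, "DG", "OP1", "O", (-3.3, 0.0, 0.0)),
        ])
        recs = detect_all(ens, 0, annotate(ens, role_table))
        # NH1-O6 hbond, NH1-OP1 hbond + salt bridge, NH2-O6 hbond at 3.6? no
        assert contact_strength(recs) == len(recs) > 0

    def test_no_records_strength_zero(self):
        assert contact_strength([]) == 0

    def test_engineered_pair_strength_two(self):
        ens, _ = gen_structure_ensemble(StructureSpec(
            sequence="GCTTACTAAGC", n_frames=1,
            probes=(ProbeContact("hbond", 3, frozenset({0})),
                    ProbeContact("apolar", 3, frozenset({0}))),
        ))
        cmap = dynamic_contact_map(ens)
        df = cmap.to_frame()
        by_probe = cmap.strength.sum(axis=0)
        assert sorted(by_probe.tolist()) == [1, 1]
        # the two probe residues target the same DNA base
        assert set(df["dna"]) == {"A:DT4"}

    def test_single_frame_map(self):
        ens, _ = gen_structure_ensemble(StructureSpec(
            sequence="GCGC", n_frames=1,
            probes=(ProbeContact("hbond", 1, frozenset({0})),)))
        cmap = dynamic_contact_map(ens)
        assert cmap.strength.shape == (1, 1)
        assert cmap.strength[0, 0] == 1
        assert cmap.occupancy[0] == 1.0

    def test_on_off_schedule_occupancy(self):
        ens, _ = gen_structure_ensemble(StructureSpec(
            sequence="GCTTACTAAGC", n_frames=10,
            probes=(ProbeContact("hbond", 4, frozenset(range(5))),)))
        cmap = dynamic_contact_map(ens)
        assert len(cmap.pairs) == 1
        assert np.isclose(cmap.occupancy[0], 0.5)
        assert list(cmap.strength[:, 0]) == [1] * 5 + [0] * 5

    def test_map_totals_equal_record_counts(self):
        ens, _ = gen_structure_ensemble(StructureSpec(
            sequence="GCTTACTAAGC", n_frames=6,
            probes=(ProbeContact("hbond", 2, frozenset({0, 1, 2})),
                    ProbeContact("salt_bridge", 5, frozenset({1, 3})),
                    ProbeContact("apolar", 7, frozenset({0, 5})))))
        cmap = dynamic_contact_map(ens)
        for f in range(6):
            n_records = sum(r.frame == f for r in cmap.records)
            assert cmap.strength[f].sum() == n_records

    def test_empty_ensemble_rejected(self, role_table):
        ens = build_frame([("A", 1, "ALA", "CB", "C", (0, 0, 0))])
        empty = StructureEnsemble(ens.serial, ens.name, ens.element,
                                  ens.residue_name, ens.residue_number,
                                  ens.chain_id, np.empty((0, 1, 3)))
        with pytest.raises(ValueError, match="empty"):
            dynamic_contact_map(empty, role_table)


class TestSubstateClustering:
    def test_constant_fingerprint_single_cluster(self):
        fp = np.ones((20, 4), dtype=bool)
        res = cluster_substates(fp)
        assert res.n_clusters == 1
        assert np.allclose(res.occupancies, [1.0])

    def test_two_alternating_states(self):
        fp = np.zeros((40, 3), dtype=bool)
        fp[::2, 0] = True
        fp[1::2, 1] = True
        res = cluster_substates(fp)
        assert res.n_clusters == 2
        assert np.allclose(res.occupancies, [0.5, 0.5])

    def test_planted_three_state_recovery(self):
        rng = np.random.default_rng(17)
        states = np.array([[1, 0, 0, 1, 0], [0, 1, 0, 1, 0],
                           [0, 0, 1, 0, 1]], dtype=bool)
        sched = np.repeat([0, 1, 2], [120, 60, 40])
        observed = sched.copy()
        flip = rng.random(len(sched)) < 0.05  # 5% label noise
        observed[flip] = rng.integers(0, 3, flip.sum())
        res = cluster_substates(states[observed])
        assert res.n_clusters == 3
        conf = np.zeros((3, 3))
        for s, l in zip(sched, res.labels):
            conf[s, l] += 1
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / len(sched) >= 0.90

    def test_rare_flicker_does_not_split(self):
        fp = np.zeros((100, 2), dtype=bool)
        fp[:, 0] = True
        fp[:5, 1] = True  # 5% flicker, below the occupancy floor
        res = cluster_substates(fp)
        assert res.n_clusters == 1

    def test_single_frame_warns_single_cluster(self):
        res = cluster_substates(np.ones((1, 3), dtype=bool))
        assert res.n_clusters == 1
        assert list(res.labels) == [0]

    def test_fingerprints_from_map(self):
        ens, _ = gen_structure_ensemble(StructureSpec(
            sequence="GCTTACTAAGC", n_frames=4,
            probes=(ProbeContact("hbond", 4, frozenset({0, 1})),)))
        cmap = dynamic_contact_map(ens)
        probe = cmap.pairs[0][0]
        fp, bits = residue_fingerprints(cmap, probe)
        assert fp.shape == (4, 1)
        assert list(fp[:, 0]) == [True, True, False, False]


class TestRoleTable:
    def test_every_builtin_atom_resolves(self, role_table):
        assert role_table.resolve("ARG", "NH1", "N").charge == "cationic"
        assert role_table.resolve("DT", "O4", "O").acceptor
        assert role_table.resolve("DA", "C1'", "C").role == "sugar"

    def test_unknown_heavy_atom_reported(self, role_table):
        table = RoleTable.default()
        assert table.resolve("XYZ", "Q1", "C") is None
        assert ("XYZ", "Q1") in table.unknown

    def test_user_extension_tsv(self, tmp_path, role_table):
        p = tmp_path / "extra.tsv"
        p.write_text("residue_name\tatom_name\trole\tdonor\tacceptor\t"
                     "charge\tapolar\nLIG\tN1\tprotein_sidechain\t1\t0\t"
                     "neutral\t0\n")
        table = RoleTable.default()
        table.merge_tsv(p)
        assert table.resolve("LIG", "N1", "N").donor
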