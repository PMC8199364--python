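
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_hbonds
from helixmd.builder import (NoiseModel, build_bundle, build_chain,
                             generate_trajectory)
from helixmd.core import AtomRecord, MolecularSystem
from helixmd.hbonds import (HBondCriterion, census, find_hbonds, helix_i_to_i4,
                            loop_bridge_table, reconstruct_amide_h)


def make_water(chain_id, res_index, o_pos, h1_pos, h2_pos, serial0=0):
    recs = []
    for i, (name, el, pos) in enumerate(
            [("OW", "O", o_pos), ("HW1", "H", h1_pos), ("HW2", "H", h2_pos)]):
        recs.append(AtomRecord(serial=serial0 + i + 1, name=name, element=el,
                               res_index=res_index, res_name="SOL",
                               chain_id=chain_id, position=np.asarray(pos, float)))
    return recs


def water_pair(o_o_dist):
    """Two waters with one O-H of the first pointing along the O-O vector."""
    o1 = np.zeros(3)
    o2 = np.array([o_o_dist, 0.0, 0.0])
    h1a = o1 + np.array([0.1, 0.0, 0.0])  # along O-O: perfect donor geometry
    h1b = o1 + np.array([-0.03, 0.095, 0.0])
    h2a = o2 + np.array([0.05, 0.087, 0.0])
    h2b = o2 + np.array([0.05, -0.087, 0.0])
    atoms = make_water("W", 1, o1, h1a, h1b) + make_water("W", 2, o2, h2a, h2b, 3)
    return MolecularSystem(atoms)


class TestFindHbonds:
    def test_water_pair_within_criterion(self):
        s = water_pair(0.28)
        recs = find_hbonds(s.coords(), s)
        assert len(recs) == 1
        assert recs[0].kind == "WW"
        assert recs[0].donor == ("W", 1, "OW") and recs[0].acceptor == ("W", 2, "OW")

    def test_water_pair_beyond_cutoff(self):
        s = water_pair(0.50)
        assert find_hbonds(s.coords(), s) == []

    def test_angle_criterion_rejects_misaligned_donor(self):
        s = water_pair(0.28)
        # rotate the aligned H away by ~45 deg
        coords = s.coords()
        coords[1] = np.array([0.1 * np.cos(np.radians(45)),
                              0.1 * np.sin(np.radians(45)), 0.0])
        coords[2] = np.array([-0.03, -0.095, 0.0])
        assert find_hbonds(coords, s) == []

    def test_ideal_helix_has_exactly_i_plus_4_pattern(self, ideal_helix):
        """20-residue ideal helix: backbone bonds exactly O(i)->N(i+4),
        16 of them, matching brute-force enumeration."""
        recs = find_hbonds(ideal_helix.coords(), ideal_helix)
        pairs = {(r.donor, r.acceptor) for r in recs}
        assert len(pairs) == 16
        for (dc, dr, _dn), (ac, ar, _an) in pairs:
            assert dr - ar == 4
        oracle = brute_force_hbonds(ideal_helix, ideal_helix.coords())
        assert pairs == oracle

    def test_each_pair_reported_once(self):
        s = water_pair(0.28)
        coords = s.coords()
        # make both hydrogens of water 1 point roughly along O-O
        coords[2] = np.array([0.09, 0.03, 0.0])
        recs = find_hbonds(coords, s)
        keys = [(r.donor, r.acceptor) for r in recs]
        assert len(keys) == len(set(keys)) == 1

    @settings(max_examples=15, deadline=None)
    @given(st.floats(0.20, 0.45), st.floats(0.20, 0.45))
    def test_count_monotone_in_distance_cutoff(self, ideal_helix, c1, c2):
        lo, hi = sorted([c1, c2])
        n_lo = len(find_hbonds(ideal_helix.coords(), ideal_helix,
                               HBondCriterion(max_da_distance=lo)))
        n_hi = len(find_hbonds(ideal_helix.coords(), ideal_helix,
                               HBondCriterion(max_da_distance=hi)))
        assert n_hi >= n_lo

    def test_reconstructed_amide_h_geometry(self):
        rng = np.random.default_rng(0)
        n = rng.normal(size=3)
        c_prev = n + rng.normal(size=3)
        ca = n + rng.normal(size=3)
        h = reconstruct_amide_h(n, c_prev, ca)
        assert abs(np.linalg.norm(h - n) - 0.1) < 1e-12
        # in the C(i-1)-N-CA plane ...
        normal = np.cross(c_prev - n, ca - n)
        normal /= np.linalg.norm(normal)
        assert abs(np.dot(h - n, normal)) < 1e-12
        # ... opposite the bisector
        u = (c_prev - n) / np.linalg.norm(c_prev - n)
        v = (ca - n) / np.linalg.norm(ca - n)
        bis = (u + v) / np.linalg.norm(u + v)
        assert np.dot((h - n) / 0.1, bis) < -0.999999


class TestCensus:
    def test_protein_only_has_no_water_classes(self, ideal_helix):
        traj = generate_trajectory(ideal_helix, 3, NoiseModel(sigma=0.001, seed=0))
        c = census(traj)
        assert c.pw is None and c.ww_per_water is None
        assert np.all(c.pp_total >= 0)

    def test_ww_per_water_counts_bond_toward_both_molecules(self):
        s = water_pair(0.28)
        traj = generate_trajectory(s, 2, NoiseModel(sigma=0.0, seed=0))
        c = census(traj)
        assert np.allclose(c.ww_per_water, 1.0)  # 2 * 1 bond / 2 waters

    def test_class_partition_exact(self, wtrop_bundle):
        system, ann = wtrop_bundle
        traj = generate_trajectory(system, 5, NoiseModel(sigma=0.02, seed=3))
        c = census(traj, system, ann)
        assert np.array_equal(c.pp_total, c.pp_interchain + c.pp_intrachain)

    def test_single_chain_bundle_has_no_interchain(self, ideal_helix):
        traj = generate_trajectory(ideal_helix, 3, NoiseModel(sigma=0.0, seed=0))
        c = census(traj)
        assert np.all(c.pp_interchain == 0)
        assert np.all(c.pp_total == c.pp_intrachain)

    def test_intrachain_rate_divides_by_all_residues(self, ideal_helix):
        traj = generate_trajectory(ideal_helix, 2, NoiseModel(sigma=0.0, seed=0))
        c = census(traj)
        assert np.allclose(c.intrachain_per_residue, c.pp_intrachain / 20.0)


class TestHelixI4:
    def test_ideal_helix_counts_n_minus_4(self, ideal_helix):
        from helixmd.core import RegionAnnotation

        ann = RegionAnnotation(labels={("A", r): "HELIX" for r in range(1, 21)})
        traj = generate_trajectory(ideal_helix, 4, NoiseModel(sigma=0.0, seed=0))
        res = helix_i_to_i4(traj, ideal_helix, ann, window=0.3, n_blocks=2)
        series = res[("A", "HELIX")]["series"]
        assert np.all(series == 16)
        assert res[("A", "HELIX")]["block"].mean == 16.0

    def test_short_helix_counts_zero_with_warning(self):
        from helixmd.core import RegionAnnotation

        s = build_chain(["ALA"] * 4, [(-60, -50)] * 4)
        ann = RegionAnnotation(labels={("A", r): "HELIX" for r in range(1, 5)})
        traj = generate_trajectory(s, 4, NoiseModel(sigma=0.0, seed=0))
        with pytest.warns(UserWarning, match="shorter than 5"):
            res = helix_i_to_i4(traj, s, ann, window=0.3, n_blocks=2)
        assert np.all(res[("A", "HELIX")]["series"] == 0)

    def test_displaced_residues_lose_their_bonds(self, ideal_helix):
        """Push residues 5-8 outward 1 nm: the i->i+4 count drops exactly by
        the bonds naming those residues, per brute-force enumeration."""
        from helixmd.core import RegionAnnotation

        ann = RegionAnnotation(labels={("A", r): "HELIX" for r in range(1, 21)})
        coords = ideal_helix.coords()
        for a in ideal_helix.atoms:
            if 5 <= a.res_index <= 8:
                coords[ideal_helix.index_of("A", a.res_index, a.name)] += \
                    np.array([1.0, 0.0, 0.0])
        frames = np.stack([coords, coords])
        from helixmd.core import Trajectory

        traj = Trajectory(ideal_helix, frames, times=[0.0, 1.0])
        res = helix_i_to_i4(traj, ideal_helix, ann, window=1.0, n_blocks=2)
        oracle = brute_force_hbonds(ideal_helix, coords)
        oracle_i4 = {p for p in oracle
                     if p[0][1] - p[1][1] == 4 and p[0][2] == "N" and p[1][2] == "O"}
        assert res[("A", "HELIX")]["series"][0] == len(oracle_i4)
        assert len(oracle_i4) < 16

    def test_count_bounded_by_length_minus_4(self, wtrop_bundle):
        system, ann = wtrop_bundle
        traj = generate_trajectory(system, 4, NoiseModel(sigma=0.03, seed=8))
        res = helix_i_to_i4(traj, system, ann, window=0.3, n_blocks=2)
        for (cid, lab, a, b) in ann.helix_ranges():
            assert np.all(res[(cid, lab)]["series"] <= (b - a + 1) - 4)


class TestLoopBridge:
    def test_constructed_bridge_is_flagged(self, wtrop_bundle):
        """Place one loop residue's carbonyl O within criterion of amide N
        atoms in both helices: that residue (and only it) bridges."""
        system, ann = wtrop_bundle
        coords = system.coords()
        o_idx = system.index_of("A", 29, "O")
        n1 = coords[system.index_of("A", 20, "N")]
        n2 = coords[system.index_of("A", 40, "N")]
        # midpoint only works if the two Ns are close enough; move O near each
        # by constructing a frame per target and averaging counts instead:
        # simpler: put helices' two N atoms near the loop O artificially
        coords[system.index_of("A", 20, "N")] = coords[o_idx] + [0.29, 0.0, 0.0]
        # keep H direction sane: move the whole residue-20 amide environment
        coords[system.index_of("A", 19, "C")] = coords[o_idx] + [0.29 + 0.12, 0.02, 0.0]
        coords[system.index_of("A", 20, "CA")] = coords[o_idx] + [0.29 + 0.10, -0.10, 0.0]
        coords[system.index_of("A", 40, "N")] = coords[o_idx] + [-0.29, 0.0, 0.0]
        coords[system.index_of("A", 39, "C")] = coords[o_idx] + [-0.29 - 0.12, 0.02, 0.0]
        coords[system.index_of("A", 40, "CA")] = coords[o_idx] + [-0.29 - 0.10, -0.10, 0.0]
        from helixmd.core import Trajectory

        traj = Trajectory(system, np.stack([coords, coords]), times=[0.0, 1.0])
        table, bridges = loop_bridge_table(traj, system, ann)
        flagged = bridges[bridges["A"]].index.get_level_values("res_index").tolist()
        assert flagged == [29]

    def test_displaced_loop_has_empty_table(self, wtrop_bundle):
        system, ann = wtrop_bundle
        coords = system.coords()
        for a in system.atoms:
            lo, hi = ann.loop_range(a.chain_id)
            if lo <= a.res_index <= hi:
                coords[system.index_of(a.chain_id, a.res_index, a.name)] += \
                    np.array([0.0, 0.0, 5.0])
        from helixmd.core import Trajectory

        traj = Trajectory(system, coords[None].repeat(2, axis=0), times=[0.0, 1.0])
        table, bridges = loop_bridge_table(traj, system, ann)
        assert float(table.to_numpy().sum()) == 0.0
        assert not bridges.to_numpy().any()

    def test_loopless_topology_rejected(self, rm6_bundle):
        system, ann = rm6_bundle
        traj = generate_trajectory(system, 2, NoiseModel(sigma=0.0, seed=0))
        with pytest.raises(ValueError, match="LOOP"):
            loop_bridge_table(traj, system, ann)


def test_reported_bonds_satisfy_criterion_on_audit(wtrop_bundle):
    """Post-hoc audit: re-measure every reported bond independently."""
    system, ann = wtrop_bundle
    traj = generate_trajectory(system, 3, NoiseModel(sigma=0.02, seed=6))
    crit = HBondCriterion()
    for k in range(traj.n_frames):
        coords = traj.frames[k]
        for rec in find_hbonds(coords, system, crit, frame_index=k):
            d = np.linalg.norm(coords[system.index_of(*rec.acceptor)]
                               - coords[system.index_of(*rec.donor)])
            assert d <= crit.max_da_distance + 1e-12
            assert 0.0 <= rec.angle <= crit.max_hda_angle + 1e-12
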