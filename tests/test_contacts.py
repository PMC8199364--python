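import numpy as np
import pytest

from helixmd.contacts import cm_distance, hydrophobic_selection, rdf
from helixmd.core import (AtomRecord, MolecularSystem, Selection, Trajectory,
                          select_atoms)


def point_system(coords, box=None):
    atoms = [AtomRecord(serial=i + 1, name="CB", element="C", res_index=i + 1,
                        res_name="LEU", chain_id="A", position=c)
             for i, c in enumerate(coords)]
    return MolecularSystem(atoms, box=box)


def selections_for(system, n_a):
    refs = [a.key for a in system.atoms]
    return Selection(refs=refs[:n_a]), Selection(refs=refs[n_a:])


class TestRdf:
    def test_uniform_points_give_ideal_gas_limit(self):
        """Cross-set g(r) of uniform random points in a periodic box is 1."""
        rng = np.random.default_rng(2024)
        L, nA, nB, F = 5.0, 150, 150, 25
        box = np.full(3, L)
        system = point_system(rng.uniform(0, L, size=(nA + nB, 3)), box=box)
        selA, selB = selections_for(system, nA)
        frames = rng.uniform(0, L, size=(F, nA + nB, 3))
        traj = Trajectory(system, frames, times=np.arange(F, dtype=float))
        res = rdf(traj, selA, selB, bin_width=0.05, r_max=2.0, periodic=True)
        sel = res.bin_centers >= 0.5
        # Poisson standard error per bin from the raw counts
        se = 1.0 / np.sqrt(np.maximum(res.counts[sel], 1.0))
        dev = np.abs(res.g[sel] - 1.0)
        assert np.all(dev <= 3.0 * se)

    def test_single_pair_lands_in_its_bin(self):
        d = 0.73
        system = point_system(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))
        selA, selB = selections_for(system, 1)
        traj = Trajectory(system, system.coords()[None],
                          times=np.array([0.0]))
        res = rdf(traj, selA, selB, bin_width=0.02, r_max=1.0, volume=8.0)
        assert res.counts.sum() == 1
        occupied = res.bin_centers[res.counts > 0]
        assert len(occupied) == 1 and abs(occupied[0] - d) <= 0.01

    def test_symmetric_in_set_order(self):
        rng = np.random.default_rng(7)
        system = point_system(rng.uniform(0, 3, size=(40, 3)), box=np.full(3, 3.0))
        selA, selB = selections_for(system, 20)
        traj = Trajectory(system, system.coords()[None], times=np.array([0.0]))
        r1 = rdf(traj, selA, selB, bin_width=0.05, r_max=1.4, periodic=True)
        r2 = rdf(traj, selB, selA, bin_width=0.05, r_max=1.4, periodic=True)
        assert np.array_equal(r1.g, r2.g)

    def test_coordination_integral_invariant_to_bin_width(self):
        rng = np.random.default_rng(9)
        L = 4.0
        system = point_system(rng.uniform(0, L, size=(60, 3)), box=np.full(3, L))
        selA, selB = selections_for(system, 30)
        traj = Trajectory(system, rng.uniform(0, L, size=(10, 60, 3)),
                          times=np.arange(10.0))
        rho = 30 / L ** 3
        c1 = rdf(traj, selA, selB, bin_width=0.01, r_max=1.8,
                 periodic=True).coordination_integral(rho)
        c2 = rdf(traj, selA, selB, bin_width=0.02, r_max=1.8,
                 periodic=True).coordination_integral(rho)
        assert abs(c1 - c2) / c1 < 0.05

    def test_min_image_never_exceeds_bound(self):
        rng = np.random.default_rng(11)
        L = 2.0
        system = point_system(rng.uniform(-5, 5, size=(30, 3)), box=np.full(3, L))
        selA, selB = selections_for(system, 15)
        traj = Trajectory(system, system.coords()[None], times=np.array([0.0]))
        res = rdf(traj, selA, selB, bin_width=0.05, r_max=1.0, periodic=True)
        # all recorded distances are below sqrt(3)/2 * L
        assert res.bin_centers[res.counts > 0].max() <= np.sqrt(3) / 2 * L

    def test_first_peak_decays_with_noise(self):
        """Blur a tight contact geometry: the first-peak height must fall
        monotonically with sigma (the hydrophobic-contact temperature trend)."""
        rng = np.random.default_rng(13)
        base = np.array([[0.0, 0.0, z] for z in np.linspace(0, 1.0, 6)]
                        + [[0.5, 0.0, z] for z in np.linspace(0, 1.0, 6)])
        system = point_system(base)
        selA, selB = selections_for(system, 6)
        peaks = []
        for sigma in (0.01, 0.05, 0.10):
            frames = base[None] + rng.normal(size=(150, 12, 3)) * sigma
            traj = Trajectory(system, frames, times=np.arange(150.0))
            res = rdf(traj, selA, selB, bin_width=0.04, r_max=1.0, volume=27.0)
            peaks.append(res.g.max())
        assert peaks[0] > peaks[1] > peaks[2]

    def test_rmax_beyond_half_box_rejected(self):
        system = point_system(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
                              box=np.full(3, 2.0))
        selA, selB = selections_for(system, 1)
        traj = Trajectory(system, system.coords()[None], times=np.array([0.0]))
        with pytest.raises(ValueError, match="half"):
            rdf(traj, selA, selB, bin_width=0.05, r_max=1.5, periodic=True)

    def test_overlapping_sets_rejected(self):
        system = point_system(np.zeros((3, 3)) + np.arange(3)[:, None])
        sel = Selection(refs=[a.key for a in system.atoms])
        traj = Trajectory(system, system.coords()[None], times=np.array([0.0]))
        with pytest.raises(ValueError, match="disjoint"):
            rdf(traj, sel, sel, volume=1.0)


class TestCmDistance:
    def test_translated_sets(self):
        coords = np.array([[0.0, 0, 0], [0, 1, 0], [0, 0, 1],
                           [1.0, 0, 0], [1, 1, 0], [1, 0, 1]])
        system = point_system(coords)
        selA, selB = selections_for(system, 3)
        assert abs(cm_distance(coords, system, selA, selB) - 1.0) < 1e-12

    def test_identical_sets_zero(self):
        coords = np.arange(9.0).reshape(3, 3)
        system = point_system(coords)
        sel = Selection(refs=[a.key for a in system.atoms])
        assert cm_distance(coords, system, sel, sel) == 0.0

    def test_matches_hand_computed_centroids(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 3, 0]])
        b = np.array([[2.0, 2, 2], [4, 2, 2], [3, 5, 8]])
        system = point_system(np.vstack([a, b]))
        selA, selB = selections_for(system, 3)
        want = np.linalg.norm(a.mean(0) - b.mean(0))
        got = cm_distance(np.vstack([a, b]), system, selA, selB)
        assert abs(got - want) < 1e-12

    def test_empty_set_rejected(self):
        system = point_system(np.zeros((2, 3)) + np.arange(2)[:, None])
        selA, _ = selections_for(system, 2)
        with pytest.raises(ValueError, match="empty"):
            cm_distance(system.coords(), system, selA, Selection(refs=[]))


class TestHydrophobicSelection:
    def test_per_chain_on_dimer(self, wtrop_bundle):
        system, ann = wtrop_bundle
        sels = hydrophobic_selection(system, ann, grouping="per_chain")
        assert len(sels) == 2
        for sel, cid in zip(sels, "AB"):
            assert len(sel) > 0
            assert all(r[0] == cid and r[2] == "CB" for r in sel.refs)
            assert all(ann.is_hydrophobic(r[0], r[1]) for r in sel.refs)

    def test_per_pair_on_tetramer(self, rm6_bundle):
        system, ann = rm6_bundle
        sels = hydrophobic_selection(system, ann, grouping="per_pair")
        assert len(sels) == 2
        assert {r[0] for r in sels[0].refs} == {"A", "B"}
        assert {r[0] for r in sels[1].refs} == {"C", "D"}

    def test_per_pair_requires_four_chains(self, wtrop_bundle):
        system, ann = wtrop_bundle
        with pytest.raises(ValueError, match="4 protein chains"):
            hydrophobic_selection(system, ann, grouping="per_pair")

    def test_no_flags_warns_and_returns_empty(self, wtrop_bundle):
        from helixmd.core import RegionAnnotation

        system, ann = wtrop_bundle
        bare = RegionAnnotation(labels=dict(ann.labels))
        with pytest.warns(UserWarning, match="no hydrophobic"):
            sels = hydrophobic_selection(system, bare)
        assert all(len(s) == 0 for s in sels)
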