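"""Hydrogen bonds, pi contacts, pi-pi classification and water bridges."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from otbind.geometry import PiPiDescriptor
from otbind.md_model import Frame, Trajectory, select
from otbind.noncovalent import (HBondCriteria, PiPiCategory,
                                bond_forming_probability, bridge_statistics,
                                classify_pipi, detect_hbonds, detect_pi_hbonds,
                                find_water_bridges)
from otbind.synthetic import (make_bridge_trajectory, make_hbond_fixture,
                              make_ring_pair)

from conftest import random_hbond_system
from oracles import brute_hbonds


class TestDetectHbonds:
    @pytest.mark.parametrize("dist,angle,expected", [
        (2.04, 160.0, True),    # a bona fide water-amide geometry
        (2.6, 170.0, False),    # distance beyond cutoff
        (2.0, 110.0, False),    # angle below cutoff
        (2.49, 121.0, True),    # just inside both boundaries
        (2.51, 121.0, False),   # just outside the distance boundary
    ])
    def test_criteria_boundaries(self, dist, angle, expected):
        top, frame = make_hbond_fixture(dist, angle, "O", "N")
        events = detect_hbonds(frame, top, [0], [2])
        assert bool(events) is expected
        if expected:
            assert events[0].distance == pytest.approx(dist, abs=1e-9)
            assert events[0].angle == pytest.approx(angle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        top, frame = random_hbond_system(rng, n_heavy=14)
        all_atoms = [a.index for a in top.atoms]
        events = detect_hbonds(frame, top, all_atoms, all_atoms)
        got = {(e.donor_heavy, e.hydrogen, e.acceptor) for e in events}
        want = set(brute_hbonds(frame.coordinates, top, all_atoms, all_atoms,
                                frame.box))
        assert got == want

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(42)
        top, frame = random_hbond_system(rng, n_heavy=12, box=None)
        all_atoms = [a.index for a in top.atoms]
        before = {(e.donor_heavy, e.hydrogen, e.acceptor)
                  for e in detect_hbonds(frame, top, all_atoms, all_atoms)}
        R = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
        moved = Frame(frame.coordinates @ R.T + np.array([5.0, -3.0, 9.0]))
        after = {(e.donor_heavy, e.hydrogen, e.acceptor)
                 for e in detect_hbonds(moved, top, all_atoms, all_atoms)}
        assert before == after

    def test_invariant_under_periodic_image_shift(self):
        rng = np.random.default_rng(43)
        top, frame = random_hbond_system(rng, n_heavy=12, box=12.0)
        all_atoms = [a.index for a in top.atoms]
        before = {(e.donor_heavy, e.hydrogen, e.acceptor)
                  for e in detect_hbonds(frame, top, all_atoms, all_atoms)}
        # shift one whole residue by a box vector
        coords = frame.coordinates.copy()
        res_atoms = top.residue_index[top.atoms[0].residue_id]
        coords[res_atoms] += np.array([12.0, 0.0, -12.0])
        after = {(e.donor_heavy, e.hydrogen, e.acceptor)
                 for e in detect_hbonds(Frame(coords, frame.box), top,
                                        all_atoms, all_atoms)}
        assert before == after


class TestBondFormingProbability:
    def test_constructed_fraction(self):
        # 2 of 10 frames carry a qualifying geometry
        on_top, on_frame = make_hbond_fixture(2.0, 150.0)
        _, off_frame = make_hbond_fixture(3.5, 150.0)
        frames = []
        for k in range(10):
            src = on_frame if k in (3, 7) else off_frame
            f = src.copy()
            f.time = float(k)
            frames.append(f)
        traj = Trajectory(on_top, frames)
        prob = bond_forming_probability(traj, [0], [2])
        assert prob.probability == pytest.approx(0.2)
        assert prob.mean_distance == pytest.approx(2.0, abs=1e-9)
        # the all-frames average mixes 2.0 and 3.5
        assert prob.mean_distance_all_frames == pytest.approx(
            (2 * 2.0 + 8 * 3.5) / 10, abs=1e-9)

    def test_always_formed_gives_one(self):
        top, frame = make_hbond_fixture(2.0, 150.0)
        frames = [Frame(frame.coordinates.copy(), time=float(k))
                  for k in range(5)]
        traj = Trajectory(top, frames)
        assert bond_forming_probability(traj, [0], [2]).probability == 1.0

    def test_bernoulli_occupancy_recovered(self):
        rng = np.random.default_rng(0)
        on_top, on_frame = make_hbond_fixture(2.0, 150.0)
        _, off_frame = make_hbond_fixture(3.5, 150.0)
        p = 0.3
        draws = rng.random(2000) < p
        frames = []
        for k, on in enumerate(draws):
            f = (on_frame if on else off_frame).copy()
            f.time = float(k)
            frames.append(f)
        traj = Trajectory(on_top, frames)
        got = bond_forming_probability(traj, [0], [2]).probability
        assert got == pytest.approx(draws.mean())
        assert got == pytest.approx(p, abs=0.03)

    def test_empty_trajectory_raises(self):
        top, _ = make_hbond_fixture(2.0, 150.0)
        with pytest.raises(ValueError):
            bond_forming_probability(Trajectory(top, []), [0], [2])


class TestPiHbonds:
    def _system(self, height, tilt_deg=0.0):
        """Water H above a hexagon centroid at the given height/approach tilt."""
        top, frame = make_ring_pair(0.0, 10.0, 0.0)  # two rings, use 'HEM'
        from otbind.md_model import AtomRecord, Topology

        atoms = list(top.atoms) + [
            AtomRecord(12, "OW", "O", "HOH", 900, "W", is_donor_heavy=True,
                       is_acceptor=True, bound_hydrogens=[13]),
            AtomRecord(13, "HW1", "H", "HOH", 900, "W"),
        ]
        top2 = Topology(atoms, rings=top.rings)
        t = np.radians(tilt_deg)
        h_pos = np.array([height * np.sin(t), 0.0, height * np.cos(t)])
        o_pos = h_pos * (np.linalg.norm(h_pos) + 0.97) / np.linalg.norm(h_pos)
        coords = np.vstack([frame.coordinates, o_pos, h_pos])
        return top2, Frame(coords)

    def test_on_axis_contact_detected(self):
        top, frame = self._system(2.3)
        events = detect_pi_hbonds(frame, top, [12], ["HEM"])
        assert len(events) == 1
        assert events[0].acceptor == "HEM"
        assert events[0].distance == pytest.approx(2.3, abs=1e-9)

    def test_in_plane_approach_rejected(self):
        top, frame = self._system(2.3, tilt_deg=90.0)
        assert detect_pi_hbonds(frame, top, [12], ["HEM"]) == []

    def test_distance_boundary(self):
        top, frame = self._system(3.5)
        assert detect_pi_hbonds(frame, top, [12], ["HEM"]) == []

    def test_approach_cone_boundary(self):
        top, frame = self._system(2.3, tilt_deg=29.0)
        assert len(detect_pi_hbonds(frame, top, [12], ["HEM"])) == 1
        top, frame = self._system(2.3, tilt_deg=31.0)
        assert detect_pi_hbonds(frame, top, [12], ["HEM"]) == []


class TestClassifyPiPi:
    def test_reference_t_shaped_geometry(self):
        desc = PiPiDescriptor(r_cen=4.72, d=4.6, theta=85.0)
        assert classify_pipi(desc) is PiPiCategory.T_SHAPED

    def test_reference_stacked_geometry(self):
        desc = PiPiDescriptor(r_cen=4.3, d=4.21, theta=25.0)
        assert classify_pipi(desc) is PiPiCategory.STACKED

    def test_threshold_midpoint_is_intermediate(self):
        desc = PiPiDescriptor(r_cen=5.0, d=3.0, theta=45.0)
        assert classify_pipi(desc) is PiPiCategory.INTERMEDIATE

    def test_far_apart_is_none(self):
        desc = PiPiDescriptor(r_cen=8.0, d=3.0, theta=85.0)
        assert classify_pipi(desc) is PiPiCategory.NONE

    @given(
        r_cen=st.floats(0.1, 12.0),
        d_frac=st.floats(0.0, 1.0),
        theta=st.floats(0.0, 90.0),
    )
    def test_categories_partition_descriptor_space(self, r_cen, d_frac, theta):
        desc = PiPiDescriptor(r_cen=r_cen, d=r_cen * d_frac, theta=theta)
        category = classify_pipi(desc)
        assert isinstance(category, PiPiCategory)  # exactly one, never raises


class TestWaterBridges:
    def test_single_water_bridge_found(self):
        traj = make_bridge_trajectory(1, 1.0, seed=0)
        waters = select(traj.topology, "water")
        bridges = find_water_bridges(traj[0], traj.topology, [1], [3], waters)
        assert len(bridges) == 1
        assert bridges[0].water_chain == [100]
        assert len(bridges[0].events) >= 2

    def test_no_water_no_bridge(self):
        traj = make_bridge_trajectory(1, 0.0, seed=0)
        waters = select(traj.topology, "water")
        assert find_water_bridges(traj[0], traj.topology, [1], [3], waters) == []

    def test_two_water_bridge_with_pi_acceptor(self):
        # ring <- water-a H, water-a <- water-b H, water-b <- amide H
        from otbind.md_model import AtomRecord, RingSpec, Topology

        ring_top, ring_frame = make_ring_pair(0.0, 20.0, 0.0)
        atoms = list(ring_top.atoms)
        coords = [c for c in ring_frame.coordinates]

        def add(name, element, resname, resid, pos, **kw):
            atoms.append(AtomRecord(len(atoms), name, element, resname, resid,
                                    "W", **kw))
            coords.append(np.asarray(pos, dtype=float))
            return len(atoms) - 1

        # water a: H 2.3 above the HEM centroid (origin), on-axis
        oa = add("OW", "O", "HOH", 900, (0, 0, 3.27), is_donor_heavy=True,
                 is_acceptor=True)
        ha1 = add("HW1", "H", "HOH", 900, (0, 0, 2.3))
        ha2 = add("HW2", "H", "HOH", 900, (0.92, 0, 3.58))
        atoms[oa].bound_hydrogens = [ha1, ha2]
        # water b: donates to water a's O
        ob = add("OW", "O", "HOH", 901, (0, 2.9, 4.4), is_donor_heavy=True,
                 is_acceptor=True)
        hb1 = add("HW1", "H", "HOH", 901, (0, 2.0, 4.05))
        hb2 = add("HW2", "H", "HOH", 901, (0.92, 3.2, 4.6))
        atoms[ob].bound_hydrogens = [hb1, hb2]
        # amide donor aimed at water b's O
        nn = add("N", "N", "MET", 374, (0, 5.8, 5.4), is_donor_heavy=True,
                 is_acceptor=True)
        hn = add("H", "H", "MET", 374, (0, 4.85, 5.05))
        atoms[nn].bound_hydrogens = [hn]
        top = Topology(atoms, rings=ring_top.rings)
        frame = Frame(np.asarray(coords))
        waters = [oa, ha1, ha2, ob, hb1, hb2]
        bridges = find_water_bridges(frame, top, ["HEM"], [nn], waters,
                                     max_waters=2)
        chains = {tuple(b.water_chain) for b in bridges}
        assert (900, 901) in chains or (901, 900) in chains
        two_water = [b for b in bridges if len(b.water_chain) == 2]
        assert len(two_water) >= 1

    def test_max_waters_limits_chain_length(self):
        rng = np.random.default_rng(0)
        traj = make_bridge_trajectory(1, 1.0, seed=0)
        waters = select(traj.topology, "water")
        bridges = find_water_bridges(traj[0], traj.topology, [1], [3], waters,
                                     max_waters=2)
        assert all(len(b.water_chain) <= 2 for b in bridges)


class TestBridgeStatistics:
    def test_full_occupancy_no_exchanges(self):
        traj = make_bridge_trajectory(30, 1.0, seed=0)
        waters = select(traj.topology, "water")
        stats = bridge_statistics(traj, 1, 3, waters)
        assert stats.occupancy == 1.0
        assert stats.exchange_count == 0

    def test_bernoulli_occupancy(self):
        traj = make_bridge_trajectory(2000, 0.7, seed=9)
        waters = select(traj.topology, "water")
        stats = bridge_statistics(traj, 1, 3, waters)
        assert stats.occupancy == pytest.approx(0.7, abs=0.03)

    def test_constructed_water_swap_counted(self):
        traj = make_bridge_trajectory(100, 1.0, exchange_frames=(50,), seed=0)
        waters = select(traj.topology, "water")
        stats = bridge_statistics(traj, 1, 3, waters)
        assert stats.exchange_count == 1

    def test_never_formed_pattern(self):
        traj = make_bridge_trajectory(20, 0.0, seed=0)
        waters = select(traj.topology, "water")
        stats = bridge_statistics(traj, 1, 3, waters)
        assert stats.occupancy == 0.0
        assert stats.exchange_count == 0
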