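"""Pair energies, interaction entropy, solvation surrogates and bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from otbind.energetics import (COULOMB_KJ_A_E2, KB_KJ_MOL_K, EnergySeries,
                               gb_energy, gb_polar_surrogate,
                               interaction_energy_series, interaction_entropy,
                               ki_to_delta_g, lj_coulomb_energy, mmpbsa_totals,
                               nonpolar_solvation, per_residue_decomposition,
                               sasa)
from otbind.md_model import (AtomRecord, Frame, Topology, Trajectory, select)
from otbind.synthetic import make_gaussian_energy_series, make_toy_complex

from oracles import brute_lj_coulomb


def two_particle_topology(q1=0.0, q2=0.0, sigma=3.0, eps=1.0):
    atoms = [
        AtomRecord(0, "A", "Ar", "GAS", 1, "G", charge=q1, lj_sigma=sigma,
                   lj_epsilon=eps, parameterized=True),
        AtomRecord(1, "B", "Ar", "GAS", 2, "G", charge=q2, lj_sigma=sigma,
                   lj_epsilon=eps, parameterized=True),
    ]
    return Topology(atoms)


class TestLjCoulomb:
    def test_lj_minimum_value(self):
        sigma, eps = 3.4, 0.9
        top = two_particle_topology(sigma=sigma, eps=eps)
        r_min = 2 ** (1 / 6) * sigma
        frame = Frame(np.array([[0.0, 0, 0], [r_min, 0, 0]]))
        e_vdw, e_coul = lj_coulomb_energy(frame, [0], [1], top, use_pbc=False)
        assert e_vdw == pytest.approx(-eps, abs=1e-12)
        assert e_coul == 0.0

    def test_coulomb_hand_value(self):
        top = two_particle_topology(q1=1.0, q2=-1.0, eps=0.0)
        frame = Frame(np.array([[0.0, 0, 0], [13.8935458, 0, 0]]))
        _, e_coul = lj_coulomb_energy(frame, [0], [1], top, use_pbc=False)
        assert e_coul == pytest.approx(-100.0, abs=0.01)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        atoms = [
            AtomRecord(i, f"A{i}", "Ar", "GAS", i + 1, "G",
                       charge=float(rng.uniform(-1, 1)),
                       lj_sigma=float(rng.uniform(2.5, 4.0)),
                       lj_epsilon=float(rng.uniform(0.1, 1.0)),
                       parameterized=True)
            for i in range(n)
        ]
        top = Topology(atoms)
        box = 20.0
        coords = rng.uniform(0, box, (n, 3))
        # keep pairs apart so r**-12 stays finite and comparable
        frame = Frame(coords * 1.0, np.full(3, box))
        group_a, group_b = list(range(5)), list(range(5, 10))
        try:
            ours = lj_coulomb_energy(frame, group_a, group_b, top)
        except ValueError:
            return  # overlapping fixture; the guard is tested elsewhere
        want = brute_lj_coulomb(
            coords, [a.charge for a in atoms], [a.lj_sigma for a in atoms],
            [a.lj_epsilon for a in atoms], group_a, group_b, [box] * 3)
        assert ours[0] == pytest.approx(want[0], rel=1e-9, abs=1e-9)
        assert ours[1] == pytest.approx(want[1], rel=1e-9, abs=1e-9)

    def test_symmetric_in_selection_order(self, toy):
        top = toy.topology
        lig = select(top, "ligand")
        rec = select(top, "residue_id 372")
        ab = lj_coulomb_energy(toy.trajectory[0], rec, lig, top)
        ba = lj_coulomb_energy(toy.trajectory[0], lig, rec, top)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_coulomb_scales_linearly_in_charge_product(self):
        top = two_particle_topology(q1=0.5, q2=-0.2, eps=0.0)
        frame = Frame(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        _, e1 = lj_coulomb_energy(frame, [0], [1], top, use_pbc=False)
        top.atom(0).charge *= 3.0
        _, e3 = lj_coulomb_energy(frame, [0], [1], top, use_pbc=False)
        assert e3 == pytest.approx(3.0 * e1, rel=1e-12)

    def test_overlap_raises(self):
        top = two_particle_topology()
        frame = Frame(np.array([[0.0, 0, 0], [0.05, 0, 0]]))
        with pytest.raises(ValueError, match="overlap"):
            lj_coulomb_energy(frame, [0], [1], top, use_pbc=False)

    def test_disjoint_selection_required(self):
        top = two_particle_topology()
        frame = Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        with pytest.raises(ValueError, match="disjoint"):
            lj_coulomb_energy(frame, [0, 1], [1], top, use_pbc=False)


class TestInteractionEnergySeries:
    def test_static_trajectory_constant_series(self):
        top = two_particle_topology(q1=0.3, q2=-0.3)
        frame = Frame(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        traj = Trajectory(top, [Frame(frame.coordinates.copy(), time=float(k))
                                for k in range(5)])
        series = interaction_energy_series(traj, [0], [1], top, use_pbc=False)
        assert np.ptp(series.values) == pytest.approx(0.0, abs=1e-12)

    def test_equals_per_frame_energy_calls(self, toy):
        top = toy.topology
        lig = select(top, "ligand")
        rec = select(top, "protein")
        traj = toy.trajectory[:5]
        series = interaction_energy_series(traj, rec, lig, top)
        for k, frame in enumerate(traj):
            v, c = lj_coulomb_energy(frame, rec, lig, top)
            assert series.values[k] == pytest.approx(v + c, abs=1e-9)

    def test_harmonic_two_particle_closed_form(self):
        # r(t) oscillates; energy must follow E(r(t)) exactly
        top = two_particle_topology(q1=0.4, q2=-0.4, sigma=3.0, eps=0.8)
        times = np.arange(20)
        rs = 5.0 + 0.5 * np.sin(2 * np.pi * times / 20)
        frames = [Frame(np.array([[0.0, 0, 0], [r, 0, 0]]), time=float(t))
                  for t, r in zip(times, rs)]
        traj = Trajectory(top, frames)
        series = interaction_energy_series(traj, [0], [1], top, use_pbc=False)
        sr6 = (3.0 / rs) ** 6
        expected = 4 * 0.8 * (sr6 ** 2 - sr6) + \
            COULOMB_KJ_A_E2 * 0.4 * (-0.4) / rs
        assert np.allclose(series.values, expected, atol=1e-9)


class TestInteractionEntropy:
    def test_constant_series_gives_exact_zero(self):
        est = interaction_entropy(EnergySeries(np.full(100, -42.0)))
        assert est.minus_TdS == 0.0

    def test_two_point_series_cosh_form(self):
        kbt = KB_KJ_MOL_K * 298.15
        est = interaction_entropy(EnergySeries(np.array([-10.0, 10.0])))
        assert est.minus_TdS == pytest.approx(kbt * np.log(np.cosh(10.0 / kbt)),
                                              rel=1e-9)

    @pytest.mark.parametrize("sigma", [1.0, 5.0])
    def test_gaussian_closed_form_small_sigma(self, sigma):
        series = make_gaussian_energy_series(sigma, 200_000, seed=0)
        est = interaction_entropy(series)
        expected = sigma ** 2 / (2 * KB_KJ_MOL_K * 298.15)
        assert est.minus_TdS == pytest.approx(expected, rel=0.05)

    def test_non_negative_on_random_series(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            values = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 5.0),
                                rng.integers(10, 500))
            est = interaction_entropy(EnergySeries(values))
            assert est.minus_TdS >= 0.0

    def test_stable_for_large_fluctuations(self):
        # beta * dE of several hundred must not overflow
        series = EnergySeries(np.array([0.0] * 100 + [1500.0]))
        est = interaction_entropy(series)
        assert np.isfinite(est.minus_TdS)
        assert est.minus_TdS > 1000.0

    def test_convergence_flag(self):
        good = make_gaussian_energy_series(1.0, 50_000, seed=3)
        assert interaction_entropy(good).converged
        drifting = EnergySeries(np.linspace(0.0, 2000.0, 500))
        assert not interaction_entropy(drifting).converged


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        frame = Frame(np.zeros((1, 3)))
        _, total = sasa(frame, [0], [1.5])
        expected = 4 * np.pi * (1.5 + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.005)

    def test_separated_atoms_additive(self):
        frame = Frame(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        areas, total = sasa(frame, [0, 1], [1.5, 1.2])
        lone0 = sasa(Frame(np.zeros((1, 3))), [0], [1.5])[1]
        lone1 = sasa(Frame(np.zeros((1, 3))), [0], [1.2])[1]
        assert total == pytest.approx(lone0 + lone1, rel=1e-12)

    def test_buried_atom_is_zero(self):
        # central atom caged by 26 overlapping neighbours
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1.5, 0, 1.5) for j in (-1.5, 0, 1.5)
                   for k in (-1.5, 0, 1.5) if (i, j, k) != (0, 0, 0)]
        coords = np.vstack([np.zeros(3)] + offsets)
        frame = Frame(coords)
        areas, _ = sasa(frame, range(len(coords)), [1.6] * len(coords))
        assert areas[0] == 0.0

    def test_deterministic_point_set(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 8, (6, 3))
        a1 = sasa(Frame(coords), range(6), [1.5] * 6)
        a2 = sasa(Frame(coords.copy()), range(6), [1.5] * 6)
        assert np.array_equal(a1[0], a2[0])


class TestSolvationSurrogates:
    def test_born_ion_closed_form(self):
        got = gb_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]))
        expected = -0.5 * (1 - 1 / 80) * COULOMB_KJ_A_E2 / 2.0
        assert got == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize("radius", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_born_closed_form_across_radii(self, radius):
        got = gb_energy(np.zeros((1, 3)), np.array([1.0]), np.array([radius]))
        expected = -0.5 * (1 - 1 / 80) * COULOMB_KJ_A_E2 / radius
        assert got == pytest.approx(expected, rel=1e-3)

    def test_neutral_system_is_zero(self):
        rng = np.random.default_rng(0)
        got = gb_energy(rng.uniform(0, 10, (5, 3)), np.zeros(5), np.ones(5))
        assert got == 0.0

    def test_two_distant_ions_approach_self_term_sum(self):
        coords = np.array([[0.0, 0, 0], [5000.0, 0, 0]])
        got = gb_energy(coords, np.array([1.0, 1.0]), np.array([2.0, 3.0]))
        self_terms = sum(
            -0.5 * (1 - 1 / 80) * COULOMB_KJ_A_E2 / r for r in (2.0, 3.0)
        )
        # the screened-Coulomb cross term decays as 1/r and is negligible here
        assert got == pytest.approx(self_terms, rel=1e-3)

    def test_nonpositive_born_radius_raises(self):
        with pytest.raises(ValueError):
            gb_energy(np.zeros((1, 3)), np.array([1.0]), np.array([0.0]))

    def test_surrogate_difference_on_toy(self, toy):
        from otbind.energetics import element_radii_for

        top = toy.topology
        lig = select(top, "ligand")
        rec = select(top, "protein")
        both = list(rec) + list(lig)
        radii = element_radii_for(top)
        ddg = gb_polar_surrogate(toy.trajectory[0], both, rec, lig, top, radii)
        assert np.isfinite(ddg)

    def test_nonpolar_zero_burial_leaves_constant(self):
        assert nonpolar_solvation(100.0, 60.0, 40.0) == pytest.approx(-3.849)

    def test_nonpolar_linear_in_buried_area(self):
        got = nonpolar_solvation(1000.0, 1500.0, 500.0)
        assert got == pytest.approx(0.0227 * (-1000.0) - 3.849, abs=1e-12)

    def test_nonpolar_gamma_zero(self):
        assert nonpolar_solvation(10.0, 500.0, 400.0, gamma=0.0) == \
            pytest.approx(-3.849)


class TestBookkeeping:
    def test_all_zero_components(self):
        table = mmpbsa_totals(0, 0, 0, 0, 0)
        assert table.dG_bind == 0.0

    @given(
        vdw=st.floats(-300, 0), coul=st.floats(-100, 100),
        pb=st.floats(0, 200), sa=st.floats(-50, 0), tds=st.floats(0, 60),
    )
    def test_ledger_identities_always_hold(self, vdw, coul, pb, sa, tds):
        table = mmpbsa_totals(vdw, coul, pb, sa, tds)
        assert table.dE_gas == pytest.approx(vdw + coul, abs=1e-9)
        assert table.dG_sol == pytest.approx(pb + sa, abs=1e-9)
        assert table.dG_bind == pytest.approx(
            table.dE_gas + tds + table.dG_sol, abs=1e-9)


class TestDecomposition:
    def test_single_residue_equals_total(self, toy):
        top = toy.topology
        lig = select(top, "ligand")
        traj = toy.trajectory[:3]
        dec = per_residue_decomposition(traj, lig, top, residue_ids=[372])
        ev = ec = 0.0
        for frame in traj:
            v, c = lj_coulomb_energy(frame, top.residue_index[372], lig, top)
            ev += v
            ec += c
        assert dec[372]["vdW"] == pytest.approx(ev / 3, abs=1e-9)
        assert dec[372]["Coul"] == pytest.approx(ec / 3, abs=1e-9)

    def test_residue_sums_conserve_total(self, toy):
        top = toy.topology
        lig = select(top, "ligand")
        traj = toy.trajectory[:3]
        dec = per_residue_decomposition(traj, lig, top)
        lig_set = set(lig)
        others = [a.index for a in top.atoms if a.index not in lig_set]
        ev = ec = 0.0
        for frame in traj:
            v, c = lj_coulomb_energy(frame, others, lig, top)
            ev += v
            ec += c
        assert sum(d["vdW"] for d in dec.values()) == \
            pytest.approx(ev / 3, abs=1e-6)
        assert sum(d["Coul"] for d in dec.values()) == \
            pytest.approx(ec / 3, abs=1e-6)

    def test_zero_charge_residue_has_zero_coulomb(self, toy):
        import copy

        top = copy.deepcopy(toy.topology)
        for i in top.residue_index[224]:
            top.atom(i).charge = 0.0
        lig = select(top, "ligand")
        dec = per_residue_decomposition(toy.trajectory[:2], lig, top,
                                        residue_ids=[224])
        assert dec[224]["Coul"] == pytest.approx(0.0, abs=1e-12)


class TestKiConversion:
    def test_weak_binder(self):
        assert ki_to_delta_g(50e-6) == pytest.approx(-25.52, abs=0.01)

    def test_strong_binder(self):
        assert ki_to_delta_g(0.53e-6) == pytest.approx(-37.24, abs=0.01)

    def test_unit_ki_is_zero(self):
        assert ki_to_delta_g(1.0) == 0.0

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            ki_to_delta_g(0.0)
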