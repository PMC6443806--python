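"""Coarse-grained folding model: topology, energetics, dynamics, WHAM."""

import numpy as np
import pytest

from swapfold import (CaTopology, IntegrationError, SimRun, ValidationError,
                      assign_charges, build_ca_topology,
                      compare_contact_probability, forces,
                      fraction_native_contacts, make_toy_structure,
                      potential_energy, run_langevin, toy_charged_hairpin,
                      ts_contact_probability, wham_free_energy)
from swapfold.sbm import ContactStats, FreeEnergyProfile


@pytest.fixture(scope="module")
def hairpin_top():
    st, h = toy_charged_hairpin()
    top = build_ca_topology(st)
    top.charges = assign_charges(top.sequence, False, h)
    return top


class TestContactMap:
    def test_matches_brute_force_all_atom_double_loop(self):
        st = make_toy_structure(14, "helix")
        top = build_ca_topology(st, cutoff=6.0, min_seq_sep=4)
        coords = st.coords[0]
        n_res = len(st.residue_numbers())
        res_of = np.repeat(np.arange(n_res), 4)  # N, CA, C, O per residue
        expected = set()
        for a in range(coords.shape[0]):
            for b in range(coords.shape[0]):
                i, j = res_of[a], res_of[b]
                if j - i >= 4 and np.linalg.norm(coords[a] - coords[b]) < 6.0:
                    expected.add((i, j))
        assert set(map(tuple, top.contacts)) == expected

    def test_sigma_is_native_ca_distance(self):
        st = make_toy_structure(14, "helix")
        top = build_ca_topology(st)
        ca = st.coords[0][st.ca_indices()]
        for (i, j), sig in zip(top.contacts, top.contact_sigma):
            assert sig == pytest.approx(np.linalg.norm(ca[i] - ca[j]))

    def test_sequence_separation_rule(self):
        st = make_toy_structure(14, "helix")
        top = build_ca_topology(st)
        assert np.all(top.contacts[:, 1] - top.contacts[:, 0] >= 4)

    def test_extended_chain_has_no_contacts(self):
        from swapfold.io import AtomRecord, StructureModel
        atoms, xyz = [], []
        for i in range(10):
            atoms.append(AtomRecord("CA", "C", "ALA", i + 1, "A"))
            xyz.append([8.0 * i, 0.0, 0.0])
        st = StructureModel(atoms=atoms, coords=np.array(xyz)[None])
        top = build_ca_topology(st)
        assert top.n_contacts == 0

    def test_json_round_trip(self, hairpin_top):
        back = CaTopology.from_json(hairpin_top.to_json())
        np.testing.assert_array_equal(back.contacts, hairpin_top.contacts)
        np.testing.assert_allclose(back.coords0, hairpin_top.coords0)
        np.testing.assert_allclose(back.charges, hairpin_top.charges)
        assert back.lambda_d == hairpin_top.lambda_d


class TestCharges:
    def test_rule_application(self):
        np.testing.assert_array_equal(assign_charges("DEKR"),
                                      [-1.0, -1.0, 1.0, 1.0])
        np.testing.assert_array_equal(assign_charges("GGGG"), np.zeros(4))

    def test_histidine_toggle_changes_one_entry(self):
        seq = "DEKAHAR"
        neutral = assign_charges(seq, False, 4)
        protonated = assign_charges(seq, True, 4)
        diff = np.nonzero(neutral != protonated)[0]
        np.testing.assert_array_equal(diff, [4])
        assert protonated[4] == 1.0

    def test_non_histidine_index_rejected(self):
        with pytest.raises(ValidationError):
            assign_charges("DEKR", True, 0)
        with pytest.raises(ValidationError):
            assign_charges("DEKR", True, 9)


class TestPotentialEnergy:
    def test_native_contact_minimum_is_minus_eps(self):
        """An isolated 12-10 contact at r = sigma contributes exactly
        -eps_C (5 - 6 = -1)."""
        top = CaTopology(
            coords0=np.array([[4.8 * i, 0, 0] for i in range(5)], dtype=float),
            sequence="AAAAA",
            contacts=np.array([[0, 4]]), contact_sigma=np.array([19.2]),
        )
        e, terms = potential_energy(top.coords0, top)
        assert terms["contact"] == pytest.approx(-1.0, abs=1e-12)

    def test_nonnative_repulsion_at_sigma(self):
        """Two non-native beads at r = sigma_NC contribute +eps_NC."""
        coords = np.array([[4.0 * i, 0, 0] for i in range(5)], dtype=float)
        top = CaTopology(coords0=coords, sequence="AAAAA",
                         contacts=np.empty((0, 2)), contact_sigma=np.empty(0))
        # place beads 0 and 4 at sigma_NC from each other, far from the rest
        x = coords.copy()
        x[4] = [0.0, 4.0, 50.0]
        x[0] = [0.0, 4.0, 54.0]
        e, terms = potential_energy(x, top)
        assert terms["non_native"] == pytest.approx(1.0, abs=1e-9)

    def test_debye_hueckel_printed_value(self):
        """Two +1 charges at r = lambda_D = 13.6 A with eps 80, B 1:
        V = 332 e^-1 / (80 * 13.6) = 0.112 in eps_C = 1 kcal/mol units."""
        coords = np.array([[3.4 * i, 0, 0] for i in range(5)], dtype=float)
        top = CaTopology(coords0=coords, sequence="KAAAK",
                         contacts=np.empty((0, 2)), contact_sigma=np.empty(0),
                         charges=assign_charges("KAAAK"), sigma_nc=0.1)
        e, terms = potential_energy(top.coords0, top)
        expected = 332.0 * np.exp(-1.0) / (80.0 * 13.6)
        assert terms["electrostatic"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.112, abs=5e-4)

    def test_overlap_guard(self, hairpin_top):
        x = hairpin_top.coords0.copy()
        x[5] = x[9] + 1e-4
        with pytest.raises(ValidationError, match="overlap"):
            potential_energy(x, hairpin_top)

    def test_force_matches_central_differences(self, hairpin_top):
        """Analytic forces agree with central differences of the energy
        to 1e-6 relative on a randomly perturbed configuration."""
        rng = np.random.default_rng(12)
        x = hairpin_top.coords0 + 0.3 * rng.standard_normal(
            hairpin_top.coords0.shape)
        f = forces(x, hairpin_top)
        h = 1e-5
        num = np.zeros_like(f)
        for i in range(x.shape[0]):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                num[i, d] = -(potential_energy(xp, hairpin_top)[0]
                              - potential_energy(xm, hairpin_top)[0]) / (2 * h)
        assert np.abs(f - num).max() / np.abs(f).max() < 1e-6


class TestDynamics:
    def test_same_seed_bitwise_identical(self, hairpin_top):
        a = run_langevin(hairpin_top, 1.0, 2000, seed=5, save_every=100)
        b = run_langevin(hairpin_top, 1.0, 2000, seed=5, save_every=100)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.energies, b.energies)

    def test_dissipative_descent_without_noise(self, hairpin_top):
        """With friction > 0 and the thermostat off (T = 0, zero initial
        velocities) the potential energy never rises above its starting
        value and decreases overall."""
        rng = np.random.default_rng(3)
        x0 = hairpin_top.coords0 + 0.4 * rng.standard_normal(
            hairpin_top.coords0.shape)
        run = run_langevin(hairpin_top, 0.0, 20000, friction=5.0, seed=1,
                           save_every=100, coords0=x0)
        assert np.all(run.energies <= run.energies[0] + 1e-9)
        assert run.energies[-1] < run.energies[0]

    def test_zero_friction_energy_conservation(self, hairpin_top):
        """Velocity-Verlet limit: total energy drift < 1e-4 eps over
        1e5 steps at dt = 0.0005."""
        run = run_langevin(hairpin_top, 0.5, 100000, friction=0.0, seed=2,
                           save_every=500)
        total = run.energies + 1.5 * hairpin_top.n_beads * run.kinetic_temps
        assert np.ptp(total) < 1e-4

    def test_equipartition_temperature(self, hairpin_top):
        run = run_langevin(hairpin_top, 0.8, 200000, friction=1.0, seed=4,
                           save_every=200)
        mean_t = run.kinetic_temps[run.frames_after_equilibration()].mean()
        assert abs(mean_t - 0.8) / 0.8 < 0.05

    def test_divergence_reports_step(self, hairpin_top):
        with pytest.raises(IntegrationError):
            run_langevin(hairpin_top, 1e8, 2000, seed=1, save_every=100)


class TestFractionNativeContacts:
    def test_native_is_one_and_rigid_motion_invariant(self, hairpin_top):
        assert fraction_native_contacts(hairpin_top.coords0, hairpin_top) == 1.0
        # arbitrary rotation + translation
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = hairpin_top.coords0 @ rot.T + np.array([5.0, -3.0, 11.0])
        assert fraction_native_contacts(moved, hairpin_top) == 1.0

    def test_expanded_coordinates_give_zero(self, hairpin_top):
        assert fraction_native_contacts(10.0 * hairpin_top.coords0,
                                        hairpin_top) == 0.0

    def test_constructed_half_formed_configuration(self):
        """Two contacts; one at its native distance, one stretched to
        1.3 sigma -> Q = 0.5."""
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0],
                           [11.4, 0, 0], [0.0, 4.0, 0], [3.8, 5.0, 0]],
                          dtype=float)
        top = CaTopology(coords0=coords, sequence="AAAAAA",
                         contacts=np.array([[0, 4], [1, 5]]),
                         contact_sigma=np.array([4.0, 5.0]))
        x = coords.copy()
        x[5] = [3.8, 6.5, 0.0]  # 1.3 * sigma for contact (1, 5)
        assert fraction_native_contacts(x, top) == 0.5


class TestWham:
    def test_single_run_equals_direct_histogram(self, hairpin_top):
        """With one run, WHAM at the run temperature reduces to
        -ln(histogram) up to an additive constant."""
        run = run_langevin(hairpin_top, 2.0, 100000, seed=8, save_every=100)
        prof = wham_free_energy([run], query_temps=[2.0], n_q_bins=13)
        idx = run.frames_after_equilibration(0.2)
        edges = np.linspace(0.0, 1.0 + 1e-9, 14)
        hist, _ = np.histogram(run.q[idx], bins=edges)
        mask = hist > 0
        direct = -np.log(hist[mask] / hist.sum())
        wham_f = prof.free_energy[2.0][mask]
        shift = (wham_f - direct).mean()
        np.testing.assert_allclose(wham_f - shift, direct, atol=1e-6)

    def test_disjoint_energy_ranges_rejected(self, hairpin_top):
        r1 = run_langevin(hairpin_top, 0.2, 20000, seed=1, save_every=100)
        r2 = run_langevin(hairpin_top, 5.0, 20000, seed=2, save_every=100)
        with pytest.raises(ValidationError, match="overlap"):
            wham_free_energy([r1, r2])

    def test_tf_between_bracketing_temperatures(self, hairpin_top):
        """Runs mostly folded at low T and mostly unfolded at high T give
        a T_F between the two."""
        lo = run_langevin(hairpin_top, 1.1, 200000, seed=3, save_every=100)
        hi = run_langevin(hairpin_top, 2.1, 200000, seed=4, save_every=100)
        prof = wham_free_energy([lo, hi], q_split=0.5)
        assert 1.1 <= prof.t_f <= 2.1


class TestContactStatistics:
    def test_native_basin_probabilities_high_at_low_temperature(
            self, hairpin_top):
        run = run_langevin(hairpin_top, 0.25, 60000, seed=6, save_every=50)
        profile = FreeEnergyProfile(
            q_centers=np.linspace(0, 1, 21), free_energy={},
            occupied=np.ones(21, bool), t_f=0.25, q_barrier=0.5,
            q_folded=0.95, q_unfolded=0.2)
        stats = ts_contact_probability(run, hairpin_top, profile,
                                       ensemble="native", min_frames=100)
        assert np.all(stats.probability >= 0.9)

    def test_extended_frames_give_zero(self, hairpin_top):
        frames = np.tile(10.0 * hairpin_top.coords0, (150, 1, 1))
        run = SimRun(steps=np.arange(150), energies=np.zeros(150),
                     q=np.zeros(150), kinetic_temps=np.zeros(150),
                     coords=frames, temperature=1.0, dt=5e-4, friction=1.0,
                     seed=0, n_steps=149)
        profile = FreeEnergyProfile(
            q_centers=np.linspace(0, 1, 21), free_energy={},
            occupied=np.ones(21, bool), t_f=1.0, q_barrier=0.5,
            q_folded=0.9, q_unfolded=0.1)
        stats = ts_contact_probability(run, hairpin_top, profile,
                                       ensemble="unfolded", min_frames=100,
                                       equilibration=0.0)
        assert np.all(stats.probability == 0.0)

    def test_too_small_ensemble_rejected(self, hairpin_top):
        run = run_langevin(hairpin_top, 0.8, 5000, seed=6, save_every=100)
        profile = FreeEnergyProfile(
            q_centers=np.linspace(0, 1, 21), free_energy={},
            occupied=np.ones(21, bool), t_f=0.8, q_barrier=0.5,
            q_folded=0.95, q_unfolded=0.2)
        with pytest.raises(ValidationError, match="frames"):
            ts_contact_probability(run, hairpin_top, profile, ensemble="ts")

    def test_comparison_thresholding(self, hairpin_top):
        nc = hairpin_top.n_contacts
        p = np.full(nc, 0.5)
        a = ContactStats(hairpin_top.contacts, p.copy(), "ts", 500)
        assert compare_contact_probability(a, a) == []
        q = p.copy()
        q[3] += 0.15
        b = ContactStats(hairpin_top.contacts, q, "ts", 500)
        hits = compare_contact_probability(b, a, threshold=0.10)
        assert len(hits) == 1
        i, j, dp = hits[0]
        assert (i, j) == tuple(hairpin_top.contacts[3])
        assert dp == pytest.approx(0.15)
        everything = compare_contact_probability(b, a, threshold=0.0)
        assert len(everything) == nc
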