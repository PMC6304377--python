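"""Pair energetics, association criteria, contact maps, profiles, surfaces."""

import numpy as np
import pytest

from helixmodes import energetics as en
from helixmodes.structure_io import ChainTopology, Frame, Residue, Trajectory


def _toy_frame(coords_a, coords_b, bead="C", charge_a=0.0, charge_b=0.0, box=(10.0, 10.0, 10.0)):
    na, nb = len(coords_a), len(coords_b)
    topo_a = ChainTopology("A", [Residue(i + 1, "LEU", bead, charge_a) for i in range(na)])
    topo_b = ChainTopology("B", [Residue(i + 1, "LEU", bead, charge_b) for i in range(nb)])
    frame = Frame(
        np.vstack([coords_a, coords_b]), np.asarray(box), np.repeat([0, 1], [na, nb])
    )
    return frame, [topo_a, topo_b]


def _brute_force_energy(frame, topologies, model):
    """Independent double-loop reference with explicit minimum image."""
    ga = np.flatnonzero(frame.chain_index == 0)
    gb = np.flatnonzero(frame.chain_index == 1)
    types = []
    charges = []
    for topo in topologies:
        for r in topo.residues:
            types.append(r.bead_type)
            charges.append(r.charge)
    total = 0.0
    for i in ga:
        for j in gb:
            d = frame.coordinates[i] - frame.coordinates[j]
            d -= frame.box * np.round(d / frame.box)
            r = float(np.linalg.norm(d))
            eps = np.sqrt(
                model.beads[types[i]]["epsilon"] * model.beads[types[j]]["epsilon"]
            )
            sig = 0.5 * (model.beads[types[i]]["sigma"] + model.beads[types[j]]["sigma"])
            if r < model.r_cut:
                x = np.clip((r - model.r_switch) / (model.r_cut - model.r_switch), 0, 1)
                s = 1 - x**3 * (x * (6 * x - 15) + 10)
                sr6 = (sig / r) ** 6
                total += 4 * eps * (sr6**2 - sr6) * s
            if r < model.coulomb_cutoff and charges[i] * charges[j] != 0:
                x = np.clip(r / model.coulomb_cutoff, 0, 1)
                s = 1 - x**3 * (x * (6 * x - 15) + 10)
                total += (
                    en.COULOMB_CONSTANT
                    * charges[i]
                    * charges[j]
                    / (model.relative_dielectric * r)
                    * s
                )
    return total


class TestPairEnergy:
    def test_beads_beyond_cutoff_contribute_nothing(self, energy_model):
        frame, topos = _toy_frame([[0.0, 0, 0]], [[1.3, 0, 0]])
        assert en.pair_energy(frame, [0], [1], topos, energy_model) == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        model = en.EnergyModel(
            beads={"C": {"epsilon": 3.5, "sigma": 0.47, "radius": 0.23}}
        )
        r_min = 2 ** (1 / 6) * 0.47  # inside the unswitched region
        frame, topos = _toy_frame([[0.0, 0, 0]], [[r_min, 0, 0]])
        e = en.pair_energy(frame, [0], [1], topos, model)
        assert e == pytest.approx(-3.5, rel=1e-12)

    def test_matches_brute_force_double_loop(self, energy_model):
        rng = np.random.default_rng(0)
        frame, topos = _toy_frame(
            rng.uniform(0, 3, (7, 3)), rng.uniform(0, 3, (5, 3))
        )
        # add charges on chain B
        topos[1] = ChainTopology(
            "B", [Residue(i + 1, "LYS", "Q", 1.0) for i in range(5)]
        )
        fast = en.pair_energy(frame, np.arange(7), np.arange(7, 12), topos, energy_model)
        slow = _brute_force_energy(frame, topos, energy_model)
        assert fast == pytest.approx(slow, rel=1e-9)

    def test_symmetric_in_group_order_and_rigid_invariant(self, energy_model):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        frame, topos = _toy_frame(rng.uniform(4, 6, (6, 3)), rng.uniform(4, 6, (4, 3)))
        ga, gb = np.arange(6), np.arange(6, 10)
        e_ab = en.pair_energy(frame, ga, gb, topos, energy_model)
        e_ba = en.pair_energy(frame, gb, ga, topos, energy_model)
        assert e_ab == pytest.approx(e_ba, rel=1e-12)
        rot = Rotation.from_euler("z", 73, degrees=True)
        moved = Frame(
            rot.apply(frame.coordinates - 5.0) + 5.0 + [0.3, -0.2, 0.1],
            frame.box,
            frame.chain_index,
        )
        assert en.pair_energy(moved, ga, gb, topos, energy_model) == pytest.approx(
            e_ab, rel=1e-9
        )

    def test_energy_and_force_continuous_across_switch_boundaries(self, energy_model):
        def e(r):
            frame, topos = _toy_frame([[0.0, 0, 0]], [[r, 0, 0]])
            return en.pair_energy(frame, [0], [1], topos, energy_model)

        h = 1e-7
        for r0 in (energy_model.r_switch, energy_model.r_cut):
            assert e(r0 + h) - e(r0 - h) == pytest.approx(0.0, abs=1e-5)
            f_below = (e(r0) - e(r0 - h)) / h
            f_above = (e(r0 + h) - e(r0)) / h
            assert f_below == pytest.approx(f_above, abs=1e-3)

    def test_unknown_bead_type_rejected(self, energy_model):
        frame, topos = _toy_frame([[0.0, 0, 0]], [[1.0, 0, 0]], bead="Z")
        with pytest.raises(KeyError, match="Z"):
            en.pair_energy(frame, [0], [1], topos, energy_model)

    def test_overlapping_groups_rejected(self, energy_model):
        frame, topos = _toy_frame([[0.0, 0, 0]], [[1.0, 0, 0]])
        with pytest.raises(ValueError, match="disjoint"):
            en.pair_energy(frame, [0, 1], [1], topos, energy_model)


class TestAssociationCriteria:
    @pytest.mark.parametrize(
        "energy,expected",
        [(-250.0, True), (-200.0, True), (-199.99, False), (0.0, False)],
    )
    def test_dimer_threshold_with_boundary_bound(self, energy, expected):
        assert en.is_dimer(energy) is expected

    @pytest.mark.parametrize(
        "energy,bsa,expected",
        [
            (-850.0, 0.09, False),  # compact enough energy, too small interface
            (-850.0, 0.10, False),  # boundary BSA is excluded (strict >)
            (-850.0, 0.101, True),
            (-800.0, 0.2, True),  # boundary energy counts as bound
            (-799.0, 0.2, False),
            (-250.0, 0.5, False),
        ],
    )
    def test_oligomer_needs_energy_and_strict_bsa(self, energy, bsa, expected):
        assert en.is_oligomer(energy, bsa) is expected

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError):
            en.is_dimer(float("nan"))
        with pytest.raises(ValueError):
            en.is_oligomer(-900.0, 1.5)


class TestContactMap:
    def test_hand_placed_two_by_two_map(self):
        coords_a = [[0.0, 0, 0], [0.0, 0, 1.0]]
        coords_b = [[0.5, 0, 0], [0.0, 0.8, 0], [0.0, 0, 2.0], [1.3, 0, 1.0]]
        # residues: A1, A2 vs B1..B4; reduce to 2x2 by keeping first two of B
        frame, topos = _toy_frame(coords_a, [[0.5, 0, 0], [0.0, 0, 2.3]])
        traj = Trajectory([frame], topos)
        cmap = en.contact_map(traj, 0, 1)
        assert cmap.values.shape == (2, 2)
        assert cmap.values.iloc[0, 0] == pytest.approx(0.5)
        assert cmap.values.iloc[0, 1] == pytest.approx(2.3)
        assert cmap.values.iloc[1, 0] == pytest.approx(np.sqrt(0.5**2 + 1.0**2))
        assert cmap.values.iloc[1, 1] == pytest.approx(1.3)

    def test_duplicate_frames_average_to_single_frame_map(self, mu_pair_frame):
        frame, topos = mu_pair_frame
        f2 = Frame(frame.coordinates, frame.box, frame.chain_index, time=1.0)
        one = en.contact_map(Trajectory([frame], topos), 0, 1)
        two = en.contact_map(
            Trajectory([frame, f2], topos), 0, 1
        )
        assert np.allclose(one.values.values, two.values.values)

    def test_matches_brute_force_over_seeded_window(self, energy_model):
        rng = np.random.default_rng(4)
        frames = []
        topos = None
        for t in range(10):
            frame, topos = _toy_frame(
                rng.uniform(0, 4, (5, 3)), rng.uniform(0, 4, (6, 3))
            )
            frame.time = float(t)
            frames.append(frame)
        traj = Trajectory(frames, topos)
        cmap = en.contact_map(traj, 0, 1).values.values
        expected = np.zeros((5, 6))
        for f in frames:
            for i in range(5):
                for j in range(6):
                    d = f.coordinates[i] - f.coordinates[5 + j]
                    d -= f.box * np.round(d / f.box)
                    expected[i, j] += np.linalg.norm(d)
        expected /= len(frames)
        assert np.abs(cmap - expected).max() < 1e-12


class TestEnergyProfile:
    def test_symmetric_dimer_has_symmetric_profile(self, mu_helix, energy_model):
        # exact C2 dimer: chain B is chain A rotated 180 deg about the
        # vertical axis through the dimer midpoint
        from helixmodes.synthetic import MIGM_TMD_SEQUENCE, build_ideal_helix

        frame_a, topo_a = mu_helix
        _, topo_b = build_ideal_helix(
            MIGM_TMD_SEQUENCE, chain_id="B", first_residue=topo_a.residues[0].number
        )
        mid = frame_a.coordinates.mean(axis=0) + [0.475, 0.0, 0.0]
        cb = frame_a.coordinates.copy()
        cb[:, 0] = 2 * mid[0] - cb[:, 0]
        cb[:, 1] = 2 * mid[1] - cb[:, 1]
        frame = Frame(
            np.vstack([frame_a.coordinates, cb]),
            frame_a.box,
            np.repeat([0, 1], 32),
        )
        topos = [topo_a, topo_b]
        traj = Trajectory([frame], topos)
        profile = en.residue_energy_profile(traj, 0, 1, energy_model)
        a = profile.relative.iloc[:32].values
        b = profile.relative.iloc[32:].values
        assert np.abs(a - b).max() < 1e-9
        assert profile.relative.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_interacting_pair_carries_everything(self, energy_model):
        coords_a = [[0.0, 0, 0], [0.0, 0, 3.0]]
        coords_b = [[0.6, 0, 0], [0.6, 0, 6.0]]
        frame, topos = _toy_frame(coords_a, coords_b)
        traj = Trajectory([frame], topos)
        profile = en.residue_energy_profile(traj, 0, 1, energy_model)
        contributing = profile.relative[profile.relative > 0]
        assert set(contributing.index) == {"A:LEU1", "B:LEU1"}
        assert contributing.sum() == pytest.approx(1.0, abs=1e-12)

    def test_per_residue_energies_match_brute_force_regrouping(self, energy_model):
        rng = np.random.default_rng(9)
        frame, topos = _toy_frame(rng.uniform(4, 6, (6, 3)), rng.uniform(4, 6, (6, 3)))
        traj = Trajectory([frame], topos)
        profile = en.residue_energy_profile(traj, 0, 1, energy_model)
        em = en.pair_energy_matrix(frame, np.arange(6), np.arange(6, 12), topos, energy_model)
        expected_a = em.sum(axis=1)
        assert np.abs(profile.raw.iloc[:6].values - expected_a).max() < 1e-9

    def test_no_attraction_is_an_error(self, energy_model):
        frame, topos = _toy_frame([[0.0, 0, 0]], [[5.0, 0, 0]])
        with pytest.raises(ValueError, match="profile"):
            en.residue_energy_profile(Trajectory([frame], topos), 0, 1, energy_model)


class TestSaltBridges:
    def _charged_frame(self):
        # Ig-alpha/Ig-beta terminal salt-bridge partners placed by hand:
        # K167-D184 and R168-D185 in contact, E138-R154 in contact,
        # K158 far from everything
        topo_a = ChainTopology(
            "Iga",
            [
                Residue(138, "GLU", "Q", -1.0),
                Residue(167, "LYS", "Q", 1.0),
                Residue(168, "ARG", "Q", 1.0),
            ],
        )
        topo_b = ChainTopology(
            "Igb",
            [
                Residue(154, "ARG", "Q", 1.0),
                Residue(158, "LYS", "Q", 1.0),
                Residue(184, "ASP", "Q", -1.0),
                Residue(185, "ASP", "Q", -1.0),
            ],
        )
        coords = np.array(
            [
                [0.0, 0.0, 0.0],  # E138
                [3.0, 0.0, 0.0],  # K167
                [3.0, 1.5, 0.0],  # R168
                [0.5, 0.0, 0.0],  # R154 (0.5 from E138)
                [7.0, 7.0, 0.0],  # K158 (far)
                [3.5, 0.0, 0.0],  # D184 (0.5 from K167)
                [3.0, 2.0, 0.0],  # D185 (0.5 from R168)
            ]
        )
        frame = Frame(coords, np.array([20.0, 20.0, 20.0]), np.repeat([0, 1], [3, 4]))
        return frame, [topo_a, topo_b]

    def test_constructed_partner_pairs_recovered_exactly(self):
        frame, topos = self._charged_frame()
        bridges = en.detect_salt_bridges(frame, 0, 1, topos)
        pairs = {(a, b) for a, b, _ in bridges}
        assert pairs == {
            ("Iga:GLU138", "Igb:ARG154"),
            ("Iga:LYS167", "Igb:ASP184"),
            ("Iga:ARG168", "Igb:ASP185"),
        }

    def test_like_charges_never_bridge(self):
        topo_a = ChainTopology("A", [Residue(1, "LYS", "Q", 1.0)])
        topo_b = ChainTopology("B", [Residue(1, "LYS", "Q", 1.0)])
        frame = Frame(
            np.array([[0.0, 0, 0], [0.5, 0, 0]]), np.array([10.0, 10, 10]), np.array([0, 1])
        )
        assert en.detect_salt_bridges(frame, 0, 1, [topo_a, topo_b]) == []


class TestSurfaces:
    def test_single_bead_sasa_matches_sphere_area(self):
        area = en.sasa(np.array([[0.0, 0, 0]]), np.array([0.23]), 0.19)
        exact = 4 * np.pi * (0.23 + 0.19) ** 2
        assert area == pytest.approx(exact, rel=0.01)
        assert exact == pytest.approx(2.2167, abs=1e-3)

    def test_separated_groups_have_zero_bsa(self, energy_model):
        frame, topos = _toy_frame([[0.0, 0, 0]], [[3.0, 0, 0]], box=(20, 20, 20))
        bsa, frac, _ = en.buried_surface_area(frame, [0], [1], topos, energy_model)
        assert bsa == 0.0
        assert frac == 0.0

    def test_two_sphere_bsa_matches_cap_formula(self, energy_model):
        radius = energy_model.beads["C"]["radius"]
        extended = radius + 0.19
        for d in np.linspace(0.2, 2 * extended * 0.95, 8):
            frame, topos = _toy_frame([[0.0, 0, 0]], [[d, 0, 0]], box=(20, 20, 20))
            bsa, _, _ = en.buried_surface_area(frame, [0], [1], topos, energy_model)
            h = extended - d / 2
            exact = 2 * (2 * np.pi * extended * h)
            assert bsa == pytest.approx(exact, rel=0.02)

    def test_bsa_nonincreasing_as_groups_separate(self, energy_model):
        rng = np.random.default_rng(2)
        cluster = rng.uniform(0, 0.5, (4, 3))
        prev = np.inf
        for d in (0.3, 0.6, 0.9, 1.2):
            frame, topos = _toy_frame(cluster, cluster + [d, 0, 0], box=(20, 20, 20))
            bsa, _, _ = en.buried_surface_area(
                frame, np.arange(4), np.arange(4, 8), topos, energy_model
            )
            assert bsa <= prev + 1e-9
            prev = bsa

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            en.sasa(np.zeros((1, 3)), np.array([-0.1]), 0.19)
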