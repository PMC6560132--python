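import numpy as np
import pytest

from bindprof.contacts import (
    HBOND_DIRECT,
    HBOND_WATER,
    HYDROPHOBIC,
    HBondParams,
    HydrophobicParams,
    compute_frame_contacts,
    find_hbonds,
    find_hydrophobic_contacts,
    find_water_bridges,
    typed_polar_atoms,
)
from bindprof.errors import ConfigError, TopologyError
from bindprof.structure_io import Frame
from bindprof.synthetic import ToySystemSpec, build_toy_complex

from conftest import make_topology
from oracles import (
    brute_direct_hbond_residues,
    brute_min_cc_distances,
    brute_water_bridge_residues,
    scramble_residues,
)


class TestPolarTyping:
    def test_hydroxyl_is_donor_and_acceptor(self, minimal_pair):
        top, _ = minimal_pair((0, 0, 0), (0.96, 0, 0), (2.9, 0, 0))
        typing = typed_polar_atoms(top)
        assert (0, 1) in typing.donors  # OG paired with its HG
        assert 0 in typing.acceptors

    def test_carbonyl_like_oxygen_acceptor_only(self, minimal_pair):
        top, _ = minimal_pair((0, 0, 0), (0.96, 0, 0), (2.9, 0, 0))
        typing = typed_polar_atoms(top)
        assert 2 in typing.acceptors  # ligand O1, no bonded H
        assert all(d != 2 for d, _ in typing.donors)

    def test_water_donates_twice(self):
        top, _ = make_topology(
            [
                ("O", "O", "HOH", 1, "W", (0, 0, 0)),
                ("H1", "H", "HOH", 1, "W", (0.96, 0, 0)),
                ("H2", "H", "HOH", 1, "W", (-0.24, 0.93, 0)),
                ("C1", "C", "LIG", 1, "L", (8, 0, 0)),
            ]
        )
        typing = typed_polar_atoms(top)
        assert sum(1 for d, _ in typing.donors if d == 0) == 2

    def test_no_hydrogens_is_an_error(self):
        top, _ = make_topology(
            [
                ("O1", "O", "LIG", 1, "L", (0, 0, 0)),
                ("C1", "C", "LIG", 1, "L", (1.4, 0, 0)),
            ]
        )
        with pytest.raises(TopologyError, match="explicit hydrogens"):
            typed_polar_atoms(top)


class TestDirectHBonds:
    @pytest.mark.parametrize(
        "acceptor_pos, hydrogen_pos, expected",
        [
            ((2.9, 0.0, 0.0), (1.0, 0.0, 0.0), True),  # collinear, 2.9 Å
            ((3.6, 0.0, 0.0), (1.0, 0.0, 0.0), False),  # distance fail
            ((3.5, 0.0, 0.0), (1.0, 0.0, 0.0), True),  # boundary distance
            # D-H-A = 140 deg (deviation 40 > 30), still 2.9 Å away
            (
                tuple(
                    np.array([1.0, 0, 0])
                    + 2.2 * np.array([np.cos(np.radians(40)), np.sin(np.radians(40)), 0])
                ),
                (1.0, 0.0, 0.0),
                False,
            ),
            # D-H-A exactly 150 deg: boundary angle counts as bonded
            (
                tuple(
                    np.array([1.0, 0, 0])
                    + 2.0 * np.array([np.cos(np.radians(30)), np.sin(np.radians(30)), 0])
                ),
                (1.0, 0.0, 0.0),
                True,
            ),
        ],
        ids=["collinear", "too_far", "boundary_distance", "angle_fail", "boundary_angle"],
    )
    def test_geometric_criteria(self, minimal_pair, acceptor_pos, hydrogen_pos, expected):
        top, frame0 = minimal_pair((0, 0, 0), hydrogen_pos, acceptor_pos)
        typing = typed_polar_atoms(top)
        events = find_hbonds(frame0, top, typing)
        assert bool(events) is expected
        if events:
            assert events[0].kind == HBOND_DIRECT
            assert events[0].residue == ("A", 1)

    def test_rotation_translation_invariance(self, minimal_pair):
        from scipy.spatial.transform import Rotation

        top, frame0 = minimal_pair((0, 0, 0), (1.0, 0, 0), (2.9, 0, 0))
        typing = typed_polar_atoms(top)
        rot = Rotation.from_euler("xyz", [31, -57, 113], degrees=True)
        moved = Frame(0, 0.0, rot.apply(frame0.coords) + np.array([5.0, -3.0, 2.0]))
        before = {(e.kind, e.residue) for e in find_hbonds(frame0, top, typing)}
        after = {(e.kind, e.residue) for e in find_hbonds(moved, top, typing)}
        assert before == after != set()

    def test_matches_bruteforce_on_scrambled_toys(self):
        top, frame0 = build_toy_complex(
            ToySystemSpec(polar_top_residues=10, hydrophobic_bottom_residues=6,
                          n_waters=8),
            seed=4,
        )
        typing = typed_polar_atoms(top)
        rng = np.random.default_rng(11)
        for _ in range(20):
            frame = Frame(0, 0.0, scramble_residues(top, frame0, rng))
            got = {e.residue for e in find_hbonds(frame, top, typing)}
            assert got == brute_direct_hbond_residues(frame.coords, top, typing)

    def test_monotone_in_cutoffs(self):
        top, frame0 = build_toy_complex(
            ToySystemSpec(polar_top_residues=8, hydrophobic_bottom_residues=4),
            seed=7,
        )
        typing = typed_polar_atoms(top)
        rng = np.random.default_rng(3)
        frame = Frame(0, 0.0, scramble_residues(top, frame0, rng, amplitude=8.0))
        tight = {
            (e.residue, e.partner_atoms)
            for e in find_hbonds(frame, top, typing, HBondParams(3.0, 20.0))
        }
        loose = {
            (e.residue, e.partner_atoms)
            for e in find_hbonds(frame, top, typing, HBondParams(3.5, 30.0))
        }
        assert tight <= loose


class TestWaterBridges:
    def _bridged_system(self, water_x=4.0):
        # receptor OG ... water ... ligand O1, collinear chain along x
        return make_topology(
            [
                ("OG", "O", "SER", 262, "A", (water_x + 2.9, 0, 0)),
                ("HG", "H", "SER", 262, "A", (water_x + 1.94, 0, 0)),
                ("O", "O", "HOH", 1, "W", (water_x, 0, 0)),
                ("H1", "H", "HOH", 1, "W", (water_x - 0.96, 0, 0)),
                ("H2", "H", "HOH", 1, "W", (water_x + 0.24, 0.93, 0)),
                ("O3", "O", "LIG", 1, "L", (water_x - 2.8, 0, 0)),
                ("C3", "C", "LIG", 1, "L", (water_x - 2.8, 1.4, 0)),
            ]
        )

    def test_bridge_detected_and_water_recorded(self):
        top, frame0 = self._bridged_system()
        typing = typed_polar_atoms(top)
        events = find_water_bridges(frame0, top, typing)
        assert len(events) == 1
        assert events[0].kind == HBOND_WATER
        assert events[0].residue == ("A", 262)
        assert events[0].water_index == 1

    def test_water_bound_to_ligand_only_is_no_bridge(self):
        top, frame0 = self._bridged_system()
        coords = frame0.coords.copy()
        coords[0] += np.array([10.0, 0, 0])  # pull the receptor hydroxyl away
        coords[1] += np.array([10.0, 0, 0])
        typing = typed_polar_atoms(top)
        assert find_water_bridges(Frame(0, 0.0, coords), top, typing) == []

    def test_two_waters_collapse_to_one_presence(self):
        # two independent collinear bridges (along x and along y) between the
        # same residue's hydroxyls and the same ligand oxygen
        top, frame0 = make_topology(
            [
                ("OG1", "O", "SER", 262, "A", (5.7, 0, 0)),
                ("HG1", "H", "SER", 262, "A", (4.74, 0, 0)),
                ("OG2", "O", "SER", 262, "A", (0, 5.7, 0)),
                ("HG2", "H", "SER", 262, "A", (0, 4.74, 0)),
                ("O", "O", "HOH", 1, "W", (2.8, 0, 0)),
                ("H1", "H", "HOH", 1, "W", (1.84, 0, 0)),
                ("H2", "H", "HOH", 1, "W", (3.04, 0.93, 0)),
                ("O", "O", "HOH", 2, "W", (0, 2.8, 0)),
                ("H1", "H", "HOH", 2, "W", (0, 1.84, 0)),
                ("H2", "H", "HOH", 2, "W", (0.93, 3.04, 0)),
                ("O3", "O", "LIG", 1, "L", (0, 0, 0)),
                ("C3", "C", "LIG", 1, "L", (-1.0, -1.0, 0)),
            ]
        )
        typing = typed_polar_atoms(top)
        events = find_water_bridges(frame0, top, typing)
        assert {e.water_index for e in events} == {1, 2}
        fc = compute_frame_contacts(frame0, top, typing)
        water_events = [e for e in fc.events if e.kind == HBOND_WATER]
        assert len(water_events) == 1  # collapsed per (kind, residue)
        assert water_events[0].residue == ("A", 262)

    def test_empty_water_group_yields_empty_list(self, minimal_pair):
        top, frame0 = minimal_pair((0, 0, 0), (0.96, 0, 0), (2.9, 0, 0))
        typing = typed_polar_atoms(top)
        assert find_water_bridges(frame0, top, typing) == []

    def test_matches_bruteforce_on_scrambled_toys(self):
        top, frame0 = build_toy_complex(
            ToySystemSpec(polar_top_residues=8, hydrophobic_bottom_residues=4,
                          n_waters=12),
            seed=5,
        )
        typing = typed_polar_atoms(top)
        rng = np.random.default_rng(21)
        for _ in range(15):
            frame = Frame(0, 0.0, scramble_residues(top, frame0, rng, amplitude=9.0))
            got = {
                (e.residue, ("W", e.water_index))
                for e in find_water_bridges(frame, top, typing)
            }
            assert got == brute_water_bridge_residues(frame.coords, top, typing)


class TestHydrophobic:
    @pytest.mark.parametrize(
        "distance, expected",
        [(5.4, True), (5.5, True), (5.6, False)],
        ids=["inside", "boundary", "outside"],
    )
    def test_minimum_distance_criterion(self, distance, expected):
        top, frame0 = make_topology(
            [
                ("CB", "C", "LEU", 93, "A", (distance, 0, 0)),
                ("C7", "C", "LIG", 1, "L", (0, 0, 0)),
            ]
        )
        events = find_hydrophobic_contacts(frame0, top)
        assert bool(events) is expected
        if events:
            assert events[0].kind == HYDROPHOBIC
            assert events[0].distance == pytest.approx(distance)

    def test_ligand_without_carbons_is_config_error(self):
        top, frame0 = make_topology(
            [
                ("CB", "C", "LEU", 1, "A", (4, 0, 0)),
                ("O1", "O", "LIG", 1, "L", (0, 0, 0)),
            ]
        )
        with pytest.raises(ConfigError, match="no carbon"):
            find_hydrophobic_contacts(frame0, top)

    def test_per_residue_minimum_matches_bruteforce(self):
        top, frame0 = build_toy_complex(
            ToySystemSpec(polar_top_residues=6, hydrophobic_bottom_residues=24),
            seed=9,
        )
        rng = np.random.default_rng(13)
        for _ in range(10):
            frame = Frame(0, 0.0, scramble_residues(top, frame0, rng, amplitude=7.0))
            events = find_hydrophobic_contacts(frame, top)
            mins = brute_min_cc_distances(frame.coords, top)
            expected = {r for r, d in mins.items() if d <= 5.5}
            assert {e.residue for e in events} == expected
            for e in events:
                assert e.distance == pytest.approx(mins[e.residue])
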