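"""Scoring function: piecewise angular scales, energy formula, detection."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrobridge.energy import (
    GeometryProbe,
    HBondParams,
    bond_energy,
    detect_hbonds,
    scale_dha,
    scale_hax,
)
from hydrobridge.model import Atom, Frame, Topology, classify_polar_roles
from hydrobridge.synthetic import make_geometry_probe_system

from conftest import brute_force_detect, brute_force_energies, random_small_system

PARAMS = HBondParams()


class TestAngularScales:
    @pytest.mark.parametrize(
        "angle, expected",
        [(180.0, 1.0), (165.0, 1.0), (100.0, 0.0), (50.0, 0.0), (132.5, 0.5)],
    )
    def test_dha_values(self, angle, expected):
        assert scale_dha(angle, PARAMS) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "angle, x_is_h, expected",
        [
            (95.0, False, 1.0),
            (85.0, False, 0.0),
            (90.0, False, 0.5),
            (85.0, True, 1.0),
            (75.0, True, 0.0),
            (80.0, True, 0.5),
        ],
    )
    def test_hax_values(self, angle, x_is_h, expected):
        assert scale_hax(angle, x_is_h, PARAMS) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("angle", [-1.0, 180.5, 361.0])
    def test_domain_error(self, angle):
        with pytest.raises(ValueError, match="outside"):
            scale_dha(angle, PARAMS)
        with pytest.raises(ValueError, match="outside"):
            scale_hax(angle, False, PARAMS)

    @given(angle=st.floats(0.0, 180.0))
    @settings(derandomize=True, max_examples=200)
    def test_scales_bounded(self, angle):
        for s in (
            scale_dha(angle, PARAMS),
            scale_hax(angle, True, PARAMS),
            scale_hax(angle, False, PARAMS),
        ):
            assert 0.0 <= s <= 1.0

    @given(a=st.floats(0.0, 180.0), b=st.floats(0.0, 180.0))
    @settings(derandomize=True, max_examples=200)
    def test_scales_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert scale_dha(lo, PARAMS) <= scale_dha(hi, PARAMS)
        assert scale_hax(lo, True, PARAMS) <= scale_hax(hi, True, PARAMS)
        assert scale_hax(lo, False, PARAMS) <= scale_hax(hi, False, PARAMS)


class TestBondEnergy:
    @pytest.mark.parametrize(
        "dist, expected",
        [(2.0, 25.0), (1.5, 25.0), (2.1, 25.0), (2.35, 12.5), (2.6, 0.0)],
    )
    def test_distance_term(self, dist, expected):
        probe = GeometryProbe(dist, 180.0, 180.0, False)
        assert bond_energy(probe, PARAMS) == pytest.approx(expected, abs=1e-12)

    def test_hydrogen_x_allows_smaller_angles(self):
        heavy = bond_energy(GeometryProbe(2.0, 180.0, 80.0, False), PARAMS)
        hydrogen = bond_energy(GeometryProbe(2.0, 180.0, 80.0, True), PARAMS)
        assert heavy == 0.0
        assert hydrogen == pytest.approx(12.5)

    def test_never_exceeds_optimum_and_monotone_in_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            dists = np.sort(rng.uniform(0.5, 3.0, size=2))
            dha = rng.uniform(0, 180)
            hax = rng.uniform(0, 180)
            e_near = bond_energy(GeometryProbe(dists[0], dha, hax, False), PARAMS)
            e_far = bond_energy(GeometryProbe(dists[1], dha, hax, False), PARAMS)
            assert e_near <= PARAMS.optimum_energy + 1e-12
            assert e_near >= e_far

    def test_nonpositive_beyond_zero_distance(self):
        assert bond_energy(GeometryProbe(3.0, 180.0, 180.0, False), PARAMS) <= 0.0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            HBondParams(d_clamp=2.6, d_zero=2.1)
        with pytest.raises(ValueError):
            HBondParams(threshold_energy=30.0)
        with pytest.raises(ValueError):
            HBondParams(dha_ramp=(165.0, 100.0))


def _water_dimer():
    """Ideal linear water dimer: exactly one donor contact at optimum."""

    def water(origin, h1_dir, h2_dir, resid):
        o = np.asarray(origin, dtype=float)
        return [o, o + 0.9572 * np.asarray(h1_dir), o + 0.9572 * np.asarray(h2_dir)]

    c, s = np.cos(np.radians(104.52)), np.sin(np.radians(104.52))
    donor = water([0, 0, 0], [1, 0, 0], [c, s, 0], 1)
    cos60, sin60 = 0.5, np.sqrt(3) / 2
    acceptor = water([2.8572, 0, 0], [cos60, sin60, 0], [cos60, -sin60, 0], 2)
    coords = np.array(donor + acceptor)
    atoms = []
    for r in range(2):
        for k, (el, name) in enumerate([("O", "O"), ("H", "H1"), ("H", "H2")]):
            i = 3 * r + k
            atoms.append(Atom(i, el, name, "HOH", r + 1, "W", i + 1))
    topology = Topology(
        atoms=atoms, covalent_adjacency={(0, 1), (0, 2), (3, 4), (3, 5)}
    )
    return topology, Frame(time=0.0, coords=coords)


class TestDetection:
    def test_water_dimer_single_bond_at_optimum(self):
        topology, frame = _water_dimer()
        roles = classify_polar_roles(topology)
        bonds = detect_hbonds(topology, frame, roles)
        assert len(bonds) == 1
        bond = bonds[0]
        assert (bond.donor_heavy, bond.hydrogen, bond.acceptor) == (0, 1, 3)
        assert bond.energy == pytest.approx(25.0, abs=1e-9)
        assert brute_force_detect(topology, frame, roles) == {(0, 1, 3)}

    def test_everything_beyond_horizon_is_empty(self):
        atoms = [
            Atom(0, "O", "O1", "RES", 1, "A", 1),
            Atom(1, "H", "H1", "RES", 1, "A", 2),
            Atom(2, "O", "O2", "RES", 2, "B", 3),
        ]
        coords = np.array([[0, 0, 0], [0.96, 0, 0], [4.0, 0, 0]])
        topology = Topology(atoms=atoms, covalent_adjacency={(0, 1)})
        roles = classify_polar_roles(topology)
        assert detect_hbonds(topology, Frame(time=0.0, coords=coords), roles) == []

    def test_energy_equal_to_threshold_not_reported(self):
        topology, frame = make_geometry_probe_system(
            GeometryProbe(2.35, 180.0, 180.0, False)
        )
        roles = classify_polar_roles(topology)
        energy = detect_hbonds(topology, frame, roles)[0].energy
        at_threshold = replace(PARAMS, threshold_energy=energy)
        assert detect_hbonds(topology, frame, roles, at_threshold) == []

    def test_strongest_per_acceptor_toggle(self):
        # second donor water approaches the acceptor oxygen from above
        # (perpendicular to both acceptor hydrogens) at a longer distance,
        # so the acceptor carries two bonds of different energies
        topology, frame = _water_dimer()
        coords = frame.coords.copy()
        extra = np.array(
            [
                [2.8572, 0.0, 3.3],  # O of second donor
                [2.8572, 0.0, 2.3],  # H pointing straight down at acceptor O
                [2.8572 + 0.24, 0.0, 4.227],
            ]
        )
        atoms = list(topology.atoms) + [
            Atom(6, "O", "O", "HOH", 3, "W", 7),
            Atom(7, "H", "H1", "HOH", 3, "W", 8),
            Atom(8, "H", "H2", "HOH", 3, "W", 9),
        ]
        topo2 = Topology(
            atoms=atoms,
            covalent_adjacency=topology.covalent_adjacency | {(6, 7), (6, 8)},
        )
        frame2 = Frame(time=0.0, coords=np.vstack([coords, extra]))
        roles = classify_polar_roles(topo2)
        all_bonds = detect_hbonds(topo2, frame2, roles)
        to_acceptor = [b for b in all_bonds if b.acceptor == 3]
        assert len(to_acceptor) == 2
        strongest = detect_hbonds(
            topo2, frame2, roles, strongest_per_acceptor=True
        )
        kept = [b for b in strongest if b.acceptor == 3]
        assert len(kept) == 1
        assert kept[0].energy == max(b.energy for b in to_acceptor)

    def test_group_pair_filter_directions(self, bridge_basic):
        fx = bridge_basic
        either = detect_hbonds(
            fx.topology, fx.frames[0], fx.roles, between=("solute_A", "solute_B")
        )
        a_to_b = detect_hbonds(
            fx.topology, fx.frames[0], fx.roles,
            between=("solute_A", "solute_B"), directional=True,
        )
        b_to_a = detect_hbonds(
            fx.topology, fx.frames[0], fx.roles,
            between=("solute_B", "solute_A"), directional=True,
        )
        assert len(either) == len(a_to_b) + len(b_to_a)

    def test_matches_brute_force_on_randomized_systems(self):
        rng = np.random.default_rng(42)
        mismatches = 0
        for _ in range(60):
            topology, frame = random_small_system(rng)
            roles = classify_polar_roles(topology)
            fast = {
                (b.donor_heavy, b.hydrogen, b.acceptor)
                for b in detect_hbonds(topology, frame, roles)
            }
            slow = brute_force_detect(topology, frame, roles)
            if fast != slow:
                mismatches += 1
        assert mismatches == 0

    def test_energies_match_brute_force(self):
        rng = np.random.default_rng(7)
        topology, frame = random_small_system(rng)
        roles = classify_polar_roles(topology)
        oracle = brute_force_energies(topology, frame, roles)
        for b in detect_hbonds(topology, frame, roles):
            key = (b.donor_heavy, b.hydrogen, b.acceptor)
            assert b.energy == pytest.approx(oracle[key], rel=1e-12)

    def test_rigid_motion_invariance(self, bridge_basic):
        from scipy.spatial.transform import Rotation

        fx = bridge_basic
        reference = detect_hbonds(fx.topology, fx.frames[0], fx.roles)
        rotation = Rotation.from_euler("xyz", [31.0, -77.0, 142.0], degrees=True)
        moved = Frame(
            time=0.0,
            coords=rotation.apply(fx.frames[0].coords) + np.array([11.0, -3.0, 8.5]),
        )
        transformed = detect_hbonds(fx.topology, moved, fx.roles)
        assert len(reference) == len(transformed)
        for b1, b2 in zip(reference, transformed):
            assert b2.energy == pytest.approx(b1.energy, rel=1e-9)
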