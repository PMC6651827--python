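"""Water bridges, contact maps and duration statistics."""

import numpy as np
import pandas as pd
import pytest

from hydrobridge.bridges import (
    WaterBridge,
    bridge_pair_presence,
    build_bridge_map,
    build_contact_map,
    duration_stats,
    find_water_bridges,
    hbond_pair_presence,
    timeseries,
)
from hydrobridge.energy import HBond
from hydrobridge.model import Atom, Topology

from conftest import detect_per_frame


def _mini_topology():
    """Six atoms: one A oxygen, one B oxygen, water (O, H, H), decoy oxygen."""
    atoms = [
        Atom(0, "O", "OA", "GAG", 1, "A", 1),
        Atom(1, "O", "OB", "LIP", 2, "B", 2),
        Atom(2, "O", "O", "HOH", 3, "W", 3),
        Atom(3, "H", "H1", "HOH", 3, "W", 4),
        Atom(4, "H", "H2", "HOH", 3, "W", 5),
        Atom(5, "O", "O", "DUM", 4, "D", 6),
    ]
    topology = Topology(atoms=atoms, covalent_adjacency={(2, 3), (2, 4)})
    return topology.with_groups([0], [1])


def _bond(donor_heavy, hydrogen, acceptor, energy=25.0):
    return HBond(
        donor_heavy=donor_heavy, hydrogen=hydrogen, acceptor=acceptor,
        chosen_X=None, dist_HA=1.9, angle_DHA=180.0, angle_HAX=180.0,
        scale_DHA=1.0, scale_HAX=1.0, energy=energy,
    )


class TestFindWaterBridges:
    def test_water_bonded_to_both_groups_is_a_bridge(self):
        topo = _mini_topology()
        bonds = [_bond(2, 3, 0), _bond(2, 4, 1)]  # water donates to A and B
        bridges = find_water_bridges([bonds], topo)
        assert len(bridges[0]) == 1
        assert bridges[0][0].water_residue == ("W", 3, "HOH")

    def test_water_bonded_to_one_group_only_is_not(self):
        topo = _mini_topology()
        bridges = find_water_bridges([[_bond(2, 3, 0)]], topo)
        assert bridges[0] == []

    def test_water_role_not_restricted(self):
        topo = _mini_topology()
        # water accepts from nothing here; instead: A-side bond has water as
        # acceptor (index 2), B-side bond has water as donor
        bonds = [_bond(0, 3, 2), _bond(2, 4, 1)]
        # hydrogen index of the A-side bond is fake but unused by bridging
        bridges = find_water_bridges([bonds], topo)
        assert len(bridges[0]) == 1

    def test_two_waters_same_pair_two_bridges_one_mapped_pair(self, ):
        atoms = [
            Atom(0, "O", "OA", "GAG", 1, "A", 1),
            Atom(1, "O", "OB", "LIP", 2, "B", 2),
            Atom(2, "O", "O", "HOH", 3, "W", 3),
            Atom(3, "H", "H1", "HOH", 3, "W", 4),
            Atom(4, "H", "H2", "HOH", 3, "W", 5),
            Atom(5, "O", "O", "HOH", 4, "W", 6),
            Atom(6, "H", "H1", "HOH", 4, "W", 7),
            Atom(7, "H", "H2", "HOH", 4, "W", 8),
        ]
        topo = Topology(
            atoms=atoms, covalent_adjacency={(2, 3), (2, 4), (5, 6), (5, 7)}
        ).with_groups([0], [1])
        bonds = [
            _bond(2, 3, 0), _bond(2, 4, 1),  # water 3 spans A-B
            _bond(5, 6, 0), _bond(5, 7, 1),  # water 4 spans the same pair
        ]
        bridges = find_water_bridges([bonds], topo)
        assert len(bridges[0]) == 2
        presence = bridge_pair_presence(bridges, topo)
        assert presence[0] == {("GAG1:OA", "LIP2:OB")}

    def test_bridge_count_bounded_by_water_count(self, bridge_basic):
        _, bridges = detect_per_frame(bridge_basic)
        n_waters = len(
            {
                bridge_basic.topology.residue_key(i)
                for i in bridge_basic.topology.groups["water"]
            }
        )
        for frame_bridges in bridges:
            assert len(frame_bridges) <= n_waters

    def test_requires_both_sides_nonempty(self):
        with pytest.raises(ValueError):
            WaterBridge(("W", 3, "HOH"), (), (_bond(2, 4, 1),), 0)


class TestTimeseries:
    def test_empty(self):
        table = timeseries([])
        assert len(table) == 0

    def test_counts_match_manifest(self, bridge_basic):
        per_frame_ab, bridges = detect_per_frame(bridge_basic)
        times = [
            f * bridge_basic.manifest.snapshot_interval_ns
            for f in range(bridge_basic.manifest.n_frames)
        ]
        table = timeseries(per_frame_ab, bridges, times)
        assert list(table["n_hbonds"]) == bridge_basic.manifest.per_frame_hbond_counts
        assert list(table["n_bridges"]) == bridge_basic.manifest.per_frame_bridge_counts

    def test_constant_series_for_repeated_frame(self, bridge_basic):
        per_frame_ab, _ = detect_per_frame(bridge_basic)
        repeated = [per_frame_ab[0]] * 4
        table = timeseries(repeated)
        assert table["n_hbonds"].nunique() == 1

    def test_smoothing_never_alters_raw_counts(self, bridge_basic):
        per_frame_ab, bridges = detect_per_frame(bridge_basic)
        raw = timeseries(per_frame_ab, bridges)
        smoothed = timeseries(per_frame_ab, bridges, smoothing_window=3)
        assert list(raw["n_hbonds"]) == list(smoothed["n_hbonds"])
        assert "n_hbonds_smooth" in smoothed


class TestContactMap:
    def test_single_bond_single_frame_is_100_percent(self):
        topo = _mini_topology()
        cmap = build_contact_map([[_bond(0, 3, 1)]], topo)
        assert cmap.total == 1
        assert cmap.percentages == {("GAG1:OA", "LIP2:OB"): 100.0}

    def test_75_25_split(self):
        atoms = [
            Atom(0, "O", "OA", "GAG", 1, "A", 1),
            Atom(1, "H", "HA", "GAG", 1, "A", 2),
            Atom(2, "O", "OB", "LIP", 2, "B", 3),
            Atom(3, "O", "OC", "LIP", 3, "B", 4),
        ]
        topo = Topology(
            atoms=atoms, covalent_adjacency={(0, 1)}
        ).with_groups([0, 1], [2, 3])
        pair1, pair2 = _bond(0, 1, 2), _bond(0, 1, 3)
        cmap = build_contact_map([[pair1], [pair1], [pair1, pair2], []], topo)
        assert cmap.pair_counts == {
            ("GAG1:OA", "LIP2:OB"): 3,
            ("GAG1:OA", "LIP3:OC"): 1,
        }
        pct = cmap.percentages
        assert pct[("GAG1:OA", "LIP2:OB")] == pytest.approx(75.0)
        assert pct[("GAG1:OA", "LIP3:OC")] == pytest.approx(25.0)

    def test_per_frame_deduplication_on_heavy_pair(self):
        atoms = [
            Atom(0, "O", "OA", "GAG", 1, "A", 1),
            Atom(1, "H", "HA1", "GAG", 1, "A", 2),
            Atom(2, "H", "HA2", "GAG", 1, "A", 3),
            Atom(3, "O", "OB", "LIP", 2, "B", 4),
        ]
        topo = Topology(
            atoms=atoms, covalent_adjacency={(0, 1), (0, 2)}
        ).with_groups([0, 1, 2], [3])
        # two hydrogens of the same heavy donor to one acceptor in one frame
        cmap = build_contact_map([[_bond(0, 1, 3), _bond(0, 2, 3)]], topo)
        assert cmap.total == 1

    def test_empty_detections(self):
        cmap = build_contact_map([[], []], _mini_topology())
        assert cmap.total == 0
        assert cmap.percentages == {}
        assert cmap.to_dataframe().empty

    def test_percentages_sum_to_100(self, bridge_basic):
        per_frame_ab, bridges = detect_per_frame(bridge_basic)
        for cmap in (
            build_contact_map(per_frame_ab, bridge_basic.topology),
            build_bridge_map(bridges, bridge_basic.topology),
        ):
            assert sum(cmap.percentages.values()) == pytest.approx(100.0, abs=0.01)

    def test_total_equals_sum_of_frame_incidences(self, bridge_basic):
        per_frame_ab, _ = detect_per_frame(bridge_basic)
        presence = hbond_pair_presence(per_frame_ab, bridge_basic.topology)
        cmap = build_contact_map(per_frame_ab, bridge_basic.topology)
        assert cmap.total == sum(len(p) for p in presence)


class TestDurations:
    def test_always_present_pair(self):
        presence = [{("a", "b")}] * 10
        table = duration_stats(presence, 0.1).table
        assert table.loc[0, "occupancy_ns"] == pytest.approx(1.0)
        assert table.loc[0, "longest_run_ns"] == pytest.approx(1.0)

    def test_interrupted_pair_frames_1_2_5(self):
        presence = [set() for _ in range(6)]
        for f in (1, 2, 5):
            presence[f] = {("a", "b")}
        table = duration_stats(presence, 0.1).table
        row = table.iloc[0]
        assert row["occupancy_ns"] == pytest.approx(0.3)
        assert row["longest_run_ns"] == pytest.approx(0.2)
        assert (row["first_frame"], row["last_frame"]) == (1, 5)

    def test_absent_pair_not_listed(self):
        table = duration_stats([set(), set()], 0.1).table
        assert table.empty

    def test_longest_run_never_exceeds_occupancy(self, bridge_basic):
        per_frame_ab, _ = detect_per_frame(bridge_basic)
        presence = hbond_pair_presence(per_frame_ab, bridge_basic.topology)
        stats = duration_stats(presence, 0.1)
        assert (stats.table["longest_run_ns"] <= stats.table["occupancy_ns"] + 1e-12).all()
        assert (stats.table["occupancy_frames"] <= stats.n_frames).all()

    def test_nonuniform_times_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            duration_stats([set()] * 3, 0.1, times_ns=[0.0, 0.1, 0.35])

    def test_occupancy_additivity_over_concatenation(self):
        rng = np.random.default_rng(5)
        pairs = [("a", "b"), ("c", "d")]
        part1 = [
            {p for p in pairs if rng.random() < 0.5} for _ in range(6)
        ]
        part2 = [
            {p for p in pairs if rng.random() < 0.5} for _ in range(5)
        ]
        whole = duration_stats(part1 + part2, 0.1).table
        t1 = duration_stats(part1, 0.1).table
        t2 = duration_stats(part2, 0.1).table

        def occupancy(table, pair):
            match = table[(table["label_A"] == pair[0]) & (table["label_B"] == pair[1])]
            return float(match["occupancy_ns"].sum())

        for pair in pairs:
            assert occupancy(whole, pair) == pytest.approx(
                occupancy(t1, pair) + occupancy(t2, pair)
            )

    def test_no_waters_means_no_bridges_but_same_hbonds(self, bridge_basic):
        fx = bridge_basic
        # reassign waters to "other": direct solute statistics are unchanged
        no_water = fx.topology.with_groups(
            fx.topology.groups["solute_A"],
            fx.topology.groups["solute_B"],
            water_aliases=("NONE",),
        )
        from hydrobridge.energy import detect_hbonds
        from hydrobridge.model import classify_polar_roles

        roles = classify_polar_roles(no_water)
        direct_ref = detect_hbonds(
            fx.topology, fx.frames[0], fx.roles, between=("solute_A", "solute_B")
        )
        direct = detect_hbonds(
            no_water, fx.frames[0], roles, between=("solute_A", "solute_B")
        )
        assert len(direct) == len(direct_ref)
        wa = detect_hbonds(no_water, fx.frames[0], roles, between=("water", "solute_A"))
        assert wa == []
        assert find_water_bridges([[]], no_water)[0] == []
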