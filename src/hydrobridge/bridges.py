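"""Water bridges, contact maps and bond-duration statistics.

A *water bridge* is a single water molecule that, in one frame, forms at
least one qualifying hydrogen bond (in either donor or acceptor role) to
each of the two solute groups, linking them indirectly.  Contact maps count
unique solute-atom pairs across frames — a pair present in a frame counts
once per frame no matter how many times it recurs — and report each pair as
a percentage of all pair-frame incidences.  Durations are occupancy
estimates: presence-frame count times the snapshot interval; the longest
contiguous run is reported alongside but never substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .energy import HBond
from .model import Topology

__all__ = [
    "WaterBridge",
    "ContactMap",
    "DurationTable",
    "find_water_bridges",
    "bridge_solute_pairs",
    "timeseries",
    "hbond_pair_presence",
    "bridge_pair_presence",
    "build_contact_map",
    "build_bridge_map",
    "duration_stats",
]

PairKey = tuple[str, str]


@dataclass(frozen=True)
class WaterBridge:
    """One water residue bonded to both solute groups in one frame."""

    water_residue: tuple[str, int, str]  # (chain, resid, resname)
    bonds_to_A: tuple[HBond, ...]
    bonds_to_B: tuple[HBond, ...]
    frame: int

    def __post_init__(self) -> None:
        if not self.bonds_to_A or not self.bonds_to_B:
            raise ValueError("a water bridge needs bonds to both solute groups")


@dataclass
class ContactMap:
    """Unique-pair counts with percentage normalisation.

    ``pair_counts`` maps (solute-A label, solute-B label) to the number of
    frames in which the pair was present; ``total`` is the sum over pairs;
    percentages are ``100 * count / total``.
    """

    pair_counts: dict[PairKey, int] = field(default_factory=dict)
    total: int = 0

    @property
    def percentages(self) -> dict[PairKey, float]:
        if self.total == 0:
            return {}
        return {k: 100.0 * v / self.total for k, v in self.pair_counts.items()}

    def to_dataframe(self) -> pd.DataFrame:
        pct = self.percentages
        rows = [
            {"label_A": a, "label_B": b, "count": c, "percent": pct[(a, b)]}
            for (a, b), c in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows, columns=["label_A", "label_B", "count", "percent"])

    def to_json_dict(self) -> dict:
        pct = self.percentages
        return {
            "total": self.total,
            "pairs": [
                {"label_A": a, "label_B": b, "count": c, "percent": pct[(a, b)]}
                for (a, b), c in sorted(self.pair_counts.items())
            ],
        }


@dataclass
class DurationTable:
    """Per-pair occupancy statistics over an equally spaced trajectory."""

    snapshot_interval_ns: float
    n_frames: int
    table: pd.DataFrame  # label_A, label_B, occupancy_frames, occupancy_ns,
    #                      longest_run_ns, first_frame, last_frame


def _water_side_residue(
    bond: HBond, topology: Topology, water: frozenset[int]
) -> Optional[tuple[str, int, str]]:
    """Residue key of the water involved in a water↔solute bond, if any."""
    if bond.donor_heavy in water:
        return topology.residue_key(bond.donor_heavy)
    if bond.acceptor in water:
        return topology.residue_key(bond.acceptor)
    return None


def _solute_side_atom(bond: HBond, water: frozenset[int]) -> int:
    """Heavy solute atom of a water↔solute bond (donor heavy or acceptor)."""
    return bond.acceptor if bond.donor_heavy in water else bond.donor_heavy


def find_water_bridges(
    hbonds_with_water: Sequence[Sequence[HBond]],
    topology: Topology,
    group_a: str = "solute_A",
    group_b: str = "solute_B",
) -> list[list[WaterBridge]]:
    """Identify water bridges in each frame.

    ``hbonds_with_water`` holds, per frame, the qualifying hydrogen bonds
    between water and the two solute groups (both orientations).  A water
    residue is a bridge in a frame iff it carries at least one bond to each
    solute group in that frame; the water's donor-versus-acceptor role is
    not restricted.
    """
    water = topology.groups.get("water", frozenset())
    members_a = topology.groups[group_a]
    members_b = topology.groups[group_b]

    per_frame: list[list[WaterBridge]] = []
    for f, bonds in enumerate(hbonds_with_water):
        by_water: dict[tuple[str, int, str], tuple[list[HBond], list[HBond]]] = {}
        for bond in bonds:
            residue = _water_side_residue(bond, topology, water)
            if residue is None:
                continue
            solute_atom = _solute_side_atom(bond, water)
            slot = by_water.setdefault(residue, ([], []))
            if solute_atom in members_a:
                slot[0].append(bond)
            elif solute_atom in members_b:
                slot[1].append(bond)
        frame_bridges = [
            WaterBridge(
                water_residue=residue,
                bonds_to_A=tuple(to_a),
                bonds_to_B=tuple(to_b),
                frame=f,
            )
            for residue, (to_a, to_b) in sorted(by_water.items())
            if to_a and to_b
        ]
        per_frame.append(frame_bridges)
    return per_frame


def bridge_solute_pairs(
    bridge: WaterBridge, topology: Topology
) -> set[tuple[int, int]]:
    """Solute (A-atom, B-atom) index pairs joined through this bridge's water.

    Every combination of an A-side and a B-side solute heavy atom bonded to
    the water counts as one linked pair.
    """
    water = topology.groups.get("water", frozenset())
    atoms_a = {_solute_side_atom(b, water) for b in bridge.bonds_to_A}
    atoms_b = {_solute_side_atom(b, water) for b in bridge.bonds_to_B}
    return {(a, b) for a in atoms_a for b in atoms_b}


def timeseries(
    per_frame_hbonds: Sequence[Sequence[HBond]],
    per_frame_bridges: Optional[Sequence[Sequence[WaterBridge]]] = None,
    times_ns: Optional[Sequence[float]] = None,
    smoothing_window: Optional[int] = None,
) -> pd.DataFrame:
    """Per-frame raw counts of hydrogen bonds and water bridges.

    The optional centred moving average is an extra column; the raw counts
    are never altered.
    """
    n = len(per_frame_hbonds)
    if per_frame_bridges is not None and len(per_frame_bridges) != n:
        raise ValueError("bond and bridge series must cover the same frames")
    times = (
        np.asarray(times_ns, dtype=float)
        if times_ns is not None
        else np.arange(n, dtype=float)
    )
    if len(times) != n:
        raise ValueError("times length must equal frame count")
    data = {
        "frame": np.arange(n, dtype=int),
        "time_ns": times,
        "n_hbonds": np.array([len(b) for b in per_frame_hbonds], dtype=int),
    }
    if per_frame_bridges is not None:
        data["n_bridges"] = np.array(
            [len(b) for b in per_frame_bridges], dtype=int
        )
    table = pd.DataFrame(data)
    if smoothing_window is not None and n > 0:
        if smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1")
        for col in ("n_hbonds", "n_bridges"):
            if col in table:
                table[f"{col}_smooth"] = (
                    table[col]
                    .rolling(smoothing_window, center=True, min_periods=1)
                    .mean()
                )
    return table


def _oriented_pair(
    bond: HBond, topology: Topology, group_a: str, group_b: str
) -> Optional[tuple[int, int]]:
    """Heavy-atom pair of an intergroup bond, oriented (A-atom, B-atom)."""
    members_a = topology.groups[group_a]
    members_b = topology.groups[group_b]
    d, a = bond.donor_heavy, bond.acceptor
    if d in members_a and a in members_b:
        return (d, a)
    if d in members_b and a in members_a:
        return (a, d)
    return None


def hbond_pair_presence(
    per_frame_bonds: Sequence[Sequence[HBond]],
    topology: Topology,
    group_a: str = "solute_A",
    group_b: str = "solute_B",
) -> list[set[PairKey]]:
    """Per-frame sets of unique (A-label, B-label) bonded pairs.

    Pair identity uses the heavy-atom pair (donor heavy, acceptor), so
    multiple hydrogens bonding the same heavy pair in one frame collapse to
    a single incidence.
    """
    presence: list[set[PairKey]] = []
    for bonds in per_frame_bonds:
        frame_pairs: set[PairKey] = set()
        for bond in bonds:
            pair = _oriented_pair(bond, topology, group_a, group_b)
            if pair is not None:
                frame_pairs.add(
                    (topology.atoms[pair[0]].label, topology.atoms[pair[1]].label)
                )
        presence.append(frame_pairs)
    return presence


def bridge_pair_presence(
    per_frame_bridges: Sequence[Sequence[WaterBridge]],
    topology: Topology,
) -> list[set[PairKey]]:
    """Per-frame sets of unique (A-label, B-label) water-linked pairs."""
    presence: list[set[PairKey]] = []
    for bridges in per_frame_bridges:
        frame_pairs: set[PairKey] = set()
        for bridge in bridges:
            for a, b in bridge_solute_pairs(bridge, topology):
                frame_pairs.add(
                    (topology.atoms[a].label, topology.atoms[b].label)
                )
        presence.append(frame_pairs)
    return presence


def _map_from_presence(presence: Iterable[set[PairKey]]) -> ContactMap:
    counts: dict[PairKey, int] = {}
    for frame_pairs in presence:
        for pair in frame_pairs:
            counts[pair] = counts.get(pair, 0) + 1
    return ContactMap(pair_counts=counts, total=sum(counts.values()))


def build_contact_map(
    per_frame_bonds: Sequence[Sequence[HBond]],
    topology: Topology,
    group_a: str = "solute_A",
    group_b: str = "solute_B",
) -> ContactMap:
    """Contact map of unique intergroup hydrogen-bond pairs.

    Each pair is counted at most once per frame; percentages normalise by
    the total number of pair-frame incidences.
    """
    return _map_from_presence(
        hbond_pair_presence(per_frame_bonds, topology, group_a, group_b)
    )


def build_bridge_map(
    per_frame_bridges: Sequence[Sequence[WaterBridge]],
    topology: Topology,
) -> ContactMap:
    """Contact map of unique water-bridged solute pairs (same normalisation
    as the direct-bond map)."""
    return _map_from_presence(bridge_pair_presence(per_frame_bridges, topology))


def duration_stats(
    presence: Sequence[set[Hashable]],
    snapshot_interval_ns: float,
    times_ns: Optional[Sequence[float]] = None,
) -> DurationTable:
    """Occupancy durations from per-frame presence sets.

    ``occupancy_ns`` is presence-frame count × snapshot interval — the
    occurrence-counting estimator; ``longest_run_ns`` is the longest
    contiguous presence streak.  Frames must be equally spaced; pass
    ``times_ns`` to have the spacing validated.
    """
    if snapshot_interval_ns <= 0:
        raise ValueError("snapshot interval must be positive")
    if times_ns is not None and len(times_ns) > 1:
        steps = np.diff(np.asarray(times_ns, dtype=float))
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError(
                "frame times are not equally spaced; resample the trajectory "
                "to a uniform interval before computing durations"
            )

    n = len(presence)
    stats: dict[Hashable, dict] = {}
    for f, frame_pairs in enumerate(presence):
        for pair in frame_pairs:
            entry = stats.setdefault(
                pair,
                {
                    "occupancy_frames": 0,
                    "first_frame": f,
                    "last_frame": f,
                    "longest_run": 0,
                    "_current_run": 0,
                    "_prev_frame": None,
                },
            )
            entry["occupancy_frames"] += 1
            entry["last_frame"] = f
            if entry["_prev_frame"] is not None and entry["_prev_frame"] == f - 1:
                entry["_current_run"] += 1
            else:
                entry["_current_run"] = 1
            entry["longest_run"] = max(entry["longest_run"], entry["_current_run"])
            entry["_prev_frame"] = f

    rows = []
    for pair, entry in stats.items():
        label_a, label_b = (
            pair if isinstance(pair, tuple) and len(pair) == 2 else (str(pair), "")
        )
        rows.append(
            {
                "label_A": label_a,
                "label_B": label_b,
                "occupancy_frames": entry["occupancy_frames"],
                "occupancy_ns": entry["occupancy_frames"] * snapshot_interval_ns,
                "longest_run_ns": entry["longest_run"] * snapshot_interval_ns,
                "first_frame": entry["first_frame"],
                "last_frame": entry["last_frame"],
            }
        )
    columns = [
        "label_A", "label_B", "occupancy_frames", "occupancy_ns",
        "longest_run_ns", "first_frame", "last_frame",
    ]
    table = pd.DataFrame(rows, columns=columns)
    if not table.empty:
        table = table.sort_values(["label_A", "label_B"]).reset_index(drop=True)
    return DurationTable(
        snapshot_interval_ns=snapshot_interval_ns, n_frames=n, table=table
    )
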