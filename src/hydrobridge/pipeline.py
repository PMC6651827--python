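"""Full-trajectory analysis orchestration.

``run_analysis`` drives the whole chain — read trajectory, resolve the two
solute selections, detect hydrogen bonds, identify water bridges, build
contact maps and duration tables, track solvent-accessible surface — and
writes a deterministic results bundle (CSV + JSON) to an output directory.
Re-running an identical configuration produces byte-identical CSVs.

Selections use a deliberately small grammar::

    expression := clause (" or " clause)*
    clause     := "chain" ID | "resname" NAME | "resid" N | "resid" N-M

e.g. ``"chain A"`` or ``"resname DPPE or resname DPPC"``.
"""

from __future__ import annotations

import json
import logging
import os
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .bridges import (
    bridge_pair_presence,
    build_bridge_map,
    build_contact_map,
    duration_stats,
    find_water_bridges,
    hbond_pair_presence,
    timeseries,
)
from .energy import HBondParams, bonds_dataframe, detect_hbonds
from .model import (
    DEFAULT_WATER_ALIASES,
    Topology,
    classify_polar_roles,
    read_pdb_trajectory,
)
from .sas import SasParams, sas_timeseries

__all__ = ["RunConfig", "ResultsBundle", "parse_selection", "run_analysis"]

logger = logging.getLogger("hydrobridge")

_CSV_KW = dict(index=False, float_format="%.6f", lineterminator="\n")


class SelectionError(ValueError):
    """A selection expression is malformed or matches nothing."""


def parse_selection(expression: str, topology: Topology) -> frozenset[int]:
    """Resolve a selection expression to a set of atom indices."""
    selected: set[int] = set()
    for clause in expression.split(" or "):
        parts = clause.strip().split()
        if len(parts) != 2:
            raise SelectionError(
                f"cannot parse selection clause {clause.strip()!r}; expected "
                "'chain X', 'resname NAME' or 'resid N[-M]'"
            )
        key, value = parts
        if key == "chain":
            matches = {a.index for a in topology.atoms if a.chain_id == value}
        elif key == "resname":
            matches = {
                a.index
                for a in topology.atoms
                if a.residue_name.upper() == value.upper()
            }
        elif key == "resid":
            if "-" in value:
                lo, hi = (int(v) for v in value.split("-", 1))
            else:
                lo = hi = int(value)
            matches = {
                a.index for a in topology.atoms if lo <= a.residue_id <= hi
            }
        else:
            raise SelectionError(
                f"unknown selection key {key!r}; use chain/resname/resid"
            )
        selected |= matches
    return frozenset(selected)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    trajectory: Path
    select_a: str
    select_b: str
    snapshot_interval_ns: float
    out_dir: Path
    water_aliases: tuple[str, ...] = DEFAULT_WATER_ALIASES
    hbond_params: HBondParams = field(default_factory=HBondParams)
    sas_params: SasParams = field(default_factory=SasParams)
    filter_mode: str = "either"  # "either" | "a_to_b" | "any"
    smoothing_window: Optional[int] = None
    log_level: str = "INFO"

    def echo(self) -> dict:
        return {
            "trajectory": str(self.trajectory),
            "select_a": self.select_a,
            "select_b": self.select_b,
            "snapshot_interval_ns": self.snapshot_interval_ns,
            "out_dir": str(self.out_dir),
            "water_aliases": list(self.water_aliases),
            "hbond_params": self.hbond_params.as_dict(),
            "sas_params": {
                "probe_radius_A": self.sas_params.probe_radius,
                "n_sphere_points": self.sas_params.n_sphere_points,
                "radii_set": dict(self.sas_params.radii_set),
            },
            "filter_mode": self.filter_mode,
            "smoothing_window": self.smoothing_window,
            "log_level": self.log_level,
        }


@dataclass
class ResultsBundle:
    """Paths of the written outputs plus the run-metadata record."""

    out_dir: Path
    timeseries_csv: Path
    hbonds_csv: Path
    hbond_map_csv: Path
    hbond_durations_csv: Path
    bridge_map_csv: Optional[Path]
    bridge_durations_csv: Optional[Path]
    sas_csv: Path
    contact_map_json: Path
    metadata_json: Path
    metadata: dict


def _write_csv_atomic(frame: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, **_CSV_KW)
    os.replace(tmp, path)


def _write_json_atomic(payload: dict, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=1, sort_keys=True))
    os.replace(tmp, path)


def run_analysis(config: RunConfig) -> ResultsBundle:
    """Run the full detection/aggregation chain and write the bundle.

    Raises :class:`SelectionError` before any computation if a solute
    selection resolves to zero atoms or the selections overlap.  An empty
    water selection only disables the bridge outputs (with a warning).
    """
    logging.basicConfig(level=config.log_level)
    started = _time.time()

    topology, frames = read_pdb_trajectory(
        config.trajectory, water_aliases=config.water_aliases
    )
    sel_a = parse_selection(config.select_a, topology)
    sel_b = parse_selection(config.select_b, topology)
    if not sel_a:
        raise SelectionError(f"selection A ({config.select_a!r}) matches no atoms")
    if not sel_b:
        raise SelectionError(f"selection B ({config.select_b!r}) matches no atoms")
    topology = topology.with_groups(sel_a, sel_b, config.water_aliases)
    have_water = bool(topology.groups["water"])
    if not have_water:
        logger.warning(
            "no water residues matched aliases %s; bridge analysis disabled",
            config.water_aliases,
        )

    roles = classify_polar_roles(topology)
    n_frames = len(frames)
    times_ns = [f * config.snapshot_interval_ns for f in range(n_frames)]
    between = None if config.filter_mode == "any" else ("solute_A", "solute_B")
    directional = config.filter_mode == "a_to_b"

    per_frame_ab = []
    per_frame_water = []
    for f, frame in enumerate(frames):
        per_frame_ab.append(
            detect_hbonds(
                topology, frame, roles, config.hbond_params,
                between=between, directional=directional,
            )
        )
        if have_water:
            bonds_wa = detect_hbonds(
                topology, frame, roles, config.hbond_params,
                between=("water", "solute_A"),
            )
            bonds_wb = detect_hbonds(
                topology, frame, roles, config.hbond_params,
                between=("water", "solute_B"),
            )
            per_frame_water.append(list(bonds_wa) + list(bonds_wb))
        logger.info(
            "frame %d/%d: %d solute-solute H-bonds", f + 1, n_frames,
            len(per_frame_ab[-1]),
        )

    per_frame_bridges = (
        find_water_bridges(per_frame_water, topology) if have_water else None
    )

    series = timeseries(
        per_frame_ab, per_frame_bridges, times_ns,
        smoothing_window=config.smoothing_window,
    )
    bonds_table = bonds_dataframe(
        topology, per_frame_ab, [t * 1000.0 for t in times_ns]
    )
    hbond_map = build_contact_map(per_frame_ab, topology)
    hbond_durations = duration_stats(
        hbond_pair_presence(per_frame_ab, topology),
        config.snapshot_interval_ns,
        times_ns,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv_atomic(series, out / "timeseries.csv")
    _write_csv_atomic(bonds_table, out / "hbonds.csv")
    _write_csv_atomic(hbond_map.to_dataframe(), out / "hbond_map.csv")
    _write_csv_atomic(hbond_durations.table, out / "hbond_durations.csv")

    bridge_map_csv = bridge_durations_csv = None
    bridge_map_payload = None
    if per_frame_bridges is not None:
        bridge_map = build_bridge_map(per_frame_bridges, topology)
        bridge_durations = duration_stats(
            bridge_pair_presence(per_frame_bridges, topology),
            config.snapshot_interval_ns,
            times_ns,
        )
        bridge_map_csv = out / "bridge_map.csv"
        bridge_durations_csv = out / "bridge_durations.csv"
        _write_csv_atomic(bridge_map.to_dataframe(), bridge_map_csv)
        _write_csv_atomic(bridge_durations.table, bridge_durations_csv)
        bridge_map_payload = bridge_map.to_json_dict()

    sas_tables = []
    for group in ("solute_A", "solute_B"):
        table = sas_timeseries(
            topology, frames, sorted(topology.groups[group]),
            config.sas_params, times_ns,
        )
        table.insert(2, "group", group)
        sas_tables.append(table)
    sas_table = pd.concat(sas_tables, ignore_index=True)
    _write_csv_atomic(sas_table, out / "sas_timeseries.csv")

    contact_map_json = out / "contact_map.json"
    _write_json_atomic(
        {
            "hbond_map": hbond_map.to_json_dict(),
            "bridge_map": bridge_map_payload,
            "n_frames": n_frames,
            "snapshot_interval_ns": config.snapshot_interval_ns,
        },
        contact_map_json,
    )

    metadata = {
        "config": config.echo(),
        "package_version": __version__,
        "n_frames": n_frames,
        "n_atoms": topology.n_atoms,
        "group_sizes": {k: len(v) for k, v in topology.groups.items()},
        "totals": {
            "hbond_incidences": hbond_map.total,
            "bridge_incidences": (
                bridge_map_payload["total"] if bridge_map_payload else None
            ),
        },
        "wall_time_s": round(_time.time() - started, 3),
    }
    metadata_json = out / "run_metadata.json"
    _write_json_atomic(metadata, metadata_json)

    logger.info(
        "analysis complete: %d frames, %d unique bonded pairs",
        n_frames, len(hbond_map.pair_counts),
    )
    return ResultsBundle(
        out_dir=out,
        timeseries_csv=out / "timeseries.csv",
        hbonds_csv=out / "hbonds.csv",
        hbond_map_csv=out / "hbond_map.csv",
        hbond_durations_csv=out / "hbond_durations.csv",
        bridge_map_csv=bridge_map_csv,
        bridge_durations_csv=bridge_durations_csv,
        sas_csv=out / "sas_timeseries.csv",
        contact_map_json=contact_map_json,
        metadata_json=metadata_json,
        metadata=metadata,
    )
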