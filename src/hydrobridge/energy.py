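"""Energy-criterion hydrogen-bond scoring and detection.

A hydrogen bond is scored from three geometric observables of a
donor–hydrogen⋯acceptor contact:

* the hydrogen–acceptor distance ``d`` (Angstrom),
* the donor–hydrogen–acceptor angle (degrees),
* the hydrogen–acceptor–X angle, where X is the covalent partner of the
  acceptor (degrees).

The energy (kJ/mol) is::

    E = E_opt * (d_zero - max(d, d_clamp)) / (d_zero - d_clamp)
        * scale_DHA * scale_HAX

with ``E_opt = 25`` kJ/mol, ``d_clamp = 2.1`` and ``d_zero = 2.6`` Angstrom
by default, so any contact at or under 2.1 Angstrom with ideal angles scores
the optimum.  Both scale factors are piecewise-linear ramps clipped to
[0, 1]: the D–H–A factor rises over 100–165 degrees; the H–A–X factor rises
over 85–95 degrees when X is a heavy atom and over 75–85 degrees (slightly
smaller angles allowed) when X is itself a hydrogen.  A bond is reported
when its energy strictly exceeds the detection threshold, 6.25 kJ/mol
(25% of the optimum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Frame, PolarRoles, Topology

__all__ = [
    "HBondParams",
    "GeometryProbe",
    "HBond",
    "scale_dha",
    "scale_hax",
    "bond_energy",
    "detect_hbonds",
    "bonds_dataframe",
]


@dataclass(frozen=True)
class HBondParams:
    """Tunable constants of the hydrogen-bond energy criterion.

    Defaults are the published scoring constants: optimum 25 kJ/mol,
    threshold 6.25 kJ/mol, distance clamp 2.1 A, distance zero 2.6 A,
    and the three angular ramps in degrees.
    """

    optimum_energy: float = 25.0  # kJ/mol
    threshold_energy: float = 6.25  # kJ/mol
    d_clamp: float = 2.1  # Angstrom
    d_zero: float = 2.6  # Angstrom
    dha_ramp: tuple[float, float] = (100.0, 165.0)
    hax_heavy_ramp: tuple[float, float] = (85.0, 95.0)
    hax_hydrogen_ramp: tuple[float, float] = (75.0, 85.0)

    def __post_init__(self) -> None:
        if not 0 < self.d_clamp < self.d_zero:
            raise ValueError("require 0 < d_clamp < d_zero")
        if not 0 < self.threshold_energy < self.optimum_energy:
            raise ValueError("require 0 < threshold_energy < optimum_energy")
        for lo, hi in (self.dha_ramp, self.hax_heavy_ramp, self.hax_hydrogen_ramp):
            if not lo < hi:
                raise ValueError("each angular ramp needs lower bound < upper bound")

    def as_dict(self) -> dict:
        return {
            "optimum_energy_kJ_mol": self.optimum_energy,
            "threshold_energy_kJ_mol": self.threshold_energy,
            "d_clamp_A": self.d_clamp,
            "d_zero_A": self.d_zero,
            "dha_ramp_deg": list(self.dha_ramp),
            "hax_heavy_ramp_deg": list(self.hax_heavy_ramp),
            "hax_hydrogen_ramp_deg": list(self.hax_hydrogen_ramp),
        }


@dataclass(frozen=True)
class GeometryProbe:
    """One hydrogen-bond geometry, independent of any atom table."""

    dist_HA: float  # Angstrom
    angle_DHA: float  # degrees
    angle_HAX: float  # degrees
    X_is_hydrogen: bool = False

    def __post_init__(self) -> None:
        if self.dist_HA <= 0:
            raise ValueError("dist_HA must be positive")
        for angle in (self.angle_DHA, self.angle_HAX):
            if not 0.0 <= angle <= 180.0:
                raise ValueError(f"angle {angle} outside [0, 180] degrees")


@dataclass(frozen=True)
class HBond:
    """A detected donor–hydrogen⋯acceptor contact above threshold."""

    donor_heavy: int
    hydrogen: int
    acceptor: int
    chosen_X: Optional[int]
    dist_HA: float
    angle_DHA: float
    angle_HAX: Optional[float]
    scale_DHA: float
    scale_HAX: float
    energy: float


def _ramp(angle: float, lo: float, hi: float) -> float:
    if not 0.0 <= angle <= 180.0:
        raise ValueError(f"angle {angle} outside [0, 180] degrees")
    return float(np.clip((angle - lo) / (hi - lo), 0.0, 1.0))


def scale_dha(angle: float, params: HBondParams = HBondParams()) -> float:
    """Donor–hydrogen–acceptor angular factor: 0 below 100 deg, 1 above
    165 deg, linear between (defaults; ramp configurable)."""
    return _ramp(angle, *params.dha_ramp)


def scale_hax(
    angle: float, X_is_hydrogen: bool, params: HBondParams = HBondParams()
) -> float:
    """Hydrogen–acceptor–X angular factor.

    Heavy X ramps over 85–95 deg; a hydrogen X permits slightly smaller
    angles, ramping over 75–85 deg (defaults).
    """
    lo, hi = params.hax_hydrogen_ramp if X_is_hydrogen else params.hax_heavy_ramp
    return _ramp(angle, lo, hi)


def bond_energy(probe: GeometryProbe, params: HBondParams = HBondParams()) -> float:
    """Hydrogen-bond energy (kJ/mol) for one probe geometry.

    The distance term clamps below ``d_clamp`` (optimum plateau) and falls
    linearly to zero at ``d_zero``; beyond ``d_zero`` it is negative, so such
    contacts can never pass the positive detection threshold.
    """
    distance_term = (params.d_zero - max(probe.dist_HA, params.d_clamp)) / (
        params.d_zero - params.d_clamp
    )
    return (
        params.optimum_energy
        * distance_term
        * scale_dha(probe.angle_DHA, params)
        * scale_hax(probe.angle_HAX, probe.X_is_hydrogen, params)
    )


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex ``b`` in degrees."""
    u = a - b
    v = c - b
    cosine = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def _passes_filter(
    group_d: str, group_a: str, between: Optional[tuple[str, str]], directional: bool
) -> bool:
    if between is None:
        return True
    ga, gb = between
    if group_d == ga and group_a == gb:
        return True
    if not directional and group_d == gb and group_a == ga:
        return True
    return False


def detect_hbonds(
    topology: Topology,
    frame: Frame,
    roles: PolarRoles,
    params: HBondParams = HBondParams(),
    *,
    between: Optional[tuple[str, str]] = None,
    directional: bool = False,
    strongest_per_acceptor: bool = False,
) -> list[HBond]:
    """Detect all hydrogen bonds in one frame.

    Enumerates (donor hydrogen, acceptor) candidates whose H–A distance is
    below ``d_zero`` (a KD-tree prefilter; pure optimisation), skips the
    degenerate pair where the acceptor is the donor's own heavy atom,
    evaluates the energy and keeps bonds with ``energy > threshold``
    strictly.  For each candidate the acceptor's X is the covalent partner
    that minimises the H–A–X scale factor; an acceptor with no covalent
    partner gets ``scale_HAX = 1``.

    ``between`` restricts bonds to a pair of topology group names
    (donor-side group, acceptor-side group); with ``directional=False``
    either orientation qualifies.  ``strongest_per_acceptor`` keeps only the
    highest-energy bond per acceptor, for the strict single-bond reading of
    the acceptor rule.
    """
    from scipy.spatial import cKDTree

    coords = frame.coords
    if coords.shape[0] != topology.n_atoms:
        raise ValueError("frame does not match topology atom count")
    donors = sorted(roles.donors)
    acceptors = sorted(roles.acceptors)
    if not donors or not acceptors:
        return []

    group_lookup = topology.group_lookup()
    neighbor_table = topology.neighbor_table()
    elements = [a.element for a in topology.atoms]

    acc_coords = coords[np.array(acceptors)]
    h_indices = np.array([h for _, h in donors])
    tree = cKDTree(acc_coords)
    neighbor_lists = tree.query_ball_point(coords[h_indices], params.d_zero)

    bonds: list[HBond] = []
    for (heavy, hydrogen), acc_positions in zip(donors, neighbor_lists):
        for pos in acc_positions:
            acceptor = acceptors[pos]
            if acceptor == heavy:
                continue
            if not _passes_filter(
                group_lookup[heavy], group_lookup[acceptor], between, directional
            ):
                continue
            dist_ha = float(np.linalg.norm(coords[hydrogen] - coords[acceptor]))
            if dist_ha >= params.d_zero or dist_ha == 0.0:
                continue
            angle_dha = _angle_deg(coords[heavy], coords[hydrogen], coords[acceptor])
            s_dha = scale_dha(angle_dha, params)

            chosen_x: Optional[int] = None
            angle_hax: Optional[float] = None
            s_hax = 1.0
            for x in neighbor_table[acceptor]:
                ang = _angle_deg(coords[hydrogen], coords[acceptor], coords[x])
                s = scale_hax(ang, elements[x] == "H", params)
                if chosen_x is None or s < s_hax:
                    chosen_x, angle_hax, s_hax = x, ang, s

            distance_term = (params.d_zero - max(dist_ha, params.d_clamp)) / (
                params.d_zero - params.d_clamp
            )
            energy = params.optimum_energy * distance_term * s_dha * s_hax
            if energy > params.threshold_energy:
                bonds.append(
                    HBond(
                        donor_heavy=heavy,
                        hydrogen=hydrogen,
                        acceptor=acceptor,
                        chosen_X=chosen_x,
                        dist_HA=dist_ha,
                        angle_DHA=angle_dha,
                        angle_HAX=angle_hax,
                        scale_DHA=s_dha,
                        scale_HAX=s_hax,
                        energy=energy,
                    )
                )

    if strongest_per_acceptor:
        best: dict[int, HBond] = {}
        for bond in bonds:
            incumbent = best.get(bond.acceptor)
            if incumbent is None or bond.energy > incumbent.energy:
                best[bond.acceptor] = bond
        bonds = list(best.values())

    bonds.sort(key=lambda b: (b.donor_heavy, b.hydrogen, b.acceptor))
    return bonds


def bonds_dataframe(
    topology: Topology,
    per_frame_bonds: Sequence[Sequence[HBond]],
    times_ps: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Flatten per-frame bond lists into a tidy table for CSV export."""
    rows = []
    for f, bonds in enumerate(per_frame_bonds):
        t = float(times_ps[f]) if times_ps is not None else float(f)
        for b in bonds:
            d, h, a = topology.atoms[b.donor_heavy], topology.atoms[b.hydrogen], topology.atoms[b.acceptor]
            x = topology.atoms[b.chosen_X] if b.chosen_X is not None else None
            rows.append(
                {
                    "frame": f,
                    "time_ps": t,
                    "donor_serial": d.serial,
                    "donor": d.label,
                    "hydrogen": h.label,
                    "acceptor_serial": a.serial,
                    "acceptor": a.label,
                    "X": x.label if x is not None else "",
                    "dist_HA_A": b.dist_HA,
                    "angle_DHA_deg": b.angle_DHA,
                    "angle_HAX_deg": b.angle_HAX if b.angle_HAX is not None else np.nan,
                    "scale_DHA": b.scale_DHA,
                    "scale_HAX": b.scale_HAX,
                    "energy_kJ_mol": b.energy,
                }
            )
    columns = [
        "frame", "time_ps", "donor_serial", "donor", "hydrogen",
        "acceptor_serial", "acceptor", "X", "dist_HA_A", "angle_DHA_deg",
        "angle_HAX_deg", "scale_DHA", "scale_HAX", "energy_kJ_mol",
    ]
    return pd.DataFrame(rows, columns=columns)
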