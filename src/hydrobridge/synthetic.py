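"""Synthetic desk-scale fixture systems with planted ground truth.

Real systems of interest (a glycosaminoglycan chain plus phospholipids in
explicit water) run to ~150k atoms; nothing that size is needed to test the
analysis machinery.  This module builds small multi-model PDB systems in
which every hydrogen bond and water bridge is *planted* at an exactly known
geometry, and records the expected detections in a :class:`FixtureManifest`
so every downstream statistic (per-frame counts, contact-map percentages,
occupancy durations) has an independent ground truth.

Conventions shared by all scenarios:

* chain ``A`` — the GAG-mimic solute (hydroxyl donors, carboxylate
  acceptors), chain ``B`` — the lipid-mimic solute (phosphate acceptors,
  ethanolamine N–H donors or donor-free choline-like heads), chain ``W`` —
  waters (residue ``HOH``), chain ``D`` — decoys (methane, a sodium ion and
  polar groups deliberately out of range or at destructive angles).
* motifs sit on a 14 A grid with a seeded random rigid rotation each, so no
  two motifs ever come within hydrogen-bonding range of each other;
  rotations never change internal geometry, so planted energies are exact.
* a planted interaction is switched off in a frame by displacing its mobile
  fragment 6.5 A out of plane, putting the contact far beyond the 2.6 A
  detection horizon.

Expected energies in the manifest are computed here with inline arithmetic
(clamped linear distance term times two angular ramps), deliberately not by
calling the scoring module, so end-to-end tests compare two independent
routes to the same number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .energy import GeometryProbe
from .model import Atom, Frame, Topology, write_pdb_trajectory

__all__ = [
    "FixtureManifest",
    "PlantedBond",
    "PlantedBridge",
    "SCENARIOS",
    "make_geometry_probe_system",
    "measure_probe",
    "generate_fixture",
    "generate_kinetic_trajectory",
    "random_rotation",
]

_WATER_OH = 0.9572  # A
_WATER_HOH = 104.52  # degrees
_IDEAL_HA = 1.9  # A, inside the distance clamp -> optimum energy
_OFF_DISPLACEMENT = np.array([0.0, 0.0, 6.5])
_SITE_GAP = 8.0  # A of guaranteed clearance between any two motifs' atoms


# ---------------------------------------------------------------------------
# Manifest records
# ---------------------------------------------------------------------------


def _expected_energy(
    dist_ha: float, angle_dha: float, angle_hax: float, x_is_hydrogen: bool
) -> float:
    """Closed-form planted-bond energy (independent of the scoring module)."""

    def ramp(angle: float, lo: float, hi: float) -> float:
        return min(1.0, max(0.0, (angle - lo) / (hi - lo)))

    distance_term = (2.6 - max(dist_ha, 2.1)) / 0.5
    s_dha = ramp(angle_dha, 100.0, 165.0)
    lo, hi = (75.0, 85.0) if x_is_hydrogen else (85.0, 95.0)
    s_hax = ramp(angle_hax, lo, hi)
    return 25.0 * distance_term * s_dha * s_hax


@dataclass
class PlantedBond:
    """One planted direct hydrogen bond and the frames it is present in."""

    donor_label: str
    hydrogen_label: str
    acceptor_label: str
    pair_a_label: str  # solute-A side heavy atom of the oriented pair
    pair_b_label: str
    direction: str  # "A->B" or "B->A"
    dist_HA: float
    angle_DHA: float
    angle_HAX: float
    X_is_hydrogen: bool
    expected_energy: float
    frames_on: list[bool]


@dataclass
class PlantedBridge:
    """One planted water bridge (two qualifying legs through one water)."""

    water_label: str  # residue label, e.g. "HOH201"
    a_atom_label: str
    b_atom_label: str
    leg_a_energy: float
    leg_b_energy: float
    frames_on: list[bool]


@dataclass
class FixtureManifest:
    """Ground truth for a generated fixture trajectory."""

    scenario: str
    rng_seed: int
    snapshot_interval_ns: float
    n_frames: int
    planted_hbonds: list[PlantedBond] = field(default_factory=list)
    planted_bridges: list[PlantedBridge] = field(default_factory=list)

    @property
    def per_frame_hbond_counts(self) -> list[int]:
        """Expected direct solute A↔B bond count per frame."""
        return [
            sum(bond.frames_on[f] for bond in self.planted_hbonds)
            for f in range(self.n_frames)
        ]

    @property
    def per_frame_bridge_counts(self) -> list[int]:
        return [
            sum(br.frames_on[f] for br in self.planted_bridges)
            for f in range(self.n_frames)
        ]

    def expected_hbond_pairs(self) -> list[set[tuple[str, str]]]:
        """Per-frame sets of oriented (A-label, B-label) bonded pairs."""
        return [
            {
                (b.pair_a_label, b.pair_b_label)
                for b in self.planted_hbonds
                if b.frames_on[f]
            }
            for f in range(self.n_frames)
        ]

    def expected_bridge_pairs(self) -> list[set[tuple[str, str]]]:
        return [
            {
                (br.a_atom_label, br.b_atom_label)
                for br in self.planted_bridges
                if br.frames_on[f]
            }
            for f in range(self.n_frames)
        ]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        payload = json.loads(Path(path).read_text())
        payload["planted_hbonds"] = [
            PlantedBond(**b) for b in payload["planted_hbonds"]
        ]
        payload["planted_bridges"] = [
            PlantedBridge(**b) for b in payload["planted_bridges"]
        ]
        return cls(**payload)


# ---------------------------------------------------------------------------
# Geometry probe system
# ---------------------------------------------------------------------------


def make_geometry_probe_system(probe: GeometryProbe) -> tuple[Topology, Frame]:
    """Build a 4-atom donor–hydrogen⋯acceptor–X system realising ``probe``.

    Atom order is [D, H, A, X]; D and H form ``solute_A``, A and X form
    ``solute_B``.  The construction is verified by recomputing distance and
    angles from the coordinates to 1e-6; a geometrically degenerate request
    (atoms collapsing onto each other) raises ``ValueError``.
    """
    d = probe.dist_HA
    theta = np.radians(probe.angle_DHA)
    phi = np.radians(probe.angle_HAX)
    bond_dh = 1.0
    bond_ax = 0.96 if probe.X_is_hydrogen else 1.43

    pos_a = np.zeros(3)
    pos_h = np.array([d, 0.0, 0.0])
    pos_d = pos_h + bond_dh * np.array([-np.cos(theta), np.sin(theta), 0.0])
    pos_x = bond_ax * np.array([np.cos(phi), -np.sin(phi), 0.0])
    coords = np.array([pos_d, pos_h, pos_a, pos_x])

    diffs = coords[:, None, :] - coords[None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    if np.any(dists[np.triu_indices(4, k=1)] < 0.4):
        raise ValueError(
            "probe geometry is unrealizable: requested angles collapse atoms "
            "onto each other"
        )

    x_element = "H" if probe.X_is_hydrogen else "C"
    atoms = [
        Atom(0, "O", "OD", "PRD", 1, "A", 1),
        Atom(1, "H", "HD", "PRD", 1, "A", 2),
        Atom(2, "O", "OA", "PRA", 2, "B", 3),
        Atom(3, x_element, "X1", "PRA", 2, "B", 4),
    ]
    topology = Topology(atoms=atoms, covalent_adjacency={(0, 1), (2, 3)})
    topology = topology.with_groups([0, 1], [2, 3])
    frame = Frame(time=0.0, coords=coords)

    check = measure_probe(topology, frame)
    if (
        abs(check.dist_HA - probe.dist_HA) > 1e-6
        or abs(check.angle_DHA - probe.angle_DHA) > 1e-6
        or abs(check.angle_HAX - probe.angle_HAX) > 1e-6
    ):
        raise AssertionError("probe construction failed self-verification")
    return topology, frame


def measure_probe(topology: Topology, frame: Frame) -> GeometryProbe:
    """Recompute the probe geometry of a 4-atom [D, H, A, X] system from its
    coordinates (the inverse of :func:`make_geometry_probe_system`)."""
    if topology.n_atoms != 4:
        raise ValueError("probe systems have exactly 4 atoms [D, H, A, X]")
    pos_d, pos_h, pos_a, pos_x = frame.coords

    def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
        u, v = a - b, c - b
        cosine = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))

    return GeometryProbe(
        dist_HA=float(np.linalg.norm(pos_h - pos_a)),
        angle_DHA=angle(pos_d, pos_h, pos_a),
        angle_HAX=angle(pos_h, pos_a, pos_x),
        X_is_hydrogen=topology.atoms[3].element == "H",
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix from a seeded generator."""
    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


# ---------------------------------------------------------------------------
# Fixture builder
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates motifs into one atom table plus per-frame coordinates."""

    def __init__(self, n_frames: int, rng: np.random.Generator) -> None:
        self.n_frames = n_frames
        self.rng = rng
        self.elements: list[str] = []
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.chains: list[str] = []
        self.base_coords: list[np.ndarray] = []
        self.bonds: set[tuple[int, int]] = set()
        # (atom indices, frames_on) for fragments displaced on off-frames
        self.mobiles: list[tuple[list[int], list[bool]]] = []
        self._cursor = 0.0
        self._last_radius = 0.0
        self._placed_any = False

    def _next_site(self, radius: float) -> np.ndarray:
        """Place motifs along x with guaranteed inter-motif clearance.

        Each motif occupies a ball of ``radius`` around its origin for any
        rotation; spacing by the sum of adjacent radii plus a fixed gap
        keeps every inter-motif atom distance >= the gap, far beyond the
        hydrogen-bond horizon.  The off-frame displacement is along z and
        cannot reduce the x separation.
        """
        if not self._placed_any:
            x = 0.0
            self._placed_any = True
        else:
            x = self._cursor + self._last_radius + radius + _SITE_GAP
        self._cursor = x
        self._last_radius = radius
        return np.array([x, 0.0, 0.0])

    def add_motif(
        self,
        atoms: Sequence[tuple[str, str, str, int, str]],  # element,name,resname,resid,chain
        local_coords: np.ndarray,
        local_bonds: Sequence[tuple[int, int]],
        mobile_local: Optional[Sequence[int]] = None,
        frames_on: Optional[Sequence[bool]] = None,
    ) -> list[int]:
        local_coords = np.asarray(local_coords, dtype=float)
        rotation = random_rotation(self.rng)
        radius = float(np.linalg.norm(local_coords, axis=1).max()) if len(local_coords) else 0.0
        origin = self._next_site(radius)
        # Round to PDB coordinate precision so the written file realises the
        # in-memory geometry exactly; manifests record the realised geometry.
        placed = np.round(local_coords @ rotation.T + origin, 3)
        offset = len(self.elements)
        indices = []
        for (element, name, resname, resid, chain), xyz in zip(atoms, placed):
            self.elements.append(element)
            self.names.append(name)
            self.resnames.append(resname)
            self.resids.append(resid)
            self.chains.append(chain)
            self.base_coords.append(np.asarray(xyz, dtype=float))
            indices.append(offset + len(indices))
        for i, j in local_bonds:
            a, b = offset + i, offset + j
            self.bonds.add((min(a, b), max(a, b)))
        if mobile_local is not None:
            if frames_on is None or len(frames_on) != self.n_frames:
                raise ValueError("frames_on must cover every frame")
            self.mobiles.append(
                ([offset + i for i in mobile_local], list(frames_on))
            )
        return indices

    def build(self, snapshot_interval_ns: float) -> tuple[Topology, list[Frame]]:
        atoms = [
            Atom(
                index=i,
                element=self.elements[i],
                name=self.names[i],
                residue_name=self.resnames[i],
                residue_id=self.resids[i],
                chain_id=self.chains[i],
                serial=i + 1,
            )
            for i in range(len(self.elements))
        ]
        topology = Topology(atoms=atoms, covalent_adjacency=set(self.bonds))
        a_idx = [i for i in range(len(atoms)) if self.chains[i] == "A"]
        b_idx = [i for i in range(len(atoms)) if self.chains[i] == "B"]
        topology = topology.with_groups(a_idx, b_idx)

        base = np.array(self.base_coords)
        frames = []
        for f in range(self.n_frames):
            coords = base.copy()
            for indices, frames_on in self.mobiles:
                if not frames_on[f]:
                    coords[indices] += _OFF_DISPLACEMENT
            frames.append(
                Frame(time=f * snapshot_interval_ns * 1000.0, coords=coords)
            )
        return topology, frames


def _unit(angle_deg: float) -> np.ndarray:
    rad = np.radians(angle_deg)
    return np.array([np.cos(rad), np.sin(rad), 0.0])


def _inline_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosine = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def _realized_bond(
    coords: Sequence[np.ndarray],
    d_i: int,
    h_i: int,
    a_i: int,
    xs: Sequence[tuple[int, bool]],
) -> tuple[float, float, float, bool, float]:
    """Realised (dist, DHA, HAX, X-is-H, energy) from emitted coordinates.

    Evaluates every candidate X and keeps the one with the smallest angular
    scale, mirroring the acceptor-X rule; all arithmetic is inline so the
    manifest stays independent of the scoring module.
    """

    def ramp(angle: float, lo: float, hi: float) -> float:
        return min(1.0, max(0.0, (angle - lo) / (hi - lo)))

    dist = float(np.linalg.norm(coords[h_i] - coords[a_i]))
    dha = _inline_angle(coords[d_i], coords[h_i], coords[a_i])
    best: Optional[tuple[float, float, bool]] = None
    for x_i, is_h in xs:
        ang = _inline_angle(coords[h_i], coords[a_i], coords[x_i])
        lo, hi = (75.0, 85.0) if is_h else (85.0, 95.0)
        s = ramp(ang, lo, hi)
        if best is None or s < best[0]:
            best = (s, ang, is_h)
    assert best is not None
    energy = 25.0 * (2.6 - max(dist, 2.1)) / 0.5 * ramp(dha, 100.0, 165.0) * best[0]
    return dist, dha, best[1], best[2], energy


def _add_direct_bond(
    builder: _Builder,
    manifest: FixtureManifest,
    *,
    frames_on: Sequence[bool],
    direction: str,  # "A->B" or "B->A"
    donor_element: str,
    donor_resname: str,
    donor_resid: int,
    acceptor_resname: str,
    acceptor_resid: int,
    x_element: str,
    dist_ha: float = _IDEAL_HA,
    angle_dha: float = 180.0,
    angle_hax: float = 180.0,
    extra_donor_hydrogen: bool = False,
    donor_hydrogens_as_carbon: bool = False,
) -> None:
    """Plant one direct solute–solute bond as a rigid motif.

    The donor fragment (donor heavy, its hydrogen(s) and a carbon parent) is
    the mobile part.  With ``donor_hydrogens_as_carbon`` the hydrogen
    positions are kept but the atoms become carbons — the choline-like
    variant with identical placement and no donor capability (then nothing
    is recorded in the manifest).
    """
    donor_chain, acceptor_chain = ("A", "B") if direction == "A->B" else ("B", "A")
    theta = np.radians(angle_dha)
    phi = np.radians(angle_hax)
    x_bond = 0.96 if x_element == "H" else 1.5

    pos_a = np.zeros(3)
    pos_h = np.array([dist_ha, 0.0, 0.0])
    dir_hd = np.array([-np.cos(theta), np.sin(theta), 0.0])
    pos_d = pos_h + 1.0 * dir_hd
    pos_x = x_bond * np.array([np.cos(phi), -np.sin(phi), 0.0])
    away = pos_d - pos_h
    away = away / np.linalg.norm(away)
    pos_cd = pos_d + 1.43 * away  # carbon parent of the donor heavy atom

    h_element = "C" if donor_hydrogens_as_carbon else "H"
    h_name = "CD1" if donor_hydrogens_as_carbon else "HD1"
    atoms = [
        ("O", "OA1", acceptor_resname, acceptor_resid, acceptor_chain),
        (x_element, "XA1", acceptor_resname, acceptor_resid, acceptor_chain),
        (donor_element, "DN1", donor_resname, donor_resid, donor_chain),
        (h_element, h_name, donor_resname, donor_resid, donor_chain),
        ("C", "CP1", donor_resname, donor_resid, donor_chain),
    ]
    coords = [pos_a, pos_x, pos_d, pos_h, pos_cd]
    bonds = [(0, 1), (2, 3), (2, 4)]
    mobile = [2, 3, 4]
    if extra_donor_hydrogen:
        h2_element = "C" if donor_hydrogens_as_carbon else "H"
        h2_name = "CD2" if donor_hydrogens_as_carbon else "HD2"
        atoms.append((h2_element, h2_name, donor_resname, donor_resid, donor_chain))
        coords.append(pos_d + np.array([0.0, 0.0, 1.0]))
        bonds.append((2, 5))
        mobile.append(5)
    indices = builder.add_motif(
        atoms, np.array(coords), bonds, mobile_local=mobile, frames_on=frames_on
    )

    if donor_hydrogens_as_carbon:
        return  # no donor capability -> nothing planted

    # manifest truth from the realised (file-precision) coordinates
    placed = [builder.base_coords[i] for i in indices]
    r_dist, r_dha, r_hax, r_x_is_h, r_energy = _realized_bond(
        placed, d_i=2, h_i=3, a_i=0, xs=[(1, x_element == "H")]
    )

    donor_label = f"{donor_resname}{donor_resid}:DN1"
    hydrogen_label = f"{donor_resname}{donor_resid}:HD1"
    acceptor_label = f"{acceptor_resname}{acceptor_resid}:OA1"
    pair = (
        (donor_label, acceptor_label)
        if direction == "A->B"
        else (acceptor_label, donor_label)
    )
    manifest.planted_hbonds.append(
        PlantedBond(
            donor_label=donor_label,
            hydrogen_label=hydrogen_label,
            acceptor_label=acceptor_label,
            pair_a_label=pair[0],
            pair_b_label=pair[1],
            direction=direction,
            dist_HA=r_dist,
            angle_DHA=r_dha,
            angle_HAX=r_hax,
            X_is_hydrogen=r_x_is_h,
            expected_energy=r_energy,
            frames_on=list(frames_on),
        )
    )


def _add_bridge(
    builder: _Builder,
    manifest: FixtureManifest,
    *,
    frames_on: Sequence[bool],
    water_resid: int,
    a_resname: str,
    a_resid: int,
    b_resname: str,
    b_resid: int,
    water_accepts_from_a: bool = False,
) -> None:
    """Plant one water bridge as a rigid motif.

    Default: the water donates one hydrogen to an acceptor on each solute
    (both legs at optimum geometry).  With ``water_accepts_from_a`` the
    A-side leg is reversed: a solute hydroxyl donates into the water oxygen
    along its lone-pair direction (both water hydrogens then sit at
    127.74 degrees from the incoming hydrogen, so the hydrogen-X scale is
    on its plateau and the leg is still at optimum energy).
    """
    half = _WATER_HOH / 2.0
    u1, u2 = _unit(half), _unit(-half)
    pos_ow = np.zeros(3)
    pos_h1 = _WATER_OH * u1
    pos_h2 = _WATER_OH * u2

    atoms = [
        ("O", "O", "HOH", water_resid, "W"),
        ("H", "H1", "HOH", water_resid, "W"),
        ("H", "H2", "HOH", water_resid, "W"),
    ]
    coords = [pos_ow, pos_h1, pos_h2]
    bonds = [(0, 1), (0, 2)]

    # B-side leg: water H2 donates to an acceptor O backed by a phosphorus.
    pos_accb = pos_h2 + _IDEAL_HA * u2
    pos_xb = pos_accb + 1.5 * u2
    atoms += [
        ("O", "OB1", b_resname, b_resid, "B"),
        ("P", "PB1", b_resname, b_resid, "B"),
    ]
    coords += [pos_accb, pos_xb]
    bonds.append((3, 4))
    b_label = f"{b_resname}{b_resid}:OB1"

    if water_accepts_from_a:
        # Solute hydroxyl donates into the water oxygen from the -x side.
        pos_ha = np.array([-_IDEAL_HA, 0.0, 0.0])
        pos_da = np.array([-(_IDEAL_HA + 1.0), 0.0, 0.0])
        pos_ca = np.array([-(_IDEAL_HA + 1.0 + 1.43), 0.0, 0.0])
        atoms += [
            ("O", "OA1", a_resname, a_resid, "A"),
            ("H", "HA1", a_resname, a_resid, "A"),
            ("C", "CA1", a_resname, a_resid, "A"),
        ]
        coords += [pos_da, pos_ha, pos_ca]
        bonds += [(5, 6), (5, 7)]
        a_label = f"{a_resname}{a_resid}:OA1"
    else:
        # A-side leg mirrors the B side: water H1 donates to a carboxylate O.
        pos_acca = pos_h1 + _IDEAL_HA * u1
        pos_xa = pos_acca + 1.5 * u1
        atoms += [
            ("O", "OA1", a_resname, a_resid, "A"),
            ("C", "CA1", a_resname, a_resid, "A"),
        ]
        coords += [pos_acca, pos_xa]
        bonds.append((5, 6))
        a_label = f"{a_resname}{a_resid}:OA1"

    indices = builder.add_motif(
        atoms,
        np.array(coords),
        bonds,
        mobile_local=[0, 1, 2],  # the water is the mobile part
        frames_on=frames_on,
    )

    # realised leg energies from the emitted coordinates
    placed = [builder.base_coords[i] for i in indices]
    if water_accepts_from_a:
        # solute O-H donates into the water oxygen; X = nearer water H
        *_, leg_a_energy = _realized_bond(
            placed, d_i=5, h_i=6, a_i=0, xs=[(1, True), (2, True)]
        )
    else:
        *_, leg_a_energy = _realized_bond(
            placed, d_i=0, h_i=1, a_i=5, xs=[(6, False)]
        )
    *_, leg_b_energy = _realized_bond(placed, d_i=0, h_i=2, a_i=3, xs=[(4, False)])

    manifest.planted_bridges.append(
        PlantedBridge(
            water_label=f"HOH{water_resid}",
            a_atom_label=a_label,
            b_atom_label=b_label,
            leg_a_energy=leg_a_energy,
            leg_b_energy=leg_b_energy,
            frames_on=list(frames_on),
        )
    )


def _add_decoys(builder: _Builder, far_pair: bool = True, bad_angle: bool = True) -> None:
    """Non-bonding atoms exercising every empty-result path.

    Methane (no polar atoms), a bare sodium ion, a donor/acceptor pair 8 A
    apart (outside the 2.6 A horizon) and a pair at hydrogen-bonding
    distance but with a 90-degree donor angle (zero angular scale).
    """
    # methane
    tet = np.array(
        [[0, 0, 0], [1.09, 0, 0], [-0.36, 1.03, 0], [-0.36, -0.51, 0.89],
         [-0.36, -0.51, -0.89]]
    )
    builder.add_motif(
        [("C", "C1", "MTH", 901, "D")] + [("H", f"H{i}", "MTH", 901, "D") for i in range(1, 5)],
        tet,
        [(0, i) for i in range(1, 5)],
    )
    # sodium ion (group "other"; never a donor or acceptor)
    builder.add_motif([("NA", "NA", "NA", 902, "D")], np.zeros((1, 3)), [])
    if far_pair:
        # hydroxyl and carbonyl 8 A apart: the distance prefilter removes it
        builder.add_motif(
            [
                ("O", "OF1", "GFD", 7, "A"),
                ("H", "HF1", "GFD", 7, "A"),
                ("C", "CF1", "GFD", 7, "A"),
                ("O", "OF2", "LFD", 107, "B"),
                ("C", "CF2", "LFD", 107, "B"),
            ],
            np.array(
                [[0, 0, 0], [0.96, 0, 0], [-1.43, 0, 0],
                 [8.96, 0, 0], [10.46, 0, 0]]
            ),
            [(0, 1), (0, 2), (3, 4)],
        )
    if bad_angle:
        # donor-hydrogen-acceptor angle of 90 degrees: energy is exactly 0
        builder.add_motif(
            [
                ("O", "OZ1", "GZD", 8, "A"),
                ("H", "HZ1", "GZD", 8, "A"),
                ("C", "CZ1", "GZD", 8, "A"),
                ("O", "OZ2", "LZD", 108, "B"),
                ("C", "CZ2", "LZD", 108, "B"),
            ],
            np.array(
                [[0, 1.0, 0], [0, 0, 0], [0, 2.43, 0],
                 [2.0, 0, 0], [3.5, 0, 0]]
            ),
            [(0, 1), (0, 2), (3, 4)],
        )


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def _scenario_bridge_basic(builder: _Builder, manifest: FixtureManifest) -> None:
    """Two direct bonds, two bridges (one with the water as acceptor on the
    A side), full decoy set; several interactions toggle over the frames."""
    _add_direct_bond(
        builder, manifest, frames_on=[True] * 5, direction="A->B",
        donor_element="O", donor_resname="GOH", donor_resid=1,
        acceptor_resname="LPO", acceptor_resid=101, x_element="P",
    )
    _add_direct_bond(
        builder, manifest, frames_on=[True, True, True, False, False],
        direction="B->A", donor_element="N", donor_resname="LEA",
        donor_resid=102, acceptor_resname="GCO", acceptor_resid=2,
        x_element="C", dist_ha=2.3, angle_dha=150.0, angle_hax=120.0,
        extra_donor_hydrogen=True,
    )
    _add_bridge(
        builder, manifest, frames_on=[True] * 5, water_resid=201,
        a_resname="GCO", a_resid=3, b_resname="LPO", b_resid=103,
    )
    _add_bridge(
        builder, manifest, frames_on=[True, False, False, True, True],
        water_resid=202, a_resname="GOH", a_resid=4, b_resname="LPO",
        b_resid=104, water_accepts_from_a=True,
    )
    _add_decoys(builder)


def _scenario_no_donors_on_b(builder: _Builder, manifest: FixtureManifest) -> None:
    """Choline-like solute B: polar nitrogen but no polar hydrogens, so B can
    never act as a donor; A-side donors and one bridge still work."""
    _add_direct_bond(
        builder, manifest, frames_on=[True] * 3, direction="A->B",
        donor_element="O", donor_resname="GOH", donor_resid=1,
        acceptor_resname="LPO", acceptor_resid=101, x_element="P",
    )
    # choline-like head: geometry of an N-H donor pair, hydrogens -> carbons
    _add_direct_bond(
        builder, manifest, frames_on=[True] * 3, direction="B->A",
        donor_element="N", donor_resname="LCH", donor_resid=102,
        acceptor_resname="GCO", acceptor_resid=2, x_element="C",
        extra_donor_hydrogen=True, donor_hydrogens_as_carbon=True,
    )
    _add_bridge(
        builder, manifest, frames_on=[True] * 3, water_resid=201,
        a_resname="GCO", a_resid=3, b_resname="LPO", b_resid=103,
    )
    _add_decoys(builder)


def _scenario_headgroup(donors: bool):
    """Matched ethanolamine-like / choline-like scenario pair.

    Identical motif layout and placement stream; the only difference is
    whether the B headgroup nitrogen carries hydrogens (ethanolamine-like)
    or carbons at the same positions (choline-like).  The donor-capable
    variant therefore forms strictly more distinct bonded sites.
    """

    def build(builder: _Builder, manifest: FixtureManifest) -> None:
        _add_direct_bond(
            builder, manifest, frames_on=[True] * 4, direction="A->B",
            donor_element="O", donor_resname="GOH", donor_resid=1,
            acceptor_resname="LPO", acceptor_resid=101, x_element="P",
        )
        _add_direct_bond(
            builder, manifest, frames_on=[True] * 4, direction="B->A",
            donor_element="N", donor_resname="LHG", donor_resid=102,
            acceptor_resname="GCO", acceptor_resid=2, x_element="C",
            extra_donor_hydrogen=True, donor_hydrogens_as_carbon=not donors,
        )
        _add_direct_bond(
            builder, manifest, frames_on=[True] * 4, direction="A->B",
            donor_element="O", donor_resname="GOH", donor_resid=5,
            acceptor_resname="LPO", acceptor_resid=105, x_element="P",
        )
        _add_decoys(builder)

    return build


SCENARIOS = {
    "bridge_basic": (_scenario_bridge_basic, 5),
    "no_donors_on_B": (_scenario_no_donors_on_b, 3),
    "ethanolamine_B": (_scenario_headgroup(donors=True), 4),
    "choline_B": (_scenario_headgroup(donors=False), 4),
}


def generate_fixture(
    scenario: str,
    out_path: str | Path,
    seed: int,
    snapshot_interval_ns: float = 0.1,
) -> tuple[Path, FixtureManifest]:
    """Write a multi-model PDB fixture plus its JSON manifest.

    Returns the PDB path and the manifest; the manifest is also written to
    ``<out_path stem>.manifest.json``.  Output is reproducible bit-for-bit
    from the seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
        )
    build, n_frames = SCENARIOS[scenario]
    rng = np.random.default_rng(seed)
    builder = _Builder(n_frames=n_frames, rng=rng)
    manifest = FixtureManifest(
        scenario=scenario,
        rng_seed=seed,
        snapshot_interval_ns=snapshot_interval_ns,
        n_frames=n_frames,
    )
    build(builder, manifest)
    topology, frames = builder.build(snapshot_interval_ns)

    out_path = Path(out_path)
    write_pdb_trajectory(out_path, topology, frames)
    manifest.to_json(out_path.with_suffix(".manifest.json"))
    return out_path, manifest


def generate_kinetic_trajectory(
    patterns: Sequence[str],
    snapshot_interval_ns: float,
    seed: int,
    out_path: str | Path,
) -> tuple[Path, FixtureManifest]:
    """Fixture trajectory with one ideal bond per on/off pattern string.

    Each pattern (e.g. ``"1110011100"``) controls one planted A→B bond:
    on '0' frames its donor fragment is displaced out of bonding range, so
    occupancy statistics must recover the pattern exactly.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    n_frames = len(patterns[0])
    if any(len(p) != n_frames for p in patterns):
        raise ValueError("all patterns must have the same length")
    if any(set(p) - {"0", "1"} for p in patterns):
        raise ValueError("patterns must be strings of '0' and '1'")

    rng = np.random.default_rng(seed)
    builder = _Builder(n_frames=n_frames, rng=rng)
    manifest = FixtureManifest(
        scenario="kinetic",
        rng_seed=seed,
        snapshot_interval_ns=snapshot_interval_ns,
        n_frames=n_frames,
    )
    for k, pattern in enumerate(patterns):
        _add_direct_bond(
            builder, manifest,
            frames_on=[c == "1" for c in pattern],
            direction="A->B", donor_element="O", donor_resname="GOH",
            donor_resid=k + 1, acceptor_resname="LPO",
            acceptor_resid=101 + k, x_element="P",
        )
    _add_decoys(builder, far_pair=False, bad_angle=False)

    topology, frames = builder.build(snapshot_interval_ns)
    out_path = Path(out_path)
    write_pdb_trajectory(out_path, topology, frames)
    manifest.to_json(out_path.with_suffix(".manifest.json"))
    return out_path, manifest
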