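"""Shared fixtures and the independent brute-force hydrogen-bond scorer."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pytest

from hydrobridge.model import Atom, Frame, PolarRoles, Topology
from hydrobridge.energy import HBondParams


# ---------------------------------------------------------------------------
# Brute-force oracle: scores every (donor hydrogen, acceptor) pair directly
# from the defining formulas, with no spatial prefilter and no shared code
# with the detection path.
# ---------------------------------------------------------------------------


def _brute_angle(a, b, c) -> float:
    ux, uy, uz = a[0] - b[0], a[1] - b[1], a[2] - b[2]
    vx, vy, vz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    dot = ux * vx + uy * vy + uz * vz
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (nu * nv)))))


def brute_force_detect(
    topology: Topology,
    frame: Frame,
    roles: PolarRoles,
    params: HBondParams = HBondParams(),
) -> set[tuple[int, int, int]]:
    """All above-threshold (donor_heavy, hydrogen, acceptor) triples."""
    coords = frame.coords
    neighbor = topology.neighbor_table()
    elements = [a.element for a in topology.atoms]
    found: set[tuple[int, int, int]] = set()
    for heavy, hydrogen in roles.donors:
        for acceptor in roles.acceptors:
            if acceptor == heavy:
                continue
            d = math.dist(coords[hydrogen], coords[acceptor])
            if d == 0.0:
                continue
            alpha = _brute_angle(coords[heavy], coords[hydrogen], coords[acceptor])
            lo, hi = params.dha_ramp
            s1 = max(0.0, min(1.0, (alpha - lo) / (hi - lo)))
            s2 = 1.0
            for x in neighbor[acceptor]:
                beta = _brute_angle(coords[hydrogen], coords[acceptor], coords[x])
                xlo, xhi = (
                    params.hax_hydrogen_ramp
                    if elements[x] == "H"
                    else params.hax_heavy_ramp
                )
                s = max(0.0, min(1.0, (beta - xlo) / (xhi - xlo)))
                s2 = min(s2, s)
            energy = (
                params.optimum_energy
                * (params.d_zero - max(d, params.d_clamp))
                / (params.d_zero - params.d_clamp)
                * s1
                * s2
            )
            if energy > params.threshold_energy:
                found.add((heavy, hydrogen, acceptor))
    return found


def brute_force_energies(
    topology: Topology,
    frame: Frame,
    roles: PolarRoles,
    params: HBondParams = HBondParams(),
) -> dict[tuple[int, int, int], float]:
    """Energies of the brute-force detections (same enumeration)."""
    coords = frame.coords
    neighbor = topology.neighbor_table()
    elements = [a.element for a in topology.atoms]
    out: dict[tuple[int, int, int], float] = {}
    for heavy, hydrogen, acceptor in brute_force_detect(
        topology, frame, roles, params
    ):
        d = math.dist(coords[hydrogen], coords[acceptor])
        alpha = _brute_angle(coords[heavy], coords[hydrogen], coords[acceptor])
        lo, hi = params.dha_ramp
        s1 = max(0.0, min(1.0, (alpha - lo) / (hi - lo)))
        s2 = 1.0
        for x in neighbor[acceptor]:
            beta = _brute_angle(coords[hydrogen], coords[acceptor], coords[x])
            xlo, xhi = (
                params.hax_hydrogen_ramp
                if elements[x] == "H"
                else params.hax_heavy_ramp
            )
            s2 = min(s2, max(0.0, min(1.0, (beta - xlo) / (xhi - xlo))))
        out[(heavy, hydrogen, acceptor)] = (
            params.optimum_energy
            * (params.d_zero - max(d, params.d_clamp))
            / (params.d_zero - params.d_clamp)
            * s1
            * s2
        )
    return out


# ---------------------------------------------------------------------------
# Randomised small systems for oracle-equivalence checks
# ---------------------------------------------------------------------------


def random_small_system(rng: np.random.Generator) -> tuple[Topology, Frame]:
    """A random <=50-atom system with valid adjacency and mixed elements.

    Heavy atoms are scattered in a tight box so some pairs fall inside the
    bonding horizon; each hydrogen is attached to one random heavy atom at
    ~1 A so donor pairs exist by construction.
    """
    n_heavy = int(rng.integers(4, 16))
    n_h = int(rng.integers(2, min(12, 50 - n_heavy)))
    heavy_elements = rng.choice(["C", "N", "O", "S", "P"], size=n_heavy)
    box = 7.0
    heavy_coords = rng.uniform(0, box, size=(n_heavy, 3))

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    adjacency: set[tuple[int, int]] = set()
    for i in range(n_heavy):
        atoms.append(
            Atom(i, str(heavy_elements[i]), f"X{i}", "RND", 1 + i // 4, "A", i + 1)
        )
        coords.append(heavy_coords[i])
    # a few heavy-heavy bonds so acceptors have X partners
    n_bonds = int(rng.integers(1, n_heavy))
    for _ in range(n_bonds):
        i, j = rng.integers(0, n_heavy, size=2)
        if i != j:
            adjacency.add((min(int(i), int(j)), max(int(i), int(j))))
    for k in range(n_h):
        idx = n_heavy + k
        parent = int(rng.integers(0, n_heavy))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        atoms.append(Atom(idx, "H", f"H{k}", "RND", 1 + parent // 4, "A", idx + 1))
        coords.append(heavy_coords[parent] + 1.0 * direction)
        adjacency.add((parent, idx))

    topology = Topology(atoms=atoms, covalent_adjacency=adjacency)
    return topology, Frame(time=0.0, coords=np.array(coords))


@pytest.fixture(scope="session")
def bridge_basic(tmp_path_factory):
    """Generated bridge_basic fixture, read back and fully grouped."""
    from hydrobridge.model import classify_polar_roles, read_pdb_trajectory
    from hydrobridge.pipeline import parse_selection
    from hydrobridge.synthetic import generate_fixture

    path = tmp_path_factory.mktemp("fixtures") / "bridge_basic.pdb"
    pdb_path, manifest = generate_fixture("bridge_basic", path, seed=7)
    topology, frames = read_pdb_trajectory(pdb_path)
    topology = topology.with_groups(
        parse_selection("chain A", topology), parse_selection("chain B", topology)
    )
    roles = classify_polar_roles(topology)

    @dataclass
    class _Fixture:
        path: object
        manifest: object
        topology: Topology
        frames: list
        roles: PolarRoles

    return _Fixture(pdb_path, manifest, topology, frames, roles)


def detect_per_frame(fx, between=("solute_A", "solute_B")):
    """Per-frame solute-solute and water-mediated detections for a fixture."""
    from hydrobridge.bridges import find_water_bridges
    from hydrobridge.energy import detect_hbonds

    per_frame_ab, per_frame_water = [], []
    for frame in fx.frames:
        per_frame_ab.append(
            detect_hbonds(fx.topology, frame, fx.roles, between=between)
        )
        wa = detect_hbonds(
            fx.topology, frame, fx.roles, between=("water", "solute_A")
        )
        wb = detect_hbonds(
            fx.topology, frame, fx.roles, between=("water", "solute_B")
        )
        per_frame_water.append(list(wa) + list(wb))
    bridges = find_water_bridges(per_frame_water, fx.topology)
    return per_frame_ab, bridges
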