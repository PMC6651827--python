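"""Molecular domain model: atoms, topologies, frames and multi-model PDB I/O.

The package analyses snapshot trajectories stored as multi-model PDB files
(one ``MODEL``/``ENDMDL`` block per frame).  This module provides the domain
types every other module consumes:

* :class:`Atom` — immutable atom record (element, name, residue identity).
* :class:`Topology` — the fixed atom table plus covalent adjacency and a
  named partition of atoms into ``solute_A`` / ``solute_B`` / ``water`` /
  ``other`` groups.
* :class:`Frame` — per-snapshot coordinates.
* :class:`PolarRoles` — donor (heavy, hydrogen) pairs and acceptor atoms.

File parsing is delegated to :mod:`biotite.structure.io.pdb`; this module
adds the trajectory-level contracts (constant atom table across models,
structured errors naming the offending model), CONECT handling and
water/ion recognition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "PolarRoles",
    "PdbParseError",
    "DEFAULT_WATER_ALIASES",
    "POLAR_ELEMENTS",
    "COVALENT_RADII",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "infer_covalent_bonds",
    "classify_polar_roles",
]

#: Residue names recognised as explicit water (common MD dialects).
DEFAULT_WATER_ALIASES: tuple[str, ...] = ("HOH", "WAT", "SOL", "TIP3", "TIP", "SPC")

#: Residue names recognised as monatomic ions; assigned to the ``other``
#: group and excluded from hydrogen-bond analysis.
ION_RESIDUES: tuple[str, ...] = ("NA", "CL", "K", "MG", "CA", "ZN")

#: Default polar-element set for donor/acceptor classification.
POLAR_ELEMENTS: frozenset[str] = frozenset({"N", "O", "S"})

#: Single-bond covalent radii in Angstrom (Cordero et al. consensus values),
#: used for distance-based bond inference.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "CL": 1.02,
    "NA": 1.66,
    "K": 2.03,
    "MG": 1.41,
    "CA": 1.76,
    "ZN": 1.22,
}

GROUP_NAMES: tuple[str, ...] = ("solute_A", "solute_B", "water", "other")


class PdbParseError(ValueError):
    """Structured parse failure for a trajectory PDB file."""


@dataclass(frozen=True)
class Atom:
    """One atom of the fixed topology.

    ``index`` is the 0-based position in the atom table; ``serial`` preserves
    the PDB atom serial for reporting.  Coordinates live in :class:`Frame`.
    """

    index: int
    element: str
    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    serial: int

    @property
    def label(self) -> str:
        """Human-readable site label, e.g. ``"HOH7:O"``."""
        return f"{self.residue_name}{self.residue_id}:{self.name}"


@dataclass(frozen=True)
class Frame:
    """Coordinates of one trajectory snapshot (Angstrom)."""

    time: float  # picoseconds; frame ordinal if the source carries no clock
    coords: np.ndarray  # (n_atoms, 3) float64

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("frame coordinates must be finite")
        object.__setattr__(self, "coords", coords)


@dataclass
class Topology:
    """Fixed atom table with covalent adjacency and named groups.

    ``covalent_adjacency`` is a set of ``(i, j)`` index pairs with ``i < j``.
    ``groups`` is a partition of all atom indices into the four canonical
    group names; atoms start in ``other`` until selections are applied.
    """

    atoms: list[Atom]
    covalent_adjacency: set[tuple[int, int]] = field(default_factory=set)
    groups: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = {name: frozenset() for name in GROUP_NAMES}
            self.groups["other"] = frozenset(range(len(self.atoms)))
        self._check_partition()
        for i, j in self.covalent_adjacency:
            if i == j:
                raise ValueError(f"covalent adjacency contains self-pair ({i},{i})")

    def _check_partition(self) -> None:
        seen: set[int] = set()
        for name, members in self.groups.items():
            if name not in GROUP_NAMES:
                raise ValueError(f"unknown group name {name!r}")
            if seen & members:
                raise ValueError("atom groups are not disjoint")
            seen |= members
        if seen != set(range(len(self.atoms))):
            raise ValueError("atom groups do not cover every atom exactly once")

    # -- convenience accessors -------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, index: int) -> list[int]:
        """Covalent partners of one atom."""
        out = []
        for i, j in self.covalent_adjacency:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return sorted(out)

    def neighbor_table(self) -> dict[int, list[int]]:
        table: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for i, j in self.covalent_adjacency:
            table[i].append(j)
            table[j].append(i)
        return table

    def group_of(self, index: int) -> str:
        for name, members in self.groups.items():
            if index in members:
                return name
        raise KeyError(index)

    def group_lookup(self) -> dict[int, str]:
        lookup: dict[int, str] = {}
        for name, members in self.groups.items():
            for i in members:
                lookup[i] = name
        return lookup

    def residue_key(self, index: int) -> tuple[str, int, str]:
        a = self.atoms[index]
        return (a.chain_id, a.residue_id, a.residue_name)

    def with_groups(
        self,
        solute_a: Iterable[int],
        solute_b: Iterable[int],
        water_aliases: Sequence[str] = DEFAULT_WATER_ALIASES,
    ) -> "Topology":
        """Return a copy with ``solute_A``/``solute_B`` assigned and waters
        recognised by residue name; everything else goes to ``other``.

        Solute selections must be disjoint and must not claim water atoms.
        """
        a_set = frozenset(solute_a)
        b_set = frozenset(solute_b)
        if a_set & b_set:
            raise ValueError("solute_A and solute_B selections overlap")
        water = frozenset(_water_atoms(self.atoms, water_aliases)) - a_set - b_set
        other = frozenset(range(self.n_atoms)) - a_set - b_set - water
        return replace(
            self,
            groups={
                "solute_A": a_set,
                "solute_B": b_set,
                "water": water,
                "other": other,
            },
        )


@dataclass(frozen=True)
class PolarRoles:
    """Donor (heavy, hydrogen) pairs and acceptor heavy atoms."""

    donors: frozenset[tuple[int, int]]
    acceptors: frozenset[int]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _water_atoms(atoms: Sequence[Atom], aliases: Sequence[str]) -> set[int]:
    """Atoms of residues that match a water alias AND have 1 O + 2 H."""
    alias_set = {a.upper() for a in aliases}
    residues: dict[tuple[str, int, str], list[Atom]] = {}
    for atom in atoms:
        if atom.residue_name.upper() in alias_set:
            residues.setdefault(
                (atom.chain_id, atom.residue_id, atom.residue_name), []
            ).append(atom)
    out: set[int] = set()
    for key, members in residues.items():
        elements = sorted(a.element for a in members)
        if elements == ["H", "H", "O"]:
            out.update(a.index for a in members)
        else:
            warnings.warn(
                f"residue {key} matches a water alias but is not O+2H; "
                "leaving it in group 'other'",
                stacklevel=3,
            )
    return out


def _infer_element(name: str, residue_name: str) -> str:
    """Best-effort element from an atom name when the element column is blank."""
    stripped = name.strip().upper()
    if residue_name.strip().upper() in ION_RESIDUES and stripped in COVALENT_RADII:
        return stripped
    if stripped[:2] in ("CL", "NA", "MG", "ZN") and stripped[:2] == residue_name.strip().upper():
        return stripped[:2]
    for ch in stripped:
        if ch.isalpha():
            return ch
    return ""


def _scan_model_atom_counts(lines: Sequence[str]) -> list[int]:
    """Per-MODEL ATOM/HETATM record counts (single implicit model if none)."""
    counts: list[int] = []
    in_model = False
    current = 0
    implicit = 0
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if in_model:
                current += 1
            else:
                implicit += 1
    if not counts:
        counts = [implicit]
    return counts


def read_pdb_trajectory(
    path: str | Path,
    water_aliases: Sequence[str] = DEFAULT_WATER_ALIASES,
    bond_tolerance: float = 0.15,
) -> tuple[Topology, list[Frame]]:
    """Read a multi-model PDB trajectory.

    Returns the fixed :class:`Topology` (waters recognised by residue name,
    everything else in ``other`` until selections are applied) and one
    :class:`Frame` per MODEL.  CONECT records, when present, define the
    covalent adjacency; otherwise bonds are inferred from the first frame
    with :func:`infer_covalent_bonds`.

    Raises
    ------
    PdbParseError
        If the file is missing, has inconsistent atom counts across models
        (the error names the 1-based model index), or contains an atom whose
        element cannot be determined.
    """
    path = Path(path)
    if not path.is_file():
        raise PdbParseError(f"trajectory file not found: {path}")
    lines = path.read_text().splitlines()

    counts = _scan_model_atom_counts(lines)
    if counts[0] == 0:
        raise PdbParseError(f"{path}: no ATOM/HETATM records found")
    for k, count in enumerate(counts, start=1):
        if count != counts[0]:
            raise PdbParseError(
                f"{path}: model {k} has {count} atoms, expected {counts[0]} "
                f"(model 1); atom table must be constant across models"
            )

    pdb_file = _pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None, extra_fields=["atom_id"])
    if isinstance(stack, struc.AtomArray):  # single implicit model
        stack = struc.stack([stack])

    n = stack.array_length()
    atoms: list[Atom] = []
    for i in range(n):
        element = str(stack.element[i]).strip().upper()
        name = str(stack.atom_name[i]).strip()
        resname = str(stack.res_name[i]).strip()
        if not element:
            element = _infer_element(name, resname)
        if element not in COVALENT_RADII:
            raise PdbParseError(
                f"{path}: cannot determine element of atom "
                f"serial {int(stack.atom_id[i])} name {name!r} residue {resname!r}"
            )
        atoms.append(
            Atom(
                index=i,
                element=element,
                name=name,
                residue_name=resname,
                residue_id=int(stack.res_id[i]),
                chain_id=str(stack.chain_id[i]).strip() or "A",
                serial=int(stack.atom_id[i]),
            )
        )

    # PDB coordinates carry exactly 3 decimals; rounding after the float32
    # parse restores the printed decimal values exactly in float64.
    frames = [
        Frame(time=float(m), coords=np.round(np.array(stack.coord[m], dtype=float), 3))
        for m in range(stack.stack_depth())
    ]

    adjacency = _read_conect(lines, atoms)
    topology = Topology(atoms=atoms, covalent_adjacency=set())
    if adjacency:
        topology.covalent_adjacency = adjacency
    else:
        topology.covalent_adjacency = infer_covalent_bonds(
            topology, frames[0], tolerance=bond_tolerance
        )

    water = frozenset(_water_atoms(atoms, water_aliases))
    other = frozenset(range(n)) - water
    topology.groups = {
        "solute_A": frozenset(),
        "solute_B": frozenset(),
        "water": water,
        "other": other,
    }
    return topology, frames


def _read_conect(lines: Sequence[str], atoms: Sequence[Atom]) -> set[tuple[int, int]]:
    serial_to_index = {a.serial: a.index for a in atoms}
    pairs: set[tuple[int, int]] = set()
    for line in lines:
        if not line.startswith("CONECT"):
            continue
        fields = [line[6:11], line[11:16], line[16:21], line[21:26], line[26:31]]
        serials = [int(f) for f in fields if f.strip()]
        if len(serials) < 2:
            continue
        center = serial_to_index.get(serials[0])
        if center is None:
            continue
        for s in serials[1:]:
            partner = serial_to_index.get(s)
            if partner is None or partner == center:
                continue
            pairs.add((min(center, partner), max(center, partner)))
    return pairs


def write_pdb_trajectory(
    path: str | Path,
    topology: Topology,
    frames: Sequence[Frame],
    write_conect: bool = True,
) -> None:
    """Write a multi-model PDB (one MODEL per frame) in the reader's dialect.

    Coordinates are written at PDB precision (3 decimals); CONECT records
    mirror the topology's covalent adjacency so a round-trip restores it.
    """
    if not frames:
        raise ValueError("cannot write a trajectory with zero frames")
    n = topology.n_atoms
    for k, frame in enumerate(frames):
        if frame.coords.shape[0] != n:
            raise ValueError(
                f"frame {k} has {frame.coords.shape[0]} coordinates, "
                f"topology has {n} atoms"
            )

    array = struc.AtomArray(n)
    array.coord = np.zeros((n, 3))
    for a in topology.atoms:
        array.chain_id[a.index] = a.chain_id
        array.res_id[a.index] = a.residue_id
        array.res_name[a.index] = a.residue_name
        array.atom_name[a.index] = a.name
        array.element[a.index] = a.element
        array.hetero[a.index] = True
    array.set_annotation("atom_id", np.array([a.serial for a in topology.atoms]))

    stack = struc.stack([array] * len(frames))
    stack.coord = np.stack([f.coords for f in frames]).astype(np.float32)

    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))

    # Biotite omits CONECT for residues in the chemical component dictionary
    # (e.g. HOH), so the full adjacency is appended explicitly: one record
    # per bonded atom, at most four partners per line.
    if write_conect and topology.covalent_adjacency:
        serial = {a.index: a.serial for a in topology.atoms}
        conect_lines = []
        for i, partners in sorted(topology.neighbor_table().items()):
            if not partners:
                continue
            for start in range(0, len(partners), 4):
                chunk = partners[start : start + 4]
                fields = "".join(f"{serial[j]:5d}" for j in [i] + chunk)
                conect_lines.append(f"CONECT{fields}")
        lines = Path(path).read_text().splitlines()
        lines = [
            ln for ln in lines if ln[:6].strip() not in ("CONECT", "END", "MASTER")
        ]
        Path(path).write_text("\n".join(lines + conect_lines + ["END"]) + "\n")


# ---------------------------------------------------------------------------
# Covalent bond inference and polar-role classification
# ---------------------------------------------------------------------------


def infer_covalent_bonds(
    topology: Topology, frame: Frame, tolerance: float = 0.15
) -> set[tuple[int, int]]:
    """Distance-based covalent adjacency.

    A pair ``(i, j)`` is bonded iff the distance does not exceed the sum of
    single-bond covalent radii scaled by ``1 + tolerance``.  Hydrogens keep
    exactly one partner (the nearest heavy atom); a hydrogen with no partner
    within the cutoff triggers a warning and ends up unbonded, which excludes
    it from donor classification downstream.
    """
    from scipy.spatial import cKDTree

    coords = frame.coords
    if coords.shape[0] != topology.n_atoms:
        raise ValueError("frame does not match topology atom count")
    radii = np.array([COVALENT_RADII[a.element] for a in topology.atoms])
    max_cut = 2.0 * radii.max() * (1.0 + tolerance)
    tree = cKDTree(coords)
    candidate_pairs = tree.query_pairs(max_cut, output_type="ndarray")

    pairs: set[tuple[int, int]] = set()
    h_partners: dict[int, list[tuple[float, int]]] = {}
    is_h = np.array([a.element == "H" for a in topology.atoms])
    for i, j in candidate_pairs:
        i, j = int(i), int(j)
        if is_h[i] and is_h[j]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > (radii[i] + radii[j]) * (1.0 + tolerance):
            continue
        if is_h[i]:
            h_partners.setdefault(i, []).append((d, j))
        elif is_h[j]:
            h_partners.setdefault(j, []).append((d, i))
        else:
            pairs.add((min(i, j), max(i, j)))

    for h, partners in h_partners.items():
        _, best = min(partners)
        pairs.add((min(h, best), max(h, best)))
    for h in np.nonzero(is_h)[0]:
        if int(h) not in h_partners:
            warnings.warn(
                f"hydrogen atom index {int(h)} "
                f"({topology.atoms[int(h)].label}) has no covalent partner "
                "within the cutoff; it will not act as a donor hydrogen",
                stacklevel=2,
            )
    return pairs


def classify_polar_roles(
    topology: Topology, polar_elements: frozenset[str] = POLAR_ELEMENTS
) -> PolarRoles:
    """Donor (heavy, H) pairs and acceptor atoms from the covalent adjacency.

    Donors are polar heavy atoms with at least one bonded hydrogen (one pair
    per hydrogen); acceptors are all polar heavy atoms.  A water oxygen is
    therefore both a donor heavy atom (twice) and an acceptor.
    """
    if not topology.covalent_adjacency:
        raise ValueError(
            "covalent adjacency is empty; run infer_covalent_bonds first"
        )
    donors: set[tuple[int, int]] = set()
    for i, j in topology.covalent_adjacency:
        ai, aj = topology.atoms[i], topology.atoms[j]
        if ai.element == "H" and aj.element in polar_elements:
            donors.add((j, i))
        elif aj.element == "H" and ai.element in polar_elements:
            donors.add((i, j))
    acceptors = frozenset(
        a.index for a in topology.atoms if a.element in polar_elements
    )
    return PolarRoles(donors=frozenset(donors), acceptors=acceptors)
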