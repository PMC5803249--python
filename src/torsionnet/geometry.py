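"""Conformer and dihedral-topology primitives.

A molecule is treated as a set of rigid fragments joined by rotatable
bonds: conformers differ only by the torsion angles about those bonds.
This module represents conformers (elements + Cartesian coordinates),
the dihedral topology (bonds, rigid fragments, rotatable dihedrals and
their moving sets), and provides the elementary operations every other
module builds on: measuring a torsion, setting it by rigid-body
rotation, steric-clash detection and XYZ file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "MolecularConformer",
    "DihedralTopology",
    "DihedralConfiguration",
    "UndefinedTorsionError",
    "XYZParseError",
    "TopologyError",
    "read_xyz",
    "write_xyz",
    "measure_dihedral",
    "measure_all_dihedrals",
    "set_dihedral",
    "set_all_dihedrals",
    "detect_clash",
    "canonical_angle",
]

#: Default steric clash threshold between eligible non-bonded atoms (Å).
DEFAULT_CLASH_THRESHOLD = 2.1


class XYZParseError(ValueError):
    """Raised when an XYZ file does not follow the standard layout."""


class UndefinedTorsionError(ValueError):
    """Raised when three of the four torsion atoms are collinear."""


class TopologyError(ValueError):
    """Raised when a dihedral topology violates its invariants."""


def canonical_angle(angle_deg):
    """Map an angle (degrees) into the canonical range [0, 360)."""
    return np.asarray(angle_deg, dtype=float) % 360.0


@dataclass
class MolecularConformer:
    """One molecular configuration: element symbols + Cartesian coordinates (Å)."""

    elements: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.elements)} element symbols for "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "MolecularConformer":
        return MolecularConformer(list(self.elements), self.coords.copy())


@dataclass
class DihedralTopology:
    """Bonds, rigid fragments and rotatable dihedrals of a molecule.

    Each dihedral is a 4-tuple (i, j, k, l): the torsion about bond j–k
    with i bonded to j and l bonded to k.  The *moving set* of a dihedral
    is every atom on the l-side of the j–k bond (the connected component
    of k once that bond is removed, minus k itself, which lies on the
    rotation axis); those are the atoms displaced when the torsion is set.
    """

    n_atoms: int
    bonds: set = field(default_factory=set)
    dihedrals: list = field(default_factory=list)
    rigid_fragments: list = field(default_factory=list)
    moving_sets: list = field(default_factory=list)

    def __post_init__(self):
        self.bonds = {tuple(sorted(map(int, b))) for b in self.bonds}
        self.dihedrals = [tuple(map(int, d)) for d in self.dihedrals]
        self.rigid_fragments = [sorted(map(int, f)) for f in self.rigid_fragments]
        if not self.moving_sets:
            self.moving_sets = [
                self._compute_moving_set(d) for d in self.dihedrals
            ]
        else:
            self.moving_sets = [set(map(int, s)) for s in self.moving_sets]
        self._validate()
        self._fragment_of = {}
        for fi, frag in enumerate(self.rigid_fragments):
            for a in frag:
                self._fragment_of[a] = fi
        self._clash_pairs = None

    # -- construction helpers -------------------------------------------------

    def _bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def _compute_moving_set(self, dihedral) -> set:
        i, j, k, l = dihedral
        g = self._bond_graph()
        if not g.has_edge(j, k):
            raise TopologyError(f"dihedral {dihedral}: j–k ({j},{k}) is not a bond")
        g.remove_edge(j, k)
        comp = nx.node_connected_component(g, k)
        if j in comp:
            raise TopologyError(
                f"dihedral {dihedral}: bond ({j},{k}) lies on a ring; "
                "rotatable bonds must be bridges"
            )
        comp.discard(k)
        return comp

    def _validate(self):
        n = self.n_atoms
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise TopologyError(f"invalid bond ({a},{b})")
        seen = set()
        for frag in self.rigid_fragments:
            if seen & set(frag):
                raise TopologyError("rigid fragments overlap")
            seen |= set(frag)
        if seen != set(range(n)):
            raise TopologyError("rigid fragments do not partition the atoms")
        frag_of = {}
        for fi, frag in enumerate(self.rigid_fragments):
            for a in frag:
                frag_of[a] = fi
        for d, mset in zip(self.dihedrals, self.moving_sets):
            i, j, k, l = d
            if tuple(sorted((j, k))) not in self.bonds:
                raise TopologyError(f"dihedral {d}: j–k is not a bond")
            if l not in mset or i in mset:
                raise TopologyError(f"dihedral {d}: moving set must contain l, not i")
            if frag_of[j] == frag_of[k]:
                raise TopologyError(
                    f"dihedral {d}: j–k bond must connect two distinct fragments"
                )

    @property
    def n_dihedrals(self) -> int:
        return len(self.dihedrals)

    # -- clash eligibility ----------------------------------------------------

    def clash_eligible_pairs(self) -> np.ndarray:
        """(m, 2) array of atom pairs eligible for the steric clash test.

        A pair is eligible iff the atoms sit in different rigid fragments
        AND are at least 4 bonds apart in the bond graph.  Intra-fragment
        and 1-2/1-3/1-4 distances are fixed or controlled directly by a
        single torsion, so flagging them would veto legitimate rotations.
        """
        if self._clash_pairs is None:
            g = self._bond_graph()
            dist = dict(nx.all_pairs_shortest_path_length(g))
            pairs = []
            for a in range(self.n_atoms):
                for b in range(a + 1, self.n_atoms):
                    if self._fragment_of[a] == self._fragment_of[b]:
                        continue
                    if dist.get(a, {}).get(b, np.inf) < 4:
                        continue
                    pairs.append((a, b))
            self._clash_pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        return self._clash_pairs

    # -- serialization --------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict, n_atoms: int | None = None) -> "DihedralTopology":
        n = int(data.get("n_atoms", n_atoms))
        return cls(
            n_atoms=n,
            bonds={tuple(b) for b in data["bonds"]},
            dihedrals=[tuple(d) for d in data["dihedrals"]],
            rigid_fragments=[list(f) for f in data["fragments"]],
        )

    @classmethod
    def from_yaml(cls, path) -> "DihedralTopology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "n_atoms": self.n_atoms,
            "bonds": sorted(list(b) for b in self.bonds),
            "dihedrals": [list(d) for d in self.dihedrals],
            "fragments": [list(f) for f in self.rigid_fragments],
        }

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass
class DihedralConfiguration:
    """Vector of the molecule's n_d torsion angles, degrees in [0, 360)."""

    angles: np.ndarray

    def __post_init__(self):
        self.angles = canonical_angle(np.atleast_1d(np.asarray(self.angles, float)))

    @property
    def n_dihedrals(self) -> int:
        return self.angles.shape[0]


# -- XYZ I/O ------------------------------------------------------------------


def read_xyz(path) -> MolecularConformer:
    """Read a standard XYZ file (count line, comment line, element x y z rows)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file (line 1)")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}: line 1: malformed atom count {lines[0]!r}")
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise XYZParseError(
            f"{path}: line {len(lines) + 1}: expected {n} atom rows, found {len(body)}"
        )
    elements, coords = [], []
    for offset, line in enumerate(body):
        lineno = offset + 3
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {lineno}: expected 'El x y z', got {line!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}: line {lineno}: non-numeric coordinate in {line!r}")
        elements.append(parts[0])
        coords.append(xyz)
    return MolecularConformer(elements, np.asarray(coords))


def write_xyz(conformer: MolecularConformer, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{conformer.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(conformer.elements, conformer.coords):
            fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


# -- torsion measurement and manipulation -------------------------------------

_COLLINEAR_TOL = 1e-10


def _torsion_from_points(p_i, p_j, p_k, p_l) -> float:
    """Signed torsion (degrees, [0,360)) of four points, IUPAC convention."""
    b1 = p_j - p_i
    b2 = p_k - p_j
    b3 = p_l - p_k
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < _COLLINEAR_TOL or np.dot(n2, n2) < _COLLINEAR_TOL:
        raise UndefinedTorsionError("collinear atoms: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def measure_dihedral(conformer: MolecularConformer, topology: DihedralTopology,
                     d_index: int) -> float:
    """Torsion angle (degrees, canonical [0, 360)) of dihedral ``d_index``."""
    i, j, k, l = topology.dihedrals[d_index]
    c = conformer.coords
    return _torsion_from_points(c[i], c[j], c[k], c[l])


def measure_all_dihedrals(conformer, topology) -> DihedralConfiguration:
    return DihedralConfiguration(
        [measure_dihedral(conformer, topology, d) for d in range(topology.n_dihedrals)]
    )


def _rotation_matrix(axis_unit: np.ndarray, angle_rad: float) -> np.ndarray:
    """Right-handed rotation by ``angle_rad`` about ``axis_unit`` (Rodrigues)."""
    ux, uy, uz = axis_unit
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cc = 1.0 - c
    return np.array([
        [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
        [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
        [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
    ])


def set_dihedral(conformer: MolecularConformer, topology: DihedralTopology,
                 d_index: int, target_deg: float) -> MolecularConformer:
    """Return a conformer with dihedral ``d_index`` rotated to ``target_deg``.

    Rigid-body rotation of the dihedral's moving set about the j–k bond
    axis: bond lengths and angles within each rigid fragment are untouched
    and atoms outside the moving set do not move.
    """
    if not np.isfinite(target_deg):
        raise ValueError("target angle must be finite")
    current = measure_dihedral(conformer, topology, d_index)
    delta = np.radians(float(target_deg) - current)
    _, j, k, _ = topology.dihedrals[d_index]
    out = conformer.copy()
    axis = out.coords[k] - out.coords[j]
    axis /= np.linalg.norm(axis)
    # rotating the l-side by +θ about the j→k axis increases the torsion by θ
    rot = _rotation_matrix(axis, delta)
    moving = sorted(topology.moving_sets[d_index])
    origin = out.coords[k]
    out.coords[moving] = (out.coords[moving] - origin) @ rot.T + origin
    return out


def set_all_dihedrals(conformer, topology, angles) -> MolecularConformer:
    """Set every dihedral to the given angles (degrees), in topology order."""
    angles = np.atleast_1d(np.asarray(angles, float))
    if angles.shape[0] != topology.n_dihedrals:
        raise ValueError("angle vector length does not match topology")
    out = conformer
    for d, a in enumerate(angles):
        out = set_dihedral(out, topology, d, a)
    return out


def detect_clash(conformer: MolecularConformer, topology: DihedralTopology,
                 threshold: float = DEFAULT_CLASH_THRESHOLD) -> bool:
    """True iff any clash-eligible atom pair is strictly closer than ``threshold`` Å.

    Eligibility (different rigid fragments, ≥ 4 bonds apart) is defined by
    :meth:`DihedralTopology.clash_eligible_pairs`.  A single distance
    threshold is used for all elements.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pairs = topology.clash_eligible_pairs()
    if pairs.shape[0] == 0:
        return False
    diff = conformer.coords[pairs[:, 0]] - conformer.coords[pairs[:, 1]]
    d2 = np.einsum("ij,ij->i", diff, diff)
    return bool(np.any(d2 < threshold * threshold))
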