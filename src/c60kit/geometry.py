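"""Fullerene geometry, crystallographic lattice expansion and superposition.

This module carries the structural primitives of the toolkit: a
truncated-icosahedron C60 builder, symmetry expansion of a crystal
structure into the set of lattice neighbours relevant for packing
analysis, Kabsch least-squares superposition, extraction of the
four-segment fullerene-binding backbone motif, inter-fullerene channel
geometry, and Matthews-coefficient / solvent-content arithmetic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .constants import MATTHEWS_SOLVENT_CONSTANT
from .errors import (
    IncompleteResidueError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    UnsupportedSymmetryError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Golden ratio, used by the truncated-icosahedron vertex table.
_PHI = (1.0 + math.sqrt(5.0)) / 2.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom with PDB-style identity and a Cartesian position in Angstrom."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise InvalidInputError("atom position must be a finite 3-vector")
        if not self.element:
            raise InvalidInputError("element symbol must be non-empty")


@dataclass
class Structure:
    """An ordered atom list with optional unit cell and space group.

    ``cell`` is ``(a, b, c, alpha, beta, gamma)`` in Angstrom/degrees.
    """

    atoms: list[AtomRecord]
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None

    def __post_init__(self):
        if self.cell is not None:
            a, b, c, al, be, ga = self.cell
            if min(a, b, c) <= 0 or not all(0 < x < 180 for x in (al, be, ga)):
                raise InvalidInputError("invalid unit-cell parameters")

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def residue_map(self) -> dict[tuple[str, int], dict[str, AtomRecord]]:
        """(chain, residue index) -> {atom name: record}."""
        out: dict[tuple[str, int], dict[str, AtomRecord]] = {}
        for atom in self.atoms:
            out.setdefault((atom.chain_id, atom.residue_index), {})[atom.atom_name] = atom
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id)
        return list(seen)


@dataclass
class FullereneTopology:
    """Truncated-icosahedron C60: 60 vertices, 90 edges, 12+20 faces."""

    vertices: np.ndarray                      # (60, 3) Angstrom
    edges: list[tuple[int, int]]              # 90 index pairs
    pentagons: list[tuple[int, ...]]          # 12 rings of 5
    hexagons: list[tuple[int, ...]]           # 20 rings of 6

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def faces(self) -> list[tuple[int, ...]]:
        return list(self.pentagons) + list(self.hexagons)

    def edge_lengths(self) -> np.ndarray:
        i, j = np.array(self.edges).T
        return np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)

    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges) + len(self.faces)


@dataclass
class LatticeImage:
    """One retained symmetry image of the source structure."""

    operator_index: int
    translation: tuple[int, int, int]
    atoms: list[AtomRecord]

    @property
    def is_identity(self) -> bool:
        return self.operator_index == 0 and self.translation == (0, 0, 0)


@dataclass
class LatticeAssembly:
    """Initial unit plus its retained crystallographic neighbours."""

    source: Structure
    images: list[LatticeImage]
    retention_rule: tuple[float, int]  # (distance cutoff A, minimum atom count)

    def all_atoms(self) -> list[AtomRecord]:
        return [a for img in self.images for a in img.atoms]


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping coords_a onto coords_b."""

    rotation: np.ndarray    # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector
    rmsd: float
    atom_count: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class MotifQuery:
    """Ordered disjoint backbone segments defining a binding-site geometry."""

    segments: list[tuple[str, int, int]]   # (chain, start, end) inclusive
    coordinates: np.ndarray                # (4 * n_residues, 3), N/CA/C/O order
    residue_names: list[str] = field(default_factory=list)

    @property
    def atom_count(self) -> int:
        return len(self.coordinates)

    @property
    def segment_lengths(self) -> list[int]:
        return [end - start + 1 for _, start, end in self.segments]


# ---------------------------------------------------------------------------
# structure I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (first model)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[AtomRecord] = []
    for chain in st[0]:
        for residue in chain:
            if residue.seqid.icode.strip():
                raise InvalidInputError(
                    f"insertion codes are not supported "
                    f"({chain.name}/{residue.seqid.num}{residue.seqid.icode})"
                )
            for atom in residue:
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_index=residue.seqid.num,
                    residue_name=residue.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))
    cell = None
    if st.cell and st.cell.a > 0:
        cell = (st.cell.a, st.cell.b, st.cell.c,
                st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = st.spacegroup_hm if st.spacegroup_hm else None
    return Structure(atoms=atoms, cell=cell, space_group=sg)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure to a PDB file."""
    st = _to_gemmi(structure)
    st.write_pdb(str(path))


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    model = gemmi.Model("1")
    by_chain: dict[str, list[AtomRecord]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain_id, []).append(a)
    for chain_id, records in by_chain.items():
        chain = gemmi.Chain(chain_id)
        groups: list[tuple[tuple, list[AtomRecord]]] = []
        for rec in records:
            key = (rec.residue_index, rec.residue_name)
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(rec)
        for (res_idx, res_name), recs in groups:
            residue = gemmi.Residue()
            residue.seqid = gemmi.SeqId(res_idx, " ")
            residue.name = res_name
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.atom_name
                atom.element = gemmi.Element(rec.element)
                atom.pos = gemmi.Position(*rec.position)
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    if structure.cell is not None:
        st.cell = gemmi.UnitCell(*structure.cell)
    if structure.space_group:
        st.spacegroup_hm = structure.space_group
    return st


def write_assembly(assembly: LatticeAssembly, pdb_path: str | Path,
                   sidecar_path: str | Path | None = None) -> None:
    """Write an expanded lattice as PDB plus a JSON image-index sidecar.

    Each image gets a fresh single-character chain id; the sidecar maps the
    new chain ids back to (operator index, translation, source chain).
    """
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    atoms: list[AtomRecord] = []
    mapping = {}
    next_id = 0
    for img in assembly.images:
        source_chains = {a.chain_id for a in img.atoms}
        remap = {}
        for src in sorted(source_chains):
            if next_id >= len(alphabet):
                raise InvalidInputError("too many images for PDB chain ids")
            remap[src] = alphabet[next_id]
            mapping[alphabet[next_id]] = {
                "operator_index": img.operator_index,
                "translation": list(img.translation),
                "source_chain": src,
            }
            next_id += 1
        for a in img.atoms:
            atoms.append(AtomRecord(remap[a.chain_id], a.residue_index,
                                    a.residue_name, a.atom_name, a.element,
                                    a.position.copy()))
    write_pdb(Structure(atoms, assembly.source.cell, assembly.source.space_group),
              pdb_path)
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(mapping, indent=1))


# ---------------------------------------------------------------------------
# C60 builder
# ---------------------------------------------------------------------------

def _truncated_icosahedron_unit() -> np.ndarray:
    """Vertices of a truncated icosahedron with edge length 2, centred at 0.

    The canonical vertex table: all cyclic coordinate permutations of
    (0, +-1, +-3phi), (+-1, +-(2+phi), +-2phi), (+-2, +-(1+2phi), +-phi).
    """
    base = [
        (0.0, 1.0, 3.0 * _PHI),
        (1.0, 2.0 + _PHI, 2.0 * _PHI),
        (2.0, 1.0 + 2.0 * _PHI, _PHI),
    ]
    verts = set()
    for x, y, z in base:
        for sx in ((1,) if x == 0 else (1, -1)):
            for sy in (1, -1):
                for sz in (1, -1):
                    v = (sx * x, sy * y, sz * z)
                    for cyc in (v, (v[1], v[2], v[0]), (v[2], v[0], v[1])):
                        verts.add(cyc)
    out = np.array(sorted(verts), dtype=float)
    assert out.shape == (60, 3)
    return out


def build_c60(bond_length: float = 1.4392) -> FullereneTopology:
    """Build uniform-bond truncated-icosahedron C60 geometry.

    All 90 carbon-carbon bonds are exactly ``bond_length`` Angstrom
    (single uniform bond length; the real molecule's slight 6:6 vs 6:5
    bond alternation is not modelled), the centroid is at the origin and
    all vertices are equidistant from it.
    """
    if not (bond_length > 0):
        raise InvalidParameterError("bond_length must be positive")
    verts = _truncated_icosahedron_unit() * (bond_length / 2.0)
    verts -= verts.mean(axis=0)

    # edges = nearest-neighbour pairs; every vertex has exactly 3 of them
    dists = np.linalg.norm(verts[:, None, :] - verts[None, :, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    edge_len = dists.min()
    ii, jj = np.where(np.isclose(dists, edge_len, rtol=0, atol=1e-9 * edge_len + 1e-12))
    edges = sorted({(int(i), int(j)) for i, j in zip(ii, jj) if i < j})

    pentagons, hexagons = _hull_faces(verts)
    topo = FullereneTopology(verts, edges, pentagons, hexagons)
    if (len(edges) != 90 or len(pentagons) != 12 or len(hexagons) != 20):
        raise InvalidInputError("fullerene construction failed topology checks")
    return topo


def _hull_faces(verts: np.ndarray) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Recover polygonal faces by merging coplanar convex-hull triangles."""
    hull = ConvexHull(verts)
    groups: dict[tuple[int, ...], set[int]] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq / np.linalg.norm(eq[:3]), 6))
        groups.setdefault(key, set()).update(int(i) for i in simplex)
    pentagons, hexagons = [], []
    for key, members in groups.items():
        idx = np.array(sorted(members))
        normal = np.array(key[:3])
        center = verts[idx].mean(axis=0)
        # order the ring by angle in the face plane
        u = verts[idx[0]] - center
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        rel = verts[idx] - center
        ang = np.arctan2(rel @ w, rel @ u)
        ring = tuple(int(i) for i in idx[np.argsort(ang)])
        (pentagons if len(ring) == 5 else hexagons).append(ring)
    return pentagons, hexagons


# ---------------------------------------------------------------------------
# lattice expansion
# ---------------------------------------------------------------------------

def _space_group_ops(symbol: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rotation/translation pairs (fractional) for a Hermann-Mauguin symbol."""
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise UnsupportedSymmetryError(f"unknown space-group symbol {symbol!r}")
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    # make the identity operator index 0
    ops.sort(key=lambda rt: (not (np.array_equal(rt[0], np.eye(3))
                                  and np.allclose(rt[1], 0)),))
    return ops


def expand_lattice(structure: Structure, cutoff: float = 16.0,
                   min_atoms: int = 3) -> LatticeAssembly:
    """Expand a crystal into the initial unit plus nearby symmetry images.

    A non-identity image is retained when at least ``min_atoms`` of its
    atoms lie within ``cutoff`` Angstrom of any atom of the initial unit.
    The integer-translation search range is derived from the fractional
    bounding boxes of the unit and each operator image plus the cutoff
    converted to fractional units, which provably bounds every image that
    can satisfy the retention rule.
    """
    if structure.cell is None or not structure.space_group:
        raise InvalidInputError("structure must carry a unit cell and space group")
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    ops = _space_group_ops(structure.space_group)
    cell = gemmi.UnitCell(*structure.cell)
    orth = np.array(cell.orth.mat.tolist(), dtype=float)      # frac -> cart
    frac_m = np.array(cell.frac.mat.tolist(), dtype=float)    # cart -> frac

    cart0 = structure.positions()
    if len(cart0) == 0:
        raise InvalidInputError("structure has no atoms")
    frac0 = cart0 @ frac_m.T
    tree = cKDTree(cart0)
    # max fractional displacement per `cutoff` of cartesian distance, per axis
    frac_margin = cutoff * np.linalg.norm(frac_m, axis=1)

    lo0, hi0 = frac0.min(axis=0), frac0.max(axis=0)
    images = [LatticeImage(0, (0, 0, 0), [_copy_atom(a, a.position) for a in structure.atoms])]
    for op_idx, (rot, tran) in enumerate(ops):
        frac_img = frac0 @ rot.T + tran
        lo, hi = frac_img.min(axis=0), frac_img.max(axis=0)
        n_lo = np.floor(lo0 - hi - frac_margin).astype(int)
        n_hi = np.ceil(hi0 - lo + frac_margin).astype(int)
        for n1 in range(n_lo[0], n_hi[0] + 1):
            for n2 in range(n_lo[1], n_hi[1] + 1):
                for n3 in range(n_lo[2], n_hi[2] + 1):
                    if op_idx == 0 and (n1, n2, n3) == (0, 0, 0):
                        continue
                    shift = np.array([n1, n2, n3], dtype=float)
                    cart = (frac_img + shift) @ orth.T
                    # bounding-box prefilter (exact-safe)
                    gap = np.maximum(cart0.min(0) - cart.max(0),
                                     cart.min(0) - cart0.max(0))
                    if np.linalg.norm(np.maximum(gap, 0.0)) > cutoff:
                        continue
                    d, _ = tree.query(cart, k=1, distance_upper_bound=cutoff)
                    if int(np.sum(np.isfinite(d))) >= min_atoms:
                        images.append(LatticeImage(
                            op_idx, (n1, n2, n3),
                            [_copy_atom(a, p) for a, p in zip(structure.atoms, cart)]))
    return LatticeAssembly(structure, images, (cutoff, min_atoms))


def _copy_atom(a: AtomRecord, position: np.ndarray) -> AtomRecord:
    return AtomRecord(a.chain_id, a.residue_index, a.residue_name,
                      a.atom_name, a.element, np.array(position, dtype=float))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(coords_a: Sequence, coords_b: Sequence) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of coords_a onto coords_b.

    Returns the proper rotation (det +1) and translation minimising the
    root-mean-square deviation ||R a + t - b||.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise InvalidInputError("coordinate lists must have equal length")
    if len(a) < 3:
        raise InvalidInputError("need at least 3 points to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    if np.allclose(a0, 0) and np.allclose(b0, 0):
        raise InvalidInputError("points must not be all coincident")
    t = cb - rot @ ca
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(a)))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd, atom_count=len(a))


def pairwise_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD after optimal superposition (no transform returned).

    Computed from the Kabsch singular values; used as the hot inner loop of
    the motif search.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = a0 @ rot.T - b0
    return float(np.sqrt((diff ** 2).sum() / len(a)))


# ---------------------------------------------------------------------------
# motif extraction
# ---------------------------------------------------------------------------

def extract_motif(structure: Structure,
                  segments: Iterable[tuple[str, int, int]]) -> MotifQuery:
    """Pull backbone (N, CA, C, O) coordinates for ordered residue segments.

    Coordinates are segment-major, N/CA/C/O within each residue; residue
    indices are 1-based as deposited.
    """
    segments = [(str(c), int(s), int(e)) for c, s, e in segments]
    seen: dict[str, list[tuple[int, int]]] = {}
    for chain, start, end in segments:
        if end < start:
            raise InvalidInputError(f"segment {chain}:{start}-{end} is reversed")
        for s0, e0 in seen.get(chain, []):
            if start <= e0 and s0 <= end:
                raise InvalidInputError(f"overlapping segments on chain {chain}")
        seen.setdefault(chain, []).append((start, end))
    resmap = structure.residue_map()
    coords: list[np.ndarray] = []
    names: list[str] = []
    for chain, start, end in segments:
        for ri in range(start, end + 1):
            residue = resmap.get((chain, ri))
            for atom_name in BACKBONE_ATOMS:
                if residue is None or atom_name not in residue:
                    raise IncompleteResidueError(chain, ri, atom_name)
                coords.append(residue[atom_name].position)
            names.append(next(iter(residue.values())).residue_name)
    arr = (np.array(coords, dtype=float) if coords
           else np.zeros((0, 3)))
    return MotifQuery(segments=segments, coordinates=arr, residue_names=names)


# ---------------------------------------------------------------------------
# channel geometry
# ---------------------------------------------------------------------------

def fullerene_centroids(assembly: LatticeAssembly,
                        residue_name: str) -> np.ndarray:
    """Centroids of every fullerene ligand instance across all images."""
    groups: dict[tuple[int, tuple, str, int], list[np.ndarray]] = {}
    for k, img in enumerate(assembly.images):
        for a in img.atoms:
            if a.residue_name == residue_name:
                groups.setdefault((k, img.translation, a.chain_id, a.residue_index),
                                  []).append(a.position)
    if not groups:
        return np.zeros((0, 3))
    return np.array([np.mean(v, axis=0) for v in groups.values()])


def fullerene_channel_distances(assembly: LatticeAssembly,
                                fullerene_selector: str,
                                axis: Sequence[float] = (0.0, 0.0, 1.0),
                                dedup_tol: float = 0.5) -> np.ndarray:
    """Consecutive centre-to-centre distances along the channel axis.

    Centroids are deduplicated (symmetry images can regenerate the same
    site), sorted by their coordinate along ``axis``, and consecutive
    nearest-neighbour distances are returned in that order.
    """
    cents = fullerene_centroids(assembly, fullerene_selector)
    cents = _dedup_points(cents, dedup_tol)
    if len(cents) < 2:
        raise InsufficientDataError("need at least two fullerene centroids")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    order = np.argsort(cents @ ax)
    cents = cents[order]
    return np.linalg.norm(np.diff(cents, axis=0), axis=1)


def _dedup_points(points: np.ndarray, tol: float) -> np.ndarray:
    kept: list[np.ndarray] = []
    for p in points:
        if all(np.linalg.norm(p - q) > tol for q in kept):
            kept.append(p)
    return np.array(kept) if kept else np.zeros((0, 3))


# ---------------------------------------------------------------------------
# crystal packing arithmetic
# ---------------------------------------------------------------------------

def cell_volume(cell: tuple[float, float, float, float, float, float]) -> float:
    """Unit-cell volume in Angstrom^3."""
    return gemmi.UnitCell(*cell).volume


def solvent_fraction(v_m: float) -> float:
    """Solvent fraction 1 - 1.23/V_M, clamped to [0, 1)."""
    if v_m <= 0:
        raise InvalidParameterError("V_M must be positive")
    frac = 1.0 - MATTHEWS_SOLVENT_CONSTANT / v_m
    if frac < 0:
        warnings.warn("V_M <= 1.23 implies non-physical negative solvent; clamping to 0")
        return 0.0
    return min(frac, np.nextafter(1.0, 0.0))


def matthews_solvent(cell: tuple[float, float, float, float, float, float],
                     space_group: str, asu_mass: float) -> tuple[float, float]:
    """Matthews coefficient (A^3/Da) and solvent fraction of a crystal.

    ``asu_mass`` is the molar mass of the asymmetric-unit contents counted
    in the coefficient (conventionally protein only; pass protein+ligand
    mass to include the ligand).
    """
    if asu_mass <= 0:
        raise InvalidParameterError("asu_mass must be positive")
    z = len(_space_group_ops(space_group))
    v_m = cell_volume(cell) / (z * asu_mass)
    return v_m, solvent_fraction(v_m)
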