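"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline input class can be generated here so the full analysis is
testable without downloads: ideal antiparallel four-helix bundles with
optionally planted binding motifs, small crystal fixtures for lattice
expansion, toy particle systems for the alchemical cycle, multi-speed
sedimentation-equilibrium datasets, and SEC calibration/trace fixtures.

Random-number discipline: every generator draws from its own named
substream of the master seed (``SeedSequence(seed, spawn_key=(stream,))``)
so adding a generator never perturbs the output of another. Identical
configs produce bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from . import alchemy, auc, mc
from .errors import InvalidInputError, InvalidParameterError
from .geometry import (
    AtomRecord,
    LatticeAssembly,
    LatticeImage,
    MotifQuery,
    Structure,
    extract_motif,
    kabsch_superpose,
)

_STREAMS = {"helix": 1, "plant": 2, "fep": 3, "auc": 4, "lattice": 5,
            "sec": 6, "channel": 7}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named, order-independent child RNG of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name], index)))


@dataclass
class GeneratorConfig:
    """All generator knobs in one reproducible record."""

    seed: int = 0
    # helix-bundle geometry
    n_residues: int = 30
    helix_rise: float = 1.5            # A per residue
    residues_per_turn: float = 3.6
    bundle_radius: float = 7.5         # A, helix axis to bundle axis
    residue_name: str = "ALA"
    # planted motif
    perturbation_sigma: float = 0.0    # A, i.i.d. Gaussian per coordinate
    # crystal fixture
    cell: tuple = (30.0, 30.0, 40.0, 90.0, 90.0, 120.0)
    space_group: str = "P 62"
    atoms_per_chain: int = 6
    # association / sedimentation
    kd: float = 118e-6                 # M, 2n-mer -> 2 n-mer dissociation
    base_mass: float = 13400.0         # Da (tetramer)
    vbar: float = 0.73                 # mL/g
    rho: float = 1.0                   # g/mL
    speeds_rpm: tuple = (25000.0, 30000.0, 35000.0, 40000.0)
    noise_sigma: float = 0.005         # AU
    loading_concentration: float = 4e-6   # M base species at reference radius
    extinction: tuple = (5000.0, 10000.0)  # AU/cm/M for n-mer, 2n-mer
    radius_window: tuple = (5.90, 6.10)    # cm
    n_radii: int = 80
    baseline: float = 0.01             # AU, per scan
    auc_temperature: float = 298.15
    # toy free-energy systems
    fep_temperature: float = 298.15
    harmonic_k: float = 10.0           # kcal/mol/A^2
    harmonic_box: float = 8.0          # A
    solvent_count: int = 40
    solvent_epsilon: float = 0.15
    solvent_rmin: float = 3.4
    solvent_box: float = 22.0
    host_box: float = 34.0
    host_epsilon: float = 2.89
    host_rmin: float = 4.0
    ligand_epsilon: float = 1.0
    ligand_rmin: float = 9.0           # self-pair minimum (vdW radius 4.5 A)
    site_circumradius: float = 6.5     # A, host triangle circumradius
    restraint_k: float = 10.0          # kcal/mol/A^2 (dummy-site and ligand-dummy)


# ---------------------------------------------------------------------------
# ideal helix backbone
# ---------------------------------------------------------------------------

_BB_INTERNAL = {
    # bond lengths (A), bond angles (deg), torsions (deg): standard
    # alpha-helical internal geometry (phi -57, psi -47, omega 180)
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
    "phi": -57.0, "psi": -47.0, "omega": 180.0,
}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    d = -bond * math.cos(ang) * bc \
        + bond * math.sin(ang) * (math.cos(tor) * m + math.sin(tor) * n)
    return c + d


def _nerf_helix(n_res: int) -> list[dict[str, np.ndarray]]:
    g = _BB_INTERNAL
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    ang = math.radians(g["ang_n_ca_c"])
    c0 = ca0 + g["ca_c"] * np.array([math.cos(ang) * -1.0, math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = residues[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], g["c_n"], g["ang_ca_c_n"], g["psi"])
        ca = _nerf(prev["CA"], prev["C"], n, g["n_ca"], g["ang_c_n_ca"], g["omega"])
        c = _nerf(prev["C"], n, ca, g["ca_c"], g["ang_n_ca_c"], g["phi"])
        residues.append({"N": n, "CA": ca, "C": c})
    for res in residues:
        res["O"] = _nerf(res["N"], res["CA"], res["C"],
                         g["c_o"], g["ang_ca_c_o"], g["psi"] + 180.0)
    return residues


@lru_cache(maxsize=1)
def _helix_cylindrical_params() -> dict:
    """Per-atom cylindrical placement parameters of an ideal alpha helix.

    Derived once from an internal-coordinate (NeRF) build: each backbone
    atom type is characterised by its radius from the helix axis, its phase
    offset relative to the same residue's CA, and its axial offset. These
    are reused parametrically so the generator can honour a requested rise
    and residues-per-turn exactly at the CA level.
    """
    n_ref = 24
    residues = _nerf_helix(n_ref)
    cas = np.array([r["CA"] for r in residues])
    center = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if (cas[-1] - cas[0]) @ axis < 0:
        axis = -axis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def cyl(p: np.ndarray) -> tuple[float, float, float]:
        rel = p - center
        z = rel @ axis
        x, y = rel @ e1, rel @ e2
        return math.hypot(x, y), math.atan2(y, x), z

    mid = range(6, n_ref - 6)
    ca_theta = np.unwrap([cyl(residues[i]["CA"])[1] for i in range(n_ref)])
    ca_z = np.array([cyl(residues[i]["CA"])[2] for i in range(n_ref)])
    d_theta = float(np.mean(np.diff(ca_theta)[list(mid)[0]:list(mid)[-1]]))
    rise = float(np.mean(np.diff(ca_z)[list(mid)[0]:list(mid)[-1]]))
    params: dict[str, tuple[float, float, float]] = {}
    for atom in ("N", "CA", "C", "O"):
        radii, dphis, dzs = [], [], []
        for i in mid:
            r, th, z = cyl(residues[i][atom])
            r_ca, th_ca, z_ca = cyl(residues[i]["CA"])
            dphi = math.remainder(th - th_ca, 2.0 * math.pi)
            radii.append(r)
            dphis.append(dphi)
            dzs.append(z - z_ca)
        params[atom] = (float(np.mean(radii)), float(np.mean(dphis)),
                        float(np.mean(dzs)))
    return {"atoms": params, "d_theta_sign": math.copysign(1.0, d_theta),
            "natural_rise": rise}


def _parametric_helix(n_res: int, rise: float, residues_per_turn: float) -> list[dict[str, np.ndarray]]:
    """Ideal helix along +z, centred at the origin, built parametrically."""
    p = _helix_cylindrical_params()
    d_theta = p["d_theta_sign"] * 2.0 * math.pi / residues_per_turn
    z0 = -(n_res - 1) * rise / 2.0
    out = []
    for i in range(n_res):
        theta_ca = i * d_theta
        z_ca = z0 + i * rise
        res = {}
        for atom, (r, dphi, dz) in p["atoms"].items():
            th = theta_ca + dphi
            res[atom] = np.array([r * math.cos(th), r * math.sin(th), z_ca + dz])
        out.append(res)
    return out


def generate_helix_bundle(config: GeneratorConfig) -> Structure:
    """Four ideal antiparallel alpha-helical backbones on a square.

    Chains A-D sit at the corners of a square of half-diagonal
    ``bundle_radius``; chains B and D run antiparallel (flipped about x).
    Residues are numbered from 1; atoms are N, CA, C, O per residue. The
    construction is deterministic (geometry only), so identical configs
    give identical coordinates.
    """
    helix = _parametric_helix(config.n_residues, config.helix_rise,
                              config.residues_per_turn)
    atoms: list[AtomRecord] = []
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    for k, chain_id in enumerate("ABCD"):
        beta = math.radians(45.0 + 90.0 * k)
        offset = np.array([config.bundle_radius * math.cos(beta),
                           config.bundle_radius * math.sin(beta), 0.0])
        flip = (k % 2 == 1)
        for i, res in enumerate(helix):
            for atom_name in ("N", "CA", "C", "O"):
                pos = res[atom_name].copy()
                if flip:
                    pos = np.array([pos[0], -pos[1], -pos[2]])
                atoms.append(AtomRecord(chain_id, i + 1, config.residue_name,
                                        atom_name, elements[atom_name],
                                        pos + offset))
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# planted motifs
# ---------------------------------------------------------------------------

def plant_motif(structure: Structure, query: MotifQuery, sigma: float,
                seed: int, segments: Sequence[tuple[str, int]] | None = None
                ) -> tuple[Structure, dict]:
    """Copy the query backbone into a structure with Gaussian coordinate noise.

    The whole query is rigidly superposed onto the chosen target segments
    (one transform, preserving its internal geometry), i.i.d. Gaussian
    noise of standard deviation ``sigma`` is added per coordinate, and the
    target backbone coordinates are overwritten. Returns the edited
    structure and a ground-truth record of where the motif was planted.
    """
    if sigma < 0:
        raise InvalidParameterError("perturbation sigma must be non-negative")
    lengths = query.segment_lengths
    if segments is None:
        segments = _default_plant_sites(structure, lengths)
    segments = [(str(c), int(s)) for c, s in segments]
    if len(segments) != len(lengths):
        raise InvalidInputError("need one target site per query segment")
    target_specs = [(c, s, s + n - 1) for (c, s), n in zip(segments, lengths)]
    target = extract_motif(structure, target_specs)   # validates room/atoms
    sup = kabsch_superpose(query.coordinates, target.coordinates)
    rng = substream(seed, "plant")
    planted = sup.apply(query.coordinates) + rng.normal(0.0, sigma,
                                                        query.coordinates.shape)
    new_atoms = [AtomRecord(a.chain_id, a.residue_index, a.residue_name,
                            a.atom_name, a.element, a.position.copy())
                 for a in structure.atoms]
    lookup = {}
    for idx, a in enumerate(new_atoms):
        lookup[(a.chain_id, a.residue_index, a.atom_name)] = idx
    cursor = 0
    for (chain, start, end), names in zip(
            target_specs, _split_names(query.residue_names, lengths)):
        for local, ri in enumerate(range(start, end + 1)):
            for atom_name in ("N", "CA", "C", "O"):
                idx = lookup[(chain, ri, atom_name)]
                new_atoms[idx].position = planted[cursor]
                cursor += 1
            if names:
                for atom_name in ("N", "CA", "C", "O"):
                    new_atoms[lookup[(chain, ri, atom_name)]].residue_name = names[local]
    truth = {"segments": [[c, s] for c, s in segments],
             "segment_lengths": lengths, "sigma": sigma, "seed": seed}
    return Structure(new_atoms, structure.cell, structure.space_group), truth


def _split_names(names: list[str], lengths: list[int]) -> list[list[str]]:
    if not names:
        return [[] for _ in lengths]
    out, pos = [], 0
    for n in lengths:
        out.append(names[pos:pos + n])
        pos += n
    return out


def _default_plant_sites(structure: Structure,
                         lengths: list[int]) -> list[tuple[str, int]]:
    chains = structure.chains()
    resmap = structure.residue_map()
    spans = {}
    for c in chains:
        indices = sorted(ri for ch, ri in resmap if ch == c)
        spans[c] = (indices[0], indices[-1])
    used: dict[str, int] = {}
    sites = []
    for i, n in enumerate(lengths):
        chain = chains[i % len(chains)]
        lo, hi = spans[chain]
        start = used.get(chain, lo + max((hi - lo + 1 - n) // 2, 0))
        if start + n - 1 > hi:
            raise InvalidInputError(
                f"chain {chain} has insufficient room for a {n}-residue segment")
        sites.append((chain, start))
        used[chain] = start + n + 1
    return sites


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# crystal / channel fixtures
# ---------------------------------------------------------------------------

def generate_crystal_fixture(config: GeneratorConfig) -> Structure:
    """Small P6_2-type crystal fixture with atoms scattered near cell faces.

    Fractional coordinates are drawn near faces and corners so that several
    non-identity images qualify under typical retention rules; used to
    exercise lattice expansion against the brute-force oracle.
    """
    rng = substream(config.seed, "lattice")
    cell = gemmi.UnitCell(*config.cell)
    orth = np.array(cell.orth.mat.tolist())
    base = np.array([
        [0.05, 0.10, 0.10], [0.90, 0.05, 0.20], [0.50, 0.95, 0.80],
        [0.10, 0.50, 0.95], [0.30, 0.30, 0.50], [0.85, 0.85, 0.05],
    ])
    n = config.atoms_per_chain
    frac = base[np.arange(n) % len(base)] + rng.uniform(-0.03, 0.03, (n, 3))
    cart = frac @ orth.T
    atoms = [AtomRecord("A", i + 1, "ALA", "CA", "C", cart[i]) for i in range(n)]
    return Structure(atoms=atoms, cell=config.cell, space_group=config.space_group)


def generate_fullerene_channel(spacings: Sequence[float] = (12.0, 17.0),
                               n_sites: int = 8, radius: float = 0.0,
                               turn_deg: float = 40.0,
                               residue_name: str = "FUL") -> LatticeAssembly:
    """A synthetic channel of fullerene centroids with known axial spacings.

    Sites alternate through ``spacings`` along z; with ``radius`` = 0 the
    consecutive centre-to-centre distances equal the spacings exactly.
    """
    atoms = []
    z = 0.0
    for i in range(n_sites):
        theta = math.radians(turn_deg * i)
        pos = np.array([radius * math.cos(theta), radius * math.sin(theta), z])
        atoms.append(AtomRecord("X", i + 1, residue_name, "C1", "C", pos))
        z += spacings[i % len(spacings)]
    structure = Structure(atoms=atoms)
    identity = LatticeImage(0, (0, 0, 0), list(structure.atoms))
    return LatticeAssembly(structure, [identity], (16.0, 3))


# ---------------------------------------------------------------------------
# toy alchemical fixtures
# ---------------------------------------------------------------------------

@dataclass
class FepFixture:
    """A system factory for the double-decoupling cycle plus ground truth."""

    kind: str
    config: GeneratorConfig
    metadata: dict = field(default_factory=dict)

    def factory(self, transformation_id: int, step_id: int) -> alchemy.StepSpec:
        if self.kind == "harmonic":
            return self._harmonic_step(transformation_id, step_id)
        if self.kind == "lj-solute":
            return self._lj_solute_step(transformation_id, step_id)
        if self.kind == "host-guest":
            return self._host_guest_step(transformation_id, step_id)
        raise InvalidParameterError(f"unsupported fixture kind {self.kind!r}")

    # -- harmonic: single particle released from a lambda-scaled well -------

    def _harmonic_step(self, tid: int, sid: int) -> alchemy.StepSpec:
        if (tid, sid) != (1, 1):
            raise InvalidInputError("harmonic fixture has a single step (1, 1)")
        cfg = self.config
        system = mc.ParticleSystem(
            positions=np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]]),
            epsilon=np.zeros(2), r_min=np.ones(2),
            restraints=[mc.RestraintSpec("atom-atom", (0,), (1,),
                                         k=cfg.harmonic_k, r0=0.0,
                                         lambda_coupled=True)],
            box=np.full(3, cfg.harmonic_box), coupling={},
            temperature=cfg.fep_temperature, fixed=frozenset({0}),
        )
        # the well itself is decoupled: k goes harmonic_k -> 0. The mapping
        # is quadratic in lambda so that uniform windows concentrate near
        # the weak-restraint end, where phase-space overlap is poorest.
        return alchemy.StepSpec(
            system=system, shift_coeff=8.0,
            restraint_schedule=lambda lam_d: cfg.harmonic_k * (1.0 - lam_d) ** 2,
            step_size=0.6,
        )

    # -- lj-solute: solvation-style transformation-2 machinery --------------

    def _solvent_positions(self, box: float, n: int) -> np.ndarray:
        rng = substream(self.config.seed, "fep", 1)
        per_axis = int(np.ceil(n ** (1 / 3)))
        grid = (np.arange(per_axis) + 0.5) / per_axis * box - box / 2
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        order = rng.permutation(len(pts))[:n]
        return pts[order] + rng.uniform(-0.3, 0.3, (n, 3))

    def _lj_solute_step(self, tid: int, sid: int) -> alchemy.StepSpec:
        if tid != 2 or sid not in (1, 2):
            raise InvalidInputError("lj-solute fixture provides transformation 2")
        cfg = self.config
        n = cfg.solvent_count
        solvent_pos = self._solvent_positions(cfg.solvent_box, n)
        if sid == 1:
            positions = np.vstack([[[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]], solvent_pos])
            eps = np.concatenate([[cfg.ligand_epsilon, cfg.ligand_epsilon],
                                  np.full(n, cfg.solvent_epsilon)])
            rmin = np.concatenate([[cfg.ligand_rmin, cfg.ligand_rmin],
                                   np.full(n, cfg.solvent_rmin)])
            system = mc.ParticleSystem(
                positions=positions, epsilon=eps, r_min=rmin,
                restraints=[mc.RestraintSpec("atom-atom", (0,), (1,),
                                             k=cfg.restraint_k, r0=0.0)],
                box=np.full(3, cfg.solvent_box),
                coupling={0: +1, 1: -1}, temperature=cfg.fep_temperature,
            )
            return alchemy.StepSpec(system=system, shift_coeff=8.0, step_size=0.5)
        positions = np.vstack([[[0.0, 0.0, 0.0]], solvent_pos])
        eps = np.concatenate([[cfg.ligand_epsilon], np.full(n, cfg.solvent_epsilon)])
        rmin = np.concatenate([[cfg.ligand_rmin], np.full(n, cfg.solvent_rmin)])
        system = mc.ParticleSystem(
            positions=positions, epsilon=eps, r_min=rmin,
            box=np.full(3, cfg.solvent_box), coupling={0: +1},
            temperature=cfg.fep_temperature,
        )
        return alchemy.StepSpec(system=system, shift_coeff=20.0, step_size=0.5)

    # -- host-guest: three-site pocket, full two-transformation cycle -------

    def _host_atoms(self) -> np.ndarray:
        rho = self.config.site_circumradius
        return np.array([
            [rho, 0.0, 0.0],
            [-rho / 2.0, rho * math.sqrt(3) / 2.0, 0.0],
            [-rho / 2.0, -rho * math.sqrt(3) / 2.0, 0.0],
        ])

    def _host_guest_step(self, tid: int, sid: int) -> alchemy.StepSpec:
        cfg = self.config
        if tid not in (1, 2) or sid not in (1, 2):
            raise InvalidInputError("host-guest steps are (1|2, 1|2)")
        host = self._host_atoms()
        box = np.full(3, cfg.host_box)
        shift = 8.0 if sid == 1 else 20.0
        if tid == 1 and sid == 1:
            # ligand swapped out of the pocket while the dummy appears
            positions = np.vstack([host, [[0.2, 0.0, 0.0]], [[0.0, 0.1, 0.0]]])
            eps = np.concatenate([np.full(3, cfg.host_epsilon),
                                  [cfg.ligand_epsilon, cfg.ligand_epsilon]])
            rmin = np.concatenate([np.full(3, cfg.host_rmin),
                                   [cfg.ligand_rmin, cfg.ligand_rmin]])
            system = mc.ParticleSystem(
                positions=positions, epsilon=eps, r_min=rmin,
                restraints=[
                    mc.RestraintSpec("centroid-centroid", (0, 1, 2), (4,),
                                     k=cfg.restraint_k, r0=0.0),
                    mc.RestraintSpec("atom-atom", (3,), (4,), k=cfg.restraint_k,
                                     r0=0.0, lambda_coupled=True),
                ],
                box=box, coupling={3: +1, 4: -1},
                temperature=cfg.fep_temperature, fixed=frozenset({0, 1, 2}),
            )
            # cubic k(lambda): spreads the ligand-confinement free energy
            # evenly over windows (a harmonic volume scales as k^-3/2, so
            # near-geometric k spacing keeps window overlaps comparable)
            return alchemy.StepSpec(system=system, shift_coeff=shift,
                                    restraint_schedule=lambda lam_d:
                                        cfg.restraint_k * lam_d ** 3,
                                    step_size=0.8)
        if tid == 1 and sid == 2:
            # dummy decoupled from the pocket (ligand absent by construction)
            positions = np.vstack([host, [[0.0, 0.1, 0.0]]])
            eps = np.concatenate([np.full(3, cfg.host_epsilon), [cfg.ligand_epsilon]])
            rmin = np.concatenate([np.full(3, cfg.host_rmin), [cfg.ligand_rmin]])
            system = mc.ParticleSystem(
                positions=positions, epsilon=eps, r_min=rmin,
                restraints=[mc.RestraintSpec("centroid-centroid", (0, 1, 2), (3,),
                                             k=cfg.restraint_k, r0=0.0)],
                box=box, coupling={3: +1},
                temperature=cfg.fep_temperature, fixed=frozenset({0, 1, 2}),
            )
            return alchemy.StepSpec(system=system, shift_coeff=shift, step_size=0.8)
        # transformation 2: same steps with no host (vacuum bulk phase)
        if sid == 1:
            positions = np.array([[0.0, 0.0, 0.0], [0.0, 0.1, 0.0]])
            eps = np.full(2, cfg.ligand_epsilon)
            rmin = np.full(2, cfg.ligand_rmin)
            system = mc.ParticleSystem(
                positions=positions, epsilon=eps, r_min=rmin,
                restraints=[mc.RestraintSpec("atom-atom", (0,), (1,),
                                             k=cfg.restraint_k, r0=0.0)],
                box=box, coupling={0: +1, 1: -1},
                temperature=cfg.fep_temperature,
            )
            return alchemy.StepSpec(system=system, shift_coeff=shift, step_size=1.5)
        system = mc.ParticleSystem(
            positions=np.array([[0.0, 0.0, 0.0]]),
            epsilon=np.array([cfg.ligand_epsilon]),
            r_min=np.array([cfg.ligand_rmin]),
            box=box, coupling={0: +1}, temperature=cfg.fep_temperature,
        )
        return alchemy.StepSpec(system=system, shift_coeff=shift, step_size=1.5)

    # -- host-guest ground-truth helpers ------------------------------------

    def occupancy_system(self) -> mc.ParticleSystem:
        """Host + fully coupled ligand, unrestrained (for occupancy counting)."""
        if self.kind != "host-guest":
            raise InvalidInputError("occupancy system is a host-guest concept")
        cfg = self.config
        host = self._host_atoms()
        positions = np.vstack([host, [[0.2, 0.0, 0.0]]])
        eps = np.concatenate([np.full(3, cfg.host_epsilon), [cfg.ligand_epsilon]])
        rmin = np.concatenate([np.full(3, cfg.host_rmin), [cfg.ligand_rmin]])
        return mc.ParticleSystem(
            positions=positions, epsilon=eps, r_min=rmin,
            box=np.full(3, cfg.host_box), temperature=cfg.fep_temperature,
            fixed=frozenset({0, 1, 2}),
        )

    @property
    def site_radius(self) -> float:
        """Radius (from the pocket centre) beyond which the ligand-host
        interaction is identically zero: circumradius + vdW cutoff."""
        return self.config.site_circumradius + mc.CUTOFF

    def exact_dg_bind(self, grid: float = 0.25) -> float:
        """Grid-quadrature reference binding dG for the host-guest system.

        Integrates exp(-U/RT) over the whole box (deterministic grid) and
        converts to the standard state; exact up to grid resolution because
        the toy system is a single ligand around fixed host atoms.
        """
        if self.kind != "host-guest":
            raise InvalidInputError("exact dG is a host-guest concept")
        cfg = self.config
        host = self._host_atoms()
        half = cfg.host_box / 2.0
        axis = np.arange(-half + grid / 2.0, half, grid)
        rt = alchemy.R_KCAL * cfg.fep_temperature
        eps_pair = math.sqrt(cfg.host_epsilon * cfg.ligand_epsilon)
        rmin_pair = 0.5 * (cfg.host_rmin + cfg.ligand_rmin)
        total = 0.0
        xs, ys = np.meshgrid(axis, axis, indexing="ij")
        for z in axis:
            pts = np.stack([xs.ravel(), ys.ravel(), np.full(xs.size, z)], axis=1)
            u = np.zeros(len(pts))
            for h in host:
                r = np.linalg.norm(pts - h, axis=1)
                r = np.clip(r, 1e-6, None)
                x6 = (rmin_pair / r) ** 6
                u += np.where(r < mc.CUTOFF,
                              eps_pair * (x6 ** 2 - 2.0 * x6) * mc.switching_factor(r),
                              0.0)
            total += float(np.sum(np.exp(-np.clip(u, -200.0, 200.0) / rt)))
        z_conf = total * grid ** 3
        c_number = alchemy.AVOGADRO / 1e27
        return float(-rt * math.log(z_conf * c_number))


def generate_fep_fixture(kind: str, config: GeneratorConfig | None = None) -> FepFixture:
    """Build a toy system factory for the alchemical cycle.

    ``harmonic`` — one particle released from a lambda-scaled harmonic
    well; the analytic decoupling dG (erf-truncated Gaussian volume vs box
    volume) is attached as metadata. ``lj-solute`` — a Lennard-Jones solute
    in a small solvent box, providing transformation-2 style solvation
    steps. ``host-guest`` — a three-atom pocket binding a single-particle
    ligand, with the full two-transformation dummy-atom cycle; the dummy
    particle mirrors the ligand (vdW radius 4.5 A, well depth 1 kcal/mol).
    """
    config = config or GeneratorConfig()
    if kind not in ("harmonic", "lj-solute", "host-guest"):
        raise InvalidParameterError(f"unsupported fixture kind {kind!r}")
    fixture = FepFixture(kind=kind, config=config)
    if kind == "harmonic":
        box = np.full(3, config.harmonic_box)
        v_well = alchemy.restrained_volume(config.harmonic_k,
                                           config.fep_temperature, box)
        v_box = float(np.prod(box))
        fixture.metadata["analytic_dg_decouple"] = \
            -alchemy.R_KCAL * config.fep_temperature * math.log(v_box / v_well)
        fixture.metadata["harmonic_k"] = config.harmonic_k
    if kind == "host-guest":
        fixture.metadata["box_volume"] = config.host_box ** 3
        fixture.metadata["site_radius"] = fixture.site_radius
        fixture.metadata["well_depth_at_centre"] = -3.0 * math.sqrt(
            config.host_epsilon * config.ligand_epsilon)
    return fixture


# ---------------------------------------------------------------------------
# sedimentation datasets
# ---------------------------------------------------------------------------

def generate_auc_dataset(config: GeneratorConfig | None = None
                         ) -> tuple[list[auc.AucScan], dict]:
    """Multi-speed tetramer-octamer equilibrium scans plus ground truth.

    Defaults follow the study conditions: Kd = 118 uM, tetramer mass
    13.4 kDa, rotor speeds 25/30/35/40 k r.p.m., Gaussian noise 0.005 AU.
    """
    config = config or GeneratorConfig()
    model = auc.AssociationModel(
        base_mass=config.base_mass, vbar=config.vbar, rho=config.rho,
        scheme="self-association", kd=config.kd,
        extinction={1: config.extinction[0], 2: config.extinction[1]},
        baselines={s: config.baseline for s in config.speeds_rpm},
    )
    radii = np.linspace(config.radius_window[0], config.radius_window[1],
                        config.n_radii)
    scans = []
    for i, speed in enumerate(config.speeds_rpm):
        child_seed = int(substream(config.seed, "auc", i).integers(2 ** 31))
        scans.append(auc.simulate_scan(
            model, speed, radii, config.loading_concentration,
            noise_sigma=config.noise_sigma, seed=child_seed,
            temperature=config.auc_temperature))
    truth = {
        "kd": config.kd, "base_mass": config.base_mass,
        "assoc_mass": 2.0 * config.base_mass, "vbar": config.vbar,
        "rho": config.rho, "noise_sigma": config.noise_sigma,
        "loading_concentration": config.loading_concentration,
        "baselines": {str(s): config.baseline for s in config.speeds_rpm},
        "extinction": list(config.extinction), "seed": config.seed,
    }
    return scans, truth


# ---------------------------------------------------------------------------
# SEC fixtures
# ---------------------------------------------------------------------------

#: Kit-like calibration truth: log10(mass) = intercept + slope * volume
_SEC_SLOPE = -0.25
_SEC_INTERCEPT = 6.945
_SEC_KIT_MASSES = (6500.0, 12400.0, 29000.0, 66000.0)


def sec_true_volume(mass: float) -> float:
    """Elution volume (mL) of a mass on the synthetic column's true line."""
    return (math.log10(mass) - _SEC_INTERCEPT) / _SEC_SLOPE


def generate_sec_standards(config: GeneratorConfig | None = None,
                           jitter: float = 0.0) -> list[tuple[float, float]]:
    """Molecular-weight standards on the synthetic column (mass Da, volume mL)."""
    config = config or GeneratorConfig()
    rng = substream(config.seed, "sec")
    return [(m, sec_true_volume(m) + (rng.normal(0.0, jitter) if jitter else 0.0))
            for m in _SEC_KIT_MASSES]


def generate_sec_trace(masses: Sequence[float], amplitudes: Sequence[float],
                       config: GeneratorConfig | None = None,
                       peak_width: float = 0.25, noise: float = 0.002
                       ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthetic chromatogram with Gaussian peaks at given species masses."""
    config = config or GeneratorConfig()
    rng = substream(config.seed, "sec", 1)
    volumes = np.arange(7.0, 17.0, 0.02)
    signal = np.zeros_like(volumes)
    centers = []
    for m, a in zip(masses, amplitudes):
        v = sec_true_volume(m)
        centers.append(v)
        signal += a * np.exp(-0.5 * ((volumes - v) / peak_width) ** 2)
    if noise > 0:
        signal = signal + rng.normal(0.0, noise, volumes.shape)
    truth = {"masses": list(map(float, masses)), "volumes": centers,
             "slope": _SEC_SLOPE, "intercept": _SEC_INTERCEPT}
    return volumes, signal, truth
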