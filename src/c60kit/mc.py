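"""Minimal particle engine: Lennard-Jones energies with lambda coupling and
Metropolis Monte Carlo sampling.

The engine supplies configurational ensembles to the alchemical module at
desk scale. Conventions:

* Energies kcal/mol, lengths Angstrom, temperature K.
* Lennard-Jones in (epsilon, r_min) form, ``U = eps*((rm/r)^12 - 2(rm/r)^6)``,
  with Lorentz-Berthelot mixing (arithmetic r_min, geometric epsilon),
  a 10 A cutoff and a polynomial switching function starting at 6 A.
* ``lam`` is the *coupling strength* of the alchemical group: 1 = fully
  interacting, 0 = fully decoupled. (The decoupling-progress convention
  used by the alchemy module is the complement; the adapter lives there.)
* Soft core: for a pair at coupling scale ``s`` the squared distance inside
  the LJ kernel is shifted by ``shift_coeff * (1 - s)`` and the interaction
  is scaled by ``s``.
* Coupling assignments are signed: particles with assignment ``+1`` scale
  with ``lam`` (they disappear as lam -> 0), particles with ``-1`` scale
  with ``1 - lam`` (they appear as lam -> 0, the dual-topology partner).
  Pairs of opposite-sign alchemical particles are excluded (they occupy
  the same site); same-sign pairs interact at full strength
  (intramolecular convention).
* Harmonic terms are ``(k/2) * (d - r0)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import R_KCAL
from .errors import InvalidInputError, InvalidParameterError

CUTOFF = 10.0      # A; nonbonded cutoff
SWITCH_ON = 6.0    # A; switching function onset


@dataclass
class RestraintSpec:
    """Harmonic distance restraint between atoms or centroids."""

    kind: str                      # "atom-atom" | "centroid-centroid"
    members_a: tuple[int, ...]
    members_b: tuple[int, ...]
    k: float                       # kcal/mol/A^2
    r0: float = 0.0                # A
    lambda_coupled: bool = False

    def __post_init__(self):
        if self.kind not in ("atom-atom", "centroid-centroid"):
            raise InvalidParameterError(f"unknown restraint kind {self.kind!r}")
        self.members_a = tuple(int(i) for i in np.atleast_1d(self.members_a))
        self.members_b = tuple(int(i) for i in np.atleast_1d(self.members_b))
        if self.kind == "atom-atom" and (len(self.members_a) != 1 or len(self.members_b) != 1):
            raise InvalidInputError("atom-atom restraint takes single indices")
        if self.k < 0 or self.r0 < 0:
            raise InvalidParameterError("restraint k and r0 must be non-negative")


@dataclass
class EnergyBreakdown:
    vdw: float
    bonded: float
    restraint: float

    @property
    def total(self) -> float:
        return self.vdw + self.bonded + self.restraint


@dataclass
class ParticleSystem:
    """Positions plus interaction parameters for the toy engine.

    ``coupling`` maps particle index -> +1 (scales with lam) or -1
    (scales with 1 - lam). ``fixed`` particles are never moved by the
    sampler. ``external`` is an optional position-dependent potential
    (kcal/mol) added to the restraint component; it is how test systems
    such as 1-D double wells are expressed.
    """

    positions: np.ndarray                  # (N, 3) A
    epsilon: np.ndarray                    # (N,) kcal/mol
    r_min: np.ndarray                      # (N,) A (self-pair minimum)
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    restraints: list[RestraintSpec] = field(default_factory=list)
    box: np.ndarray | None = None          # (3,) A, orthorhombic, or None
    coupling: dict[int, int] = field(default_factory=dict)
    temperature: float = 298.15
    fixed: frozenset[int] = frozenset()
    external: Callable[[np.ndarray], float] | None = None

    def __post_init__(self):
        self.positions = np.array(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.r_min = np.asarray(self.r_min, dtype=float)
        if self.epsilon.shape != (n,) or self.r_min.shape != (n,):
            raise InvalidInputError("epsilon/r_min must have one entry per particle")
        pairs = [(min(i, j), max(i, j)) for i, j, _, _ in self.bonds]
        if len(pairs) != len(set(pairs)):
            raise InvalidInputError("duplicate bonds")
        if any(not (0 <= i < n) for p in pairs for i in p):
            raise InvalidInputError("bond index out of range")
        if any(not (0 <= i < n) for i in self.coupling):
            raise InvalidInputError("coupling set must be a subset of particle indices")
        if any(s not in (-1, 1) for s in self.coupling.values()):
            raise InvalidInputError("coupling assignments must be +1 or -1")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise InvalidInputError("box edges must be positive")
            if np.any(self.epsilon > 0) and np.any(self.box <= 2 * CUTOFF):
                raise InvalidInputError(
                    "periodic box edges must exceed twice the interaction cutoff")
        self.fixed = frozenset(self.fixed)
        self._excluded = frozenset(pairs)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image displacement(s) a - b."""
        d = a - b
        if self.box is not None:
            d = d - self.box * np.round(d / self.box)
        return d


def switching_factor(r: np.ndarray) -> np.ndarray:
    """CHARMM-style energy switching on [SWITCH_ON, CUTOFF]."""
    r = np.asarray(r, dtype=float)
    r2 = r * r
    on2, off2 = SWITCH_ON ** 2, CUTOFF ** 2
    s = (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / (off2 - on2) ** 3
    return np.where(r2 <= on2, 1.0, np.where(r2 >= off2, 0.0, s))


class _PairTable:
    """Precomputed N x N pair parameters at a fixed coupling strength.

    ``scale`` carries the per-pair interaction scale (0 disables a pair —
    used both for exclusions and for fully decoupled states), ``shift`` the
    per-pair soft-core squared-distance shift, and ``lam_dep`` marks pairs
    whose energy depends on lambda (for perturbation energies).
    """

    def __init__(self, system: ParticleSystem, lam: float, shift_coeff: float):
        n = system.n_particles
        eps = np.sqrt(np.outer(system.epsilon, system.epsilon))
        rmin = 0.5 * (system.r_min[:, None] + system.r_min[None, :])
        scale = np.ones((n, n))
        lam_dep = np.zeros((n, n), dtype=bool)
        for i, sign in system.coupling.items():
            s_i = lam if sign > 0 else 1.0 - lam
            scale[i, :] = s_i
            scale[:, i] = s_i
            lam_dep[i, :] = True
            lam_dep[:, i] = True
        for i, si in system.coupling.items():
            for j, sj in system.coupling.items():
                if i == j:
                    continue
                if si != sj:
                    scale[i, j] = 0.0       # dual-topology exclusion
                else:
                    scale[i, j] = 1.0       # intramolecular: full strength
                lam_dep[i, j] = False
        for i, j in system._excluded:
            scale[i, j] = scale[j, i] = 0.0
            lam_dep[i, j] = lam_dep[j, i] = False
        np.fill_diagonal(scale, 0.0)
        np.fill_diagonal(lam_dep, False)
        active = (eps > 0) & (scale > 0)
        lam_dep &= (eps > 0)
        self.eps = eps
        self.rmin2 = rmin * rmin
        self.scale = scale
        self.shift = shift_coeff * (1.0 - scale)
        self.active = active
        self.lam_dep = lam_dep
        self.box = system.box

    def row_energy(self, positions: np.ndarray, i: int,
                   mask: np.ndarray | None = None) -> float:
        """Sum of pair energies between particle i and all active partners."""
        act = self.active[i] if mask is None else (self.active[i] & mask)
        if not act.any():
            return 0.0
        d = positions[act] - positions[i]
        if self.box is not None:
            d -= self.box * np.round(d / self.box)
        r2 = np.einsum("ij,ij->i", d, d)
        within = r2 < CUTOFF ** 2
        if not within.any():
            return 0.0
        r2 = r2[within]
        sw = switching_factor(np.sqrt(r2))
        x = self.rmin2[i, act][within] / (r2 + self.shift[i, act][within])
        x3 = x * x * x
        e = self.scale[i, act][within] * self.eps[i, act][within] \
            * (x3 * x3 - 2.0 * x3) * sw
        return float(e.sum())

    def total_energy(self, positions: np.ndarray,
                     which: np.ndarray | None = None) -> float:
        """Sum over pairs; ``which`` restricts to a pair mask (upper use)."""
        n = len(positions)
        total = 0.0
        sel = self.active if which is None else (self.active & which)
        for i in range(n - 1):
            mask = np.zeros(n, dtype=bool)
            mask[i + 1:] = True
            row = sel[i] & mask
            if not row.any():
                continue
            d = positions[row] - positions[i]
            if self.box is not None:
                d -= self.box * np.round(d / self.box)
            r2 = np.einsum("ij,ij->i", d, d)
            within = r2 < CUTOFF ** 2
            if not within.any():
                continue
            r2 = r2[within]
            sw = switching_factor(np.sqrt(r2))
            x = self.rmin2[i, row][within] / (r2 + self.shift[i, row][within])
            x3 = x * x * x
            total += float((self.scale[i, row][within] * self.eps[i, row][within]
                            * (x3 * x3 - 2.0 * x3) * sw).sum())
        return total


def _restraint_distance(system: ParticleSystem, positions: np.ndarray,
                        spec: RestraintSpec) -> float:
    pa = positions[list(spec.members_a)].mean(axis=0)
    pb = positions[list(spec.members_b)].mean(axis=0)
    return float(np.linalg.norm(system.displacement(pa, pb)))


def _restraint_energy(system: ParticleSystem, positions: np.ndarray,
                      coupled_restraint_k: float | None) -> float:
    total = 0.0
    for spec in system.restraints:
        k = spec.k
        if spec.lambda_coupled and coupled_restraint_k is not None:
            k = coupled_restraint_k
        if k == 0.0:
            continue
        d = _restraint_distance(system, positions, spec)
        total += 0.5 * k * (d - spec.r0) ** 2
    if system.external is not None:
        total += float(system.external(positions))
    return total


def _bond_energy(system: ParticleSystem, positions: np.ndarray) -> float:
    total = 0.0
    for i, j, k, r0 in system.bonds:
        r = float(np.linalg.norm(system.displacement(positions[i], positions[j])))
        total += 0.5 * k * (r - r0) ** 2
    return total


def energy(system: ParticleSystem, lam: float = 1.0, shift_coeff: float = 8.0,
           coupled_restraint_k: float | None = None,
           positions: np.ndarray | None = None) -> EnergyBreakdown:
    """Total energy breakdown at coupling strength ``lam``.

    ``coupled_restraint_k`` overrides the force constant of every
    lambda-coupled restraint (the alchemy layer computes it from its
    restraint schedule); plain restraints always use their own ``k``.
    """
    if not (0.0 <= lam <= 1.0):
        raise InvalidParameterError("lam must lie in [0, 1]")
    if shift_coeff < 0:
        raise InvalidParameterError("shift_coeff must be non-negative")
    pos = system.positions if positions is None else np.asarray(positions, float)
    table = _PairTable(system, lam, shift_coeff)
    return EnergyBreakdown(
        vdw=table.total_energy(pos),
        bonded=_bond_energy(system, pos),
        restraint=_restraint_energy(system, pos, coupled_restraint_k),
    )


def coupling_energy(system: ParticleSystem, positions: np.ndarray, lam: float,
                    shift_coeff: float,
                    coupled_restraint_k: float | None) -> float:
    """The lambda-dependent part of the energy (used for FEP Delta-U).

    Includes alchemical-pair vdW terms and lambda-coupled restraints;
    lambda-independent terms cancel in window differences and are omitted.
    """
    table = _PairTable(system, lam, shift_coeff)
    total = table.total_energy(positions, which=table.lam_dep)
    for spec in system.restraints:
        if spec.lambda_coupled:
            k = spec.k if coupled_restraint_k is None else coupled_restraint_k
            if k != 0.0:
                d = _restraint_distance(system, positions, spec)
                total += 0.5 * k * (d - spec.r0) ** 2
    return total


def _particle_energy(system: ParticleSystem, table: _PairTable,
                     positions: np.ndarray, i: int,
                     coupled_restraint_k: float | None) -> float:
    """All energy terms that involve particle i (for single-particle moves)."""
    total = table.row_energy(positions, i)
    for idx, j, k, r0 in system.bonds:
        if i in (idx, j):
            r = float(np.linalg.norm(system.displacement(positions[idx], positions[j])))
            total += 0.5 * k * (r - r0) ** 2
    for spec in system.restraints:
        if i in spec.members_a or i in spec.members_b:
            k = spec.k
            if spec.lambda_coupled and coupled_restraint_k is not None:
                k = coupled_restraint_k
            if k != 0.0:
                d = _restraint_distance(system, positions, spec)
                total += 0.5 * k * (d - spec.r0) ** 2
    if system.external is not None:
        total += float(system.external(positions))
    return total


@dataclass
class SampleRecord:
    step: int
    energy: EnergyBreakdown | None
    delta_u: dict[float, float]    # neighbour lam -> U(neigh) - U(current)


@dataclass
class SampleResult:
    records: list[SampleRecord]
    acceptance_rate: float
    final_positions: np.ndarray
    positions_trace: np.ndarray | None = None   # (n_records, N, 3) if recorded

    def delta_u_to(self, lam: float) -> np.ndarray:
        return np.array([rec.delta_u[lam] for rec in self.records])


def _pair_lists(system: ParticleSystem, lam: float, shift_coeff: float):
    """Float-native per-particle pair lists for the sampler's inner loop."""
    table = _PairTable(system, lam, shift_coeff)
    n = system.n_particles
    partners: list[list[tuple]] = [[] for _ in range(n)]
    lam_dep_pairs: list[tuple] = []   # (i, j, eps, rmin2, sign)
    for i in range(n):
        for j in range(i + 1, n):
            if table.active[i, j]:
                entry = (float(table.eps[i, j]), float(table.rmin2[i, j]),
                         float(table.scale[i, j]), float(table.shift[i, j]))
                partners[i].append((j,) + entry)
                partners[j].append((i,) + entry)
            if table.lam_dep[i, j]:
                sign = system.coupling.get(i, system.coupling.get(j))
                lam_dep_pairs.append((i, j, float(table.eps[i, j]),
                                      float(table.rmin2[i, j]), int(sign)))
    return partners, lam_dep_pairs


_SW_DENOM = (CUTOFF ** 2 - SWITCH_ON ** 2) ** 3


def _switch_r2(r2: float) -> float:
    on2, off2 = SWITCH_ON ** 2, CUTOFF ** 2
    if r2 <= on2:
        return 1.0
    if r2 >= off2:
        return 0.0
    return (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / _SW_DENOM


def _lam_dep_energy(pos, lam_dep_pairs, lam: float, shift_coeff: float,
                    box) -> float:
    """Lambda-dependent pair energy on float positions (soft-core LJ)."""
    e = 0.0
    for i, j, eps, rmin2, sign in lam_dep_pairs:
        s = lam if sign > 0 else 1.0 - lam
        if s <= 0.0:
            continue
        dx = pos[i][0] - pos[j][0]
        dy = pos[i][1] - pos[j][1]
        dz = pos[i][2] - pos[j][2]
        if box is not None:
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= CUTOFF ** 2:
            continue
        x = rmin2 / (r2 + shift_coeff * (1.0 - s))
        x3 = x * x * x
        e += s * eps * (x3 * x3 - 2.0 * x3) * _switch_r2(r2)
    return e


def _restraint_distance_f(pos, spec: RestraintSpec, box) -> float:
    ax = ay = az = 0.0
    for m in spec.members_a:
        ax += pos[m][0]; ay += pos[m][1]; az += pos[m][2]
    na = len(spec.members_a)
    ax /= na; ay /= na; az /= na
    bx = by = bz = 0.0
    for m in spec.members_b:
        bx += pos[m][0]; by += pos[m][1]; bz += pos[m][2]
    nb = len(spec.members_b)
    bx /= nb; by /= nb; bz /= nb
    dx, dy, dz = ax - bx, ay - by, az - bz
    if box is not None:
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def sample(system: ParticleSystem, lam: float, n_steps: int, step_size: float,
           seed: int, shift_coeff: float = 8.0,
           coupled_restraint_k: float | None = None,
           neighbors: Sequence[tuple[float, float | None]] = (),
           sample_every: int = 10, equilibration: int = 0,
           record_positions: bool = False, record_energy: bool = True,
           initial_positions: np.ndarray | None = None) -> SampleResult:
    """Metropolis Monte Carlo at the system temperature.

    Single-particle trial moves, uniform in a cube of half-width
    ``step_size``; deterministic given ``seed``. After ``equilibration``
    steps, every ``sample_every``-th step records the energy breakdown
    (unless ``record_energy`` is off) and the perturbation energies
    Delta-U to each ``(lam, restraint_k)`` neighbour state.
    """
    if system.n_particles == 0:
        raise InvalidInputError("cannot sample a zero-particle system")
    if n_steps <= 0:
        raise InvalidParameterError("n_steps must be positive")
    if not (0.0 <= lam <= 1.0):
        raise InvalidParameterError("lam must lie in [0, 1]")
    movable = [i for i in range(system.n_particles) if i not in system.fixed]
    if not movable:
        raise InvalidInputError("all particles are fixed")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (R_KCAL * system.temperature)
    start = (system.positions if initial_positions is None
             else np.asarray(initial_positions, float))
    pos = [[float(x), float(y), float(z)] for x, y, z in start]
    partners, lam_dep_pairs = _pair_lists(system, lam, shift_coeff)
    box = None if system.box is None else tuple(float(b) for b in system.box)
    cut2 = CUTOFF ** 2
    bonds_by: dict[int, list] = {}
    for bond in system.bonds:
        bonds_by.setdefault(bond[0], []).append(bond)
        bonds_by.setdefault(bond[1], []).append(bond)
    restr_by: dict[int, list] = {}
    for spec in system.restraints:
        for m in set(spec.members_a) | set(spec.members_b):
            restr_by.setdefault(m, []).append(spec)

    def site_energy(i: int) -> float:
        px, py, pz = pos[i]
        e = 0.0
        for j, eps, rmin2, s, shift in partners[i]:
            dx = px - pos[j][0]
            dy = py - pos[j][1]
            dz = pz - pos[j][2]
            if box is not None:
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
                dz -= box[2] * round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2:
                continue
            x = rmin2 / (r2 + shift)
            x3 = x * x * x
            e += s * eps * (x3 * x3 - 2.0 * x3) * _switch_r2(r2)
        for bi, bj, bk, br0 in bonds_by.get(i, ()):
            dx = pos[bi][0] - pos[bj][0]
            dy = pos[bi][1] - pos[bj][1]
            dz = pos[bi][2] - pos[bj][2]
            if box is not None:
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
                dz -= box[2] * round(dz / box[2])
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            e += 0.5 * bk * (r - br0) ** 2
        for spec in restr_by.get(i, ()):
            k = spec.k
            if spec.lambda_coupled and coupled_restraint_k is not None:
                k = coupled_restraint_k
            if k != 0.0:
                d = _restraint_distance_f(pos, spec, box)
                e += 0.5 * k * (d - spec.r0) ** 2
        if system.external is not None:
            e += float(system.external(np.array(pos)))
        return e

    def lam_part(lam_value: float, k_value: float | None) -> float:
        total = _lam_dep_energy(pos, lam_dep_pairs, lam_value, shift_coeff, box)
        for spec in system.restraints:
            if spec.lambda_coupled:
                kk = spec.k if k_value is None else k_value
                if kk != 0.0:
                    d = _restraint_distance_f(pos, spec, box)
                    total += 0.5 * kk * (d - spec.r0) ** 2
        return total

    records: list[SampleRecord] = []
    traces: list[np.ndarray] = []
    accepted = 0
    total_moves = equilibration + n_steps
    n_mov = len(movable)
    half = None if box is None else tuple(b / 2.0 for b in box)
    for step in range(total_moves):
        i = movable[int(rng.integers(n_mov))]
        old = pos[i]
        e_old = site_energy(i)
        trial = [old[0] + (2.0 * rng.random() - 1.0) * step_size,
                 old[1] + (2.0 * rng.random() - 1.0) * step_size,
                 old[2] + (2.0 * rng.random() - 1.0) * step_size]
        if box is not None:
            for d in range(3):
                trial[d] = (trial[d] + half[d]) % box[d] - half[d]
        pos[i] = trial
        e_new = site_energy(i)
        de = e_new - e_old
        if de <= 0 or rng.random() < math.exp(-beta * de):
            accepted += 1
        else:
            pos[i] = old
        collect = step >= equilibration
        if collect and (step - equilibration) % sample_every == sample_every - 1:
            ebd = energy(system, lam, shift_coeff, coupled_restraint_k,
                         positions=np.array(pos)) if record_energy else None
            u_here = lam_part(lam, coupled_restraint_k)
            dus = {}
            for nlam, nk in neighbors:
                dus[nlam] = lam_part(nlam, nk) - u_here
            records.append(SampleRecord(step=step, energy=ebd, delta_u=dus))
            if record_positions:
                traces.append(np.array(pos))
    return SampleResult(
        records=records,
        acceptance_rate=accepted / total_moves,
        final_positions=np.array(pos),
        positions_trace=np.array(traces) if record_positions else None,
    )


# ---------------------------------------------------------------------------
# YAML system I/O
# ---------------------------------------------------------------------------

def system_to_dict(system: ParticleSystem) -> dict:
    return {
        "positions": system.positions.tolist(),
        "epsilon": system.epsilon.tolist(),
        "r_min": system.r_min.tolist(),
        "bonds": [list(b) for b in system.bonds],
        "restraints": [{
            "kind": r.kind, "members_a": list(r.members_a),
            "members_b": list(r.members_b), "k": r.k, "r0": r.r0,
            "lambda_coupled": r.lambda_coupled,
        } for r in system.restraints],
        "box": None if system.box is None else system.box.tolist(),
        "coupling": {int(k): int(v) for k, v in system.coupling.items()},
        "temperature": system.temperature,
        "fixed": sorted(system.fixed),
    }


def system_from_dict(data: dict) -> ParticleSystem:
    return ParticleSystem(
        positions=np.array(data["positions"], dtype=float),
        epsilon=np.array(data["epsilon"], dtype=float),
        r_min=np.array(data["r_min"], dtype=float),
        bonds=[tuple(b) for b in data.get("bonds", [])],
        restraints=[RestraintSpec(**r) for r in data.get("restraints", [])],
        box=None if data.get("box") is None else np.array(data["box"], dtype=float),
        coupling={int(k): int(v) for k, v in data.get("coupling", {}).items()},
        temperature=float(data.get("temperature", 298.15)),
        fixed=frozenset(data.get("fixed", [])),
    )


def load_system_yaml(path) -> ParticleSystem:
    import yaml
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))


def dump_system_yaml(system: ParticleSystem, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)
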