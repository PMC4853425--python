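"""Free-energy estimation and double-decoupling cycle bookkeeping.

The binding free energy of a ligand for its site is computed from two
alchemical transformations, each split into two steps by a single-atom
"dummy" intermediate that keeps the path reversible:

* transformation 1 (bound complex): step 1 swaps the ligand out while the
  dummy appears in the site; step 2 decouples the dummy (the ligand need
  not be present).
* transformation 2 (ligand in bulk): the same two steps without the host.

Because the gas-phase dummy appears in both end states its contribution
cancels, and

    dG_bind = dG(transformation 2) - dG(transformation 1) + dG_corr,

where ``dG_corr`` converts the harmonically restrained decoupled ligand
to the 1 M standard state. Per-window free energies use the Zwanzig
(exponential-averaging / FEP) estimator; lambda here is the *decoupling
progress* (0 = fully coupled, 1 = fully decoupled) and is adapted to the
engine's coupling-strength convention internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf, logsumexp

from . import mc
from .constants import AVOGADRO, R_KCAL
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def zwanzig(delta_u: Sequence[float], temperature: float) -> float:
    """Zwanzig/FEP free-energy difference from perturbation energies.

    dG = -RT ln < exp(-dU/RT) >, evaluated with log-sum-exp so single
    extreme samples cannot overflow.
    """
    du = np.asarray(delta_u, dtype=float)
    if du.size == 0:
        raise InsufficientDataError("need at least one perturbation sample")
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    rt = R_KCAL * temperature
    return float(-rt * (logsumexp(-du / rt) - math.log(du.size)))


def bar(delta_u_forward: Sequence[float], delta_u_reverse: Sequence[float],
        temperature: float, tol: float = 1e-10) -> float:
    """Bennett acceptance ratio estimate (optional cross-check estimator).

    ``delta_u_forward`` are U1-U0 sampled in state 0; ``delta_u_reverse``
    are U0-U1 sampled in state 1. Returns dG(0 -> 1).
    """
    from scipy.optimize import brentq

    wf = np.asarray(delta_u_forward, float)
    wr = np.asarray(delta_u_reverse, float)
    if wf.size == 0 or wr.size == 0:
        raise InsufficientDataError("BAR needs samples from both states")
    rt = R_KCAL * temperature

    def log_mean_fermi(x: np.ndarray) -> float:
        # log < 1/(1+exp(x)) > via logsumexp for stability
        return float(logsumexp(-np.logaddexp(0.0, x)) - math.log(x.size))

    def imbalance(c: float) -> float:
        # monotone increasing in c; root is the self-consistent constant
        return log_mean_fermi((wf - c) / rt) - log_mean_fermi((wr + c) / rt)

    guess = zwanzig(wf, temperature)
    lo, hi = guess - 1.0, guess + 1.0
    for _ in range(200):
        if imbalance(lo) < 0 and imbalance(hi) > 0:
            break
        lo -= 10.0
        hi += 10.0
    c_star = brentq(imbalance, lo, hi, xtol=tol)
    return float(c_star - rt * math.log(wr.size / wf.size))


def importance_reweight(samples: Sequence[float], bias_energies: Sequence[float],
                        temperature: float) -> float:
    """Unbias an expectation sampled under an added bias potential.

    <A>_unbiased = <A exp(+U_bias/RT)> / <exp(+U_bias/RT)>, log-sum-exp
    stable.
    """
    a = np.asarray(samples, dtype=float)
    u = np.asarray(bias_energies, dtype=float)
    if a.shape != u.shape:
        raise InvalidInputError("samples and bias energies must align")
    if a.size == 0:
        raise InsufficientDataError("need at least one sample")
    rt = R_KCAL * temperature
    logw = u / rt
    logw -= logw.max()
    w = np.exp(logw)
    return float(np.sum(a * w) / np.sum(w))


# ---------------------------------------------------------------------------
# restraint schedule and standard-state correction
# ---------------------------------------------------------------------------

def restraint_schedule(lam: float, k_max: float = 10.0) -> float:
    """Ligand-dummy restraint force constant along the decoupling path.

    ``lam`` is decoupling progress (0 = fully coupled, 1 = fully
    decoupled); the default form is linear, k = k_max * lam, rising from 0
    to ``k_max`` (kcal/mol/A^2) as the ligand is decoupled. Any monotone
    form with these endpoints yields the same end-state physics; the form
    only affects variance.
    """
    if not (0.0 <= lam <= 1.0):
        raise InvalidParameterError("lam must lie in [0, 1]")
    return k_max * lam


def restrained_volume(k: float, temperature: float,
                      box: Sequence[float] | None = None) -> float:
    """Configurational volume of a 3-D harmonic restraint, A^3.

    V_k = integral exp(-k r^2 / 2RT) d^3r = (2 pi RT / k)^(3/2); with a
    finite periodic box the integral is truncated per axis (erf form).
    """
    if k <= 0:
        raise InvalidParameterError("divergent volume: k must be positive")
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    rt = R_KCAL * temperature
    if box is None:
        return float((2.0 * math.pi * rt / k) ** 1.5)
    vol = 1.0
    for edge in np.asarray(box, float):
        a = k / (2.0 * rt)
        vol *= math.sqrt(math.pi / a) * erf((edge / 2.0) * math.sqrt(a))
    return float(vol)


def standard_state_correction(k: float, temperature: float,
                              c_standard: float = 1.0) -> float:
    """Free energy of swapping the restraint volume for the standard volume.

    Returns -RT ln(c_std * V_k) with the concentration converted to
    molecules/A^3, i.e. +RT ln(V_std / V_k); added to
    dG(T2) - dG(T1) it converts the restrained decoupled end state of
    transformation 1 to the ``c_standard`` (default 1 M) reference.
    """
    if c_standard <= 0:
        raise InvalidParameterError("c_standard must be positive")
    v_k = restrained_volume(k, temperature)          # validates k, T
    rt = R_KCAL * temperature
    c_number = c_standard * AVOGADRO / 1e27          # molecules per A^3
    return float(-rt * math.log(c_number * v_k))


def kd_from_dg(dg_bind: float, temperature: float, c_standard: float = 1.0) -> float:
    """Dissociation constant (M) from a standard binding free energy."""
    return float(c_standard * math.exp(dg_bind / (R_KCAL * temperature)))


def dg_from_kd(kd: float, temperature: float, c_standard: float = 1.0) -> float:
    if kd <= 0:
        raise InvalidParameterError("Kd must be positive")
    return float(R_KCAL * temperature * math.log(kd / c_standard))


def dg_from_bound_fraction(bound_fraction: float, v_unbound: float,
                           temperature: float, c_standard: float = 1.0) -> float:
    """Standard binding dG from direct occupancy counting.

    For a single ligand in a box whose interaction with the host vanishes
    outside a site of known complementary volume ``v_unbound`` (A^3), the
    configurational integral is Z = v_unbound / (1 - f) with ``f`` the
    observed bound fraction, and dG = -RT ln(Z * c_std) on the molar scale.
    """
    if not (0.0 < bound_fraction < 1.0):
        raise InvalidParameterError("bound fraction must lie strictly in (0, 1)")
    if v_unbound <= 0:
        raise InvalidParameterError("unbound volume must be positive")
    rt = R_KCAL * temperature
    c_number = c_standard * AVOGADRO / 1e27
    return float(-rt * math.log(v_unbound / (1.0 - bound_fraction) * c_number))


# ---------------------------------------------------------------------------
# schedules and transformation runs
# ---------------------------------------------------------------------------

@dataclass
class LambdaSchedule:
    """Uniform lambda windows with per-window sampler lengths."""

    n_windows: int = 20
    equilibration: int = 1000      # sampler steps per window
    collection: int = 19000        # sampler steps per window

    def __post_init__(self):
        if self.n_windows < 2:
            raise InvalidParameterError("need at least 2 windows")
        if self.equilibration < 0 or self.collection <= 0:
            raise InvalidParameterError("invalid window lengths")

    @property
    def lambdas(self) -> np.ndarray:
        """Window boundaries: n_windows + 1 values, uniform on [0, 1]."""
        return np.linspace(0.0, 1.0, self.n_windows + 1)


@dataclass
class StepSpec:
    """End-state-correct system for one step of one transformation."""

    system: mc.ParticleSystem
    shift_coeff: float = 8.0
    restraint_schedule: Callable[[float], float] | None = None
    step_size: float = 0.4


SystemFactory = Callable[[int, int], StepSpec]


@dataclass
class TransformationResult:
    """Per-window free energies of one replicate of one step."""

    transformation_id: int
    step_id: int
    direction: str                 # "forward" | "reverse"
    seed: int
    lambdas: np.ndarray            # decoupling-progress window boundaries
    per_window_dg: np.ndarray      # kcal/mol, in run order
    acceptance_rates: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def cumulative_dg(self) -> float:
        return float(self.per_window_dg.sum())

    @property
    def dg_decoupling(self) -> float:
        """Cumulative dG reported in the decoupling direction.

        Reverse-direction runs are negated on reporting so that all values
        share the decoupling sign convention.
        """
        return self.cumulative_dg if self.direction == "forward" else -self.cumulative_dg


def run_transformation(factory: SystemFactory, schedule: LambdaSchedule,
                       transformation_id: int, step_id: int, direction: str,
                       seed: int, sample_every: int = 10) -> TransformationResult:
    """Run one replicate of one step of a decoupling transformation.

    ``factory(transformation_id, step_id)`` must return a
    :class:`StepSpec` whose system encodes the correct end states
    (alchemical coupling assignments, restraints). Forward runs walk the
    decoupling progress 0 -> 1; reverse runs walk 1 -> 0. Each window
    samples at its starting lambda and estimates dG to the next lambda by
    the Zwanzig estimator; the lambda-coupled restraint force constant
    follows the step's restraint schedule and its energy enters the
    perturbation energies.
    """
    if direction not in ("forward", "reverse"):
        raise ConfigurationError("direction must be 'forward' or 'reverse'")
    spec = factory(transformation_id, step_id)
    if not isinstance(spec, StepSpec):
        raise ConfigurationError("system factory must return a StepSpec")
    lam_d = schedule.lambdas
    order = range(schedule.n_windows) if direction == "forward" \
        else range(schedule.n_windows - 1, -1, -1)
    k_of = spec.restraint_schedule
    per_window = []
    acc = []
    positions = None
    for w_idx, w in enumerate(order):
        if direction == "forward":
            l_here, l_next = lam_d[w], lam_d[w + 1]
        else:
            l_here, l_next = lam_d[w + 1], lam_d[w]
        k_here = None if k_of is None else k_of(l_here)
        k_next = None if k_of is None else k_of(l_next)
        result = mc.sample(
            spec.system, lam=1.0 - l_here, n_steps=schedule.collection,
            step_size=spec.step_size, seed=seed * 100003 + w_idx,
            shift_coeff=spec.shift_coeff, coupled_restraint_k=k_here,
            neighbors=[(1.0 - l_next, k_next)], sample_every=sample_every,
            equilibration=schedule.equilibration, initial_positions=positions,
            record_energy=False,
        )
        positions = result.final_positions
        du = result.delta_u_to(1.0 - l_next)
        per_window.append(zwanzig(du, spec.system.temperature))
        acc.append(result.acceptance_rate)
    return TransformationResult(
        transformation_id=transformation_id, step_id=step_id,
        direction=direction, seed=seed, lambdas=lam_d,
        per_window_dg=np.array(per_window), acceptance_rates=np.array(acc),
    )


# ---------------------------------------------------------------------------
# cycle combination and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CycleResult:
    """Combined double-decoupling cycle with error propagation."""

    step_summary: dict              # (transformation, step) -> (mean, se, n)
    dg_transformation_1: float
    dg_transformation_2: float
    correction: float
    dg_bind: float
    se: float
    kd: float
    temperature: float
    c_standard: float = 1.0


def _summarise_steps(results: Sequence[TransformationResult]) -> dict:
    groups: dict[tuple[int, int], list[float]] = {}
    for r in results:
        groups.setdefault((r.transformation_id, r.step_id), []).append(r.dg_decoupling)
    out = {}
    for key, vals in groups.items():
        arr = np.array(vals)
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out[key] = (float(arr.mean()), se, len(arr))
    return out


def combine_cycle(results_1: Sequence[TransformationResult],
                  results_2: Sequence[TransformationResult],
                  correction: float, temperature: float = 298.15,
                  c_standard: float = 1.0) -> CycleResult:
    """Combine the two transformations into a standard-state binding dG.

    Replicates of each step (forward and negated reverse pooled) are
    averaged; the standard error of the final estimate is propagated in
    quadrature over the four step-level standard errors. The dissociation
    constant is Kd = c_std * exp(dG_bind / RT).
    """
    summary = _summarise_steps(list(results_1) + list(results_2))
    for tid, results in ((1, results_1), (2, results_2)):
        for sid in (1, 2):
            if (tid, sid) not in summary:
                raise ConfigurationError(
                    f"incomplete cycle: transformation {tid} step {sid} missing")
        if any(r.transformation_id != tid for r in results):
            raise ConfigurationError("results passed under the wrong transformation")
    dg1 = summary[(1, 1)][0] + summary[(1, 2)][0]
    dg2 = summary[(2, 1)][0] + summary[(2, 2)][0]
    dg_bind = dg2 - dg1 + correction
    se = math.sqrt(sum(v[1] ** 2 for v in summary.values()))
    return CycleResult(
        step_summary=summary, dg_transformation_1=dg1, dg_transformation_2=dg2,
        correction=correction, dg_bind=dg_bind, se=se,
        kd=kd_from_dg(dg_bind, temperature, c_standard),
        temperature=temperature, c_standard=c_standard,
    )


def hysteresis_report(results: Sequence[TransformationResult]) -> pd.DataFrame:
    """Forward/reverse convergence table per (transformation, step).

    ``discrepancy`` is |mean forward - mean negated-reverse|; a step is
    flagged when it exceeds twice the combined standard error.
    """
    keys = sorted({(r.transformation_id, r.step_id) for r in results})
    rows = []
    for tid, sid in keys:
        fwd = [r.dg_decoupling for r in results
               if (r.transformation_id, r.step_id) == (tid, sid) and r.direction == "forward"]
        rev = [r.dg_decoupling for r in results
               if (r.transformation_id, r.step_id) == (tid, sid) and r.direction == "reverse"]
        if not fwd or not rev:
            raise InsufficientDataError(
                f"transformation {tid} step {sid}: need both directions")
        fwd, rev = np.array(fwd), np.array(rev)
        se_f = fwd.std(ddof=1) / math.sqrt(len(fwd)) if len(fwd) > 1 else 0.0
        se_r = rev.std(ddof=1) / math.sqrt(len(rev)) if len(rev) > 1 else 0.0
        combined = math.sqrt(se_f ** 2 + se_r ** 2)
        disc = abs(fwd.mean() - rev.mean())
        rows.append({
            "transformation": tid, "step": sid,
            "mean_forward": fwd.mean(), "se_forward": se_f,
            "mean_reverse_negated": rev.mean(), "se_reverse": se_r,
            "discrepancy": disc, "combined_se": combined,
            "flagged": bool(disc > 2.0 * combined),
        })
    return pd.DataFrame(rows)


def campaign_time_ns(n_windows: int = 20, equil_ps: float = 10.0,
                     collect_ps: float = 190.0, pre_equil_ps: float = 200.0,
                     replicates: int = 10, directions: int = 2,
                     steps: int = 2, transformations: int = 2) -> float:
    """Total simulated time implied by a window/replicate FEP protocol.

    Counts per-run pre-equilibration plus every window's equilibration and
    collection, over all steps, transformations, directions and replicates.
    """
    runs = transformations * steps * directions * replicates
    per_run_ps = pre_equil_ps + n_windows * (equil_ps + collect_ps)
    return runs * per_run_ps / 1000.0
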