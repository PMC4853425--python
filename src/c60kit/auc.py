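"""Sedimentation-equilibrium simulation and global self-association fitting.

At equilibrium every sedimenting species follows an exponential radial
concentration gradient,

    c(r) = c_ref * exp[ sigma * (r^2 - r_ref^2) ],
    sigma = M (1 - vbar rho) omega^2 / (2 R T)        [cm^-2],

and a self-associating n-mer <-> 2n-mer system is linked thermodynamically
at every radius by mass action, c_2n(r) = c_n(r)^2 / Kd. Because the
2n-mer's molar mass is exactly twice the n-mer's (shared partial specific
volume), sigma_2n = 2 sigma_n and the mass-action link imposed at the
reference radius holds at every radius — the simulator constructs
profiles this way, and the property is what makes the global multi-speed
fit identifiable.

Kd here is the dissociation constant of the 2n-mer into two n-mers,
Kd = [n-mer]^2 / [2n-mer], in molar units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import R_ERG
from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError


@dataclass
class AucScan:
    """One absorbance-vs-radius scan at a single rotor speed."""

    speed_rpm: float
    radii: np.ndarray          # cm, strictly increasing
    absorbance: np.ndarray     # AU
    wavelength: float = 340.0  # nm
    temperature: float = 298.15

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.radii.ndim != 1 or np.any(np.diff(self.radii) <= 0):
            raise InvalidInputError("radii must be strictly increasing")
        if self.absorbance.shape != self.radii.shape or not np.all(np.isfinite(self.absorbance)):
            raise InvalidInputError("absorbance must be finite and match radii")


@dataclass
class AssociationModel:
    """Species definition for simulation and fitting.

    ``base_mass`` is the n-mer (e.g. tetramer) molar mass; the associated
    species is the 2n-mer at exactly twice that mass. ``extinction`` maps
    species multiplicity (1 for the n-mer, 2 for the 2n-mer) to molar
    extinction in AU cm^-1 M^-1 per mole of that species.
    """

    base_mass: float                       # Da
    vbar: float = 0.73                     # mL/g
    rho: float = 1.0                       # g/mL
    scheme: str = "self-association"       # "single" | "self-association"
    kd: float | None = None                # M; required for self-association
    extinction: dict[int, float] = field(default_factory=lambda: {1: 5.0e3, 2: 1.0e4})
    path_length: float = 1.2               # cm
    baselines: dict[float, float] = field(default_factory=dict)  # speed -> AU

    def __post_init__(self):
        if self.base_mass <= 0:
            raise InvalidParameterError("base mass must be positive")
        if not (0.0 < self.vbar * self.rho < 1.0):
            raise InvalidParameterError("need 0 < vbar*rho < 1 for a sedimenting species")
        if self.scheme not in ("single", "self-association"):
            raise InvalidParameterError(f"unknown association scheme {self.scheme!r}")
        if self.scheme == "self-association":
            if self.kd is None or self.kd <= 0:
                raise InvalidParameterError("self-association requires Kd > 0")


def rpm_to_omega(rpm: float) -> float:
    """Rotor speed in r.p.m. to angular velocity in rad/s."""
    return rpm * 2.0 * math.pi / 60.0


def reduced_mass_sigma(mass: float, vbar: float, rho: float, omega: float,
                       temperature: float) -> float:
    """Exponent coefficient sigma = M (1 - vbar rho) omega^2 / (2RT), cm^-2."""
    if mass <= 0 or vbar <= 0 or rho <= 0 or temperature <= 0 or omega < 0:
        raise InvalidParameterError("all sigma inputs must be positive (omega >= 0)")
    buoyancy = 1.0 - vbar * rho
    if buoyancy <= 0:
        raise InvalidParameterError("vbar*rho >= 1: species does not sediment")
    return mass * buoyancy * omega ** 2 / (2.0 * R_ERG * temperature)


def species_profiles(model: AssociationModel, speed_rpm: float, radii: np.ndarray,
                     c_ref: float, r_ref: float | None = None,
                     temperature: float = 298.15) -> dict[int, np.ndarray]:
    """Molar concentration profile per species (keyed by multiplicity).

    ``c_ref`` is the base-species molar concentration at the reference
    radius (default: innermost radius). For the self-associating scheme the
    2n-mer is linked by mass action at the reference radius and carries its
    own exponential with sigma_2n = 2 sigma_n, so c_2n(r) = c_n(r)^2 / Kd
    holds at every radius.
    """
    radii = np.asarray(radii, dtype=float)
    if r_ref is None:
        r_ref = float(radii[0])
    omega = rpm_to_omega(speed_rpm)
    sigma1 = reduced_mass_sigma(model.base_mass, model.vbar, model.rho, omega,
                                temperature)
    arg = sigma1 * (radii ** 2 - r_ref ** 2)
    out = {1: c_ref * np.exp(arg)}
    if model.scheme == "self-association":
        c2_ref = c_ref ** 2 / model.kd
        out[2] = c2_ref * np.exp(2.0 * arg)
    return out


def simulate_scan(model: AssociationModel, speed_rpm: float, radii: Sequence[float],
                  c_ref: float, noise_sigma: float = 0.0, seed: int | None = None,
                  r_ref: float | None = None, wavelength: float = 340.0,
                  temperature: float = 298.15) -> AucScan:
    """Simulate one equilibrium absorbance scan with additive Gaussian noise."""
    radii = np.asarray(radii, dtype=float)
    profiles = species_profiles(model, speed_rpm, radii, c_ref, r_ref, temperature)
    absorbance = np.zeros_like(radii)
    for mult, conc in profiles.items():
        absorbance += model.extinction[mult] * model.path_length * conc
    absorbance += model.baselines.get(speed_rpm, 0.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sigma, radii.shape)
    return AucScan(speed_rpm=speed_rpm, radii=radii, absorbance=absorbance,
                   wavelength=wavelength, temperature=temperature)


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model_name: str                       # "single" | "self-association"
    parameters: dict[str, float]
    standard_errors: dict[str, float]
    residuals: list[np.ndarray]           # per scan
    rms: float                            # global
    converged: bool
    n_observations: int
    n_parameters: int
    comparison: dict | None = None        # filled by select_model


def _pack_predict(template: AssociationModel, scans: Sequence[AucScan],
                  fit_mass: bool):
    """Build (residual fn, initial params, names) for least_squares."""
    n = len(scans)
    names: list[str] = []
    if template.scheme == "self-association":
        names.append("log10_kd")
        x0 = [math.log10(template.kd if template.kd else 1e-4)]
    else:
        x0 = []
    if fit_mass:
        names.append("base_mass")
        x0.append(template.base_mass)
    for i in range(n):
        names += [f"ln_cref_{i}", f"baseline_{i}"]
        a = scans[i].absorbance
        span = max(a.max() - a.min(), 1e-6)
        eps_l = template.extinction[1] * template.path_length
        x0 += [math.log(max(span / eps_l / 3.0, 1e-12)), float(a.min())]

    def predict(x: np.ndarray, scan_idx: int) -> np.ndarray:
        model = template
        pos = 0
        if template.scheme == "self-association":
            model = replace(model, kd=10.0 ** x[pos])
            pos += 1
        if fit_mass:
            model = replace(model, base_mass=abs(x[pos]))
            pos += 1
        c_ref = math.exp(x[pos + 2 * scan_idx])
        baseline = x[pos + 2 * scan_idx + 1]
        scan = scans[scan_idx]
        profiles = species_profiles(model, scan.speed_rpm, scan.radii, c_ref,
                                    temperature=scan.temperature)
        a = np.zeros_like(scan.radii)
        for mult, conc in profiles.items():
            a += model.extinction[mult] * model.path_length * conc
        return a + baseline

    def residual(x: np.ndarray) -> np.ndarray:
        return np.concatenate([predict(x, i) - scans[i].absorbance
                               for i in range(n)])

    return residual, np.array(x0, dtype=float), names


def fit_global(scans: Sequence[AucScan], template: AssociationModel,
               fit_mass: bool | None = None, max_nfev: int = 2000) -> FitResult:
    """Global nonlinear least squares over all scans simultaneously.

    Shared parameters: Kd (self-association) and, optionally, the base
    molar mass (default: fitted for the single-species template, fixed for
    self-association). Per-scan nuisance parameters: reference
    concentration and baseline. Standard errors come from the Jacobian at
    the solution; non-convergence is flagged on the result, not raised.
    """
    if len(scans) == 0:
        raise InsufficientDataError("need at least one scan")
    if fit_mass is None:
        fit_mass = template.scheme == "single"
    residual, x0, names = _pack_predict(template, scans, fit_mass)
    sol = least_squares(residual, x0, max_nfev=max_nfev, method="lm")
    res = residual(sol.x)
    n_obs, n_par = res.size, sol.x.size
    rms = float(np.sqrt(np.mean(res ** 2)))
    # parameter covariance from the Jacobian
    ses = {}
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (res @ res) / max(n_obs - n_par, 1)
        diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
        ses = dict(zip(names, diag))
    except np.linalg.LinAlgError:
        ses = {name: float("inf") for name in names}
    params = dict(zip(names, sol.x))
    out_params: dict[str, float] = {}
    out_ses: dict[str, float] = {}
    for name, value in params.items():
        if name == "log10_kd":
            out_params["kd"] = 10.0 ** value
            # se via first-order propagation through 10**x
            out_ses["kd"] = ses.get(name, np.inf) * out_params["kd"] * math.log(10.0)
        elif name.startswith("ln_cref"):
            idx = name.split("_")[-1]
            out_params[f"cref_{idx}"] = math.exp(value)
            out_ses[f"cref_{idx}"] = ses.get(name, np.inf) * out_params[f"cref_{idx}"]
        else:
            out_params[name] = value if name != "base_mass" else abs(value)
            out_ses[name] = ses.get(name, np.inf)
    # per-scan residual vectors
    lengths = [len(s.radii) for s in scans]
    splits = np.cumsum(lengths)[:-1]
    return FitResult(
        model_name=template.scheme, parameters=out_params, standard_errors=out_ses,
        residuals=list(np.split(res, splits)), rms=rms,
        converged=bool(sol.success), n_observations=n_obs, n_parameters=n_par,
    )


def select_model(scans: Sequence[AucScan], single_template: AssociationModel,
                 assoc_template: AssociationModel,
                 rms_improvement: float = 0.10) -> FitResult:
    """Fit both templates and accept the simpler one unless the
    self-association model improves the global rms by more than
    ``rms_improvement`` (fractional) with a finite Kd standard error."""
    fit_single = fit_global(scans, single_template)
    fit_assoc = fit_global(scans, assoc_template)
    improved = fit_assoc.rms < (1.0 - rms_improvement) * fit_single.rms
    kd_se_ok = np.isfinite(fit_assoc.standard_errors.get("kd", np.inf))
    chosen = fit_assoc if (improved and kd_se_ok) else fit_single
    chosen.comparison = {
        "single_rms": fit_single.rms,
        "self-association_rms": fit_assoc.rms,
        "improvement": 1.0 - fit_assoc.rms / fit_single.rms,
        "accepted": chosen.model_name,
    }
    return chosen


def species_distribution(model: AssociationModel,
                         totals: Sequence[float]) -> pd.DataFrame:
    """Equilibrium species fractions over a grid of total concentration.

    ``totals`` are total base-species-equivalent molar concentrations
    (tetramer equivalents for a tetramer-octamer system). Fractions are in
    base-equivalent units and sum to 1: the 2n-mer counts twice.
    """
    if model.scheme != "self-association":
        raise InvalidInputError("species distribution needs an association scheme")
    rows = []
    for total in np.asarray(totals, dtype=float):
        if total <= 0:
            raise InvalidParameterError("total concentration must be positive")
        # 2 c1^2/Kd + c1 = total  ->  c1 = Kd/4 (sqrt(1 + 8 total/Kd) - 1)
        c1 = model.kd / 4.0 * (math.sqrt(1.0 + 8.0 * total / model.kd) - 1.0)
        c2 = c1 ** 2 / model.kd
        rows.append({"total": total, "c_base": c1, "c_assoc": c2,
                     "frac_base": c1 / total, "frac_assoc": 2.0 * c2 / total})
    return pd.DataFrame(rows)
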