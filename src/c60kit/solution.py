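"""Solution-phase quantification: Beer-Lambert concentrations,
protein:fullerene stoichiometry, and SEC calibration / apparent mass.

The stoichiometry estimate mirrors how a fullerene-to-protein ratio is
read off absorbance data: the fullerene concentration comes from its
340 nm extinction, the peptide concentration is converted to oligomer
(tetramer) units, and the ratio of the two is reported as oligomers per
fullerene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError


@dataclass
class Spectrum:
    """Absorbance spectrum measured in a cell of known path length."""

    wavelengths: np.ndarray    # nm, increasing
    absorbance: np.ndarray     # AU
    path_length: float = 1.0   # cm

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise InvalidInputError("wavelength and absorbance arrays must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidInputError("wavelengths must be increasing")
        if self.path_length <= 0:
            raise InvalidParameterError("path length must be positive")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance at a wavelength."""
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))


def beer_lambert(absorbance: float, epsilon: float, path: float = 1.0) -> float:
    """Concentration (M) from absorbance: c = A / (epsilon * l)."""
    if epsilon <= 0 or path <= 0:
        raise InvalidParameterError("epsilon and path length must be positive")
    return absorbance / (epsilon * path)


def absorbance_from_concentration(concentration: float, epsilon: float,
                                  path: float = 1.0) -> float:
    """Inverse of :func:`beer_lambert`: A = c * epsilon * l."""
    if epsilon <= 0 or path <= 0:
        raise InvalidParameterError("epsilon and path length must be positive")
    return concentration * epsilon * path


def stoichiometry_ratio(monomer_concentration: float, oligomer_n: int,
                        ligand_concentration: float) -> float:
    """Oligomers per ligand: (monomer / n) / ligand.

    E.g. 585 uM peptide as tetramers (n = 4) against 6.22 uM fullerene
    gives ~23.5 tetramers per fullerene.
    """
    if ligand_concentration == 0:
        raise ZeroDivisionError("ligand concentration is zero")
    if monomer_concentration <= 0 or ligand_concentration < 0:
        raise InvalidParameterError("concentrations must be positive")
    if oligomer_n < 1:
        raise InvalidParameterError("oligomer size must be >= 1")
    return (monomer_concentration / oligomer_n) / ligand_concentration


# ---------------------------------------------------------------------------
# SEC calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Linear fit of log10(molar mass) against elution volume."""

    standards: list[tuple[float, float]]   # (mass Da, elution volume mL)
    slope: float
    intercept: float
    r_squared: float

    @property
    def volume_range(self) -> tuple[float, float]:
        volumes = [v for _, v in self.standards]
        return min(volumes), max(volumes)


def sec_calibrate(standards: list[tuple[float, float]]) -> CalibrationCurve:
    """Least-squares calibration line on log10(mass) vs elution volume."""
    if len(standards) < 2:
        raise InsufficientDataError("need at least two calibration standards")
    masses = np.array([m for m, _ in standards], dtype=float)
    volumes = np.array([v for _, v in standards], dtype=float)
    if np.any(masses <= 0):
        raise InvalidParameterError("standard masses must be positive")
    if len(np.unique(volumes)) < len(volumes):
        raise InvalidInputError("duplicate elution volumes make the fit singular")
    slope, intercept = np.polyfit(volumes, np.log10(masses), 1)
    fitted = slope * volumes + intercept
    y = np.log10(masses)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(standards=list(standards), slope=float(slope),
                            intercept=float(intercept), r_squared=r2)


def sec_apparent_mass(curve: CalibrationCurve, elution_volume: float) -> float:
    """Apparent molar mass (Da) at an elution volume, 10^(slope*V + b).

    Queries outside the calibrated volume range are answered but flagged
    with a warning (extrapolation beyond the standards kit).
    """
    lo, hi = curve.volume_range
    if not (lo <= elution_volume <= hi):
        warnings.warn(
            f"elution volume {elution_volume:.3g} mL is outside the calibrated "
            f"range [{lo:.3g}, {hi:.3g}] mL; apparent mass is an extrapolation",
            stacklevel=2)
    return float(10.0 ** (curve.slope * elution_volume + curve.intercept))


# ---------------------------------------------------------------------------
# SEC trace peak calling
# ---------------------------------------------------------------------------

def detect_peaks(volumes: np.ndarray, signal: np.ndarray,
                 min_fraction: float = 0.1, smooth_window: int = 5) -> list[float]:
    """Elution volumes of local maxima above a fraction of the global max.

    The trace is smoothed with a centred moving average (window in points)
    before peak calling; peak positions are reported on the smoothed trace.
    """
    volumes = np.asarray(volumes, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if volumes.shape != signal.shape or volumes.size < 3:
        raise InvalidInputError("need aligned volume/signal arrays of length >= 3")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(signal, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="valid")[:signal.size]
    else:
        smoothed = signal
    threshold = min_fraction * smoothed.max()
    peaks = []
    for i in range(1, len(smoothed) - 1):
        if smoothed[i] >= smoothed[i - 1] and smoothed[i] > smoothed[i + 1] \
                and smoothed[i] >= threshold:
            peaks.append(float(volumes[i]))
    return peaks
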