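"""Spectroscopic observables and SVD component analysis.

Converts raw instrument signals into the derived observables used by the
downstream stability analysis:

* the intensity-averaged fluorescence emission wavelength λ̄, an integral
  probe of tertiary-structure change;
* mean residue ellipticity [Θ] from raw circular-dichroism millidegrees;
* protein concentration from A280 and the molar absorptivity;
* singular-value decomposition of a spectral series to count independent
  spectroscopic components and strip high-frequency noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .constants import MEAN_RESIDUE_MASS
from .errors import (
    DegenerateSpectrum,
    GridMismatch,
    InvalidGeometry,
    InvalidSignal,
)

__all__ = [
    "Probe",
    "Spectrum",
    "SpectralSeries",
    "SVDResult",
    "intensity_averaged_wavelength",
    "mean_residue_ellipticity",
    "concentration_from_a280",
    "svd_analyze",
]


class Probe(str, Enum):
    """Spectroscopic channel."""

    FARUV_CD = "farUV_CD"
    NEARUV_CD = "nearUV_CD"
    FLUORESCENCE = "fluorescence"


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed signal scan.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid, nm, all > 0.
    values
        Signal on the grid: mdeg for CD probes, arbitrary units for
        fluorescence.
    probe
        Which channel recorded the scan.
    temperature
        Sample temperature, °C.
    sample_id
        Free-text sample identifier.
    concentration, path_length
        Optional, mg/mL and cm; required for mean residue ellipticity.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    probe: Probe = Probe.FARUV_CD
    temperature: float = 20.0
    sample_id: str = ""
    concentration: float | None = None
    path_length: float | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", val)
        if wl.ndim != 1 or val.ndim != 1 or wl.size != val.size or wl.size < 2:
            raise ValueError("wavelengths and values must be equal-length 1-D, length >= 2")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(wl > 0):
            raise ValueError("wavelengths must be positive")
        for name in ("concentration", "path_length"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidGeometry(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class SpectralSeries:
    """Spectra collected along a condition axis (denaturant or temperature),
    all on one shared wavelength grid."""

    condition_values: np.ndarray
    spectra: tuple[Spectrum, ...]

    def __post_init__(self):
        cond = np.asarray(self.condition_values, dtype=float)
        object.__setattr__(self, "condition_values", cond)
        object.__setattr__(self, "spectra", tuple(self.spectra))
        if len(self.spectra) != cond.size or cond.size < 2:
            raise ValueError("need >= 2 conditions with one spectrum each")
        if np.any(np.diff(cond) < 0):
            raise ValueError("condition values must be nondecreasing")
        grid = self.spectra[0].wavelengths
        for s in self.spectra[1:]:
            if s.wavelengths.shape != grid.shape or not np.allclose(
                s.wavelengths, grid, rtol=0, atol=1e-12
            ):
                raise GridMismatch("all spectra in a series must share one wavelength grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def to_matrix(self) -> np.ndarray:
        """Stack values into a (n_wavelengths, n_conditions) matrix."""
        return np.column_stack([s.values for s in self.spectra])


@dataclass(frozen=True)
class SVDResult:
    """Outcome of SVD component analysis on a spectral series."""

    singular_values: np.ndarray
    basis_spectra: np.ndarray        # (n_wavelengths, k) left singular vectors
    amplitude_vectors: np.ndarray    # (k, n_conditions) rows of Vt
    estimated_rank: int
    denoised_series: SpectralSeries
    policy: str = "singular-value threshold"


def intensity_averaged_wavelength(spectrum: Spectrum) -> float:
    """Intensity-averaged emission wavelength λ̄ = Σ(I·λ)/Σ(I), nm.

    An integral measure of the position/shape of a fluorescence emission
    spectrum, largely insensitive to noise; red shifts track exposure of
    tryptophans on unfolding.

    Raises
    ------
    InvalidSignal
        If any intensity is negative or the probe is not fluorescence.
    DegenerateSpectrum
        If every intensity is zero.
    """
    if spectrum.probe is not Probe.FLUORESCENCE:
        raise InvalidSignal(f"λ̄ is defined for fluorescence spectra, got {spectrum.probe}")
    intensities = spectrum.values
    if np.any(intensities < 0):
        raise InvalidSignal("negative fluorescence intensity")
    total = intensities.sum()
    if total == 0:
        raise DegenerateSpectrum("all-zero intensities")
    return float((intensities * spectrum.wavelengths).sum() / total)


def mean_residue_ellipticity(
    theta_mdeg: float,
    concentration: float,
    path_length: float,
    mean_residue_mass: float = MEAN_RESIDUE_MASS,
) -> float:
    """Mean residue ellipticity [Θ], deg·cm²·dmol⁻¹.

    ``theta_mdeg`` is the raw ellipticity in millidegrees, ``concentration``
    in mg/mL, ``path_length`` in cm. Uses the standard normalisation
    [Θ] = θ·MRW / (10·l·c) with a default mean residue mass of 110 g/mol.
    """
    if concentration <= 0 or path_length <= 0:
        raise InvalidGeometry("concentration and path_length must be > 0")
    return theta_mdeg * mean_residue_mass / (10.0 * path_length * concentration)


def concentration_from_a280(
    a280: float,
    molar_absorptivity: float,
    molecular_mass: float,
    path_length: float = 1.0,
) -> float:
    """Protein concentration (mg/mL) from absorbance at 280 nm.

    Beer–Lambert: molar concentration a280/(ε·l) times the molecular mass
    (Da) gives g/L ≡ mg/mL.
    """
    if a280 < 0:
        raise InvalidSignal("negative absorbance")
    if molar_absorptivity <= 0 or molecular_mass <= 0 or path_length <= 0:
        raise InvalidGeometry("molar_absorptivity, molecular_mass, path_length must be > 0")
    return a280 / (molar_absorptivity * path_length) * molecular_mass


def _rank_by_threshold(s: np.ndarray, factor: float, floor: float) -> int:
    # Noise level estimated from the trailing half of the singular spectrum;
    # the relative floor guards the noiseless case where that median is ~0.
    if s.size == 0 or s[0] == 0:
        return 0
    tail = s[s.size // 2 :]
    threshold = max(factor * float(np.median(tail)), floor * float(s[0]))
    return int(np.sum(s > threshold))


def _rank_by_autocorrelation(u: np.ndarray, vt: np.ndarray, s: np.ndarray,
                             min_autocorr: float, floor: float) -> int:
    # Signal components have smooth singular vectors (high lag-1
    # autocorrelation); noise components do not.
    rank = 0
    for i in range(s.size):
        if s[i] <= floor * s[0]:
            break
        col = u[:, i]
        row = vt[i, :]
        def ac(x):
            # correlation of successive pairs (unbiased for short vectors)
            a, b = x[:-1] - x[:-1].mean(), x[1:] - x[1:].mean()
            denom = float(np.sqrt(np.dot(a, a) * np.dot(b, b)))
            if denom == 0:
                return 0.0
            return float(np.dot(a, b) / denom)
        if ac(col) >= min_autocorr and (row.size < 4 or ac(row) >= min_autocorr):
            rank += 1
        else:
            break
    return rank


def svd_analyze(
    series: SpectralSeries,
    policy: str = "threshold",
    threshold_factor: float = 5.0,
    min_autocorr: float = 0.8,
    relative_floor: float = 1e-8,
) -> SVDResult:
    """Full SVD of the wavelength × condition matrix of a spectral series.

    Counts the independent spectroscopic components (the number of
    thermodynamic states contributing distinct spectra) and returns the
    rank-truncated reconstruction as a denoised series.

    Parameters
    ----------
    policy
        ``"threshold"`` retains components whose singular value exceeds
        ``threshold_factor`` times the median of the trailing half of the
        singular spectrum (with a small relative floor for noiseless data);
        ``"autocorrelation"`` retains leading components whose singular
        vectors are smooth (lag-1 autocorrelation >= ``min_autocorr``).
    """
    matrix = series.to_matrix()
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    if policy == "threshold":
        rank = _rank_by_threshold(s, threshold_factor, relative_floor)
    elif policy == "autocorrelation":
        rank = _rank_by_autocorrelation(u, vt, s, min_autocorr, relative_floor)
    else:
        raise ValueError(f"unknown rank policy {policy!r}")
    rank = min(rank, s.size)
    denoised = u[:, :rank] @ np.diag(s[:rank]) @ vt[:rank, :] if rank else np.zeros_like(matrix)
    denoised_spectra = tuple(
        replace(spec, values=denoised[:, j]) for j, spec in enumerate(series.spectra)
    )
    return SVDResult(
        singular_values=s,
        basis_spectra=u,
        amplitude_vectors=vt,
        estimated_rank=rank,
        denoised_series=SpectralSeries(series.condition_values, denoised_spectra),
        policy=policy,
    )
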