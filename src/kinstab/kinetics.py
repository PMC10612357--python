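"""Enzyme kinetics: initial rates, Michaelis–Menten and Arrhenius fits.

Progress curves from the chelation-enhanced fluorescence (ChEF) assay —
fluorescence at 490 nm rising as a sensor peptide is phosphorylated — are
reduced to initial rates via a linear fit over the early, approximately
zero-order window. Rates across substrate concentrations give Km, Vmax,
kcat = Vmax/[E] and the catalytic efficiency kcat/Km; rates across assay
temperatures give the temperature of maximal activity (Tmax) and, from the
sub-Tmax points, the Arrhenius activation energy Ea.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import NM_TO_UM, R_KCAL, celsius_to_kelvin
from .errors import (
    AboveTmaxError,
    EdgeMaximumWarning,
    FitDiverged,
    InsufficientRange,
    InvalidAssay,
    NoLinearPhase,
    PoorSaturationWarning,
    TieWarning,
)

__all__ = [
    "ProgressCurve",
    "RatePoint",
    "MichaelisMentenFit",
    "ArrheniusFit",
    "initial_rate",
    "fit_michaelis_menten",
    "find_tmax",
    "fit_arrhenius",
    "arrhenius_loglinear",
    "michaelis_menten_rate",
]


@dataclass(frozen=True)
class ProgressCurve:
    """Fluorescence (490 nm) vs time for one assay condition.

    ``calibration`` converts fluorescence to product concentration,
    AU per µM phosphopeptide; it is instrument-specific and must be
    supplied with the data.
    """

    time: np.ndarray                 # s, strictly increasing from 0
    fluorescence: np.ndarray         # AU
    substrate_conc: float            # µM
    enzyme_conc: float               # nM
    temperature: float = 30.0        # °C
    calibration: float = 1.0         # AU/µM

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size != f.size or t.size < 3:
            raise ValueError("need matched arrays with at least 3 points")
        if t[0] != 0 or not np.all(np.diff(t) > 0):
            raise ValueError("time must increase strictly from 0")
        if self.calibration <= 0 or self.enzyme_conc <= 0 or self.substrate_conc <= 0:
            raise ValueError("calibration, enzyme_conc and substrate_conc must be > 0")


@dataclass(frozen=True)
class RatePoint:
    """An initial rate at one substrate concentration and temperature."""

    substrate_conc: float  # µM
    rate: float            # µM/s
    temperature: float = 30.0  # °C

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


@dataclass(frozen=True)
class MichaelisMentenFit:
    """Km/Vmax with the derived kcat and catalytic efficiency.

    The identities kcat = Vmax/[E] (enzyme in µM) and
    efficiency = kcat/Km hold exactly on every instance.
    """

    Km: float          # µM
    Vmax: float        # µM/s
    kcat: float        # s⁻¹
    efficiency: float  # s⁻¹·µM⁻¹
    enzyme_conc: float  # nM
    standard_errors: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters over the 10 °C → Tmax activity range."""

    Ea: float                      # kcal/mol
    A: float                       # s⁻¹ (pre-exponential)
    Tmax: float                    # °C
    fit_temperatures: tuple[float, ...]  # °C, all <= Tmax
    standard_error_Ea: float = float("nan")


def michaelis_menten_rate(s, Vmax: float, Km: float):
    """v = Vmax·S/(Km + S), µM/s."""
    s = np.asarray(s, dtype=float)
    v = Vmax * s / (Km + s)
    return v if v.ndim else float(v)


def initial_rate(
    curve: ProgressCurve,
    max_window_s: float = 60.0,
    max_conversion: float = 0.10,
    curvature_tol: float = 0.15,
) -> RatePoint:
    """Initial rate (µM/s) from the early linear phase of a progress curve.

    The fit window is the earliest span satisfying both limits: at most
    ``max_window_s`` seconds and at most ``max_conversion`` of the
    substrate converted to product. If a quadratic term contributes more
    than ``curvature_tol`` of the signal change over the window, the
    window is shrunk; if no >= 3-point window is linear enough the curve
    is rejected.

    Raises
    ------
    NoLinearPhase
        If every candidate window is too curved.
    InvalidAssay
        If the slope is negative beyond its standard error.
    """
    t = curve.time
    product = (curve.fluorescence - curve.fluorescence[0]) / curve.calibration  # µM
    in_window = (t <= max_window_s) & (product <= max_conversion * curve.substrate_conc)
    n = t.size if in_window.all() else int(np.argmax(~in_window))
    n = max(n, 3)

    while n >= 3:
        tw, pw = t[:n], product[:n]
        if n > 3:
            c2, c1, _ = np.polyfit(tw, pw, 2)
            linear_change = abs(c1 * (tw[-1] - tw[0]))
            quad_change = abs(c2) * (tw[-1] - tw[0]) ** 2
            if linear_change > 0 and quad_change / linear_change > curvature_tol:
                n -= max(1, n // 4)
                continue
        slope, intercept = np.polyfit(tw, pw, 1)
        resid = pw - (slope * tw + intercept)
        dof = max(n - 2, 1)
        se = float(np.sqrt(resid @ resid / dof / ((tw - tw.mean()) @ (tw - tw.mean()))))
        if slope < 0 and abs(slope) > 3 * se:
            raise InvalidAssay(f"negative slope {slope:.3g} µM/s beyond noise")
        return RatePoint(
            substrate_conc=curve.substrate_conc,
            rate=float(max(slope, 0.0)),
            temperature=curve.temperature,
        )
    raise NoLinearPhase("no candidate window of >= 3 points is acceptably linear")


def fit_michaelis_menten(
    points: list[RatePoint],
    enzyme_conc: float,
) -> MichaelisMentenFit:
    """Nonlinear least-squares Michaelis–Menten fit, v = Vmax·S/(Km+S).

    ``enzyme_conc`` in nM. Requires rates at >= 5 substrate
    concentrations. Warns (:class:`PoorSaturationWarning`) when the
    largest substrate concentration is below the fitted Km.
    """
    if len(points) < 5:
        raise ValueError("need rates at >= 5 substrate concentrations")
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    s = np.array([p.substrate_conc for p in points], dtype=float)
    v = np.array([p.rate for p in points], dtype=float)

    vmax0 = float(v.max()) or 1.0
    half = 0.5 * vmax0
    km0 = float(np.interp(half, np.sort(v), s[np.argsort(v)])) if v.max() > 0 else 1.0
    km0 = max(km0, 1e-6)

    params = lmfit.Parameters()
    params.add("vmax", value=vmax0 * 1.2, min=1e-12)
    params.add("km", value=km0, min=1e-9)

    def residuals(p):
        return michaelis_menten_rate(s, p["vmax"], p["km"]) - v

    result = lmfit.minimize(residuals, params, method="leastsq")
    if not result.success:
        raise FitDiverged("Michaelis-Menten fit did not converge",
                          {"message": result.message})
    km = float(result.params["km"].value)
    vmax = float(result.params["vmax"].value)
    if s.max() < km:
        warnings.warn(
            f"max substrate {s.max():.3g} µM below Km estimate {km:.3g} µM",
            PoorSaturationWarning, stacklevel=2,
        )
    kcat = vmax / (enzyme_conc * NM_TO_UM)
    se = {
        "Km": float(result.params["km"].stderr or np.nan),
        "Vmax": float(result.params["vmax"].stderr or np.nan),
    }
    return MichaelisMentenFit(
        Km=km, Vmax=vmax, kcat=kcat, efficiency=kcat / km,
        enzyme_conc=enzyme_conc, standard_errors=se,
    )


def find_tmax(rates_by_temperature: list[RatePoint]) -> float:
    """Temperature of maximal activity from the measured grid (°C).

    No interpolation: the grid temperature with the largest rate is
    returned. Ties resolve to the lower temperature with a
    :class:`TieWarning`; a maximum at either end of the grid raises an
    :class:`EdgeMaximumWarning`.
    """
    if len(rates_by_temperature) < 4:
        raise ValueError("need rates at >= 4 temperatures")
    pts = sorted(rates_by_temperature, key=lambda p: p.temperature)
    rates = np.array([p.rate for p in pts])
    temps = np.array([p.temperature for p in pts])
    best = int(np.argmax(rates))  # argmax takes the first (= lowest T) on ties
    if np.sum(rates == rates[best]) > 1:
        warnings.warn("tied maximal rates; reporting the lower temperature",
                      TieWarning, stacklevel=2)
    if best in (0, temps.size - 1):
        warnings.warn(
            f"activity maximum at grid edge ({temps[best]:.1f} °C)",
            EdgeMaximumWarning, stacklevel=2,
        )
    return float(temps[best])


def arrhenius_loglinear(points: list[RatePoint], R: float = R_KCAL) -> tuple[float, float]:
    """Closed-form log-linear Arrhenius estimate (Ea kcal/mol, A).

    ln k = ln A − Ea/(R·T); ordinary least squares on (1/T, ln k).
    Exact for noiseless data; used as the independent cross-check of the
    nonlinear fit.
    """
    inv_t = np.array([1.0 / celsius_to_kelvin(p.temperature) for p in points])
    ln_k = np.log([p.rate for p in points])
    slope, intercept = np.polyfit(inv_t, ln_k, 1)
    return float(-slope * R), float(np.exp(intercept))


def fit_arrhenius(
    rates_by_temperature: list[RatePoint],
    tmax: float,
    R: float = R_KCAL,
) -> ArrheniusFit:
    """Nonlinear Arrhenius fit k = A·exp(−Ea/(R·T)) on the sub-Tmax points.

    Every supplied point must satisfy T <= ``tmax``: above the temperature
    of maximal activity the enzyme inactivates and the Arrhenius law no
    longer describes the rates, so such points are refused rather than
    silently fitted (filter them out first).

    Raises
    ------
    AboveTmaxError
        If any point lies above ``tmax``.
    InsufficientRange
        With fewer than 3 usable positive-rate points.
    """
    offenders = [p.temperature for p in rates_by_temperature if p.temperature > tmax]
    if offenders:
        raise AboveTmaxError(
            f"points above Tmax={tmax} °C must be excluded before fitting: {offenders}"
        )
    usable = [p for p in rates_by_temperature if p.rate > 0]
    if len(usable) < 3:
        raise InsufficientRange("need >= 3 positive-rate points at T <= Tmax")

    t_k = np.array([celsius_to_kelvin(p.temperature) for p in usable])
    k = np.array([p.rate for p in usable])
    ea0, a0 = arrhenius_loglinear(usable, R=R)

    params = lmfit.Parameters()
    params.add("ea", value=max(ea0, 1e-3), min=1e-6)
    params.add("lna", value=np.log(a0))

    def residuals(p):
        return np.exp(p["lna"] - p["ea"] / (R * t_k)) - k

    result = lmfit.minimize(residuals, params, method="leastsq")
    if not result.success:
        raise FitDiverged("Arrhenius fit did not converge", {"message": result.message})
    ea = float(result.params["ea"].value)
    return ArrheniusFit(
        Ea=ea,
        A=float(np.exp(result.params["lna"].value)),
        Tmax=tmax,
        fit_temperatures=tuple(sorted(p.temperature for p in usable)),
        standard_error_Ea=float(result.params["ea"].stderr or np.nan),
    )
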