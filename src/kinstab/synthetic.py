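"""Seeded synthetic datasets with the statistical structure of the assays.

Every generator evaluates the corresponding forward model on a realistic
instrument grid, adds homoscedastic Gaussian noise (default 2% of the
signal span), and returns the dataset together with the generating truth,
so fit stages can be validated by parameter-recovery round trips. The
default true parameters are the wild-type values of the study conditions
the package targets (two-state stability ΔG_H2O = 2.51 kcal/mol,
m = 0.91 kcal/mol/M; Tm = 55 °C; Km = 1.81 µM, Vmax = 1.10e-2 µM/s at
5 nM enzyme; Ea = 9.95 kcal/mol with Tmax = 30 °C).

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .constants import R_KCAL, UNFOLDING_T_K, celsius_to_kelvin
from .kinetics import ProgressCurve, RatePoint, michaelis_menten_rate
from .thermal import ThermalMelt
from .unfolding import (
    DenaturationProbe,
    DenaturationSeries,
    three_state_signal,
    two_state_signal,
)

__all__ = [
    "SimulationSpec",
    "KineticsBundle",
    "gen_two_state_series",
    "gen_three_state_series",
    "gen_thermal_melt",
    "gen_kinetics",
]

#: Default instrument grids (denaturant 0-8 M; melt 20-90 °C every 0.5 °C;
#: 5-min progress curves; substrate 0.069-40 µM at 10 concentrations;
#: assay temperatures 10-45 °C).
DENATURANT_GRID = np.arange(0.0, 8.0 + 1e-9, 0.25)
MELT_GRID_C = np.arange(20.0, 90.0 + 1e-9, 0.5)
TIME_GRID_S = np.arange(0.0, 300.0 + 1e-9, 5.0)
SUBSTRATE_GRID_UM = np.geomspace(0.069, 40.0, 10)
ASSAY_TEMPS_C = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 37.0, 40.0, 42.0, 45.0)

#: Wild-type truths used as generator defaults.
DEFAULT_TWO_STATE = dict(dG_H2O=2.51, m=0.91, yN=-11500.0, sN=30.0,
                         yU=-2000.0, sU=-10.0)
DEFAULT_THREE_STATE = dict(D50_IN=0.78, m_IN=4.69, D50_UI=3.03, m_UI=0.96,
                           F_I=-7000.0, aN=-11500.0, bN=30.0,
                           aU=-2000.0, bU=-10.0)
DEFAULT_MELT = dict(tm=(55.0,), width=(2.5,), amplitude=(9.0,),
                    intercept=-11.0, slope=0.01)
DEFAULT_KINETICS = dict(Km=1.81, Vmax=1.10e-2, enzyme_nM=5.0,
                        Ea=9.95, Tmax=30.0, calibration=100.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Seeded description of one synthetic dataset.

    ``noise_sd`` is in observable units; ``None`` means 2% of the
    noiseless signal span. ``params`` overrides entries of the relevant
    generator's default truth.
    """

    seed: int
    noise_sd: float | None = None
    params: dict = field(default_factory=dict)
    grid: np.ndarray | None = None

    def __post_init__(self):
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.size == 0 or np.any(np.diff(g) < 0):
                raise ValueError("grid must be nonempty and sorted")
            object.__setattr__(self, "grid", g)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise_sd(spec: SimulationSpec, clean: np.ndarray) -> float:
    if spec.noise_sd is not None:
        return spec.noise_sd
    span = float(clean.max() - clean.min())
    return 0.02 * span


def gen_two_state_series(
    spec: SimulationSpec,
    probe: DenaturationProbe = DenaturationProbe.CD222,
    temperature: float = UNFOLDING_T_K,
) -> tuple[DenaturationSeries, dict]:
    """Two-state LEM forward model on the denaturant grid plus noise."""
    truth = {**DEFAULT_TWO_STATE, **spec.params}
    x = spec.grid if spec.grid is not None else DENATURANT_GRID
    clean = two_state_signal(x, T=temperature, **truth)
    sd = _noise_sd(spec, clean)
    y = clean + spec.rng().normal(0.0, sd, size=x.size)
    series = DenaturationSeries(
        denaturant=x, observable=y, probe=probe, temperature=temperature,
        replicate_id=f"sim-seed{spec.seed}",
    )
    return series, {**truth, "noise_sd": sd, "temperature": temperature}


def gen_three_state_series(
    spec: SimulationSpec,
    probe: DenaturationProbe = DenaturationProbe.CD222,
    temperature: float = UNFOLDING_T_K,
) -> tuple[DenaturationSeries, dict]:
    """Three-state (N ⇌ I ⇌ U) forward model on the denaturant grid plus noise."""
    truth = {**DEFAULT_THREE_STATE, **spec.params}
    x = spec.grid if spec.grid is not None else DENATURANT_GRID
    clean = three_state_signal(x, T=temperature, **truth)
    sd = _noise_sd(spec, clean)
    y = clean + spec.rng().normal(0.0, sd, size=x.size)
    series = DenaturationSeries(
        denaturant=x, observable=y, probe=probe, temperature=temperature,
        replicate_id=f"sim-seed{spec.seed}",
    )
    return series, {**truth, "noise_sd": sd, "temperature": temperature}


def melt_signal(t, tm, width, amplitude, intercept, slope):
    """Sum of logistic transitions on a shared linear baseline."""
    t = np.asarray(t, dtype=float)
    y = intercept + slope * t
    for c, w, a in zip(tm, width, amplitude):
        y = y + a / (1.0 + np.exp(-(t - c) / w))
    return y


def gen_thermal_melt(spec: SimulationSpec) -> tuple[ThermalMelt, dict]:
    """Sigmoidal (optionally biphasic) melt of θ222 on the heating grid.

    The transition centres are the true Tm values: with a shared linear
    baseline the noiseless derivative extremum of each logistic falls
    exactly at its centre.
    """
    truth = {**DEFAULT_MELT, **spec.params}
    t = spec.grid if spec.grid is not None else MELT_GRID_C
    clean = melt_signal(t, truth["tm"], truth["width"], truth["amplitude"],
                        truth["intercept"], truth["slope"])
    sd = _noise_sd(spec, clean)
    y = clean + spec.rng().normal(0.0, sd, size=t.size)
    melt = ThermalMelt(temperatures=t, ellipticity222=y,
                       sample_id=f"sim-seed{spec.seed}")
    return melt, {**truth, "noise_sd": sd}


def _integrate_depletion(s0: float, vmax: float, km: float, t: np.ndarray) -> np.ndarray:
    """Substrate concentration S(t) under dS/dt = −Vmax·S/(Km+S)."""
    sol = solve_ivp(
        lambda _, s: -vmax * s / (km + s), (t[0], t[-1]), [s0],
        t_eval=t, rtol=1e-10, atol=1e-13,
    )
    return np.clip(sol.y[0], 0.0, None)


def activity_profile(temps_c, A, Ea, tmax_c, inactivation_width=2.0, R=R_KCAL):
    """Rate constant vs temperature: Arrhenius up to Tmax, then a logistic
    inactivation decline.

    The super-Tmax branch is a fixture-only stand-in (enzyme inactivation
    is not modelled physically); it exists so the activity maximum is an
    interior grid point.
    """
    temps_c = np.asarray(temps_c, dtype=float)
    k = A * np.exp(-Ea / (R * celsius_to_kelvin(temps_c)))
    above = temps_c > tmax_c
    decline = 2.0 / (1.0 + np.exp((temps_c[above] - tmax_c) / inactivation_width))
    k[above] *= decline
    return k


@dataclass(frozen=True)
class KineticsBundle:
    """Synthetic kinetic dataset: progress curves at 30 °C across substrate,
    reduced rate points, a temperature-activity series, and the truth."""

    progress_curves: tuple[ProgressCurve, ...]
    mm_rates: tuple[RatePoint, ...]
    temperature_rates: tuple[RatePoint, ...]
    calibration: float
    truth: dict


def gen_kinetics(spec: SimulationSpec) -> KineticsBundle:
    """Progress curves, Michaelis–Menten rate points and a temperature
    series from one set of true kinetic parameters.

    Progress curves integrate substrate depletion and convert product to
    fluorescence through the emitted calibration factor; rate points carry
    Gaussian noise scaled to Vmax; the temperature series follows
    :func:`activity_profile` at 1 µM substrate (below Km, per assay
    design).
    """
    truth = {**DEFAULT_KINETICS, **spec.params}
    km, vmax = truth["Km"], truth["Vmax"]
    calibration = truth["calibration"]
    rng = spec.rng()
    t = spec.grid if spec.grid is not None else TIME_GRID_S
    substrate = np.asarray(truth.get("substrate_uM", SUBSTRATE_GRID_UM), dtype=float)
    rate_noise = spec.noise_sd if spec.noise_sd is not None else 0.02 * vmax

    curves = []
    for s0 in substrate:
        s_t = _integrate_depletion(s0, vmax, km, t)
        fluor = calibration * (s0 - s_t)
        fluor = fluor + rng.normal(0.0, rate_noise * calibration * 5.0, size=t.size)
        curves.append(ProgressCurve(
            time=t, fluorescence=fluor, substrate_conc=float(s0),
            enzyme_conc=truth["enzyme_nM"], temperature=30.0,
            calibration=calibration,
        ))

    mm_rates = tuple(
        RatePoint(float(s), float(max(v, 0.0)), 30.0)
        for s, v in zip(
            substrate,
            michaelis_menten_rate(substrate, vmax, km)
            + rng.normal(0.0, rate_noise, size=substrate.size),
        )
    )

    temps = np.asarray(truth.get("assay_temps_C", ASSAY_TEMPS_C), dtype=float)
    # Pre-exponential chosen so the rate at 30 °C matches the saturating-limit
    # turnover scale; only Ea and the shape matter to the fits.
    a_pre = truth.get("A", vmax * np.exp(truth["Ea"] / (R_KCAL * celsius_to_kelvin(30.0))))
    k = activity_profile(temps, a_pre, truth["Ea"], truth["Tmax"])
    k_noise = (spec.noise_sd if spec.noise_sd is not None else 0.02 * float(k.max()))
    k = np.clip(k + rng.normal(0.0, k_noise, size=temps.size), 1e-12, None)
    temp_rates = tuple(RatePoint(1.0, float(v), float(tc)) for tc, v in zip(temps, k))

    return KineticsBundle(
        progress_curves=tuple(curves),
        mm_rates=mm_rates,
        temperature_rates=temp_rates,
        calibration=calibration,
        truth={**truth, "A": float(a_pre), "rate_noise_sd": rate_noise},
    )
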