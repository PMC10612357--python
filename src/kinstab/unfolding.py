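"""Equilibrium-unfolding thermodynamics from denaturation series.

Fits GdmCl-induced unfolding transitions, monitored by far-UV CD at 222 nm
or by the intensity-averaged fluorescence emission wavelength, to

* the two-state linear extrapolation model (LEM): the unfolding free energy
  varies linearly with denaturant, ΔG([D]) = ΔG_H2O − m·[D], so the
  unfolding equilibrium constant is K([D]) = exp(−ΔG([D])/RT) and the
  observed signal interpolates between sloping native and unfolded
  baselines weighted by the state populations;
* a three-state model N ⇌ I ⇌ U with an intermediate of constant signal
  F_I, each step carrying its own midpoint D50 and m value.

The transition midpoint of the LEM is [D]₀.₅ = ΔG_H2O / m, reported for
every fit. Multiple replicate series can be fitted globally with a shared
m value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import lmfit
import numpy as np
from scipy.signal import savgol_filter

from .constants import R_KCAL, UNFOLDING_T_K
from .errors import (
    BoundaryFitWarning,
    FitDiverged,
    InvalidSlope,
    NoModel,
    UnbracketedTransition,
)

__all__ = [
    "DenaturationProbe",
    "DenaturationSeries",
    "TwoStateFit",
    "ThreeStateFit",
    "ModelSelection",
    "two_state_signal",
    "three_state_signal",
    "midpoint_from_lem",
    "fit_two_state",
    "fit_three_state",
    "select_model",
]


class DenaturationProbe(str, Enum):
    CD222 = "CD222"
    AVG_WAVELENGTH = "avg_wavelength"


@dataclass(frozen=True)
class DenaturationSeries:
    """Observable vs denaturant concentration for one probe.

    ``denaturant`` in M GdmCl (nonnegative, nondecreasing), ``observable``
    in the probe's units ([Θ]222 or λ̄ nm). At least 8 points are required
    so both baselines and the transition can be resolved.
    """

    denaturant: np.ndarray
    observable: np.ndarray
    probe: DenaturationProbe = DenaturationProbe.CD222
    temperature: float = UNFOLDING_T_K
    replicate_id: str = ""

    def __post_init__(self):
        x = np.asarray(self.denaturant, dtype=float)
        y = np.asarray(self.observable, dtype=float)
        object.__setattr__(self, "denaturant", x)
        object.__setattr__(self, "observable", y)
        if x.size != y.size or x.size < 8:
            raise ValueError("need matched arrays with at least 8 points")
        if np.any(x < 0) or np.any(np.diff(x) < 0):
            raise ValueError("denaturant must be nonnegative and nondecreasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


@dataclass(frozen=True)
class TwoStateFit:
    """Two-state LEM parameters with baselines and uncertainties.

    ``midpoint`` always equals ``dG_H2O / m`` exactly.
    """

    dG_H2O: float
    m: float
    midpoint: float
    yN: float
    sN: float
    yU: float
    sU: float
    temperature: float = UNFOLDING_T_K
    standard_errors: dict[str, float] = field(default_factory=dict)
    covariance: np.ndarray | None = None

    def signal(self, x) -> np.ndarray:
        return two_state_signal(
            x, self.dG_H2O, self.m, self.yN, self.sN, self.yU, self.sU,
            T=self.temperature,
        )


@dataclass(frozen=True)
class ThreeStateFit:
    """Three-state (N ⇌ I ⇌ U) parameters: per-step midpoints and m values,
    constant intermediate signal F_I and linear N/U baselines."""

    D50_IN: float
    m_IN: float
    D50_UI: float
    m_UI: float
    F_I: float
    aN: float
    bN: float
    aU: float
    bU: float
    temperature: float = UNFOLDING_T_K
    standard_errors: dict[str, float] = field(default_factory=dict)
    covariance: np.ndarray | None = None

    def signal(self, x) -> np.ndarray:
        return three_state_signal(
            x, self.D50_IN, self.m_IN, self.D50_UI, self.m_UI, self.F_I,
            self.aN, self.bN, self.aU, self.bU, T=self.temperature,
        )


class UnfoldingModel(str, Enum):
    TWO_STATE = "two_state"
    THREE_STATE = "three_state"


@dataclass(frozen=True)
class ModelSelection:
    chosen: UnfoldingModel
    criterion_values: dict[str, float]
    svd_rank_hint: int | None = None
    two_state: TwoStateFit | None = None
    three_state: ThreeStateFit | None = None


def midpoint_from_lem(dG_H2O: float, m: float) -> float:
    """Transition midpoint [D]₀.₅ = ΔG_H2O/m (M) of the LEM."""
    if m <= 0:
        raise InvalidSlope(f"m must be > 0, got {m}")
    return dG_H2O / m


def two_state_signal(x, dG_H2O, m, yN, sN, yU, sU, T=UNFOLDING_T_K, R=R_KCAL):
    """Observed signal of a two-state unfolder at denaturant ``x`` (M).

    y = (yN + sN·x + (yU + sU·x)·K) / (1 + K), K = exp(−(ΔG_H2O − m·x)/RT).
    """
    x = np.asarray(x, dtype=float)
    k = np.exp(-(dG_H2O - m * x) / (R * T))
    y = (yN + sN * x + (yU + sU * x) * k) / (1.0 + k)
    return y if y.ndim else float(y)


def three_state_signal(x, D50_IN, m_IN, D50_UI, m_UI, F_I,
                       aN, bN, aU, bU, T=UNFOLDING_T_K, R=R_KCAL):
    """Observed signal of a three-state unfolder at denaturant ``x`` (M).

    F = (F_N + e₁·(F_I + F_U·e₂)) / (1 + e₁·(1 + e₂)) with
    e₁ = exp(m_IN·(x − D50_IN)/RT), e₂ = exp(m_UI·(x − D50_UI)/RT) and
    linear baselines F_N = aN + bN·x, F_U = aU + bU·x.
    """
    x = np.asarray(x, dtype=float)
    rt = R * T
    e1 = np.exp(m_IN * (x - D50_IN) / rt)
    e2 = np.exp(m_UI * (x - D50_UI) / rt)
    fn = aN + bN * x
    fu = aU + bU * x
    y = (fn + e1 * (F_I + fu * e2)) / (1.0 + e1 * (1.0 + e2))
    return y if y.ndim else float(y)


# -- initialisation helpers -------------------------------------------------

def _baseline_estimates(x: np.ndarray, y: np.ndarray, frac: float = 0.15):
    """Linear fits to the first and last ``frac`` of points."""
    n = max(2, int(round(frac * x.size)))
    sN, yN = np.polyfit(x[:n], y[:n], 1)
    sU, yU = np.polyfit(x[-n:], y[-n:], 1)
    return yN, sN, yU, sU


def _derivative_peaks(x: np.ndarray, y: np.ndarray, n_peaks: int = 1):
    """Midpoint guesses from extrema of a lightly smoothed first derivative."""
    if x.size >= 7:
        window = min(7, x.size - (1 - x.size % 2))
        ys = savgol_filter(y, window_length=window, polyorder=2)
    else:
        ys = y
    dy = np.abs(np.gradient(ys, x))
    order = np.argsort(dy)[::-1]
    picks: list[float] = []
    for idx in order:
        xi = float(x[idx])
        if all(abs(xi - p) > 0.15 * (x[-1] - x[0]) for p in picks):
            picks.append(xi)
        if len(picks) == n_peaks:
            break
    while len(picks) < n_peaks:
        picks.append(float(0.5 * (x[0] + x[-1])))
    return sorted(picks)


def _errors_from_result(result: lmfit.minimizer.MinimizerResult, names):
    se = {}
    for name in names:
        p = result.params[name]
        se[name] = float(p.stderr) if p.stderr is not None else float("nan")
    cov = result.covar if result.covar is not None else None
    return se, cov


def fit_two_state(
    series: DenaturationSeries | list[DenaturationSeries],
    share_m: bool = False,
    T: float | None = None,
    R: float = R_KCAL,
) -> TwoStateFit | list[TwoStateFit]:
    """Least-squares two-state LEM fit of one or more denaturation series.

    With ``share_m`` a single m value is estimated jointly across the
    series (the usual treatment of replicates of one probe); all other
    parameters stay per-series. Returns one :class:`TwoStateFit` per input
    series (a bare fit for a bare series).

    Raises
    ------
    UnbracketedTransition
        If the fitted midpoint falls outside the measured denaturant range,
        i.e. no baseline plateau brackets the transition.
    FitDiverged
        On optimizer failure, with diagnostics attached.
    """
    single = isinstance(series, DenaturationSeries)
    series_list = [series] if single else list(series)
    if not series_list:
        raise ValueError("no series to fit")
    temp = T if T is not None else series_list[0].temperature

    params = lmfit.Parameters()
    for i, s in enumerate(series_list):
        x, y = s.denaturant, s.observable
        yN, sN, yU, sU = _baseline_estimates(x, y)
        (mid,) = _derivative_peaks(x, y, 1)
        tag = f"_{i}"
        m_name = "m_0" if share_m else f"m{tag}"
        if not share_m or i == 0:
            params.add(m_name, value=1.5, min=1e-6, max=20.0)
        params.add(f"dG{tag}", value=max(mid, 0.1) * 1.5, min=1e-6, max=100.0)
        params.add(f"yN{tag}", value=yN)
        params.add(f"sN{tag}", value=sN)
        params.add(f"yU{tag}", value=yU)
        params.add(f"sU{tag}", value=sU)

    def residuals(p):
        res = []
        for i, s in enumerate(series_list):
            tag = f"_{i}"
            m = p["m_0"] if share_m else p[f"m{tag}"]
            res.append(
                two_state_signal(
                    s.denaturant, p[f"dG{tag}"], m,
                    p[f"yN{tag}"], p[f"sN{tag}"], p[f"yU{tag}"], p[f"sU{tag}"],
                    T=temp, R=R,
                )
                - s.observable
            )
        return np.concatenate(res)

    result = lmfit.minimize(residuals, params, method="leastsq")
    if not result.success:
        raise FitDiverged(
            "two-state fit did not converge",
            {"message": result.message, "nfev": result.nfev},
        )

    fits = []
    for i, s in enumerate(series_list):
        tag = f"_{i}"
        m_name = "m_0" if share_m else f"m{tag}"
        p = result.params
        dG = float(p[f"dG{tag}"].value)
        m = float(p[m_name].value)
        mid = midpoint_from_lem(dG, m)
        if not (s.denaturant.min() < mid < s.denaturant.max()):
            raise UnbracketedTransition(
                f"fitted midpoint {mid:.2f} M outside the measured range "
                f"[{s.denaturant.min():.2f}, {s.denaturant.max():.2f}] M"
            )
        if m >= 20.0 - 1e-6:
            warnings.warn("m at upper bound", BoundaryFitWarning, stacklevel=2)
        names = [f"dG{tag}", m_name, f"yN{tag}", f"sN{tag}", f"yU{tag}", f"sU{tag}"]
        se, cov = _errors_from_result(result, names)
        fits.append(
            TwoStateFit(
                dG_H2O=dG, m=m, midpoint=mid,
                yN=float(p[f"yN{tag}"].value), sN=float(p[f"sN{tag}"].value),
                yU=float(p[f"yU{tag}"].value), sU=float(p[f"sU{tag}"].value),
                temperature=temp,
                standard_errors={
                    "dG_H2O": se[f"dG{tag}"], "m": se[m_name],
                    "yN": se[f"yN{tag}"], "sN": se[f"sN{tag}"],
                    "yU": se[f"yU{tag}"], "sU": se[f"sU{tag}"],
                },
                covariance=cov,
            )
        )
    return fits[0] if single else fits


def fit_three_state(
    series: DenaturationSeries,
    T: float | None = None,
    R: float = R_KCAL,
) -> ThreeStateFit:
    """Least-squares fit of the nine-parameter three-state model.

    Initialisation: baselines from the outer 15% of points, the two
    midpoints from the two strongest peaks of the smoothed first
    derivative, m values started at 2 kcal/mol/M. The second midpoint is
    parameterised as D50_IN plus a nonnegative increment so the transitions
    stay ordered.
    """
    temp = T if T is not None else series.temperature
    x, y = series.denaturant, series.observable
    yN, sN, yU, sU = _baseline_estimates(x, y)
    mid1, mid2 = _derivative_peaks(x, y, 2)
    span = x[-1] - x[0]
    if mid2 - mid1 < 0.1 * span:
        mid1, mid2 = mid1 - 0.1 * span, mid1 + 0.2 * span

    params = lmfit.Parameters()
    params.add("d50_in", value=max(mid1, 0.05), min=0.0, max=float(x[-1]) * 2)
    params.add("dd50", value=max(mid2 - mid1, 0.1), min=0.01, max=float(x[-1]) * 2)
    params.add("d50_ui", expr="d50_in + dd50")
    params.add("m_in", value=2.0, min=1e-6, max=20.0)
    params.add("m_ui", value=2.0, min=1e-6, max=20.0)
    params.add("f_i", value=float(np.interp(0.5 * (mid1 + mid2), x, y)))
    params.add("a_n", value=yN)
    params.add("b_n", value=sN)
    params.add("a_u", value=yU)
    params.add("b_u", value=sU)

    def residuals(p):
        return (
            three_state_signal(
                x, p["d50_in"], p["m_in"], p["d50_ui"], p["m_ui"], p["f_i"],
                p["a_n"], p["b_n"], p["a_u"], p["b_u"], T=temp, R=R,
            )
            - y
        )

    result = lmfit.minimize(residuals, params, method="leastsq")
    if not result.success:
        raise FitDiverged(
            "three-state fit did not converge",
            {"message": result.message, "nfev": result.nfev},
        )
    p = result.params
    for name in ("m_in", "m_ui"):
        if p[name].value >= 20.0 - 1e-6 or p[name].value <= 1e-6 * 2:
            warnings.warn(f"{name} at bound", BoundaryFitWarning, stacklevel=2)
    names = ["d50_in", "m_in", "dd50", "m_ui", "f_i", "a_n", "b_n", "a_u", "b_u"]
    se, cov = _errors_from_result(result, names)
    d50_ui_se = float(p["d50_ui"].stderr) if p["d50_ui"].stderr is not None else float("nan")
    return ThreeStateFit(
        D50_IN=float(p["d50_in"].value), m_IN=float(p["m_in"].value),
        D50_UI=float(p["d50_ui"].value), m_UI=float(p["m_ui"].value),
        F_I=float(p["f_i"].value),
        aN=float(p["a_n"].value), bN=float(p["b_n"].value),
        aU=float(p["a_u"].value), bU=float(p["b_u"].value),
        temperature=temp,
        standard_errors={
            "D50_IN": se["d50_in"], "m_IN": se["m_in"],
            "D50_UI": d50_ui_se, "m_UI": se["m_ui"], "F_I": se["f_i"],
            "aN": se["a_n"], "bN": se["b_n"], "aU": se["a_u"], "bU": se["b_u"],
        },
        covariance=cov,
    )


def _aicc(n: int, rss: float, k: int) -> float:
    # Gaussian log-likelihood AIC with small-sample correction.
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)


def select_model(
    series: DenaturationSeries,
    svd_hint: int | None = None,
    T: float | None = None,
    aicc_margin: float = 2.0,
) -> ModelSelection:
    """Choose between the two- and three-state descriptions of a series.

    Default rule: corrected-AIC comparison of the two fits, preferring the
    two-state model when ΔAICc < ``aicc_margin`` (parsimony tie-break). An
    SVD component count of >= 3 overrides the criterion in favour of the
    three-state model.
    """
    two = three = None
    two_err = three_err = None
    try:
        two = fit_two_state(series, T=T)
    except Exception as exc:  # noqa: BLE001 - recorded, decision continues
        two_err = exc
    try:
        three = fit_three_state(series, T=T)
    except Exception as exc:  # noqa: BLE001
        three_err = exc
    if two is None and three is None:
        raise NoModel(f"both fits failed: two-state [{two_err}], three-state [{three_err}]")

    n = series.denaturant.size
    criteria: dict[str, float] = {}
    if two is not None:
        rss2 = float(np.sum((two.signal(series.denaturant) - series.observable) ** 2))
        criteria["two_state_aicc"] = _aicc(n, rss2, 6)
    if three is not None:
        rss3 = float(np.sum((three.signal(series.denaturant) - series.observable) ** 2))
        criteria["three_state_aicc"] = _aicc(n, rss3, 9)

    if svd_hint is not None and svd_hint >= 3 and three is not None:
        chosen = UnfoldingModel.THREE_STATE
    elif two is None:
        chosen = UnfoldingModel.THREE_STATE
    elif three is None:
        chosen = UnfoldingModel.TWO_STATE
    else:
        delta = criteria["two_state_aicc"] - criteria["three_state_aicc"]
        chosen = UnfoldingModel.THREE_STATE if delta >= aicc_margin else UnfoldingModel.TWO_STATE
    return ModelSelection(
        chosen=chosen, criterion_values=criteria, svd_rank_hint=svd_hint,
        two_state=two, three_state=three,
    )
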