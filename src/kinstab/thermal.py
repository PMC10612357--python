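"""Melting temperatures from θ222-vs-temperature scans.

The apparent Tm of a thermal unfolding transition is read from the
extremum of the first derivative of the 222-nm ellipticity with respect to
temperature. Transitions of these kinases are irreversible, so only
apparent melting temperatures are reported — no van't Hoff thermodynamics.
Biphasic melts (a populated intermediate) yield one Tm per derivative peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import InvalidScan, NoTransition

__all__ = ["ThermalMelt", "TmResult", "melting_temperatures"]


@dataclass(frozen=True)
class ThermalMelt:
    """A continuous heating scan of ellipticity at 222 nm.

    ``temperatures`` in °C, strictly increasing (typically 20→90 in 0.5 °C
    steps); ``ellipticity222`` in mdeg or mean residue ellipticity — Tm
    extraction is invariant to affine rescaling of the signal.
    """

    temperatures: np.ndarray
    ellipticity222: np.ndarray
    heating_rate: float = 1.0  # °C/min
    sample_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.ellipticity222, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "ellipticity222", y)
        if t.size != y.size or t.size < 20:
            raise ValueError("need matched arrays with at least 20 points")
        if not np.all(np.diff(t) > 0):
            raise InvalidScan("temperature grid must be strictly increasing")


@dataclass(frozen=True)
class TmResult:
    """Apparent melting temperatures, ascending, with peak prominences."""

    tm_values: tuple[float, ...]
    peak_prominences: tuple[float, ...]
    smoothing_window: float
    reversible: bool = False

    @property
    def principal(self) -> float:
        """Tm of the most prominent transition (the main unfolding event)."""
        return self.tm_values[int(np.argmax(self.peak_prominences))]


def melting_temperatures(
    melt: ThermalMelt,
    smoothing_window: float = 2.5,
    polyorder: int = 2,
    prominence: float = 0.1,
) -> TmResult:
    """Locate all thermal transitions of a melt.

    The scan is normalised to its span (making the result invariant to
    affine transformation of the signal), smoothed with a moving polynomial
    of width ``smoothing_window`` °C, and differentiated; temperatures of
    all derivative peaks whose prominence exceeds ``prominence`` times the
    global derivative maximum are returned, refined by parabolic
    interpolation around the discrete peak.

    Raises
    ------
    NoTransition
        For a flat scan or when no peak passes the prominence threshold.
    """
    t = melt.temperatures
    y = melt.ellipticity222
    span = float(y.max() - y.min())
    if span == 0.0:
        raise NoTransition("flat scan: signal has zero span")
    # orient so that unfolding increases the normalised signal
    direction = np.sign(y[-1] - y[0]) or 1.0
    yn = direction * (y - y.min()) / span

    step = float(np.median(np.diff(t)))
    window = int(round(smoothing_window / step))
    window = max(window | 1, polyorder + 1 + ((polyorder + 1) % 2 == 0))  # odd, > polyorder
    window = min(window, t.size - (1 - t.size % 2))
    ys = savgol_filter(yn, window_length=window, polyorder=polyorder)
    dy = np.gradient(ys, t)

    peak_max = float(dy.max())
    if peak_max <= 0:
        raise NoTransition("no rising transition found")
    # a real transition is at least as wide as the smoothing window at half
    # prominence; narrower derivative spikes are residual noise
    idx, props = find_peaks(
        dy, prominence=prominence * peak_max, width=max(window // 2, 1)
    )
    if idx.size == 0:
        raise NoTransition("no derivative peak above the prominence threshold")

    tms = []
    for i in idx:
        if 0 < i < t.size - 1:
            # parabola through the three points around the discrete maximum
            denom = dy[i - 1] - 2 * dy[i] + dy[i + 1]
            offset = 0.5 * (dy[i - 1] - dy[i + 1]) / denom if denom != 0 else 0.0
            offset = float(np.clip(offset, -1.0, 1.0))
            tms.append(float(t[i] + offset * step))
        else:
            tms.append(float(t[i]))
    order = np.argsort(tms)
    return TmResult(
        tm_values=tuple(round(tms[j], 1) for j in order),
        peak_prominences=tuple(float(props["prominences"][j]) for j in order),
        smoothing_window=smoothing_window,
    )
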