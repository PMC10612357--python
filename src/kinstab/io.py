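"""CSV dialects and JSON result records.

All on-disk formats are plain delimited text with a mandatory header and
'.' as the decimal separator; results are serialized as JSON. Readers
validate the header against the expected schema and report the first
offending row/column on parse failure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .kinetics import ProgressCurve, RatePoint
from .spectra import Probe, SpectralSeries, Spectrum
from .thermal import ThermalMelt
from .unfolding import DenaturationProbe, DenaturationSeries

__all__ = [
    "read_table",
    "read_denaturation_series",
    "write_denaturation_series",
    "read_thermal_melt",
    "write_thermal_melt",
    "read_progress_curves",
    "write_progress_curves",
    "read_rate_points",
    "write_rate_points",
    "read_spectral_series",
    "write_spectral_series",
    "write_json",
    "result_to_dict",
]

# column -> dtype converter per table kind
SCHEMAS = {
    "denaturation": {"denaturant_M": float, "value": float, "probe": str,
                     "replicate_id": str, "temperature_K": float},
    "thermal": {"temperature_C": float, "theta222": float, "sample_id": str},
    "progress": {"time_s": float, "fluorescence_AU": float, "substrate_uM": float,
                 "enzyme_nM": float, "temperature_C": float,
                 "calibration_AU_per_uM": float},
    "rates": {"substrate_uM": float, "rate_uM_per_s": float, "temperature_C": float},
    "spectra": {"wavelength_nm": float, "value": float, "condition": float,
                "probe": str, "sample_id": str},
    "variants": {"protein": str, "substitution": str, "phospho_state": str,
                 "group": str},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one CSV table.

    ``schema`` names an entry of :data:`SCHEMAS`. Missing columns raise
    :class:`SchemaError` naming the column; unparseable cells raise
    :class:`ParseError` with the 1-based data row and the column.
    """
    columns = SCHEMAS[schema]
    frame = pd.read_csv(path, dtype=str)
    for col in columns:
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out = {}
    for col, conv in columns.items():
        if conv is str:
            out[col] = frame[col].fillna("").astype(str)
            continue
        cleaned = frame[col].str.replace(" ", "", regex=False)
        probe = pd.to_numeric(cleaned, errors="coerce")
        bad = probe.isna() & frame[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1
            raise ParseError(
                f"{path}: cannot parse {frame[col][bad].iloc[0]!r} "
                f"at row {row}, column {col!r}"
            )
        # exact (correctly rounded) conversion; pd.to_numeric's fast parser
        # is not round-trip precise
        out[col] = cleaned.fillna("nan").astype(float)
    return pd.DataFrame(out)


# -- denaturation series ---------------------------------------------------

def read_denaturation_series(path: str | Path) -> list[DenaturationSeries]:
    frame = read_table(path, "denaturation")
    series = []
    for (probe, rep, temp), sub in frame.groupby(
        ["probe", "replicate_id", "temperature_K"], sort=False
    ):
        sub = sub.sort_values("denaturant_M")
        series.append(DenaturationSeries(
            denaturant=sub["denaturant_M"].to_numpy(),
            observable=sub["value"].to_numpy(),
            probe=DenaturationProbe(probe),
            temperature=float(temp),
            replicate_id=str(rep),
        ))
    return series


def write_denaturation_series(series: list[DenaturationSeries], path: str | Path):
    rows = []
    for s in series:
        for x, y in zip(s.denaturant, s.observable):
            rows.append({"denaturant_M": x, "value": y, "probe": s.probe.value,
                         "replicate_id": s.replicate_id,
                         "temperature_K": s.temperature})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# -- thermal melts ---------------------------------------------------------

def read_thermal_melt(path: str | Path) -> list[ThermalMelt]:
    frame = read_table(path, "thermal")
    return [
        ThermalMelt(
            temperatures=sub.sort_values("temperature_C")["temperature_C"].to_numpy(),
            ellipticity222=sub.sort_values("temperature_C")["theta222"].to_numpy(),
            sample_id=str(sid),
        )
        for sid, sub in frame.groupby("sample_id", sort=False)
    ]


def write_thermal_melt(melts: list[ThermalMelt], path: str | Path):
    rows = []
    for m in melts:
        for t, y in zip(m.temperatures, m.ellipticity222):
            rows.append({"temperature_C": t, "theta222": y, "sample_id": m.sample_id})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# -- kinetics --------------------------------------------------------------

def read_progress_curves(path: str | Path) -> list[ProgressCurve]:
    frame = read_table(path, "progress")
    curves = []
    keys = ["substrate_uM", "enzyme_nM", "temperature_C", "calibration_AU_per_uM"]
    for (s, e, t, cal), sub in frame.groupby(keys, sort=False):
        sub = sub.sort_values("time_s")
        curves.append(ProgressCurve(
            time=sub["time_s"].to_numpy(),
            fluorescence=sub["fluorescence_AU"].to_numpy(),
            substrate_conc=float(s), enzyme_conc=float(e),
            temperature=float(t), calibration=float(cal),
        ))
    return curves


def write_progress_curves(curves: list[ProgressCurve], path: str | Path):
    rows = []
    for c in curves:
        for t, f in zip(c.time, c.fluorescence):
            rows.append({
                "time_s": t, "fluorescence_AU": f, "substrate_uM": c.substrate_conc,
                "enzyme_nM": c.enzyme_conc, "temperature_C": c.temperature,
                "calibration_AU_per_uM": c.calibration,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_rate_points(path: str | Path) -> list[RatePoint]:
    frame = read_table(path, "rates")
    return [
        RatePoint(float(r.substrate_uM), float(r.rate_uM_per_s), float(r.temperature_C))
        for r in frame.itertuples()
    ]


def write_rate_points(points: list[RatePoint], path: str | Path):
    pd.DataFrame([
        {"substrate_uM": p.substrate_conc, "rate_uM_per_s": p.rate,
         "temperature_C": p.temperature}
        for p in points
    ]).to_csv(path, index=False, float_format="%.17g")


# -- spectra ---------------------------------------------------------------

def read_spectral_series(path: str | Path) -> SpectralSeries:
    frame = read_table(path, "spectra")
    conditions = []
    spectra = []
    for cond, sub in frame.groupby("condition", sort=True):
        sub = sub.sort_values("wavelength_nm")
        conditions.append(float(cond))
        spectra.append(Spectrum(
            wavelengths=sub["wavelength_nm"].to_numpy(),
            values=sub["value"].to_numpy(),
            probe=Probe(sub["probe"].iloc[0]),
            sample_id=str(sub["sample_id"].iloc[0]),
        ))
    return SpectralSeries(np.array(conditions), tuple(spectra))


def write_spectral_series(series: SpectralSeries, path: str | Path):
    rows = []
    for cond, spec in zip(series.condition_values, series.spectra):
        for wl, v in zip(spec.wavelengths, spec.values):
            rows.append({"wavelength_nm": wl, "value": v, "condition": cond,
                         "probe": spec.probe.value, "sample_id": spec.sample_id})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# -- results ---------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def result_to_dict(fit, model_name: str | None = None) -> dict:
    """A fit dataclass as a JSON-ready record (with the model name)."""
    record = _jsonify(dataclasses.asdict(fit))
    if model_name is not None:
        record = {"model": model_name, **record}
    return record


def write_json(record: dict, path: str | Path):
    Path(path).write_text(json.dumps(_jsonify(record), indent=2, sort_keys=True) + "\n")
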