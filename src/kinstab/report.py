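"""Variant classification and the per-variant comparison ledger.

Missense variants of MAPK1/MAPK3 are classified into three groups by the
relation of the mutated residue to the common docking site (CD-site), the
docking surface opposite the catalytic cleft: group I — residue interacts
with the CD-site; group II — residue lies in the CD-site; group III —
residue elsewhere in the protein. Group membership ships as packaged data
so other kinases or variant sets can reuse the reporter with their own
table.

For each variant the comparison ledger records, against the wild type:
ΔTm in both phospho-states, the catalytic-efficiency ratio
(kcat/Km)_variant / (kcat/Km)_wt, ΔTmax, ΔEa, and the tertiary-change /
three-state-unfolding flags. Flags are recorded judgments from the
upstream analyses, not inferred here.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, fields
from importlib import resources

import pandas as pd

from .errors import EmptyReport, IncompleteRecord, ParseError

__all__ = [
    "VariantRecord",
    "ComparisonRow",
    "parse_substitution",
    "classify_variant",
    "compare_to_wildtype",
    "render_report",
    "load_group_table",
    "load_reference_records",
]

WILDTYPE = "WT"

#: Sequence lengths used to bound substitution positions.
SEQUENCE_LENGTH = {"MAPK1": 360, "MAPK3": 379}

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Parse ``E81K`` into (wild-type residue, position, mutant residue)."""
    m = _SUB_RE.match(text.strip())
    if not m:
        raise ParseError(f"substitution {text!r} does not parse as letter-integer-letter")
    return m.group(1), int(m.group(2)), m.group(3)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("kinstab.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_group_table() -> pd.DataFrame:
    """The packaged CD-site group table (protein, substitution, group)."""
    return _read_packaged_csv("variant_groups.csv")


def classify_variant(
    protein: str,
    substitution: str,
    group_table: pd.DataFrame | None = None,
) -> str:
    """CD-site group (I/II/III) of a variant, or ``"Unclassified"``.

    ``group_table`` defaults to the packaged table; a user-supplied frame
    with the same columns extends the reporter to other variant sets.
    """
    if protein not in SEQUENCE_LENGTH:
        raise ParseError(f"unknown protein {protein!r}")
    wt, pos, mut = parse_substitution(substitution)
    if not 1 <= pos <= SEQUENCE_LENGTH[protein]:
        raise ParseError(
            f"position {pos} outside {protein} sequence (1..{SEQUENCE_LENGTH[protein]})"
        )
    table = group_table if group_table is not None else load_group_table()
    hit = table[(table["protein"] == protein) & (table["substitution"] == substitution)]
    if hit.empty:
        return "Unclassified"
    return str(hit["group"].iloc[0])


@dataclass(frozen=True)
class VariantRecord:
    """Per-variant summary of the upstream fits, both phospho-states.

    ``tm_NP``/``tm_P`` are the (first) apparent melting temperatures;
    kinetic fields describe the phosphorylated, active enzyme. ``None``
    marks an absent upstream result.
    """

    protein: str
    substitution: str  # "WT" for the wild type
    group: str | None = None
    tm_NP: float | None = None
    tm_P: float | None = None
    efficiency: float | None = None  # kcat/Km, s⁻¹µM⁻¹
    tmax: float | None = None        # °C
    Ea: float | None = None          # kcal/mol
    tertiary_change_NP: bool | None = None
    tertiary_change_P: bool | None = None
    three_state_NP: bool | None = None
    three_state_P: bool | None = None

    def __post_init__(self):
        if self.substitution != WILDTYPE:
            parse_substitution(self.substitution)


@dataclass(frozen=True)
class ComparisonRow:
    """One row of the variant-vs-wild-type ledger."""

    protein: str
    substitution: str
    group: str | None
    delta_tm_NP: float
    delta_tm_P: float
    efficiency_ratio: float
    delta_tmax: float
    delta_Ea: float
    tertiary_change_NP: bool | None = None
    tertiary_change_P: bool | None = None
    three_state_NP: bool | None = None
    three_state_P: bool | None = None


_REQUIRED = ("tm_NP", "tm_P", "efficiency", "tmax", "Ea")


def compare_to_wildtype(variant: VariantRecord, wildtype: VariantRecord) -> ComparisonRow:
    """Δ values (variant − wild type) and the catalytic-efficiency ratio.

    Antisymmetric by construction: swapping the arguments negates every
    delta and inverts the ratio. A wild-type self-comparison gives all
    deltas 0 and ratio 1.
    """
    missing = [
        f"{which}.{name}"
        for which, rec in (("variant", variant), ("wildtype", wildtype))
        for name in _REQUIRED
        if getattr(rec, name) is None
    ]
    if missing:
        raise IncompleteRecord("missing upstream fits: " + ", ".join(missing), missing)
    if wildtype.efficiency <= 0:
        raise ValueError("wild-type efficiency must be > 0")
    return ComparisonRow(
        protein=variant.protein,
        substitution=variant.substitution,
        group=variant.group,
        delta_tm_NP=variant.tm_NP - wildtype.tm_NP,
        delta_tm_P=variant.tm_P - wildtype.tm_P,
        efficiency_ratio=variant.efficiency / wildtype.efficiency,
        delta_tmax=variant.tmax - wildtype.tmax,
        delta_Ea=variant.Ea - wildtype.Ea,
        tertiary_change_NP=variant.tertiary_change_NP,
        tertiary_change_P=variant.tertiary_change_P,
        three_state_NP=variant.three_state_NP,
        three_state_P=variant.three_state_P,
    )


def format_ratio(value: float) -> str:
    """3 significant figures; scientific notation below 10⁻²."""
    if value != 0 and abs(value) < 1e-2:
        return f"{value:.2e}"
    return f"{value:.3g}"


def _flag(v: bool | None) -> str:
    return "" if v is None else ("yes" if v else "no")


def rows_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "protein": r.protein,
            "substitution": r.substitution,
            "group": r.group or "",
            "tertiary_change_NP": _flag(r.tertiary_change_NP),
            "tertiary_change_P": _flag(r.tertiary_change_P),
            "three_state_NP": _flag(r.three_state_NP),
            "three_state_P": _flag(r.three_state_P),
            "delta_tm_NP_C": round(r.delta_tm_NP, 1),
            "delta_tm_P_C": round(r.delta_tm_P, 1),
            "efficiency_ratio": format_ratio(r.efficiency_ratio),
            "delta_tmax_C": round(r.delta_tmax, 1),
            "delta_Ea_kcal_mol": round(r.delta_Ea, 2),
        }
        for r in rows
    ])


def render_report(rows: list[ComparisonRow], fmt: str = "csv") -> str:
    """Deterministic tabular report; row order equals input order.

    ``fmt`` is ``"csv"`` (delimited) or ``"text"`` (fixed-width,
    human-readable).
    """
    if not rows:
        raise EmptyReport("no comparison rows to render")
    frame = rows_to_frame(rows)
    if fmt == "csv":
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "text":
        return frame.to_string(index=False) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def _first_tm(cell: str) -> float:
    return float(str(cell).split(";")[0])


def load_reference_records() -> dict[tuple[str, str], VariantRecord]:
    """Variant records assembled from the packaged printed-parameter tables.

    Joins the per-state stability summary (Tm, unfolding model,
    tertiary-change flag) with the kinetic parameter table; keyed by
    (protein, substitution).
    """
    stab = _read_packaged_csv("reference_stability.csv")
    kin = _read_packaged_csv("reference_kinetics.csv")
    groups = load_group_table()
    records: dict[tuple[str, str], VariantRecord] = {}
    for (protein, variant), sub in stab.groupby(["protein", "variant"], sort=False):
        by_state = {row["state"]: row for _, row in sub.iterrows()}
        krow = kin[(kin["protein"] == protein) & (kin["variant"] == variant)]
        k = krow.iloc[0] if not krow.empty else None
        if variant == WILDTYPE:
            group = None
        else:
            group = classify_variant(protein, variant, groups)
        def state(field, conv, st):
            row = by_state.get(st)
            return conv(row[field]) if row is not None else None
        records[(protein, variant)] = VariantRecord(
            protein=protein,
            substitution=variant,
            group=group,
            tm_NP=state("tm_C", _first_tm, "NP"),
            tm_P=state("tm_C", _first_tm, "P"),
            efficiency=float(k["efficiency"]) if k is not None else None,
            tmax=float(k["Tmax_C"]) if k is not None else None,
            Ea=float(k["Ea_kcal_mol"]) if k is not None else None,
            tertiary_change_NP=state("tertiary_change", lambda v: v == "yes", "NP"),
            tertiary_change_P=state("tertiary_change", lambda v: v == "yes", "P"),
            three_state_NP=state("model", lambda v: v == "three", "NP"),
            three_state_P=state("model", lambda v: v == "three", "P"),
        )
    return records
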