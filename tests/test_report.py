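"""Variant classification and the comparison ledger."""

import pytest

from kinstab.errors import EmptyReport, IncompleteRecord, ParseError
from kinstab.report import (
    ComparisonRow,
    VariantRecord,
    classify_variant,
    compare_to_wildtype,
    format_ratio,
    load_reference_records,
    parse_substitution,
    render_report,
)


@pytest.fixture(scope="module")
def reference():
    return load_reference_records()


class TestClassification:
    @pytest.mark.parametrize(
        "protein,sub,group",
        [
            ("MAPK1", "E81K", "I"),
            ("MAPK1", "P319S", "II"),
            ("MAPK1", "E322V", "II"),
            ("MAPK3", "I73M", "III"),
            ("MAPK3", "E98K", "I"),
            ("MAPK3", "P336Q", "II"),
        ],
    )
    def test_group_lookup(self, protein, sub, group):
        assert classify_variant(protein, sub) == group

    def test_unknown_variant_unclassified(self):
        assert classify_variant("MAPK1", "A17V") == "Unclassified"

    @pytest.mark.parametrize("bad", ["E81", "81K", "e81k", "E81KX", ""])
    def test_malformed_substitution(self, bad):
        with pytest.raises(ParseError):
            parse_substitution(bad)

    def test_position_outside_sequence(self):
        with pytest.raises(ParseError):
            classify_variant("MAPK1", "E400K")  # MAPK1 has 360 residues


class TestComparison:
    def test_wildtype_self_comparison(self, reference):
        wt = reference[("MAPK1", "WT")]
        row = compare_to_wildtype(wt, wt)
        assert row.delta_tm_NP == 0.0
        assert row.delta_tm_P == 0.0
        assert row.delta_tmax == 0.0
        assert row.delta_Ea == 0.0
        assert row.efficiency_ratio == 1.0

    def test_antisymmetry(self, reference):
        a = reference[("MAPK1", "E322V")]
        b = reference[("MAPK1", "WT")]
        fwd = compare_to_wildtype(a, b)
        rev = compare_to_wildtype(b, a)
        assert fwd.delta_tm_NP == -rev.delta_tm_NP
        assert fwd.delta_tmax == -rev.delta_tmax
        assert fwd.delta_Ea == -rev.delta_Ea
        assert fwd.efficiency_ratio == pytest.approx(1 / rev.efficiency_ratio)

    def test_incomplete_record_lists_missing(self):
        partial = VariantRecord(protein="MAPK1", substitution="E81K", tm_NP=55.0)
        wt = VariantRecord(protein="MAPK1", substitution="WT", tm_NP=55.0,
                           tm_P=55.0, efficiency=1.22, tmax=30.0, Ea=9.95)
        with pytest.raises(IncompleteRecord) as err:
            compare_to_wildtype(partial, wt)
        assert any("tm_P" in m for m in err.value.missing)


# (variant, field, printed value) - cells of the published comparison ledger
# that recompute exactly from the per-variant parameter tables; cells with
# source rounding inconsistencies or ambiguous multi-valued Tm entries are
# excluded.
MAPK1_LEDGER = [
    ("E81K", "delta_tm_NP", 0.0), ("E81K", "delta_tm_P", -0.9),
    ("E81K", "delta_tmax", 5.0), ("E81K", "delta_Ea", -3.05),
    ("R135K", "delta_tm_NP", 0.1), ("R135K", "efficiency_ratio", 3.75),
    ("R135K", "delta_tmax", 5.0),
    ("D162G", "delta_tm_P", 5.0), ("D162G", "efficiency_ratio", 5.33e-4),
    ("D162G", "delta_tmax", 10.0), ("D162G", "delta_Ea", -3.01),
    ("R191H", "delta_tm_NP", 3.0), ("R191H", "delta_tm_P", 3.1),
    ("R191H", "efficiency_ratio", 2.98e-4), ("R191H", "delta_Ea", -1.86),
    ("Y316F", "efficiency_ratio", 3.57), ("Y316F", "delta_Ea", -4.21),
    ("P319S", "delta_tm_NP", -4.0), ("P319S", "efficiency_ratio", 6.97e-2),
    ("P319S", "delta_Ea", -2.39),
    ("E322V", "delta_tm_NP", 2.1), ("E322V", "delta_tm_P", 1.0),
    ("E322V", "efficiency_ratio", 1.11), ("E322V", "delta_tmax", 7.0),
    ("E322V", "delta_Ea", -5.96),
    ("E33Q", "delta_tm_P", 4.0), ("E33Q", "efficiency_ratio", 4.16e-1),
    ("E33Q", "delta_tmax", -5.0), ("E33Q", "delta_Ea", 1.15),
    ("L121I", "delta_tm_P", 7.0), ("L121I", "efficiency_ratio", 8.28e-3),
    ("L200F", "efficiency_ratio", 6.16e-3), ("L200F", "delta_tmax", 0.0),
    ("D235V", "delta_tm_P", 6.1), ("D235V", "efficiency_ratio", 6.40e-2),
]
MAPK3_LEDGER = [
    ("E98K", "delta_tm_NP", 6.0), ("E98K", "delta_tm_P", 0.0),
    ("E98K", "efficiency_ratio", 1.66), ("E98K", "delta_tmax", -12.0),
    ("E98K", "delta_Ea", 1.60),
    ("R152W", "delta_tm_NP", 3.0), ("R152W", "efficiency_ratio", 2.46e-1),
    ("R152W", "delta_tmax", 3.0), ("R152W", "delta_Ea", 1.29),
    ("P336Q", "delta_tm_NP", -2.0), ("P336Q", "delta_Ea", 1.98),
    ("E339V", "efficiency_ratio", 5.69e-1), ("E339V", "delta_tmax", -7.0),
    ("Q79H", "efficiency_ratio", 7.69e-2), ("Q79H", "delta_Ea", 4.33),
    ("A160T", "delta_tm_NP", -3.9), ("A160T", "delta_tm_P", -3.0),
    ("A160T", "efficiency_ratio", 9.23e-1), ("A160T", "delta_Ea", 5.04),
    ("T198I", "efficiency_ratio", 5.046), ("T198I", "delta_Ea", 3.88),
    ("E214D", "efficiency_ratio", 9.23e-2), ("E214D", "delta_Ea", 4.47),
    ("L281I", "delta_tmax", -7.0), ("L281I", "delta_Ea", 5.92),
    ("V290A", "delta_tm_P", 8.9), ("V290A", "efficiency_ratio", 1.38e-1),
    ("V290A", "delta_tmax", -17.0), ("V290A", "delta_Ea", 8.42),
    ("R359W", "delta_tm_P", 9.0), ("R359W", "efficiency_ratio", 7.08e-1),
    ("E362K", "delta_tm_NP", -1.9), ("E362K", "efficiency_ratio", 2.61e-1),
    ("E362K", "delta_Ea", 6.82),
]


class TestLedgerRegression:
    @pytest.mark.parametrize("protein,ledger",
                             [("MAPK1", MAPK1_LEDGER), ("MAPK3", MAPK3_LEDGER)])
    def test_deltas_and_ratios_reproduce_printed_cells(self, reference, protein, ledger):
        wt = reference[(protein, "WT")]
        rows = {
            sub: compare_to_wildtype(reference[(protein, sub)], wt)
            for sub in {v for v, _, _ in ledger}
        }
        for sub, fld, printed in ledger:
            got = getattr(rows[sub], fld)
            if fld == "efficiency_ratio":
                assert float(format_ratio(got)) == pytest.approx(printed, rel=5e-3), (sub, fld)
            else:
                assert round(got, 2) == pytest.approx(printed, abs=5e-3), (sub, fld)


class TestRendering:
    def test_empty_report_raises(self):
        with pytest.raises(EmptyReport):
            render_report([], "csv")

    def test_self_row_renders_zeros_and_one(self, reference):
        wt = reference[("MAPK1", "WT")]
        out = render_report([compare_to_wildtype(wt, wt)], "csv")
        assert "0.0,0.0,1,0.0,0.0" in out

    def test_scientific_notation_below_threshold(self):
        assert format_ratio(5.328e-4) == "5.33e-04"
        assert format_ratio(1.662) == "1.66"

    def test_text_format_and_row_order(self, reference):
        wt = reference[("MAPK1", "WT")]
        rows = [
            compare_to_wildtype(reference[("MAPK1", v)], wt)
            for v in ("E322V", "E81K")
        ]
        text = render_report(rows, "text")
        assert text.index("E322V") < text.index("E81K")
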