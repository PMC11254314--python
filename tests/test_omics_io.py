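"""Differential-table and phenotype I/O: validation, dedup, normalization, round-trip."""

import pytest
from hypothesis import given, settings, strategies as st

from triomic.errors import FormatError, ValidationError
from triomic.groups import GroupKey
from triomic.omics_io import (
    DifferentialRecord,
    build_table,
    normalize_id,
    parse_direction,
    read_differential_table,
    read_phenotype_series,
    write_differential_table,
    write_phenotype_series,
    PhenotypeSeries,
)

G = GroupKey(100, 12)


def _write(tmp_path, text, name="t.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGroupKey:
    def test_render_and_parse_roundtrip(self):
        assert str(G) == "100uM-12h"
        assert GroupKey.parse("200uM-48h") == GroupKey(200, 48)
        assert GroupKey.parse(str(G)) == G

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            GroupKey(0, 12)


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,kind,expected",
        [
            ("  Rrm2 ", "gene", "rrm2"),
            ("RRM2", "protein", "rrm2"),
            ("Uric   Acid", "metabolite", "uric acid"),
            ("D-Glucose 1-phosphate", "metabolite", "d-glucose 1-phosphate"),
        ],
    )
    def test_normalize_id(self, raw, kind, expected):
        assert normalize_id(raw, kind) == expected

    @pytest.mark.parametrize("token,expected", [("up", "up"), ("↑", "up"), ("+1", "up"),
                                                ("down", "down"), ("↓", "down"), ("-1", "down")])
    def test_direction_tokens(self, token, expected):
        assert parse_direction(token) == expected

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValidationError):
            parse_direction("sideways")


class TestReadDifferentialTable:
    def test_identical_duplicate_rows_collapse(self, tmp_path):
        p = _write(tmp_path, "id\tkind\tdose_uM\ttime_h\tdirection\n"
                             "A\tgene\t100\t12\tup\nB\tgene\t100\t12\tdown\nA\tgene\t100\t12\tup\n")
        table = read_differential_table(p, "gene")
        assert len(table) == 2
        assert table.ids_in_group(G) == {"a", "b"}

    def test_conflicting_directions_rejected(self, tmp_path):
        p = _write(tmp_path, "id\tkind\tdose_uM\ttime_h\tdirection\n"
                             "A\tgene\t100\t12\tup\nA\tgene\t100\t12\tdown\n")
        with pytest.raises(ValidationError, match="conflicting"):
            read_differential_table(p, "gene")

    def test_missing_column_named_in_error(self, tmp_path):
        p = _write(tmp_path, "id\tdose_uM\tdirection\nA\t100\tup\n")
        with pytest.raises(FormatError, match="time_h"):
            read_differential_table(p, "gene")

    def test_dedup_keeps_largest_magnitude(self):
        table = build_table("gene", [
            DifferentialRecord("A", "gene", G, "up", magnitude=1.0),
            DifferentialRecord("A", "gene", G, "up", magnitude=-3.0),
        ])
        assert len(table) == 1
        assert table.records[0].magnitude == -3.0

    def test_fixture_metabolites_match_published_catalogue(self, fixture_tables):
        """The bundled transcription: 13 unique metabolites spread over 4 groups."""
        _, _, mets = fixture_tables
        assert len(mets) == 13
        assert len({r.key for r in mets.records}) == 13
        assert len(mets.groups) == 4
        assert mets.direction_of("uric acid", G) == "up"
        assert mets.direction_of("uridine", GroupKey(200, 12)) == "down"


class TestPhenotype:
    def test_bundled_series_reproduces_printed_values(self, fixture_phenotype):
        expected = {
            GroupKey(100, 12): 96.9, GroupKey(100, 24): 92.7, GroupKey(100, 48): 90.1,
            GroupKey(200, 12): 96.1, GroupKey(200, 24): 89.3, GroupKey(200, 48): 81.8,
        }
        assert fixture_phenotype.values == expected

    def test_empty_file_gives_empty_series(self, tmp_path, caplog):
        p = _write(tmp_path, "dose_uM\ttime_h\tvalue\n")
        series = read_phenotype_series(p)
        assert len(series) == 0

    def test_duplicate_group_rejected(self, tmp_path):
        p = _write(tmp_path, "dose_uM\ttime_h\tvalue\n100\t12\t96.9\n100\t12\t90.0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_phenotype_series(p)

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValidationError):
            PhenotypeSeries({G: 0.0})

    def test_roundtrip(self, tmp_path, fixture_phenotype):
        out = tmp_path / "ph.tsv"
        write_phenotype_series(fixture_phenotype, out)
        assert read_phenotype_series(out).values == fixture_phenotype.values


ids = st.text(alphabet="abcdeXY ", min_size=1, max_size=8).filter(lambda s: s.strip())
records = st.builds(
    DifferentialRecord,
    entity_id=ids,
    entity_kind=st.just("gene"),
    group=st.sampled_from([GroupKey(100, 12), GroupKey(200, 48)]),
    direction=st.sampled_from(["up", "down"]),
    magnitude=st.one_of(st.none(), st.floats(-5, 5, allow_nan=False)),
)


@settings(max_examples=60, derandomize=True)
@given(st.lists(records, max_size=25))
def test_write_read_roundtrip_is_identity(tmp_path_factory, recs):
    """write(read(f)) == read(f) record-for-record on any valid table."""
    try:
        table = build_table("gene", recs)
    except ValidationError:
        return  # conflicting directions: not a valid table
    path = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_differential_table(table, path)
    back = read_differential_table(path, "gene")
    assert back.records == table.records
    assert len(table) <= len(recs)
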