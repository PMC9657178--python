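"""Input-table parsing, validation, harmonization and round-trips."""

import numpy as np
import pytest

from degconsensus import (
    CountMatrix,
    SampleInfo,
    ValidationError,
    harmonize,
    parse_counts,
    parse_sample_info,
)
from degconsensus.tables_io import write_counts, write_sample_info


class TestParseCounts:
    def test_toy_table_parses_verbatim(self, counts_path):
        cm = parse_counts(counts_path)
        assert cm.n_genes == 10
        assert cm.n_samples == 7
        g = cm.gene_ids.index("FBgn0000008")
        s = cm.sample_names.index("Treated1")
        assert cm.counts[g, s] == 140
        assert cm.gene_ids[0] == "FBgn0000003"
        assert cm.sample_names == (
            "Treated1", "Treated2", "Treated3",
            "Untreated1", "Untreated2", "Untreated3", "Untreated4",
        )

    def test_column_sums_match_manual_totals(self, counts_path):
        cm = parse_counts(counts_path)
        sums = dict(zip(cm.sample_names, cm.counts.sum(axis=0)))
        assert sums["Treated1"] == 8780
        assert sums["Treated2"] == 4163

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda lines: lines + [lines[2]], "duplicate gene id"),
            (lambda lines: lines[:2] + [lines[2].replace("140", "3.7")], "non-integer"),
            (lambda lines: lines[:2] + [lines[2].replace("140", "-1")], "negative"),
            (lambda lines: lines[:2] + [lines[2].replace("140", "x")], "non-numeric"),
            (
                lambda lines: ["\t".join(l.split("\t")[:2]) for l in lines],
                "at least 2 sample columns",
            ),
        ],
        ids=["duplicate-id", "fractional", "negative", "non-numeric", "too-few-columns"],
    )
    def test_validation_errors_name_the_offence(self, counts_path, tmp_path, mutate, match):
        lines = counts_path.read_text().rstrip("\n").split("\n")
        bad = tmp_path / "bad.tsv"
        bad.write_text("\n".join(mutate(lines)) + "\n")
        with pytest.raises(ValidationError, match=match):
            parse_counts(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ValidationError, match="not found"):
            parse_counts(tmp_path / "nope.tsv")


class TestParseSampleInfo:
    def test_toy_table_parses(self, coldata_path):
        info = parse_sample_info(coldata_path)
        assert len(info.sample_names) == 7
        assert info.levels == ("treated", "untreated")
        assert len(info.samples_for("treated")) == 3
        assert len(info.samples_for("untreated")) == 4

    def test_third_condition_level_rejected(self, coldata_path, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(coldata_path.read_text() + "mock1\tmock\n")
        with pytest.raises(ValidationError, match="exactly two values"):
            parse_sample_info(bad)

    def test_wrong_header_rejected(self, coldata_path, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(coldata_path.read_text().replace("condition", "group"))
        with pytest.raises(ValidationError, match='"condition"'):
            parse_sample_info(bad)

    def test_duplicate_sample_rejected(self, coldata_path, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(coldata_path.read_text() + "treated1\ttreated\n")
        with pytest.raises(ValidationError, match="duplicate sample"):
            parse_sample_info(bad)


class TestHarmonize:
    def test_case_insensitive_match_with_warning(self, counts_path, coldata_path):
        cm = parse_counts(counts_path)
        info = parse_sample_info(coldata_path)
        with pytest.warns(UserWarning, match="case-insensitively"):
            ds = harmonize(cm, info)
        assert ds.counts.sample_names == info.sample_names
        assert ds.condition_order == ("treated", "untreated")
        # counts follow the columns, not just the names
        g = ds.counts.gene_ids.index("FBgn0000008")
        assert ds.counts.counts[g, 0] == 140

    def test_strict_mode_rejects_case_mismatch(self, counts_path, coldata_path):
        cm = parse_counts(counts_path)
        info = parse_sample_info(coldata_path)
        with pytest.raises(ValidationError, match="not found"):
            harmonize(cm, info, strict_names=True)

    def test_already_ordered_is_identity_and_idempotent(self, counts_path):
        cm = parse_counts(counts_path)
        info = SampleInfo(
            sample_names=cm.sample_names,
            condition=("t",) * 3 + ("u",) * 4,
        )
        ds = harmonize(cm, info)
        assert np.array_equal(ds.counts.counts, cm.counts)
        ds2 = harmonize(ds.counts, ds.design)
        assert np.array_equal(ds2.counts.counts, ds.counts.counts)
        assert ds2.counts.sample_names == ds.counts.sample_names

    def test_unmatched_sample_errors(self, counts_path, coldata_path):
        cm = parse_counts(counts_path)
        info = parse_sample_info(coldata_path)
        extra = SampleInfo(
            sample_names=info.sample_names + ("treated5",),
            condition=info.condition + ("treated",),
        )
        with pytest.warns(UserWarning, match="case-insensitively"):
            with pytest.raises(ValidationError, match="treated5"):
                harmonize(cm, extra)

    def test_reference_override(self, counts_path, coldata_path):
        cm = parse_counts(counts_path)
        info = parse_sample_info(coldata_path)
        with pytest.warns(UserWarning):
            ds = harmonize(cm, info, reference="untreated")
        assert ds.condition_order == ("untreated", "treated")


class TestRoundTrip:
    def test_counts_round_trip_bytes(self, counts_path, tmp_path):
        cm = parse_counts(counts_path)
        out = tmp_path / "cts.tsv"
        write_counts(cm, out, id_header="Transcript_name")
        assert out.read_text() == counts_path.read_text()
        again = parse_counts(out)
        assert again.gene_ids == cm.gene_ids
        assert again.sample_names == cm.sample_names
        assert np.array_equal(again.counts, cm.counts)

    def test_sample_info_round_trip_bytes(self, coldata_path, tmp_path):
        info = parse_sample_info(coldata_path)
        out = tmp_path / "coldata.tsv"
        write_sample_info(info, out)
        assert out.read_text() == coldata_path.read_text()
        assert parse_sample_info(out) == info


class TestInvariants:
    def test_count_matrix_rejects_duplicates(self):
        with pytest.raises(ValidationError, match="duplicate gene"):
            CountMatrix(("a", "a"), ("s1", "s2"), np.zeros((2, 2), dtype=int))

    def test_count_matrix_rejects_negative(self):
        with pytest.raises(ValidationError, match="negative"):
            CountMatrix(("a",), ("s1", "s2"), np.array([[1, -1]]))

    def test_sample_info_needs_two_levels(self):
        with pytest.raises(ValidationError, match="exactly two"):
            SampleInfo(("a", "b"), ("x", "x"))
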