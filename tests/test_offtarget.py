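import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnai_nto.io_formats import DiffExprTable, SequenceRecord
from rnai_nto.offtarget_scan import (
    bin_by_match_length,
    longest_contiguous_match,
    match_fold_change_correlation,
    reverse_complement,
    scan_transcriptome,
    summary_from_counts,
)
from rnai_nto.synthetic_data import longest_common_substring_dp

from conftest import random_seq


def de_table_from(genes, log2fc, fdr):
    df = pd.DataFrame(
        {
            "base_mean": 10.0,
            "log2fc": log2fc,
            "pvalue": fdr,
            "fdr": fdr,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DiffExprTable(df).classify()


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("ANT", "ANT")]
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_involution_and_length(self, seq):
        rc = reverse_complement(seq)
        assert len(rc) == len(seq)
        assert reverse_complement(rc) == seq

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")


class TestLongestContiguousMatch:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGTACGT", "ACGTACGT", 8),
            ("AAAA", "CCCC", 0),
            ("ACGTN" + "ACGT", "NACGT", 4),  # windows containing N excluded
        ],
    )
    def test_examples(self, a, b, expected):
        length, _ = longest_contiguous_match(a, b)
        assert length == expected

    def test_positions_reverify_as_exact_matches(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = random_seq(rng, int(rng.integers(1, 51)))
            b = random_seq(rng, int(rng.integers(1, 51)))
            length, positions = longest_contiguous_match(a, b)
            assert length == longest_common_substring_dp(a, b)
            assert positions  # a maximal match always has >= 1 occurrence
            for i, j in positions:
                assert a[i : i + length] == b[j : j + length]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            longest_contiguous_match("", "ACGT")


class TestScanTranscriptome:
    def test_identical_transcript_is_full_length_sense(self):
        rng = np.random.default_rng(1)
        ds = SequenceRecord("dsRNA", random_seq(rng, 60))
        (res,) = scan_transcriptome(ds, [SequenceRecord("t1", ds.sequence)])
        assert res.max_match == 60
        assert res.max_match_sense == 60
        assert all(strand == "sense" for _, _, strand in res.positions)

    def test_reverse_complement_transcript_is_antisense(self):
        rng = np.random.default_rng(2)
        ds = SequenceRecord("dsRNA", random_seq(rng, 60))
        rc = reverse_complement(ds.sequence)
        (res,) = scan_transcriptome(ds, [SequenceRecord("t1", rc)])
        assert res.max_match == 60
        assert res.max_match_antisense == 60

    def test_planted_lengths_recovered(self, small_dataset):
        ds = small_dataset
        results = {
            r.gene_id: r for r in scan_transcriptome(ds.dsrna, ds.transcripts)
        }
        planted = ds.truth.planted_match_genes()
        assert {g: results[g].max_match for g in planted.index} == dict(
            planted["true_max_match"]
        )

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        ds = SequenceRecord("dsRNA", random_seq(rng, 100))
        transcripts = [
            SequenceRecord(f"t{i}", random_seq(rng, 150)) for i in range(20)
        ]
        fwd = scan_transcriptome(ds, transcripts, min_report_len=1)
        flipped = [
            SequenceRecord(t.id, reverse_complement(t.sequence)) for t in transcripts
        ]
        rev = scan_transcriptome(ds, flipped, min_report_len=1)
        for a, b in zip(fwd, rev):
            assert a.max_match == b.max_match
            assert a.max_match_sense == b.max_match_antisense
            assert a.max_match_antisense == b.max_match_sense

    def test_below_threshold_retained(self):
        ds = SequenceRecord("dsRNA", "ACGTACGTACGT")
        (res,) = scan_transcriptome(ds, [SequenceRecord("t1", "AAAAAAAACG")])
        assert res.below_threshold
        assert res.max_match == 3

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            scan_transcriptome(SequenceRecord("d", "ACGTACGT"), [])


class TestBinByMatchLength:
    def _results(self, lengths):
        rng = np.random.default_rng(4)
        ds = SequenceRecord("dsRNA", random_seq(rng, 403))
        out = []
        from rnai_nto.offtarget_scan import MatchResult

        for i, L in enumerate(lengths):
            out.append(MatchResult(f"g{i}", L, 0))
        return out

    def test_partition_and_direction_counts(self):
        lengths = [6, 7, 7, 9, 15, 18]
        results = self._results(lengths)
        de = de_table_from(
            [f"g{i}" for i in range(6)],
            log2fc=[3.0, 2.0, -2.0, 0.0, 0.0, 2.0],
            fdr=[0.01, 0.01, 0.01, 0.9, 0.9, 0.01],
        )
        table = bin_by_match_length(results, de)
        # g0 (match 6) excluded; bins partition the rest
        assert int(table["total_genes"].sum()) == 5
        assert table.loc[7, "n_up"] == 1 and table.loc[7, "n_down"] == 1
        assert table.loc[9, "n_unchanged"] == 1
        # 15 bin collects >= 15
        assert table.loc[15, "total_genes"] == 2
        assert (
            table["n_up"] + table["n_down"] + table["n_unchanged"]
        ).equals(table["total_genes"])

    def test_gene_missing_from_de_counts_unchanged(self):
        results = self._results([8])
        de = de_table_from(["other"], [2.0], [0.01])
        table = bin_by_match_length(results, de)
        assert table.loc[8, "n_unchanged"] == 1
        assert table.attrs["n_missing_from_de"] == 1

    def test_empty_bin_renders_dashes(self):
        table = summary_from_counts({7: (0, 0, 0, 0)})
        assert table.loc[7, "up_cell"] == "–"
        assert np.isnan(table.loc[7, "pct_up"])

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="bin 7"):
            summary_from_counts({7: (10, 1, 1, 1)})


class TestMatchFoldChangeCorrelation:
    def _results(self, lengths):
        from rnai_nto.offtarget_scan import MatchResult

        return [MatchResult(f"g{i}", L, 0) for i, L in enumerate(lengths)]

    def test_monotone_gives_rho_one(self):
        lengths = list(range(7, 17))
        de = de_table_from(
            [f"g{i}" for i in range(10)],
            log2fc=[0.1 * (i + 1) for i in range(10)],
            fdr=[0.5] * 10,
        )
        _, rho, _ = match_fold_change_correlation(self._results(lengths), de)
        assert rho == pytest.approx(1.0)

    def test_constant_fold_change_flagged(self):
        de = de_table_from(["g0", "g1", "g2"], [1.0, 1.0, 1.0], [0.5] * 3)
        frame, rho, p = match_fold_change_correlation(self._results([7, 9, 11]), de)
        assert rho == 0.0 and p == 1.0
        assert frame.attrs["constant_input"]

    def test_too_few_genes_rejected(self):
        de = de_table_from(["g0", "g1"], [1.0, 2.0], [0.5, 0.5])
        with pytest.raises(ValueError, match=">=3"):
            match_fold_change_correlation(self._results([7, 9]), de)

    def test_color_classes_use_inclusive_boundaries(self):
        de = de_table_from(
            ["g0", "g1", "g2"], [1.0, 1.5, 0.5], [0.05, 0.5, 0.01]
        )
        frame, _, _ = match_fold_change_correlation(self._results([7, 8, 9]), de)
        assert frame.loc["g0", "color_class"] == "red"  # |lfc|>=1, fdr<=0.05
        assert frame.loc["g1", "color_class"] == "blue"
        assert frame.loc["g2", "color_class"] == "gray"
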