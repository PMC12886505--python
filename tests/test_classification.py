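import math

import numpy as np
import pandas as pd
import pytest
from Bio import Align

from rnai_nto.classification import (
    assign_pathway_levels,
    classify_degs,
    evalue_from_score,
    find_homologs,
    level_summary_from_counts,
    smith_waterman,
    summarize_levels,
)
from rnai_nto.io_formats import DiffExprTable, GeneSetCollection, SequenceRecord
from rnai_nto.offtarget_scan import MatchResult
from rnai_nto.synthetic_data import SimulationConfig, generate_transcriptome

from conftest import random_seq


def biopython_aligner():
    """Independent affine-gap local-alignment oracle (gap of k costs 5 + 2k)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def de_table_from(genes, log2fc, fdr):
    df = pd.DataFrame(
        {"base_mean": 10.0, "log2fc": log2fc, "pvalue": fdr, "fdr": fdr},
        index=pd.Index(genes, name="gene"),
    )
    return DiffExprTable(df).classify()


class TestSmithWaterman:
    def test_identical_sequences_score_full_span(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 30)
        aln = smith_waterman(seq, seq)
        assert aln.score == 60
        assert aln.query_span == (0, 30)
        assert aln.subject_span == (0, 30)

    def test_disjoint_sequences_empty_alignment(self):
        aln = smith_waterman("AAAA", "TTTT")
        assert aln.score == 0
        assert aln.query_span == (0, 0)

    def test_n_scores_as_mismatch_even_against_n(self):
        assert smith_waterman("NNNN", "NNNN").score == 0

    def test_matches_independent_oracle_on_random_pairs(self):
        aligner = biopython_aligner()
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = random_seq(rng, int(rng.integers(5, 41)))
            b = random_seq(rng, int(rng.integers(5, 41)))
            assert smith_waterman(a, b).score == aligner.score(a, b)

    def test_score_symmetric_in_query_subject(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(5, 40)))
            b = random_seq(rng, int(rng.integers(5, 40)))
            assert smith_waterman(a, b).score == smith_waterman(b, a).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")


class TestEvalue:
    def test_fixed_point_gives_e_of_one(self):
        m, n = 400, 10_000
        K, lam = 0.41, 0.625
        s = math.log(K * m * n) / lam
        assert evalue_from_score(s, m, n) == pytest.approx(1.0)

    def test_linear_in_database_length(self):
        e1 = evalue_from_score(100, 400, 10**7)
        e2 = evalue_from_score(100, 400, 2 * 10**7)
        assert e2 == pytest.approx(2 * e1)

    def test_direct_formula_value(self):
        expected = 0.41 * 400 * 1e7 * math.exp(-62.5)
        assert evalue_from_score(100, 400, 10**7) == pytest.approx(expected)

    def test_monotone_decreasing_in_score(self):
        scores = [10, 50, 100, 200]
        evals = [evalue_from_score(s, 400, 10**6) for s in scores]
        assert all(a > b for a, b in zip(evals, evals[1:]))

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            evalue_from_score(10, 0, 100)


class TestFindHomologs:
    def test_exact_copy_is_top_hit(self):
        rng = np.random.default_rng(3)
        target = SequenceRecord("target", random_seq(rng, 200))
        transcriptome = [
            SequenceRecord("copy", target.sequence),
            SequenceRecord("noise", random_seq(rng, 200)),
        ]
        hits = find_homologs(target, transcriptome)
        assert hits and hits[0].gene_id == "copy"
        assert hits[0].strand == "sense"

    def test_reverse_complement_copy_found_antisense(self):
        from rnai_nto.offtarget_scan import reverse_complement

        rng = np.random.default_rng(4)
        target = SequenceRecord("target", random_seq(rng, 200))
        transcriptome = [
            SequenceRecord("rc", reverse_complement(target.sequence)),
        ]
        hits = find_homologs(target, transcriptome)
        assert hits and hits[0].strand == "antisense"

    def test_random_transcriptome_yields_no_hits(self):
        rng = np.random.default_rng(5)
        target = SequenceRecord("target", random_seq(rng, 403))
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            transcriptome = [
                SequenceRecord(f"g{i}", random_seq(r, 1000)) for i in range(10)
            ]
            assert find_homologs(target, transcriptome) == []

    def test_planted_homologs_recovered(self, small_dataset):
        ds = small_dataset
        hits = find_homologs(ds.dsrna, ds.transcripts)
        assert {h.gene_id for h in hits} >= set(ds.truth.homolog_genes())
        for h in hits:
            assert h.evalue < 1e-10


class TestPathwayLevels:
    def chain_sets(self):
        return GeneSetCollection(
            {"P1": {"a", "b"}, "P2": {"b", "c"}, "P3": {"c", "d"}}
        )

    def test_chain_levels_and_gene_minimum(self):
        assignment = assign_pathway_levels(self.chain_sets(), {"a"})
        assert assignment.pathway_levels == {"P1": 1, "P2": 2, "P3": 3}
        assert assignment.gene_levels == {"b": 1, "c": 2, "d": 3}

    def test_disconnected_pathway_unassigned(self):
        sets = GeneSetCollection({"P1": {"a", "b"}, "Px": {"y", "z"}})
        assignment = assign_pathway_levels(sets, {"a"})
        assert "Px" not in assignment.pathway_levels

    def test_seed_in_every_pathway_all_level_one(self):
        sets = GeneSetCollection({"P1": {"a", "b"}, "P2": {"a", "c"}})
        assignment = assign_pathway_levels(sets, {"a"})
        assert set(assignment.pathway_levels.values()) == {1}

    def test_order_invariance(self):
        sets = self.chain_sets().sets
        fwd = assign_pathway_levels(GeneSetCollection(dict(sets)), {"a"})
        rev = assign_pathway_levels(
            GeneSetCollection(dict(reversed(list(sets.items())))), {"a"}
        )
        assert fwd.pathway_levels == rev.pathway_levels
        assert fwd.gene_levels == rev.gene_levels

    def test_max_level_truncates_bfs(self):
        assignment = assign_pathway_levels(self.chain_sets(), {"a"}, max_level=2)
        assert assignment.pathway_levels == {"P1": 1, "P2": 2}

    def test_min_overlap_parameter(self):
        sets = GeneSetCollection({"P1": {"a", "b"}, "P2": {"b", "c", "d"}})
        strict = assign_pathway_levels(sets, {"a"}, min_overlap=2)
        assert "P2" not in strict.pathway_levels

    def test_no_seed_pathway_warns_and_empties(self):
        with pytest.warns(UserWarning):
            assignment = assign_pathway_levels(self.chain_sets(), {"zzz"})
        assert assignment.pathway_levels == {}

    def test_empty_seeds_rejected(self):
        with pytest.raises(ValueError):
            assign_pathway_levels(self.chain_sets(), set())


class TestSummarizeLevels:
    def test_counts_directions_and_total(self):
        assignment = assign_pathway_levels(
            GeneSetCollection({"P1": {"s", "up1", "down1"}, "P2": {"down1", "flat1"}}),
            {"s"},
        )
        de = de_table_from(
            ["up1", "down1", "flat1"], [2.0, -2.0, 0.1], [0.01, 0.01, 0.9]
        )
        table = summarize_levels(assignment, de)
        assert table.loc["Level 1", "n_up"] == 1
        assert table.loc["Level 1", "n_down"] == 1
        # flat1 is level 2 (down1 counted once, at level 1)
        assert table.loc["Level 2", "total_genes"] == 1
        assert table.loc["Total", "total_genes"] == 3

    def test_from_counts_requires_consistency(self):
        with pytest.raises(ValueError):
            level_summary_from_counts({1: (10, 3, 3, 3)})


class TestClassifyDegs:
    def test_labels_and_unattributed_bucket(self):
        hits = []
        rng = np.random.default_rng(6)
        target = SequenceRecord("t", random_seq(rng, 120))
        hits = find_homologs(target, [SequenceRecord("hom", target.sequence)])
        assignment = assign_pathway_levels(
            GeneSetCollection({"P1": {"s", "pg"}}), {"s"}
        )
        matches = [MatchResult("hom", 9, 0), MatchResult("pg", 3, 0)]
        frame, summary = classify_degs(
            ["hom", "pg", "orphan"], hits, assignment, matches
        )
        assert frame.loc["hom", "labels"] == "homolog_of_target;continuous_match_9"
        assert frame.loc["pg", "labels"] == "pathway_level_1"
        assert frame.loc["orphan", "labels"] == "unattributed"
        assert summary["classes"]["unattributed"] == 1

    def test_planted_homolog_degs_all_labelled(self, small_dataset):
        ds = small_dataset
        hits = find_homologs(ds.dsrna, ds.transcripts)
        homologs = set(ds.truth.homolog_genes())
        frame, summary = classify_degs(sorted(homologs), hits, None, [])
        assert summary["classes"]["homolog_of_target"] == len(homologs)
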