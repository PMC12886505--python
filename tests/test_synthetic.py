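import numpy as np
import pytest

from rnai_nto.offtarget_scan import scan_transcriptome
from rnai_nto.synthetic_data import (
    PathwaySpec,
    SimulationConfig,
    blank_truth,
    generate_counts,
    generate_dsrna,
    generate_homologs,
    generate_pathways,
    generate_transcriptome,
    longest_common_substring_dp,
    oracle_max_match,
)


def small_config(**kw):
    defaults = dict(
        seed=11,
        n_genes=40,
        transcript_length_range=(250, 400),
        planted_matches=((2, 7, "sense"), (4, 9, "antisense"), (6, 12, "sense")),
        planted_homologs=((8, 0.9),),
        de_fraction=0.1,
        mean_depth=1e5,
        pathway_spec=PathwaySpec(n_pathways=4, size_range=(3, 6)),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_artifacts(self):
        cfg = small_config()
        ds1, tr1, truth1 = generate_transcriptome(cfg)
        ds2, tr2, truth2 = generate_transcriptome(cfg)
        assert ds1 == ds2
        assert tr1 == tr2
        c1 = generate_counts(truth1, cfg)
        c2 = generate_counts(truth2, cfg)
        assert c1.counts.equals(c2.counts)
        p1 = generate_pathways(truth1, cfg)
        p2 = generate_pathways(truth2, cfg)
        assert p1.sets == p2.sets

    def test_different_seed_differs(self):
        a = generate_dsrna(small_config(seed=1))
        b = generate_dsrna(small_config(seed=2))
        assert a.sequence != b.sequence


class TestTranscriptome:
    def test_planted_matches_exact_and_others_below_threshold(self):
        cfg = small_config()
        dsrna, transcripts, truth = generate_transcriptome(cfg)
        planted = {idx for idx, _, _ in cfg.planted_matches}
        homologs = {idx for idx, _ in cfg.planted_homologs}
        for g, rec in enumerate(transcripts):
            verified = oracle_max_match(rec.sequence, dsrna.sequence)
            row = truth.genes.loc[rec.id]
            assert verified == row["true_max_match"]
            if g in planted:
                assert row["planted_match"]
            elif g not in homologs:
                assert verified < cfg.min_match_len

    def test_scan_recovers_planted_truth_end_to_end(self):
        cfg = small_config(seed=13)
        dsrna, transcripts, truth = generate_transcriptome(cfg)
        results = {r.gene_id: r for r in scan_transcriptome(dsrna, transcripts)}
        planted = truth.planted_match_genes()
        for g, row in planted.iterrows():
            assert results[g].max_match == row["true_max_match"]
            strands = {s for _, _, s in results[g].positions}
            assert row["match_strand"] in strands

    def test_planted_length_longer_than_dsrna_rejected(self):
        with pytest.raises(ValueError, match="planted match length"):
            small_config(planted_matches=((2, 500, "sense"),))

    def test_no_planted_matches_all_below_threshold(self):
        cfg = small_config(planted_matches=(), planted_homologs=(), seed=17)
        dsrna, transcripts, truth = generate_transcriptome(cfg)
        assert (truth.genes["true_max_match"] < cfg.min_match_len).all()


class TestHomologs:
    def test_identity_one_is_exact_copy(self):
        cfg = small_config()
        target = generate_dsrna(cfg)
        rng = np.random.default_rng(0)
        (seq, realized), = generate_homologs(target, [1.0], rng)
        assert seq == target.sequence and realized == 1.0

    def test_substitution_count_matches_identity(self):
        cfg = small_config()
        target = generate_dsrna(cfg)  # 403 bp
        rng = np.random.default_rng(1)
        (seq, realized), = generate_homologs(target, [0.9], rng)
        diffs = sum(a != b for a, b in zip(seq, target.sequence))
        assert diffs == round(0.1 * len(target.sequence))
        assert realized == pytest.approx(1 - diffs / len(target.sequence))

    def test_out_of_range_identity_rejected(self):
        target = generate_dsrna(small_config())
        with pytest.raises(ValueError):
            generate_homologs(target, [0.4], np.random.default_rng(0))


class TestCounts:
    def test_zero_de_fraction_plants_nothing(self):
        cfg = SimulationConfig(seed=5, n_genes=200, de_fraction=0.0, mean_depth=1e5)
        truth = blank_truth(cfg)
        generate_counts(truth, cfg)
        assert not truth.genes["is_de"].any()

    def test_poisson_limit_variance_to_mean(self):
        """At vanishing dispersion the NB collapses to Poisson (var ~ mean)."""
        cfg = SimulationConfig(
            seed=6, n_genes=2000, de_fraction=0.0, nb_dispersion=1e-6,
            mean_depth=2e6, n_replicates_per_group=10,
        )
        cm = generate_counts(blank_truth(cfg), cfg)
        arr = cm.counts.to_numpy(dtype=float)
        means = arr.mean(axis=1)
        keep = means > 100  # enough signal to estimate the ratio
        ratio = arr.var(axis=1, ddof=1)[keep] / means[keep]
        assert abs(ratio.mean() - 1.0) < 0.1

    def test_planted_fold_change_visible_in_group_means(self):
        cfg = SimulationConfig(
            seed=7, n_genes=500, de_fraction=0.2, de_log2fc_magnitude=2.0,
            nb_dispersion=0.01, mean_depth=1e6,
        )
        truth = blank_truth(cfg)
        cm = generate_counts(truth, cfg)
        t_cols = [s for s in cm.sample_ids if s.startswith("treatment")]
        c_cols = [s for s in cm.sample_ids if s.startswith("control")]
        de = truth.genes["is_de"]
        mt = cm.counts.loc[de, t_cols].mean(axis=1) + 0.5
        mc = cm.counts.loc[de, c_cols].mean(axis=1) + 0.5
        observed = np.log2(mt / mc)
        assert np.median(np.abs(observed)) == pytest.approx(2.0, abs=0.3)

    def test_wrong_depth_factor_length_rejected(self):
        cfg = small_config(depth_factors=(1.0, 2.0))
        truth = blank_truth(cfg)
        with pytest.raises(ValueError, match="depth_factors"):
            generate_counts(truth, cfg)


class TestPathways:
    def test_chain_realizes_levels(self):
        cfg = small_config()
        _, _, truth = generate_transcriptome(cfg)
        generate_pathways(truth, cfg)
        assert truth.pathway_levels == {"P00": 1, "P01": 2, "P02": 3, "P03": None}

    def test_no_seed_pathways_all_none(self):
        cfg = small_config(
            pathway_spec=PathwaySpec(n_pathways=3, size_range=(3, 5),
                                     seed_pathways=())
        )
        _, _, truth = generate_transcriptome(cfg)
        generate_pathways(truth, cfg)
        assert set(truth.pathway_levels.values()) == {None}

    def test_bad_edge_rejected(self):
        cfg = small_config(
            pathway_spec=PathwaySpec(n_pathways=3, size_range=(3, 5),
                                     edges=((0, 9),))
        )
        _, _, truth = generate_transcriptome(cfg)
        with pytest.raises(ValueError, match="edge"):
            generate_pathways(truth, cfg)

    def test_pool_exhaustion_rejected(self):
        cfg = small_config(
            pathway_spec=PathwaySpec(n_pathways=10, size_range=(20, 30))
        )
        _, _, truth = generate_transcriptome(cfg)
        with pytest.raises(ValueError, match="distinct genes"):
            generate_pathways(truth, cfg)


class TestDpOracle:
    def test_known_values(self):
        assert longest_common_substring_dp("ACGTACGT", "ACGTACGT") == 8
        assert longest_common_substring_dp("AAAA", "CCCC") == 0
        assert longest_common_substring_dp("ACGNT", "ACGNT") == 3  # N matches nothing
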