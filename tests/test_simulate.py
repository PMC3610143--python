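"""The synthetic-data generator: planted structure must be recoverable."""

import math

import numpy as np
import pytest

from tagdge import (CleanTagLibrary, LibraryCounts, build_reference_library,
                    call_de, digest_transcript, filter_raw_tags,
                    generate_annotations, generate_transcriptome, make_truth,
                    map_library, simulate_libraries)
from tagdge.simulate import DEFAULT_ADAPTOR, SyntheticTruth


class TestGenerateTranscriptome:
    def test_site_layout_matches_digestion(self):
        records, meta = generate_transcriptome(40, seed=5)
        for rec, (_, row) in zip(records, meta.iterrows()):
            sense = [t for t in digest_transcript(rec) if t.strand == "sense"]
            planted = row["tags"].split(",")
            assert len(sense) == row["n_sites"] == len(planted)
            # 3'-most planted tag carries rank 1
            by_rank = {t.position_rank: t.tag_seq for t in sense}
            assert by_rank[1] == row["rank1_tag"]
            assert sorted(t.tag_seq for t in sense) == sorted(planted)

    def test_same_seed_reproduces_sequences(self):
        r1, m1 = generate_transcriptome(10, seed=3)
        r2, m2 = generate_transcriptome(10, seed=3)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert m1.equals(m2)

    def test_no_shared_tags_means_fully_unambiguous_senses(self):
        records, meta = generate_transcriptome(60, seed=1,
                                               shared_tag_fraction=0.0)
        lib = build_reference_library(records)
        for tag in meta["rank1_tag"]:
            assert lib.is_unambiguous(tag)

    def test_shared_fraction_plants_ambiguity(self):
        records, meta = generate_transcriptome(50, seed=2,
                                               shared_tag_fraction=0.3)
        lib = build_reference_library(records)
        shared = [t for t in meta["rank1_tag"] if not lib.is_unambiguous(t)]
        assert len(shared) > 0

    def test_infeasible_length_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_transcriptome(5, length_range=(30, 40),
                                   catg_sites_per_gene_range=(3, 3))


class TestSimulateLibraries:
    def test_single_gene_no_noise_gives_single_tag(self):
        records, meta = generate_transcriptome(3, seed=0)
        genes = list(meta["gene_id"])
        truth = SyntheticTruth(
            abundance={genes[0]: 1.0, genes[1]: 0.0, genes[2]: 0.0},
            log2_effects={}, n_a=500, n_b=800, error_rate=0.0,
            adaptor_fraction=0.0, lowq_fraction=0.0, seed=4)
        raw_a, raw_b, _ = simulate_libraries(truth, meta)
        clean_a, _ = filter_raw_tags(raw_a, [DEFAULT_ADAPTOR])
        assert clean_a.counts == {meta.loc[0, "rank1_tag"]: 500}

    def test_contamination_fractions_recovered_in_ledger(self):
        records, meta = generate_transcriptome(50, seed=6)
        truth = make_truth(list(meta["gene_id"]), seed=6, n_a=30_000,
                           n_b=40_000, n_planted=0, error_rate=0.0,
                           adaptor_fraction=0.03, lowq_fraction=0.02)
        raw_a, _, _ = simulate_libraries(truth, meta)
        _, ledger = filter_raw_tags(raw_a, [DEFAULT_ADAPTOR])
        n = ledger.n_raw
        for observed, frac in ((ledger.n_adaptor, 0.03),
                               (ledger.n_low_quality, 0.02)):
            se = math.sqrt(n * frac * (1 - frac))
            assert abs(observed - n * frac) <= 3 * se

    def test_error_free_run_maps_every_clean_tag_to_a_gene(self):
        records, meta = generate_transcriptome(80, seed=7)
        truth = make_truth(list(meta["gene_id"]), seed=7, n_a=20_000,
                           n_b=25_000, n_planted=0, error_rate=0.0,
                           adaptor_fraction=0.0, lowq_fraction=0.0)
        raw_a, _, _ = simulate_libraries(truth, meta)
        clean_a, _ = filter_raw_tags(raw_a, [DEFAULT_ADAPTOR])
        library = build_reference_library(records)
        _, summary, _ = map_library(clean_a, library)
        assert summary.tags_mapped_to_gene == summary.total_clean
        assert summary.unknown_tags == 0

    def test_ledger_expected_counts_match_observations(self):
        records, meta = generate_transcriptome(60, seed=8)
        truth = make_truth(list(meta["gene_id"]), seed=8, n_a=40_000,
                           n_b=50_000, n_planted=4, planted_log2fc=2.0,
                           min_expected_count=10.0, error_rate=0.0,
                           adaptor_fraction=0.0, lowq_fraction=0.0)
        raw_a, raw_b, ledger = simulate_libraries(truth, meta)
        clean_a, _ = filter_raw_tags(raw_a, [DEFAULT_ADAPTOR])
        tag_of = dict(zip(meta["gene_id"], meta["rank1_tag"]))
        for _, row in ledger.iterrows():
            exp = row["expected_count_a"]
            if exp < 50:
                continue
            obs = clean_a.counts.get(tag_of[row["gene_id"]], 0)
            assert abs(obs - exp) <= 5 * math.sqrt(exp)

    def test_planted_four_fold_gene_recovered_across_seeds(self):
        # count-level check of the planted-effect machinery: a 4-fold gene
        # with comfortable depth must be called in >= 9 of 10 seeds
        hits = 0
        for seed in range(10):
            records, meta = generate_transcriptome(100, seed=seed)
            genes = list(meta["gene_id"])
            truth = make_truth(genes, seed=seed, n_a=30_000, n_b=40_000,
                               n_planted=2, planted_log2fc=2.0,
                               min_expected_count=25.0, error_rate=0.0,
                               adaptor_fraction=0.0, lowq_fraction=0.0)
            planted = set(truth.log2_effects)
            ab_a, ab_b = truth.library_abundances()
            rng = np.random.default_rng(seed + 1000)
            xs = rng.multinomial(truth.n_a, [ab_a[g] for g in genes])
            ys = rng.multinomial(truth.n_b, [ab_b[g] for g in genes])
            a = LibraryCounts("a", dict(zip(genes, map(int, xs))), truth.n_a)
            b = LibraryCounts("b", dict(zip(genes, map(int, ys))), truth.n_b)
            called = {r.gene_id for r in call_de(a, b, lfc_min=1.0)
                      if r.significant}
            hits += planted <= called
        assert hits >= 9


class TestGenerateAnnotations:
    def test_deterministic_per_seed(self):
        genes = [f"G{i:05d}" for i in range(50)]
        t1 = generate_annotations(genes, term_size_range=(5, 25), seed=9)
        t2 = generate_annotations(genes, term_size_range=(5, 25), seed=9)
        assert t1.equals(t2)

    def test_term_sizes_within_range(self):
        genes = [f"G{i:05d}" for i in range(200)]
        memb = generate_annotations(genes, n_terms=20,
                                    term_size_range=(5, 15), seed=0)
        sizes = memb.groupby("term_id").size()
        assert sizes.between(5, 15).all()

    def test_odds_ratio_one_is_not_systematically_enriched(self):
        from tagdge import TermAnnotation, hypergeom_enrich
        from tagdge.enrichment import PATHWAY
        genes = [f"G{i:05d}" for i in range(300)]
        de = set(genes[:60])
        small_p = 0
        for seed in range(10):
            memb = generate_annotations(
                genes, n_terms=0, seed=seed,
                enriched_term={"term_id": "T", "de_genes": de,
                               "odds_ratio": 1.0, "baseline": 0.2})
            members = set(memb["gene_id"])
            res = hypergeom_enrich(de, set(genes),
                                   [TermAnnotation("T", "T", PATHWAY,
                                                   members)])
            small_p += res[0].p_value < 0.05 if res else 0
        assert small_p <= 3

    def test_infeasible_term_size_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_annotations(["g1", "g2"], term_size_range=(1, 5))
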