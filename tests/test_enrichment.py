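import math

import numpy as np
import pytest

from _oracles import bh_stepup_reference, hypergeom_tail_enumerated, hypergeom_tail_exact
from conftest import single_gene_genome

from peakminer.enrichment import (
    DynamicRange,
    IDMapping,
    PromoterSpec,
    TFDataset,
    bh_adjust,
    build_target_set,
    combined_score,
    compute_dynamic_range,
    convert_ids,
    enrich_gene_list,
    enrichment_score,
    hypergeom_p,
    load_store,
)
from peakminer.genome_model import AttributeParams
from peakminer.intervals import OverlapCriterion, Peak, PeakSet
from peakminer.simulate import (
    FixtureSpec,
    synth_boundary_dataset,
    synth_genome,
    synth_tf_store,
)

CRIT = OverlapCriterion("bp", 20)
PARAMS = AttributeParams()


class TestHypergeometric:
    def test_known_exact_value(self):
        assert hypergeom_p(3, 4, 5, 10) == pytest.approx(55 / 210, rel=1e-14)

    def test_zero_hits_is_certain(self):
        assert hypergeom_p(0, 10, 50, 100) == pytest.approx(1.0)

    def test_all_draws_hit(self):
        # listHits = listSize = genomeHits: only one way to draw all successes
        assert hypergeom_p(4, 4, 4, 10) == pytest.approx(
            hypergeom_tail_enumerated(4, 4, 4, 10), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_full_enumeration_tiny(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(n, K) + 1))
        assert hypergeom_p(k, n, K, N) == pytest.approx(
            hypergeom_tail_enumerated(k, n, K, N), rel=1e-12
        )

    def test_matches_exact_combinatorics(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_p(k, n, K, N) == pytest.approx(
                hypergeom_tail_exact(k, n, K, N), rel=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_p(5, 4, 10, 100)
        with pytest.raises(ValueError):
            hypergeom_p(1, 4, 101, 100)


class TestScores:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 100, 500, 10_000), 2.0), ((5, 100, 500, 10_000), 1.0), ((0, 100, 500, 10_000), 0.0)],
    )
    def test_enrichment_score(self, counts, expected):
        assert enrichment_score(*counts) == pytest.approx(expected)

    def test_zero_denominator_is_undefined(self):
        assert enrichment_score(0, 0, 5, 10) is None
        assert enrichment_score(0, 5, 0, 10) is None

    @pytest.mark.parametrize(
        "score,p,expected", [(2.0, 0.01, 4.0), (3.0, 1.0, 0.0), (0.0, 0.5, 0.0)]
    )
    def test_combined_score(self, score, p, expected):
        assert combined_score(score, p) == pytest.approx(expected)

    def test_zero_p_floored_finite(self):
        value = combined_score(1.0, 0.0)
        assert value is not None and math.isfinite(value) and value > 300


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_evenly_spaced_all_collapse(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_sorted_input_gives_nondecreasing_output(self):
        out = bh_adjust(sorted([0.001, 0.2, 0.04, 0.9, 0.5]))
        assert all(a <= b for a, b in zip(out, out[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40))).tolist()
        assert bh_adjust(p) == pytest.approx(bh_stepup_reference(p), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBuildTargetSet:
    def dataset(self, peaks):
        return TFDataset("d1", "TF1", PeakSet("d1", peaks))

    def test_peak_on_tss_is_target(self):
        ga = single_gene_genome()  # '+' gene, TSS at 10000
        d = self.dataset([Peak("chr1", 9_900, 10_100)])
        assert build_target_set(d, ga, PromoterSpec(), CRIT, PARAMS) == {"g1"}

    def test_peak_outside_fixed_window_is_not(self):
        ga = single_gene_genome()
        d = self.dataset([Peak("chr1", 7_000, 7_500)])  # TSS-3000..TSS-2500
        assert build_target_set(d, ga, PromoterSpec("fixed", 2_000, 500), CRIT, PARAMS) == set()

    def test_dynamic_window_membership(self):
        ga = single_gene_genome()
        d = self.dataset([Peak("chr1", 7_000, 7_500)])
        spec = PromoterSpec.dynamic()
        def dr(upstream):
            return DynamicRange("d1", (0,) * 400, 0.0, (0.0,) * 400, upstream)
        assert build_target_set(d, ga, spec, CRIT, PARAMS, dynamic=dr(500)) == set()
        assert build_target_set(d, ga, spec, CRIT, PARAMS, dynamic=dr(5_000)) == {"g1"}

    def test_minus_strand_window_is_mirrored(self):
        ga = single_gene_genome(strand="-")  # TSS at 20000, upstream to the right
        d = self.dataset([Peak("chr1", 21_000, 21_400)])
        assert build_target_set(d, ga, PromoterSpec(), CRIT, PARAMS) == {"g1"}
        assert build_target_set(
            d, ga, PromoterSpec(), CRIT, AttributeParams(respect_strand=False)
        ) == set()

    def test_dynamic_mode_requires_range(self):
        ga = single_gene_genome()
        d = self.dataset([Peak("chr1", 9_900, 10_100)])
        with pytest.raises(ValueError, match="DynamicRange"):
            build_target_set(d, ga, PromoterSpec.dynamic(), CRIT, PARAMS)


class TestConvertIds:
    def test_identity_mapping_preserves_input(self):
        ids = ["a", "b", "c"]
        out, dropped = convert_ids(ids, IDMapping.identity(ids))
        assert out == ids and dropped == []

    def test_unmapped_dropped_and_reported(self):
        mapping = IDMapping({"a": "A", "b": "B", "c": "C"})
        out, dropped = convert_ids(["a", "x", "b", "y", "c"], mapping)
        assert out == ["A", "B", "C"] and dropped == ["x", "y"]

    def test_many_to_one_deduplicates_with_warning(self, caplog):
        mapping = IDMapping({"a": "Z", "b": "Z"})
        with caplog.at_level("WARNING"):
            out, _ = convert_ids(["a", "b"], mapping)
        assert out == ["Z"]
        assert any("duplicate" in r.message for r in caplog.records)


class TestEnrichGeneList:
    @pytest.fixture
    def fixture(self, small_spec, small_genome):
        store, truth = synth_tf_store(small_spec, small_genome)
        return small_genome, store, truth

    def test_store_superset_means_full_hits(self, fixture):
        ga, store, truth = fixture
        targets = truth["ds_planted"]
        recs = enrich_gene_list(targets[:5], store, ga, PromoterSpec(), CRIT)
        planted = next(r for r in recs if r.dataset_id == "ds_planted")
        assert planted.list_hits == planted.list_size == 5

    def test_planted_tf_ranks_first(self, fixture):
        ga, store, truth = fixture
        recs = enrich_gene_list(truth["ds_planted"], store, ga, PromoterSpec(), CRIT)
        assert recs[0].factor_name == "TF_PLANTED"
        assert recs[0].fdr < 0.05

    def test_whole_background_gives_unit_scores(self, fixture):
        ga, store, _ = fixture
        recs = enrich_gene_list(ga.gene_ids(), store, ga, PromoterSpec(), CRIT)
        for r in recs:
            if r.genome_hits:
                assert r.score == pytest.approx(1.0)

    def test_invariant_to_gene_and_store_order(self, fixture):
        ga, store, truth = fixture
        genes = truth["ds_planted"]
        a = enrich_gene_list(genes, store, ga, PromoterSpec(), CRIT)
        b = enrich_gene_list(genes[::-1], store[::-1], ga, PromoterSpec(), CRIT)
        assert [(r.dataset_id, r.p_value, r.fdr) for r in a] == [
            (r.dataset_id, r.p_value, r.fdr) for r in b
        ]

    def test_empty_store_and_unmappable_ids_error(self, fixture):
        ga, store, truth = fixture
        with pytest.raises(ValueError):
            enrich_gene_list(truth["ds_planted"], [], ga, PromoterSpec(), CRIT)
        with pytest.raises(ValueError, match="dropped"):
            enrich_gene_list(
                ["zzz"], store, ga, PromoterSpec(), CRIT, mapping=IDMapping({"a": "b"})
            )

    def test_record_count_invariants_hold(self, fixture):
        ga, store, truth = fixture
        recs = enrich_gene_list(truth["ds_planted"], store, ga, PromoterSpec(), CRIT)
        for r in recs:
            assert r.list_hits <= min(r.list_size, r.genome_hits)
            assert r.genome_hits <= r.genome_size
            assert 0 <= r.fdr <= 1


class TestDynamicRange:
    def test_far_peaks_fall_back_to_default(self):
        ga = single_gene_genome(tx=(500_000, 510_000), cds=None)
        d = TFDataset("d", "TF", PeakSet("d", [Peak("chr1", 0, 200), Peak("chr1", 1_000, 1_200)]))
        dr = compute_dynamic_range(d, ga)
        assert sum(dr.histogram) == 0
        assert dr.upstream_tss == 2_000

    def test_uniform_background_only_falls_back(self):
        spec = FixtureSpec(seed=21, n_genes=50, chrom_len=1_250_000, strand_mode="plus")
        ga = synth_genome(spec)
        d = synth_boundary_dataset(spec, ga, 19_999, peaks_per_gene=0, background_peaks=2_000)
        dr = compute_dynamic_range(d, ga)
        # flat histogram: the smoothed curve sits below median + 3*std right away
        assert dr.upstream_tss == 2_000

    def test_histogram_mass_conservation(self):
        spec = FixtureSpec(seed=22, n_genes=20, chrom_len=500_000, strand_mode="plus")
        ga = synth_genome(spec)
        d = synth_boundary_dataset(spec, ga, 2_000, peaks_per_gene=3, background_peaks=200)
        dr = compute_dynamic_range(d, ga)
        # brute force: count peaks whose midpoint lies < 20 kb upstream of a TSS
        tss = sorted(t.tss() for t in ga.transcripts())
        n_assignable = 0
        for p in d.peakset.peaks:
            mid = (p.start + p.end) // 2
            dists = [t - mid for t in tss if t >= mid]
            if dists and min(dists) < 20_000:
                n_assignable += 1
        assert sum(dr.histogram) == n_assignable

    def test_planted_boundary_recovered(self):
        spec = FixtureSpec(seed=23, n_genes=50, chrom_len=1_250_000, strand_mode="plus")
        ga = synth_genome(spec)
        d = synth_boundary_dataset(spec, ga, 2_000, peaks_per_gene=60, background_peaks=3_000)
        dr = compute_dynamic_range(d, ga)
        assert abs(dr.upstream_tss - 2_000) <= 100

    def test_empty_annotation_errors(self):
        from peakminer.genome_model import GenomeAnnotation

        d = TFDataset("d", "TF", PeakSet("d", [Peak("chr1", 0, 100)]))
        with pytest.raises(ValueError):
            compute_dynamic_range(d, GenomeAnnotation())

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DynamicRange("d", (0,) * 399, 0.0, (0.0,) * 399, 2_000)
        with pytest.raises(ValueError):
            DynamicRange("d", (0,) * 400, 0.0, (0.0,) * 400, 2_025)


def test_store_round_trip(tmp_path, small_spec, small_genome):
    from peakminer.simulate import write_fixture_dir

    write_fixture_dir(small_spec, str(tmp_path / "fx"), n_experiments=2)
    store = load_store(str(tmp_path / "fx" / "store"))
    assert {d.dataset_id for d in store} == {"ds_planted"} | {
        f"ds_decoy{i}" for i in range(small_spec.n_decoy_tfs)
    }
    planted = next(d for d in store if d.dataset_id == "ds_planted")
    assert planted.factor_name == small_spec.planted_tf_name
    assert len(planted.peakset) > 0
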