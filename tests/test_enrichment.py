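"""Targeted-gene fractions, hypergeometric enrichment, brain report."""

import math

import numpy as np
import pytest

from cnvmir.enrichment import (
    brain_fraction_report,
    hypergeometric_enrichment,
    mirnas_targeting,
    targeted_genes,
    two_stage_enrichment,
)
from cnvmir.io_formats import GeneSet, MirnaAnnotation, TargetMap


class TestTargetedGenes:
    @pytest.mark.parametrize(
        "n_genes, n_targeted, expected_pct",
        [(838, 87, 10.4), (266, 3, 1.1), (737, 84, 11.4)],
    )
    def test_percentages(self, n_genes, n_targeted, expected_pct):
        genes = {f"G{i}" for i in range(n_genes)}
        tmap = TargetMap({"miR-X": {f"G{i}" for i in range(n_targeted)}})
        rep = targeted_genes("grp", genes, tmap)
        assert rep.n_targeted == n_targeted
        assert round(rep.percent_targeted, 1) == expected_pct

    def test_empty_target_map(self):
        rep = targeted_genes("grp", {"G1", "G2"}, TargetMap({}))
        assert rep.n_targeted == 0
        assert rep.percent_targeted == 0.0

    def test_targeted_subset_of_genes(self):
        tmap = TargetMap({"miR-X": {"G1", "G9"}})
        rep = targeted_genes("grp", {"G1", "G2"}, tmap)
        assert rep.targeted == {"G1"}


class TestHypergeometricEnrichment:
    def test_whole_universe_set_p_one(self):
        universe = {f"G{i}" for i in range(30)}
        sets = [GeneSet("ALL", "", frozenset(universe))]
        res = hypergeometric_enrichment({"G0", "G1"}, sets, universe,
                                        adjp_threshold=None, top_k=None)
        assert res[0].raw_p == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        universe = {f"G{i}" for i in range(30)}
        sets = [GeneSet("S", "", frozenset({"G20", "G21"}))]
        res = hypergeometric_enrichment({"G0", "G1"}, sets, universe,
                                        adjp_threshold=None, top_k=None)
        assert res[0].raw_p == pytest.approx(1.0)

    def test_matches_combinatorial_enumeration(self):
        """P(overlap >= k) by direct enumeration over C(20, 5) draws."""
        universe = {f"G{i}" for i in range(20)}
        set_genes = frozenset({"G0", "G1", "G2", "G3", "G4"})
        query = {"G0", "G1", "G2", "G3", "G10"}  # overlap 4
        res = hypergeometric_enrichment(query, [GeneSet("S", "", set_genes)],
                                        universe, adjp_threshold=None, top_k=None)
        p_oracle = sum(
            math.comb(5, j) * math.comb(15, 5 - j) for j in range(4, 6)
        ) / math.comb(20, 5)
        assert res[0].raw_p == pytest.approx(p_oracle)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            hypergeometric_enrichment({"NOPE"}, [], {"G1"})

    def test_overlap_monotone_in_query(self):
        universe = {f"G{i}" for i in range(40)}
        sets = [GeneSet("S", "", frozenset({f"G{i}" for i in range(10)}))]
        small = hypergeometric_enrichment({"G0", "G1"}, sets, universe,
                                          adjp_threshold=None, top_k=None)
        big = hypergeometric_enrichment({"G0", "G1", "G2"}, sets, universe,
                                        adjp_threshold=None, top_k=None)
        assert big[0].n_overlap >= small[0].n_overlap

    def test_raw_p_super_uniform_under_null(self):
        """Random queries give P(raw p < a) <= about a (coarse check)."""
        rng = np.random.default_rng(21)
        universe = [f"G{i}" for i in range(60)]
        sets = [GeneSet("S", "", frozenset(universe[:15]))]
        hits = 0
        trials = 400
        for _ in range(trials):
            q = set(rng.choice(universe, size=10, replace=False))
            res = hypergeometric_enrichment(q, sets, set(universe),
                                            adjp_threshold=None, top_k=None)
            hits += res[0].raw_p < 0.05
        assert hits / trials <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)

    def test_planted_pathway_ranks_first(self, small_cohort):
        from cnvmir.annotation import FeatureTrack, features_in_region

        truth = small_cohort.truth
        gene_track = FeatureTrack(small_cohort.genes)
        universe = {g.feature_id for g in small_cohort.genes}
        rare = [c for c in small_cohort.cnvs
                if truth.true_class[c.cnv_id] in ("de_novo", "decipher")]
        cnv_genes = set()
        for c in rare:
            cnv_genes |= features_in_region(c.interval, gene_track)
        targeted = cnv_genes & small_cohort.target_map.all_targets()
        results = hypergeometric_enrichment(
            targeted, small_cohort.gene_sets, universe)
        assert results, "no set passed adjP < 0.05"
        assert results[0].set_name == truth.planted_pathway
        assert results[0].adj_p < 0.05


class TestMirnasTargeting:
    def test_single_hit(self):
        tmap = TargetMap({"miR-A": {"G1"}})
        assert mirnas_targeting({"G1"}, tmap) == {"miR-A"}

    def test_empty_gene_set(self):
        assert mirnas_targeting(set(), TargetMap({"miR-A": {"G1"}})) == set()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(13)
        genes = [f"G{i}" for i in range(40)]
        tmap = TargetMap({
            f"miR-{m}": {genes[int(i)] for i in rng.integers(0, 40, size=4)}
            for m in range(50)
        })
        query = {genes[int(i)] for i in rng.integers(0, 40, size=8)}
        oracle = set()
        for mirna in tmap.mirnas():
            for g in tmap.targets(mirna):
                if g in query:
                    oracle.add(mirna)
        assert mirnas_targeting(query, tmap) == oracle

    def test_round_trip_with_targeted_genes(self):
        tmap = TargetMap({"miR-A": {"G1", "G2"}, "miR-B": {"G3"}})
        rep = targeted_genes("grp", {"G1", "G3", "G9"}, tmap)
        back = mirnas_targeting(set(rep.targeted), tmap)
        assert back == {"miR-A", "miR-B"}


class TestBrainFraction:
    def _annotations(self, n_with_data, n_brain, n_total):
        anns = []
        for i in range(n_total):
            has = i < n_with_data
            brain = i < n_brain
            anns.append(MirnaAnnotation(f"m{i}", has, brain and has))
        return anns

    @pytest.mark.parametrize(
        "n_total, n_data, n_brain, expected_pct",
        [(90, 24, 11, 46), (14, 4, 2, 50), (30, 3, 0, 0)],
    )
    def test_percentages(self, n_total, n_data, n_brain, expected_pct):
        anns = self._annotations(n_data, n_brain, n_total)
        rep = brain_fraction_report("grp", [f"m{i}" for i in range(n_total)], anns)
        assert rep.n_with_data == n_data
        assert rep.n_brain == n_brain
        assert round(rep.percent_brain) == expected_pct

    def test_missing_ids_count_as_no_data(self):
        anns = [MirnaAnnotation("m0", True, True)]
        rep = brain_fraction_report("grp", ["m0", "unseen"], anns)
        assert rep.n_mirnas == 2
        assert rep.n_with_data == 1


def test_two_stage_enrichment_runs(small_cohort):
    from cnvmir.annotation import FeatureTrack, features_in_region

    gene_track = FeatureTrack(small_cohort.genes)
    universe = {g.feature_id for g in small_cohort.genes}
    rare = [c for c in small_cohort.cnvs
            if small_cohort.truth.true_class[c.cnv_id] in ("de_novo", "decipher")]
    cnv_genes = set()
    for c in rare:
        cnv_genes |= features_in_region(c.interval, gene_track)
    stage1, stage2 = two_stage_enrichment(
        cnv_genes, small_cohort.target_map, small_cohort.gene_sets, universe)
    for r in stage1 + stage2:
        assert r.adj_p >= r.raw_p - 1e-12
        assert r.adj_p < 0.05
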