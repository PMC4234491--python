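"""Retention permutation test, founder pool, dominance regression,
duplication classification and hotspot detection."""

import math

import numpy as np
import pandas as pd
import pytest

from rgenevo.catalog import Hsp, HspSet
from rgenevo.io_formats import GeneModel, assign_ranks
from rgenevo.paleo import (
    AncestralMap,
    DuplicatedBlockPair,
    classify_duplication,
    detect_hotspots,
    dominance_cluster_regression,
    pti_eti_trend_test,
    reconstruct_founder_pool,
    retention_permutation_test,
)


class TestPermutationTest:
    def test_symmetric_counts_are_null(self):
        res = retention_permutation_test(
            DuplicatedBlockPair(("A1.1", "A1.2"), 50, 20, 20), seed=1
        )
        assert res.observed_diff == 0
        assert abs(res.z) < 0.2
        assert res.p_two_sided > 0.8

    def test_matches_binomial_closed_form(self):
        # D deletions split Bin(D, 1/2): null sd of the difference is sqrt(D)
        res = retention_permutation_test(
            DuplicatedBlockPair(("A1.1", "A1.2"), 50, 30, 10), reps=5000, seed=2
        )
        z_closed = 20 / math.sqrt(60)
        assert res.z == pytest.approx(z_closed, rel=0.05)
        assert res.p_two_sided == pytest.approx(0.0098, abs=0.004)

    def test_null_moments_converge(self):
        block = DuplicatedBlockPair(("A1.1", "A1.2"), 80, 25, 15)
        d = 2 * 80 - 25 - 15
        res = retention_permutation_test(block, reps=5000, seed=3)
        assert abs(res.null_mean) < 3 * math.sqrt(d / 5000)
        assert abs(res.null_sd**2 - d) / d < 0.2

    def test_deterministic_under_seed(self):
        block = DuplicatedBlockPair(("A1.1", "A1.2"), 50, 28, 12)
        a = retention_permutation_test(block, seed=7)
        b = retention_permutation_test(block, seed=7)
        assert a == b

    def test_literal_formula_mode_inflates_z(self):
        block = DuplicatedBlockPair(("A1.1", "A1.2"), 50, 26, 20)
        sd = retention_permutation_test(block, seed=5, mode="sd")
        literal = retention_permutation_test(block, seed=5, mode="sd_over_sqrt_n")
        assert abs(literal.z) == pytest.approx(
            abs(sd.z) * math.sqrt(sd.reps), rel=1e-9
        )

    def test_degenerate_no_deletions(self):
        res = retention_permutation_test(
            DuplicatedBlockPair(("A1.1", "A1.2"), 20, 20, 20), seed=1
        )
        assert res.p_two_sided == 1.0

    def test_counts_exceeding_ancestral_content_rejected(self):
        with pytest.raises(ValueError):
            DuplicatedBlockPair(("A1.1", "A1.2"), 10, 12, 3)


class TestRegression:
    def test_perfectly_collinear_r2_one(self):
        pts = [(x, 2 * x + 1, "dominant") for x in range(5)]
        out = dominance_cluster_regression(pts)
        assert out["dominant"].r2 == pytest.approx(1.0)

    def test_hand_dataset_against_normal_equations(self):
        xs, ys = [0, 1, 2, 3], [1, 2, 2, 4]
        pts = [(x, y, "sensitive") for x, y in zip(xs, ys)]
        fit = dominance_cluster_regression(pts)["sensitive"]
        # normal-equations oracle
        xm, ym = np.mean(xs), np.mean(ys)
        sxy = sum((x - xm) * (y - ym) for x, y in zip(xs, ys))
        sxx = sum((x - xm) ** 2 for x in xs)
        syy = sum((y - ym) ** 2 for y in ys)
        assert fit.slope == pytest.approx(sxy / sxx)
        assert fit.r2 == pytest.approx(sxy**2 / (sxx * syy))
        assert fit.r2 == pytest.approx(0.8526, abs=5e-4)

    def test_degenerate_strata_rejected(self):
        with pytest.raises(ValueError):
            dominance_cluster_regression([(1, 2, "dominant")] * 2)
        with pytest.raises(ValueError):
            dominance_cluster_regression([(1, y, "dominant") for y in range(4)])


TOY_WINDOW = 4  # 2 flanking genes per side keeps the toy neighborhoods local


def _toy_dup_setup():
    """Two chromosomes: locus a (chr1_4) and locus b (chr2_4) share flanking
    duplicates; locus c (chr2_8) sits in unrelated context."""
    genes = []
    for i in range(9):
        genes.append(GeneModel("sp", "chr1", 100 * i + 1, 100 * i + 50, f"c1_{i}"))
    for i in range(9):
        genes.append(GeneModel("sp", "chr2", 100 * i + 1, 100 * i + 50, f"c2_{i}"))
    genes = assign_ranks(genes)
    flank = {
        frozenset(("c1_3", "c2_3")): 1e-30,
        frozenset(("c1_5", "c2_5")): 1e-25,
    }
    return genes, flank


def _rpair(a, b, identity=90.0):
    aln = 95
    nid = int(round(identity / 100 * aln))
    return HspSet(a, b, (Hsp(nid, aln, 1, aln),), 100, 1e-60)


class TestDuplicationClassification:
    def test_segmental_vs_single_gene(self):
        genes, flank = _toy_dup_setup()
        calls = classify_duplication(
            [_rpair("c1_4", "c2_4"), _rpair("c1_4", "c2_8")],
            genes, {}, flank, window=TOY_WINDOW,
        )
        by_pair = {(c.locus_a, c.locus_b): c.call for c in calls}
        assert by_pair[("c1_4", "c2_4")] == "segmental"
        assert by_pair[("c1_4", "c2_8")] == "single_gene"

    def test_subthreshold_pair_excluded(self):
        genes, flank = _toy_dup_setup()
        calls = classify_duplication(
            [_rpair("c1_4", "c2_4", identity=65.0)], genes, {}, flank,
            window=TOY_WINDOW,
        )
        assert calls == []

    def test_symmetric_in_locus_order(self):
        genes, flank = _toy_dup_setup()
        fwd = classify_duplication([_rpair("c1_4", "c2_4")], genes, {}, flank,
                                   window=TOY_WINDOW)
        rev = classify_duplication([_rpair("c2_4", "c1_4")], genes, {}, flank,
                                   window=TOY_WINDOW)
        assert [(c.locus_a, c.locus_b, c.call) for c in fwd] == [
            (c.locus_a, c.locus_b, c.call) for c in rev
        ]

    def test_cluster_members_collapse_to_one_locus(self):
        genes, flank = _toy_dup_setup()
        cluster_of = {"c1_4": "CL1", "c1_5": "CL1"}
        calls = classify_duplication(
            [_rpair("c1_4", "c1_5")], genes, cluster_of, flank,
            window=TOY_WINDOW,
        )
        assert calls == []  # same locus, skipped

    def test_cohort_recovery_of_planted_events(self, default_cohort, pipeline_result):
        cohort, res = default_cohort, pipeline_result
        cat = {r.gene.gene_id for r in res.catalog_records}
        cluster_of = {
            gid: c.cluster_id
            for sp in cohort.species
            for c in res.clusters_by_species[sp]
            for gid in c.members
        }
        call_map = {
            frozenset((c.locus_a, c.locus_b)): c.call
            for sp in res.dup_calls
            for c in res.dup_calls[sp]
        }
        total = correct = 0
        for pair, klass in cohort.truth_dup_class.items():
            a, b = sorted(pair)
            la, lb = cluster_of.get(a, a), cluster_of.get(b, b)
            if la == lb or a not in cat or b not in cat:
                continue
            total += 1
            correct += call_map.get(frozenset((la, lb))) == klass
        assert total > 20
        assert correct / total >= 0.95


class TestHotspots:
    def test_two_unrelated_partners_make_a_hotspot(self):
        from rgenevo.paleo import DuplicationCall

        calls = [
            DuplicationCall("A", "B", 0, "single_gene"),
            DuplicationCall("A", "C", 0, "single_gene"),
        ]
        related = {frozenset(("A", "B")), frozenset(("A", "C"))}
        assert detect_hotspots(calls, related) == {"A"}

    def test_single_partner_is_not_a_hotspot(self):
        from rgenevo.paleo import DuplicationCall

        calls = [DuplicationCall("A", "B", 0, "single_gene")]
        assert detect_hotspots(calls, {frozenset(("A", "B"))}) == set()

    def test_related_partners_disqualify(self):
        from rgenevo.paleo import DuplicationCall

        calls = [
            DuplicationCall("A", "B", 0, "single_gene"),
            DuplicationCall("A", "C", 0, "single_gene"),
        ]
        related = {
            frozenset(("A", "B")),
            frozenset(("A", "C")),
            frozenset(("B", "C")),  # partners are themselves related
        }
        assert detect_hotspots(calls, related) == set()

    def test_order_invariance(self):
        from rgenevo.paleo import DuplicationCall

        calls = [
            DuplicationCall("A", "B", 0, "single_gene"),
            DuplicationCall("C", "A", 0, "single_gene"),
            DuplicationCall("B", "D", 0, "single_gene"),
        ]
        related = {frozenset(p) for p in [("A", "B"), ("C", "A"), ("B", "D")]}
        fwd = detect_hotspots(calls, related)
        rev = detect_hotspots(list(reversed(calls)), related)
        assert fwd == rev


class TestFounderPoolAndTrend:
    def _toy(self):
        genes = assign_ranks(
            [
                GeneModel("ref", "chr1", 1, 300, "ref_1"),
                GeneModel("ref", "chr1", 400, 700, "ref_2"),
                GeneModel("oth", "chr1", 1, 300, "oth_1"),
            ]
        )
        from rgenevo.catalog import RGeneRecord, classify_rgene
        from rgenevo.homology import HomologyPair

        records = []
        for g, doms in zip(genes, [{"NBS", "LRR"}, {"LRR"}, {"NBS", "LRR"}]):
            rc, grp = classify_rgene(doms)
            records.append(
                RGeneRecord(g, frozenset(doms), frozenset({"pfam"}), rc, grp)
            )
        pairs = [HomologyPair("ref_1", "oth_1", 90, 95, 1e-50, "ortholog")]
        anc = AncestralMap(
            pd.DataFrame(
                [
                    ("ref", "ref_1", "A1", "A1.1", "dominant"),
                    ("ref", "ref_2", "A2", "A2.1", "dominant"),
                ],
                columns=list(AncestralMap.COLUMNS),
            )
        )
        return records, pairs, anc

    def test_min_species_and_placement_rules(self):
        records, pairs, anc = self._toy()
        pool = reconstruct_founder_pool(records, pairs, anc, "ref", min_species=2)
        assert pool.size == 1
        assert pool.loci[0].ref_gene == "ref_1"
        assert pool.loci[0].domains == {"NBS", "LRR"}
        # a group present in a single species is excluded
        pool3 = reconstruct_founder_pool(records, pairs, anc, "ref", min_species=3)
        assert pool3.size == 0

    def test_cohort_founder_recovery_within_10pct(
        self, default_cohort, pipeline_result
    ):
        cohort = default_cohort
        ref = cohort.config.reference
        # truth: ancestral R loci with R descendants in >= 2 species,
        # reference included (the pool is reference-anchored)
        truth = sum(
            1
            for locus in cohort.anc_r_loci
            if len(
                [
                    sp
                    for sp in cohort.species
                    if set(cohort.truth_orthology.get(locus, {}).get(sp, []))
                    & cohort.r_ids[sp]
                ]
            )
            >= 2
            and set(cohort.truth_orthology.get(locus, {}).get(ref, []))
            & cohort.r_ids[ref]
        )
        got = pipeline_result.founder_pool.size
        assert abs(got - truth) / truth <= 0.10

    def test_trend_directions(self):
        anc = {"PTI": 60, "ETI": 10, "R-pathway": 30}
        modern = {"PTI": 20, "ETI": 40, "R-pathway": 40}
        out = pti_eti_trend_test(anc, modern)
        assert out["PTI"].direction == "loss" and out["PTI"].p < 0.05
        assert out["ETI"].direction == "gain" and out["ETI"].p < 0.05
        same = pti_eti_trend_test({"PTI": 5, "ETI": 5}, {"PTI": 10, "ETI": 10})
        assert same["PTI"].p == pytest.approx(1.0)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            pti_eti_trend_test({}, {"PTI": 3})
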