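"""Catalog construction: CIP/CALP, evidence filtering, merge, and the
domain-architecture classification over every possible domain set."""

from itertools import combinations

import numpy as np
import pytest

from rgenevo.catalog import (
    FAMILIES,
    DomainHit,
    Hsp,
    HspSet,
    classify_rgene,
    compute_cip_calp,
    filter_pfam_hits,
    filter_prgdb_hits,
    merge_evidence,
)
from rgenevo.io_formats import GeneModel, assign_ranks


def _set(hsps, qlen, q="q", s="s"):
    return HspSet(query=q, subject=s, hsps=tuple(hsps), query_len=qlen)


class TestCipCalp:
    def test_single_perfect_hsp(self):
        assert compute_cip_calp(_set([Hsp(100, 100, 1, 100)], 100)) == (100.0, 100.0)

    def test_worked_two_hsp_example(self):
        # (90/100) + (30/50) on query length 200: CIP 120/150, CALP 150/200
        cip, calp = compute_cip_calp(
            _set([Hsp(90, 100, 1, 100), Hsp(30, 50, 101, 150)], 200)
        )
        assert cip == pytest.approx(80.0)
        assert calp == pytest.approx(75.0)

    def test_fully_overlapping_duplicate_hsp_discarded(self):
        one = compute_cip_calp(_set([Hsp(90, 100, 1, 100)], 200))
        two = compute_cip_calp(
            _set([Hsp(90, 100, 1, 100), Hsp(90, 100, 1, 100)], 200)
        )
        assert two == one

    def test_empty_hsp_list_is_error(self):
        with pytest.raises(ValueError):
            compute_cip_calp(_set([], 100))

    def test_calp_clamped_at_100(self, caplog):
        # two non-overlapping query spans whose alignment lengths exceed
        # the query length (gappy alignments)
        cip, calp = compute_cip_calp(
            _set([Hsp(50, 80, 1, 50), Hsp(50, 80, 60, 100)], 100)
        )
        assert calp == 100.0

    def test_agrees_with_bruteforce_on_fuzzed_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            qlen = int(rng.integers(50, 500))
            hsps = []
            for _ in range(int(rng.integers(1, 6))):
                qstart = int(rng.integers(1, qlen))
                qend = int(rng.integers(qstart, qlen + 1))
                aln = max(1, qend - qstart + 1 + int(rng.integers(0, 10)))
                nid = int(rng.integers(1, aln + 1))
                hsps.append(Hsp(nid, aln, qstart, qend))
            got = compute_cip_calp(_set(hsps, qlen))
            # independent recomputation of the retain-then-sum definition
            retained = []
            for h in hsps:
                span = h.qend - h.qstart + 1
                if all(
                    min(h.qend, k.qend) - max(h.qstart, k.qstart) + 1
                    <= 0.1 * span
                    for k in retained
                ):
                    retained.append(h)
            cip = 100.0 * sum(h.n_identities for h in retained) / sum(
                h.aln_len for h in retained
            )
            calp = min(
                100.0, 100.0 * sum(h.aln_len for h in retained) / qlen
            )
            assert got[0] == pytest.approx(cip, abs=1e-9)
            assert got[1] == pytest.approx(calp, abs=1e-9)


class TestEvidenceFilters:
    def test_pfam_evalue_threshold_inclusive(self):
        hits = [
            DomainHit("g1", "NBS", "pfam", 1e-20),
            DomainHit("g2", "NBS", "pfam", 1e-9),
            DomainHit("g3", "NBS", "pfam", 1e-10),
        ]
        kept = {h.gene_id for h in filter_pfam_hits(hits)}
        assert kept == {"g1", "g3"}
        assert filter_pfam_hits([]) == []

    def test_prgdb_acceptance_at_70_70(self):
        ok = _set([Hsp(85, 100, 1, 100)], 110, q="PRG1", s="gA")  # 85 / 90.9
        low_cip = _set([Hsp(69, 100, 1, 100)], 100, q="PRG1", s="gB")
        assert filter_prgdb_hits([ok, low_cip]) == {"gA"}

    def test_no_pooling_across_subject_pairs(self):
        # two sub-threshold pairs for one gene never pool into acceptance
        half1 = _set([Hsp(40, 50, 1, 50)], 120, q="PRG1", s="gC")  # CALP 41.7
        half2 = _set([Hsp(40, 50, 1, 50)], 120, q="PRG2", s="gC")
        assert filter_prgdb_hits([half1, half2]) == set()


class TestMergeEvidence:
    @pytest.fixture()
    def genes(self):
        return {
            g.gene_id: g
            for g in assign_ranks(
                GeneModel("sp", "chr1", 100 * i + 1, 100 * i + 50, gid)
                for i, gid in enumerate("abc")
            )
        }

    def test_union_with_sources(self, genes):
        records = merge_evidence(
            ["a", "b"], [DomainHit("b", "NBS", "pfam", 1e-20),
                         DomainHit("c", "LRR", "pfam", 1e-30)], ["c"], genes
        )
        by_id = {r.gene.gene_id: r for r in records}
        assert set(by_id) == {"a", "b", "c"}
        assert by_id["b"].sources == {"annotation", "pfam"}
        assert by_id["a"].domains == {"RG"}  # no PFAM domain evidence
        assert by_id["c"].sources == {"pfam", "prgdb"}

    def test_idempotent(self, genes):
        hits = [DomainHit("b", "NBS", "pfam", 1e-20)]
        once = merge_evidence(["a"], hits, ["c"], genes)
        again = merge_evidence(
            [r.gene.gene_id for r in once if "annotation" in r.sources],
            hits,
            [r.gene.gene_id for r in once if "prgdb" in r.sources],
            genes,
        )
        assert {(r.gene.gene_id, r.domains) for r in again} == {
            (r.gene.gene_id, r.domains) for r in once
        }

    def test_unknown_id_skipped_and_empty_streams(self, genes):
        assert merge_evidence([], [], [], genes) == []
        records = merge_evidence(["nope", "a"], [], [], genes)
        assert [r.gene.gene_id for r in records] == ["a"]


def _expected_class(domains: frozenset) -> tuple[str, str]:
    """Independent restatement of the classification precedence."""
    if {"NBS", "LRR"} <= domains:
        return ("TNL" if "TIR" in domains else "CNL", "ETI")
    if "LysM" in domains or "LRR" in domains:
        return ("RLK" if "PKinase" in domains else "RLP", "PTI")
    if domains & {"NBS", "TIR", "RG"}:
        return ("RGA", "R-combination")
    return ("none", "R-pathway")


class TestClassify:
    @pytest.mark.parametrize(
        "domains,expected",
        [
            ({"TIR", "NBS", "LRR"}, ("TNL", "ETI")),
            ({"NBS", "LRR"}, ("CNL", "ETI")),
            ({"LRR", "PKinase"}, ("RLK", "PTI")),
            ({"LRR"}, ("RLP", "PTI")),
            ({"LysM", "PKinase"}, ("RLK", "PTI")),
            ({"NBS", "WRKY"}, ("RGA", "R-combination")),
            ({"TIR"}, ("RGA", "R-combination")),
            ({"RG"}, ("RGA", "R-combination")),
            ({"PKinase"}, ("none", "R-pathway")),
            ({"WRKY", "PKinase"}, ("none", "R-pathway")),
        ],
    )
    def test_reference_architectures(self, domains, expected):
        assert classify_rgene(domains) == expected

    def test_total_over_all_127_domain_sets(self):
        for k in range(1, len(FAMILIES) + 1):
            for combo in combinations(FAMILIES, k):
                s = frozenset(combo)
                assert classify_rgene(s) == _expected_class(s)

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            classify_rgene(set())
        with pytest.raises(ValueError):
            classify_rgene({"COILED_COIL"})
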