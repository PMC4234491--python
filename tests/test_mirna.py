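"""miRNA mismatch scoring (with a brute-force alignment oracle) and the
interactome statistics helpers."""

import numpy as np
import pytest

from rgenevo.io_formats import load_table_fixtures
from rgenevo.mirna import (
    MatureMiRNA,
    interactome_summary,
    overall_targeted_fraction,
    paired_t_test,
    revcomp,
    scan_targets,
    score_target,
    wgd_correlation,
)

MIR = MatureMiRNA("m1", "UGACCUAGGCAUUCAGGAUCA")


def _pen(a, b):
    pair = {"A": "U", "U": "A", "G": "C", "C": "G"}
    if pair[a] == b:
        return 0.0
    if (a, b) in {("G", "U"), ("U", "G")}:
        return 0.5
    return 1.0


def _w(pos1):  # 1-based miRNA position weight
    return 2.0 if 2 <= pos1 <= 13 else 1.0


def _oracle_best(mir, transcript):
    """Exhaustive enumeration of every site x {no-bulge, one bulge on either
    strand at every internal position}; independent of the scanner."""
    t = transcript.upper().replace("T", "U")
    m, L = len(mir), len(t)
    best = float("inf")
    for start in range(L):
        for site_len in (m - 1, m, m + 1):
            if start + site_len > L:
                continue
            site = t[start: start + site_len][::-1]  # 3'->5' vs miRNA
            if site_len == m:
                s = sum(_pen(mir[i], site[i]) * _w(i + 1) for i in range(m))
                best = min(best, s)
            elif site_len == m + 1:
                for k in range(1, m):  # unpaired target base before mir pos k
                    s = (
                        sum(_pen(mir[i], site[i]) * _w(i + 1) for i in range(k))
                        + _w(k + 1)
                        + sum(
                            _pen(mir[i], site[i + 1]) * _w(i + 1)
                            for i in range(k, m)
                        )
                    )
                    best = min(best, s)
            else:
                for k in range(1, m - 1):  # miRNA position k unpaired
                    s = (
                        sum(_pen(mir[i], site[i]) * _w(i + 1) for i in range(k))
                        + _w(k + 1)
                        + sum(
                            _pen(mir[i], site[i - 1]) * _w(i + 1)
                            for i in range(k + 1, m)
                        )
                    )
                    best = min(best, s)
    return best


class TestScorer:
    def test_perfect_complement_scores_zero(self):
        tx = "AAC" + revcomp(MIR.seq).replace("U", "T") + "GGA"
        hits = score_target(MIR, tx)
        assert hits[0].score == 0.0
        assert hits[0].site_start == 4

    def test_wobble_outside_seed_costs_half(self):
        pos = next(i for i in range(14, 22) if MIR.seq[i - 1] == "G")
        site = list(revcomp(MIR.seq))
        site[21 - pos] = "U"
        tx = "".join(site).replace("U", "T")
        assert score_target(MIR, tx)[0].score == 0.5

    def test_seed_mismatch_costs_two(self):
        site = list(revcomp(MIR.seq))
        base = MIR.seq[4]  # position 5, inside the doubled region
        site[21 - 5] = {"A": "A", "C": "C", "G": "A", "U": "C"}[base]
        tx = "".join(site).replace("U", "T")
        assert score_target(MIR, tx)[0].score == 2.0

    def test_matches_bruteforce_oracle_on_random_transcripts(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        for trial in range(30):
            tx = "".join(rng.choice(bases, size=40))
            if trial % 2:  # plant a corrupted site so scores span the range
                site = list(revcomp(MIR.seq).replace("U", "T"))
                for _ in range(int(rng.integers(0, 4))):
                    site[int(rng.integers(21))] = str(rng.choice(bases))
                ins = int(rng.integers(0, 19))
                tx = tx[:ins] + "".join(site) + tx[ins:]
            expected = _oracle_best(MIR.seq, tx)
            got = score_target(MIR, tx, threshold=99.0, strict=True)
            best = got[0].score if got else float("inf")
            assert best == pytest.approx(min(expected, best), abs=1e-9)
            if expected < 90.0:
                assert best == pytest.approx(expected, abs=1e-9)

    def test_score_monotone_under_added_mutations(self):
        rng = np.random.default_rng(23)
        site = list(revcomp(MIR.seq).replace("U", "T"))
        prev = 0.0
        for _ in range(5):
            i = int(rng.integers(21))
            site[i] = {"A": "C", "C": "A", "G": "G", "T": "T"}.get(site[i], "A")
            tx = "CCA" + "".join(site) + "TTG"
            hits = score_target(MIR, tx, threshold=99.0)
            score = hits[0].score if hits else float("inf")
            assert score >= prev - 1e-9
            prev = score

    def test_threshold_strictness(self):
        # construct a site scoring exactly 4.0: four non-seed mismatches
        site = list(revcomp(MIR.seq))
        changed = 0
        for pos in (14, 15, 16, 17):
            base = MIR.seq[pos - 1]
            site[21 - pos] = {"A": "A", "C": "C", "G": "A", "U": "C"}[base]
            changed += 1
        tx = "".join(site).replace("U", "T")
        strict = score_target(MIR, tx, threshold=4.0, strict=True)
        loose = score_target(MIR, tx, threshold=4.0, strict=False)
        assert strict == []
        assert loose and loose[0].score == 4.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            score_target(MIR, "ACGTNNNACGT" * 3)
        with pytest.raises(ValueError):
            MatureMiRNA("bad", "ACGU")  # too short

    def test_scan_dedup_and_empty(self):
        tx = {"g1": "AA" + revcomp(MIR.seq).replace("U", "T") + "CC"}
        hits = scan_targets([MIR], tx)
        assert len(hits) == 1 and hits[0].gene_id == "g1"
        assert scan_targets([], tx) == []


class TestPlantedRecovery:
    def test_all_planted_sites_recovered(self, default_cohort):
        cohort = default_cohort
        planted = {
            (m, g) for m, g, start, score in cohort.truth_targets if score <= 3.5
        }
        targets = {g for _, g in planted}
        hits = scan_targets(
            cohort.mirnas, {g: cohort.transcripts[g] for g in targets}
        )
        found = {(h.mirna_id, h.gene_id) for h in hits}
        assert planted <= found

    def test_duplication_bias_recovered(self):
        from rgenevo.synthetic_data import SimConfig, generate_cohort
        from scipy.stats import fisher_exact

        cohort = generate_cohort(
            SimConfig(seed=21, target_bias_duplicated=0.9, n_mirna=16,
                      targets_per_mirna=10)
        )
        targeted = {g for _, g, _, _ in cohort.truth_targets}
        dup = set()
        for pair in cohort.truth_dup_class:
            dup |= set(pair)
        for _, members in cohort.truth_clusters:
            dup |= set(members)
        r_all = set().union(*cohort.r_ids.values())
        dup &= r_all
        single = r_all - dup
        table = [
            [len(dup & targeted), len(dup - targeted)],
            [len(single & targeted), len(single - targeted)],
        ]
        _, p = fisher_exact(table, alternative="greater")
        assert p < 0.05


class TestStatsHelpers:
    def test_wgd_correlation_matches_covariance_formula(self):
        pts = [(0, 0.1), (0, 0.2), (1, 0.35), (1, 0.3), (2, 0.45), (2, 0.5)]
        r, p = wgd_correlation(pts)
        x = np.array([a for a, _ in pts])
        y = np.array([b for _, b in pts])
        rx = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(rx, abs=1e-12)

    def test_perfect_linearity(self):
        r, p = wgd_correlation([(i, 0.1 * i) for i in range(5)])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_published_table_reproduces_r_and_p(self):
        _, t2 = load_table_fixtures()
        pts = [
            (
                row.wgd_rounds,
                overall_targeted_fraction(
                    row.cons_targets,
                    row.cons_total,
                    row.noncons_targets,
                    row.noncons_total,
                ),
            )
            for row in t2
            if row.lineage == "eudicot"
        ]
        r, p = wgd_correlation(pts)
        assert r == pytest.approx(0.7133, abs=2e-3)
        assert p == pytest.approx(0.031, abs=0.005)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            wgd_correlation([(1, 0.5), (1, 0.6), (1, 0.7)])

    def test_paired_t_hand_value(self):
        x, y = [2, 4, 6, 8], [1, 2, 3, 4]  # diffs 1,2,3,4
        t, p = paired_t_test(x, y)
        assert t == pytest.approx(3.873, abs=1e-3)

    def test_paired_t_degenerate_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_t_test([2, 3, 4], [1, 2, 3])  # constant +1 difference


class TestInteractomeSummary:
    def test_no_hits_gives_zero_percentages(self, default_cohort):
        cohort = default_cohort
        from rgenevo.catalog import RGeneRecord, classify_rgene

        records = []
        for sp in cohort.species[:1]:
            for g in cohort.genomes[sp][:5]:
                rc, grp = classify_rgene({"LRR"})
                records.append(
                    RGeneRecord(g, frozenset({"LRR"}), frozenset({"pfam"}), rc, grp)
                )
        df = interactome_summary([], records)
        assert (df["pct_r_targeted"] == 0).all()
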