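"""The forward simulator: determinism, configured distributions, and
recoverability of the planted ground truth by the analysis modules."""

import numpy as np
import pytest
from scipy import stats

from rgenevo.catalog import hspsets_from_blast
from rgenevo.clusters import call_clusters
from rgenevo.homology import call_orthologs
from rgenevo.synthetic_data import (
    SimConfig,
    apply_wgd_and_diploidize,
    generate_cohort,
    simulate_ancestor,
    simulate_block_pairs,
    write_cohort,
)


class TestAncestor:
    def test_r_count_within_binomial_interval(self):
        cfg = SimConfig(seed=1, n_anc_chr=5, genes_per_chr=200, r_fraction=0.08)
        genes = simulate_ancestor(cfg)
        assert len(genes) == 1000
        n_r = sum(g.is_r for g in genes)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.08)
        assert lo <= n_r <= hi

    def test_zero_r_fraction(self):
        genes = simulate_ancestor(SimConfig(seed=1, r_fraction=0.0))
        assert not any(g.is_r for g in genes)

    def test_same_seed_identical(self):
        a = simulate_ancestor(SimConfig(seed=9))
        b = simulate_ancestor(SimConfig(seed=9))
        assert a == b

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genes_per_chr=0)


class TestWgd:
    def test_full_retention_doubles_gene_count(self):
        cfg = SimConfig(seed=2, retention_rate=1.0, r_retention_rate=1.0)
        anc = simulate_ancestor(cfg)
        proto, labels = apply_wgd_and_diploidize(anc, cfg)
        assert len(proto) == 2 * len(anc)
        assert set(labels.values()) == {"dominant", "sensitive"}

    def test_total_bias_empties_sensitive_blocks(self):
        cfg = SimConfig(seed=2, retention_rate=0.0, r_retention_rate=0.0,
                        dominance_bias=1.0)
        anc = simulate_ancestor(cfg)
        proto, labels = apply_wgd_and_diploidize(anc, cfg)
        sensitive = [g for g in proto if labels[g.chromosome] == "sensitive"]
        assert sensitive == []
        assert len(proto) == len(anc)

    def test_no_wgd_mode(self):
        cfg = SimConfig(seed=2, wgd=False)
        anc = simulate_ancestor(cfg)
        proto, labels = apply_wgd_and_diploidize(anc, cfg)
        assert len(proto) == len(anc)
        assert set(labels.values()) == {"unknown"}


class TestBlockPairSimulation:
    def test_forced_bias_forces_all_losses_to_sensitive(self):
        blocks = simulate_block_pairs(5, 40, 0.0, 1.0, seed=1)
        for b in blocks:
            assert b.n2 == 0 and b.n1 == 40

    def test_null_is_calibrated(self):
        # under no bias the retention test rejects at close to alpha
        from rgenevo.paleo import block_retention_scan

        blocks = simulate_block_pairs(100, 60, 0.06, 0.0, seed=11)
        df = block_retention_scan(blocks, reps=1000, seed=12)
        assert 0.02 <= (df["p"] < 0.05).mean() <= 0.09


class TestTandem:
    def test_rate_zero_plants_nothing(self):
        cohort = generate_cohort(SimConfig(seed=3, tandem_rate=0.0))
        assert cohort.truth_clusters == []

    def test_array_sizes_follow_geometric(self):
        cfg = SimConfig(seed=4, tandem_rate=1.0, tandem_geom_p=0.5, n_species=2,
                        genes_per_chr=400)
        cohort = generate_cohort(cfg)
        sizes = np.array([len(m) for _, m in cohort.truth_clusters])
        copies = sizes - 1  # array size = 1 + Geometric(p)
        assert len(copies) >= 200
        kmax = 6
        observed = np.bincount(np.minimum(copies, kmax), minlength=kmax + 1)[1:]
        probs = np.array([0.5**k for k in range(1, kmax)] + [0.5 ** (kmax - 1)])
        chi = stats.chisquare(observed, probs * observed.sum())
        assert chi.pvalue > 0.01

    def test_planted_arrays_recovered_exactly_without_insertions(self):
        cfg = SimConfig(seed=5, ssd_rate=0.0, species_loss=0.0, n_species=2)
        cohort = generate_cohort(cfg)
        for sp in cohort.species:
            clusters, _ = call_clusters(cohort.genomes[sp], cohort.r_ids[sp])
            called = {frozenset(c.members) for c in clusters}
            for s, members in cohort.truth_clusters:
                if s != sp:
                    continue
                # every planted array is inside one called cluster
                assert any(set(members) <= c for c in called)


class TestHomologyEmission:
    def test_zero_divergence_gives_perfect_cip_calp(self):
        cfg = SimConfig(
            seed=6,
            n_species=2,
            divergence={"SP1": 0.0, "SP2": 0.0},
            tandem_rate=0.0,
            ssd_rate=0.0,
        )
        cohort = generate_cohort(cfg)
        df = cohort.homology[("SP1", "SP2")]
        lengths = {
            g.gene_id: g.length for sp in cohort.species for g in cohort.genomes[sp]
        }
        true_pairs = {
            frozenset((a, b))
            for locus, per in cohort.truth_orthology.items()
            for a in per.get("SP1", [])
            for b in per.get("SP2", [])
        }
        from rgenevo.catalog import compute_cip_calp

        for hs in hspsets_from_blast(df, lengths):
            if frozenset((hs.query, hs.subject)) in true_pairs:
                cip, calp = compute_cip_calp(hs)
                assert cip == pytest.approx(100.0)
                assert calp == pytest.approx(100.0)

    def test_ortholog_recovery_and_false_positives(self, default_cohort):
        cohort = default_cohort
        lengths = {
            g.gene_id: g.length for sp in cohort.species for g in cohort.genomes[sp]
        }
        species_of = {
            g.gene_id: sp for sp in cohort.species for g in cohort.genomes[sp]
        }
        truth_pairs = set()
        ref = cohort.config.reference
        for locus, per in cohort.truth_orthology.items():
            for a in per.get(ref, []):
                for sp in cohort.species[1:]:
                    for b in per.get(sp, []):
                        truth_pairs.add(frozenset((a, b)))
        called = set()
        n_candidates = 0
        for sp in cohort.species[1:]:
            key = tuple(sorted((ref, sp)))
            sets = hspsets_from_blast(cohort.homology[key], lengths)
            sets = [s for s in sets if species_of[s.query] != species_of[s.subject]]
            n_candidates += len(sets)
            for p in call_orthologs(sets, species_of):
                if p.relation == "ortholog":
                    called.add(frozenset((p.query, p.subject)))
        recall = len(called & truth_pairs) / len(truth_pairs)
        false_pos = len(called - truth_pairs)
        assert recall >= 0.95
        assert false_pos / max(1, n_candidates) <= 0.01


class TestDeterminismAndScale:
    def test_cohort_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(seed=8, n_species=2, genes_per_chr=60)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(cfg), d1)
        write_cohort(generate_cohort(cfg), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_every_gene_traces_to_one_lineage(self, default_cohort):
        cohort = default_cohort
        seen = {}
        for locus, per in cohort.truth_orthology.items():
            for sp, ids in per.items():
                for gid in ids:
                    assert gid not in seen, f"{gid} in two lineages"
                    seen[gid] = locus
        all_ids = {g.gene_id for sp in cohort.species for g in cohort.genomes[sp]}
        assert set(seen) == all_ids
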