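#!/usr/bin/env python
"""Paleogenomics of the R-gene repertoire: reconstruct the ancestral founder
pool on the protochromosome map, test biased duplicate retention between
post-WGD block pairs with the permutation Z-test, regress conservation on
clusterization by block dominance status, and test the PTI/ETI trend
between ancestor and modern species.

Reads scratch/cohort/ and results/02_catalog.tsv; writes four tables under
results/.
"""

import logging
from pathlib import Path

import pandas as pd

from rgenevo import catalog, clusters, homology, io_formats, paleo
from rgenevo._util import seed_for

logging.getLogger("rgenevo.paleo").setLevel(logging.ERROR)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
REFERENCE = "SP1"
SEED = 0


def main() -> None:
    records = io_formats.read_catalog_tsv(ROOT / "results" / "02_catalog.tsv")
    r_ids_all = {r.gene.gene_id for r in records}
    species = sorted(p.stem for p in COHORT.glob("*.gff3"))
    genomes = {sp: io_formats.read_gff3(COHORT / f"{sp}.gff3", sp) for sp in species}
    lengths = {g.gene_id: g.length for sp in species for g in genomes[sp]}
    species_of = {g.gene_id: sp for sp in species for g in genomes[sp]}
    anc_map = paleo.AncestralMap.read_tsv(COHORT / "ancestral_map.tsv")
    out = ROOT / "results"

    # R-gene ortholog pairs against the reference (for the founder pool)
    ortho_r = []
    for sp in species:
        if sp == REFERENCE:
            continue
        a, b = sorted((REFERENCE, sp))
        df = io_formats.read_blast_tab(COHORT / f"homology.{a}-{b}.tsv")
        sets = [
            s
            for s in catalog.hspsets_from_blast(df, lengths)
            if species_of[s.query] != species_of[s.subject]
        ]
        ortho_r.extend(
            p
            for p in homology.call_orthologs(sets, species_of)
            if p.query in r_ids_all and p.subject in r_ids_all
        )

    pool = paleo.reconstruct_founder_pool(records, ortho_r, anc_map, REFERENCE)
    pd.DataFrame(
        [{"family": fam, "n_founder_loci": n} for fam, n in pool.family_totals]
    ).to_csv(out / "05_founder_pool.tsv", sep="\t", index=False)
    print(f"founder pool: {pool.size} ancestral R loci; per-family totals:")
    print("  " + ", ".join(f"{fam}={n}" for fam, n in pool.family_totals if n))

    # retention bias between duplicated block pairs
    blocks = paleo.build_block_pairs(anc_map, r_ids_all)
    scan = paleo.block_retention_scan(
        blocks, reps=1000, seed=seed_for(SEED, "block_scan")
    )
    scan.to_csv(out / "05_block_retention.tsv", sep="\t", index=False)
    n_biased = int((scan["label"] == "biased").sum())
    print(
        f"\nretention scan: {n_biased}/{len(scan)} block pairs biased at "
        f"alpha=0.05 (permutation Z-test, 1000 replicates)"
    )

    # conservation vs clusterization by block dominance status
    conserved = {g for p in ortho_r for g in (p.query, p.subject)}
    clustered = set()
    for sp in species:
        cl, _ = clusters.call_clusters(genomes[sp], r_ids_all)
        clustered |= {gid for c in cl for gid in c.members}
    points = []
    r_rows = anc_map.rows[anc_map.rows["gene_id"].isin(r_ids_all)]
    for (_, _, _, status), grp in r_rows.groupby(
        ["species", "anc_chr", "block_id", "block_status"], sort=True
    ):
        gids = set(grp["gene_id"])
        points.append((len(gids & clustered), len(gids & conserved), status))
    fits = paleo.dominance_cluster_regression(points)
    pd.DataFrame(
        [
            {
                "block_status": status,
                "slope": round(f.slope, 3),
                "r2": round(f.r2, 3),
                "p": f"{f.p:.3g}",
                "n_blocks": f.n,
            }
            for status, f in fits.items()
        ]
    ).to_csv(out / "05_dominance_regression.tsv", sep="\t", index=False)
    for status, f in fits.items():
        print(
            f"{status} blocks: conserved ~ clustered, r2={f.r2:.2f}, "
            f"p={f.p:.2g} (n={f.n})"
        )

    # PTI/ETI trend: founder pool vs each modern species
    anc_counts: dict[str, int] = {}
    for locus in pool.loci:
        _, grp = catalog.classify_rgene(locus.domains)
        anc_counts[grp] = anc_counts.get(grp, 0) + 1
    rows = []
    for sp in species:
        modern: dict[str, int] = {}
        for r in records:
            if r.gene.species == sp:
                modern[r.group] = modern.get(r.group, 0) + 1
        for grp, res in paleo.pti_eti_trend_test(anc_counts, modern).items():
            rows.append(
                {
                    "species": sp,
                    "group": grp,
                    "anc_share": round(res.anc_share, 3),
                    "modern_share": round(res.modern_share, 3),
                    "direction": res.direction,
                    "p": f"{res.p:.3g}",
                }
            )
    trend = pd.DataFrame(rows)
    trend.to_csv(out / "05_pti_eti_trend.tsv", sep="\t", index=False)
    print("\nPTI/ETI trend (ancestor vs modern):")
    print(trend.to_string(index=False))


if __name__ == "__main__":
    main()
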