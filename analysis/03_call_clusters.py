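#!/usr/bin/env python
"""Call R-gene clusters with the gap rule (at most eight intervening non-R
genes) and profile the domain combinations inside clusters.

Reads scratch/cohort/ and results/02_catalog.tsv; writes the per-species
cluster typology and the domain-combination table under results/.
"""

from pathlib import Path

import pandas as pd

from rgenevo import clusters, io_formats

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    records = io_formats.read_catalog_tsv(ROOT / "results" / "02_catalog.tsv")
    r_ids = {r.gene.gene_id for r in records}
    by_id = {r.gene.gene_id: r for r in records}
    species = sorted(p.stem for p in COHORT.glob("*.gff3"))

    all_clusters = []
    for sp in species:
        genomes = io_formats.read_gff3(COHORT / f"{sp}.gff3", sp)
        cl, _ = clusters.call_clusters(genomes, r_ids)
        all_clusters.extend(cl)

    typ = clusters.cluster_typology(all_clusters, records)
    rows = [
        {
            "species": t.species,
            "n_rgenes": t.n_rgenes,
            "n_in_clusters": t.n_in_clusters,
            "pct_in_clusters": round(t.pct_in_clusters, 1),
            "pct_size2": round(t.pct_size2, 1),
            "max_size": max((s for s, _ in t.size_histogram), default=0),
        }
        for t in typ.values()
    ]
    summary = pd.DataFrame(rows)

    prof = clusters.domain_combination_profile(all_clusters, by_id)
    combos = pd.DataFrame(
        [
            {"combination": "-".join(c), "count": n}
            for c, n in sorted(prof.combo_counts, key=lambda kv: -kv[1])
        ]
    )

    out = ROOT / "results"
    summary.to_csv(out / "03_cluster_typology.tsv", sep="\t", index=False)
    combos.to_csv(out / "03_domain_combinations.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\ndomain combinations in clusters: {prof.pct_with_lrr:.1f}% include "
        f"LRR; among LRR partnerships "
        f"{dict(prof.lrr_partner_shares)['PKinase']:.0f}% with PKinase vs "
        f"{dict(prof.lrr_partner_shares)['NBS']:.0f}% with NBS"
    )


if __name__ == "__main__":
    main()
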