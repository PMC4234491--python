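#!/usr/bin/env python
"""Call orthologs against the reference species (CIP/CALP >= 60/70) and
contrast R-gene conservation with background gene conservation (Fisher
exact test).

Reads scratch/cohort/ and results/02_catalog.tsv; writes
results/04_conservation.tsv.
"""

from pathlib import Path

import pandas as pd

from rgenevo import catalog, homology, io_formats

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
REFERENCE = "SP1"


def main() -> None:
    records = io_formats.read_catalog_tsv(ROOT / "results" / "02_catalog.tsv")
    r_ids_all = {r.gene.gene_id for r in records}
    species = sorted(p.stem for p in COHORT.glob("*.gff3"))
    genomes = {sp: io_formats.read_gff3(COHORT / f"{sp}.gff3", sp) for sp in species}
    lengths = {g.gene_id: g.length for sp in species for g in genomes[sp]}
    species_of = {g.gene_id: sp for sp in species for g in genomes[sp]}

    ortho_all, ortho_r = [], []
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
        called = homology.call_orthologs(sets, species_of)
        ortho_all.extend(called)
        ortho_r.extend(
            p for p in called if p.query in r_ids_all and p.subject in r_ids_all
        )

    rgene_ids = {
        sp: {r.gene.gene_id for r in records if r.gene.species == sp}
        for sp in species
    }
    gene_ids = {sp: {g.gene_id for g in genomes[sp]} for sp in species}
    summaries = homology.conservation_summary(
        rgene_ids, gene_ids, ortho_r, ortho_all, REFERENCE, species_of
    )
    rows = [
        {
            "species": s.species,
            "n_rgene": s.n_rgene,
            "n_rgene_conserved": s.n_rgene_conserved,
            "pct_rgene": round(s.pct_rgene, 1),
            "n_gene": s.n_gene,
            "n_gene_conserved": s.n_gene_conserved,
            "pct_gene": round(s.pct_gene, 1),
            "fisher_p": f"{s.fisher_p:.3g}",
            "odds_ratio": round(s.odds_ratio, 3),
        }
        for s in summaries.values()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "04_conservation.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\nconservation is measured against the reference "
        f"({REFERENCE}) with the species' own catalog as denominator"
    )


if __name__ == "__main__":
    main()
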