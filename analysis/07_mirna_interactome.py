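#!/usr/bin/env python
"""Compute the miRNA/R-gene interactome: scan mature miRNAs against R-gene
transcripts (mismatch score < 4), summarize targeting rates by conservation,
clusterization and domain family, and reproduce the published correlation
between WGD rounds and targeted fraction from the packaged table.

Reads scratch/cohort/, results/02_catalog.tsv and results/04_conservation
inputs; writes results/07_interactome.tsv and results/07_wgd_correlation.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from rgenevo import catalog, clusters, homology, io_formats, mirna
from rgenevo._util import seed_for

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
REFERENCE = "SP1"
SEED = 0
NONR_SAMPLE = 150


def main() -> None:
    records = io_formats.read_catalog_tsv(ROOT / "results" / "02_catalog.tsv")
    r_ids_all = {r.gene.gene_id for r in records}
    species = sorted(p.stem for p in COHORT.glob("*.gff3"))
    genomes = {sp: io_formats.read_gff3(COHORT / f"{sp}.gff3", sp) for sp in species}
    lengths = {g.gene_id: g.length for sp in species for g in genomes[sp]}
    species_of = {g.gene_id: sp for sp in species for g in genomes[sp]}

    mirnas = [
        mirna.MatureMiRNA(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(COHORT / "mirna.fasta"), "fasta")
    ]
    rng = np.random.default_rng(seed_for(SEED, "mirna_scan"))
    transcripts: dict[str, str] = {}
    nonr_scanned: dict[str, set] = {}
    for sp in species:
        seqs = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(COHORT / f"{sp}.transcripts.fasta"), "fasta")
        }
        non_r = sorted(set(seqs) - r_ids_all)
        if len(non_r) > NONR_SAMPLE:
            idx = rng.choice(len(non_r), size=NONR_SAMPLE, replace=False)
            non_r = [non_r[i] for i in sorted(idx)]
        nonr_scanned[sp] = set(non_r)
        for gid in sorted(set(seqs) & r_ids_all) + non_r:
            transcripts[gid] = seqs[gid]
    hits = mirna.scan_targets(mirnas, transcripts)

    # conserved R-genes (threshold-passing orthologs with the reference)
    conserved = set()
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
        for p in homology.call_orthologs(sets, species_of):
            if (
                p.relation == "ortholog"
                and p.query in r_ids_all
                and p.subject in r_ids_all
            ):
                conserved |= {p.query, p.subject}

    clustered = set()
    for sp in species:
        cl, _ = clusters.call_clusters(genomes[sp], r_ids_all)
        clustered |= {gid for c in cl for gid in c.members}

    summary = mirna.interactome_summary(
        hits,
        records,
        conserved_ids=conserved,
        clustered_ids=clustered,
        nonr_scanned=nonr_scanned,
    )
    out = ROOT / "results"
    summary.round(2).to_csv(out / "07_interactome.tsv", sep="\t", index=False)
    cols = [
        "species",
        "pct_r_targeted",
        "pct_nonr_targeted",
        "pct_cluster_targeted",
        "pct_singleton_targeted",
    ]
    print(summary[cols].round(1).to_string(index=False))

    # published WGD-rounds vs targeted-fraction correlation (eudicot table)
    _, t2 = io_formats.load_table_fixtures()
    pts = [
        (
            r.wgd_rounds,
            mirna.overall_targeted_fraction(
                r.cons_targets, r.cons_total, r.noncons_targets, r.noncons_total
            ),
        )
        for r in t2
        if r.lineage == "eudicot"
    ]
    r_val, p_val = mirna.wgd_correlation(pts)
    pd.DataFrame(
        [{"n_species": len(pts), "pearson_r": round(r_val, 4), "p": round(p_val, 4)}]
    ).to_csv(out / "07_wgd_correlation.tsv", sep="\t", index=False)
    print(
        f"\nWGD rounds vs targeted fraction over {len(pts)} eudicots: "
        f"r = {r_val:.4f}, p = {p_val:.3f}"
    )


if __name__ == "__main__":
    main()
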