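"""End-to-end orchestration: run every stage over an on-disk cohort.

The pipeline consumes the input layout written by
:func:`rgenevo.synthetic_data.write_cohort` (per-species GFF3, evidence
streams, per-pair HSP tables, ancestral map, miRNA FASTA) and produces the
stage outputs as TSVs with a provenance header. One seed governs all
stochastic stages (per-stage streams are split by stage-name hashing), so a
rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__, catalog, clusters, homology, io_formats, mirna, paleo
from ._util import ParseError, seed_for

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the published values."""

    hmm_evalue: float = 1e-10
    cip_dedup: float = 70.0
    calp_dedup: float = 70.0
    cip_ortho: float = 60.0
    calp_ortho: float = 70.0
    cluster_gap: int = 8
    flank_window: int = 40
    flank_evalue: float = 1e-10
    mirna_score: float = 4.0
    mirna_strict: bool = True
    perm_reps: int = 1000
    alpha: float = 0.05
    nonr_scan_sample: int = 150
    seed: int = 0
    reference_species: str = "SP1"

    def __post_init__(self) -> None:
        for name in (
            "hmm_evalue",
            "cip_dedup",
            "calp_dedup",
            "cip_ortho",
            "calp_ortho",
            "flank_evalue",
            "mirna_score",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_gap < 0 or self.flank_window <= 0 or self.perm_reps < 1:
            raise ValueError("invalid window/replicate settings")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def sha(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: dict[str, list[io_formats.GeneModel]]
    catalog_records: list
    clusters_by_species: dict[str, list]
    singletons: dict[str, list[str]]
    conservation: dict
    founder_pool: paleo.FounderPool | None
    block_scan: pd.DataFrame
    regression: dict
    dup_calls: dict[str, list]
    hotspots: dict[str, set[str]]
    mirna_hits: list
    interactome: pd.DataFrame
    trend: dict
    summary1: pd.DataFrame
    summary2: pd.DataFrame


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str):
    with open(path, "w") as fh:
        fh.write(f"# rgenevo {__version__} stage={stage} config_sha={config.sha()}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_species(input_dir: Path) -> list[str]:
    species = sorted(p.stem for p in input_dir.glob("*.gff3"))
    if not species:
        raise ParseError(f"{input_dir}: no per-species GFF3 inputs found")
    return species


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, outdir: str | Path
) -> PipelineResult:
    """Run catalog, clusters, conservation, paleo tests, duplication calls
    and the miRNA interactome over one cohort directory; write stage TSVs."""
    input_dir, outdir = Path(input_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = _read_species(input_dir)
    reference = config.reference_species
    if reference not in species:
        raise ParseError(f"reference species {reference} not among {species}")

    # --- stage: inputs -----------------------------------------------------
    genomes = {sp: io_formats.read_gff3(input_dir / f"{sp}.gff3", sp) for sp in species}
    genes_by_id = {g.gene_id: g for sp in species for g in genomes[sp]}
    gene_lengths = {gid: g.length for gid, g in genes_by_id.items()}
    species_of = {gid: g.species for gid, g in genes_by_id.items()}
    logger.info("stage=inputs species=%d genes=%d", len(species), len(genes_by_id))

    # --- stage: catalog ----------------------------------------------------
    records = []
    for sp in species:
        annot_path = input_dir / f"{sp}.annotation_rgenes.txt"
        annotation = (
            [l.strip() for l in open(annot_path) if l.strip()]
            if annot_path.exists()
            else []
        )
        hits = io_formats.read_domtblout(input_dir / f"{sp}.domtblout")
        hits = catalog.filter_pfam_hits(hits, evalue_cut=config.hmm_evalue)
        prg_df = io_formats.read_blast_tab(input_dir / f"{sp}.prgdb.tsv")
        qlens = pd.read_csv(
            input_dir / f"{sp}.prgdb_query_lengths.tsv", sep="\t"
        ).set_index("query")["length"]
        prg_sets = catalog.hspsets_from_blast(prg_df, qlens.to_dict())
        prg_ids = catalog.filter_prgdb_hits(
            prg_sets, cip_min=config.cip_dedup, calp_min=config.calp_dedup
        )
        sp_genes = {g.gene_id: g for g in genomes[sp]}
        records.extend(catalog.merge_evidence(annotation, hits, prg_ids, sp_genes))
    io_formats.write_catalog_tsv(records, outdir / "catalog.tsv")
    r_ids_all = {r.gene.gene_id for r in records}
    logger.info("stage=catalog records=%d", len(records))

    # --- stage: clusters ---------------------------------------------------
    clusters_by_species: dict[str, list] = {}
    singletons: dict[str, list[str]] = {}
    for sp in species:
        cl, single = clusters.call_clusters(
            genomes[sp],
            r_ids_all & {g.gene_id for g in genomes[sp]},
            max_gap=config.cluster_gap,
        )
        clusters_by_species[sp] = cl
        singletons[sp] = single
    cluster_rows = [
        {
            "cluster_id": c.cluster_id,
            "species": c.species,
            "chromosome": c.chromosome,
            "size": c.size,
            "members": ",".join(c.members),
        }
        for sp in species
        for c in clusters_by_species[sp]
    ]
    _write_tsv(
        pd.DataFrame(
            cluster_rows,
            columns=["cluster_id", "species", "chromosome", "size", "members"],
        ),
        outdir / "clusters.tsv",
        config,
        "clusters",
    )
    clustered_ids = {
        gid for cl in clusters_by_species.values() for c in cl for gid in c.members
    }
    logger.info(
        "stage=clusters clusters=%d clustered_genes=%d",
        len(cluster_rows),
        len(clustered_ids),
    )

    # --- stage: homology / conservation ------------------------------------
    ortho_pairs_all: list[homology.HomologyPair] = []
    ortho_pairs_r: list[homology.HomologyPair] = []
    for sp in species:
        if sp == reference:
            continue
        a, b = sorted((reference, sp))
        path = input_dir / f"homology.{a}-{b}.tsv"
        if not path.exists():
            continue
        df = io_formats.read_blast_tab(path)
        sets = catalog.hspsets_from_blast(df, gene_lengths)
        sets = [s for s in sets if species_of[s.query] != species_of[s.subject]]
        called = homology.call_orthologs(
            sets, species_of, cip_min=config.cip_ortho, calp_min=config.calp_ortho
        )
        ortho_pairs_all.extend(called)
        ortho_pairs_r.extend(
            p for p in called if p.query in r_ids_all and p.subject in r_ids_all
        )
    rgene_ids = {
        sp: {r.gene.gene_id for r in records if r.gene.species == sp}
        for sp in species
    }
    gene_ids = {sp: {g.gene_id for g in genomes[sp]} for sp in species}
    conservation = homology.conservation_summary(
        rgene_ids, gene_ids, ortho_pairs_r, ortho_pairs_all, reference, species_of
    )
    cons_rows = [
        {
            "species": c.species,
            "n_rgene": c.n_rgene,
            "n_rgene_conserved": c.n_rgene_conserved,
            "pct_rgene": round(c.pct_rgene, 2),
            "n_gene": c.n_gene,
            "n_gene_conserved": c.n_gene_conserved,
            "pct_gene": round(c.pct_gene, 2),
            "fisher_p": c.fisher_p,
            "odds_ratio": c.odds_ratio,
        }
        for c in conservation.values()
    ]
    _write_tsv(
        pd.DataFrame(cons_rows), outdir / "conservation.tsv", config, "conserve"
    )
    conserved_ids = {
        gid
        for p in ortho_pairs_r
        if p.relation == "ortholog"
        for gid in (p.query, p.subject)
    }
    logger.info(
        "stage=conserve ortholog_pairs=%d conserved_rgenes=%d",
        sum(1 for p in ortho_pairs_r if p.relation == "ortholog"),
        len(conserved_ids),
    )

    # --- stage: paleo ------------------------------------------------------
    anc_path = input_dir / "ancestral_map.tsv"
    founder = None
    block_scan = pd.DataFrame()
    regression: dict = {}
    trend: dict = {}
    if anc_path.exists():
        anc_map = paleo.AncestralMap.read_tsv(anc_path)
        founder = paleo.reconstruct_founder_pool(
            records, ortho_pairs_r, anc_map, reference
        )
        blocks = paleo.build_block_pairs(anc_map, r_ids_all)
        block_scan = paleo.block_retention_scan(
            blocks,
            reps=config.perm_reps,
            alpha=config.alpha,
            seed=seed_for(config.seed, "block_scan"),
        )
        _write_tsv(block_scan, outdir / "block_retention.tsv", config, "paleotest")

        # per-block clusterization vs conservation, by dominance status
        points = []
        rows = anc_map.rows
        r_rows = rows[rows["gene_id"].isin(r_ids_all)]
        for (_, _, block_id, status), grp in r_rows.groupby(
            ["species", "anc_chr", "block_id", "block_status"], sort=True
        ):
            gids = set(grp["gene_id"])
            points.append(
                (
                    len(gids & clustered_ids),
                    len(gids & conserved_ids),
                    status,
                )
            )
        try:
            regression = paleo.dominance_cluster_regression(points)
        except ValueError as exc:
            logger.warning("regression skipped: %s", exc)

        # PTI/ETI trend: founder pool vs each modern species
        anc_counts: dict[str, int] = {}
        for locus in founder.loci:
            _, grp = catalog.classify_rgene(locus.domains)
            anc_counts[grp] = anc_counts.get(grp, 0) + 1
        for sp in species:
            modern_counts: dict[str, int] = {}
            for r in records:
                if r.gene.species == sp:
                    modern_counts[r.group] = modern_counts.get(r.group, 0) + 1
            if anc_counts and modern_counts:
                trend[sp] = paleo.pti_eti_trend_test(anc_counts, modern_counts)
        logger.info(
            "stage=paleotest blocks=%d founder_loci=%d",
            len(block_scan),
            founder.size,
        )

    # --- stage: duplication classes ----------------------------------------
    dup_calls: dict[str, list] = {}
    hotspots: dict[str, set[str]] = {}
    for sp in species:
        path = input_dir / f"homology.{sp}-{sp}.tsv"
        if not path.exists():
            continue
        df = io_formats.read_blast_tab(path)
        sets = catalog.hspsets_from_blast(df, gene_lengths)
        sets = [s for s in sets if s.query != s.subject]
        r_sets = [
            s for s in sets if s.query in r_ids_all and s.subject in r_ids_all
        ]
        cluster_of = {
            gid: c.cluster_id for c in clusters_by_species[sp] for gid in c.members
        }
        calls = paleo.classify_duplication(
            r_sets,
            genomes[sp],
            cluster_of,
            paleo.flank_evalue_map(df),
            window=config.flank_window,
            flank_evalue=config.flank_evalue,
            cip_min=config.cip_dedup,
            calp_min=config.calp_dedup,
        )
        dup_calls[sp] = calls
        related = {frozenset((c.locus_a, c.locus_b)) for c in calls}
        hotspots[sp] = paleo.detect_hotspots(calls, related)
    dup_rows = [
        {
            "species": sp,
            "locus_a": c.locus_a,
            "locus_b": c.locus_b,
            "n_flank_hits": c.n_flank_hits,
            "call": c.call,
        }
        for sp in sorted(dup_calls)
        for c in dup_calls[sp]
    ]
    _write_tsv(
        pd.DataFrame(
            dup_rows,
            columns=["species", "locus_a", "locus_b", "n_flank_hits", "call"],
        ),
        outdir / "duplication_calls.tsv",
        config,
        "dupclass",
    )
    logger.info(
        "stage=dupclass calls=%d hotspots=%d",
        len(dup_rows),
        sum(len(h) for h in hotspots.values()),
    )

    # --- stage: miRNA interactome -------------------------------------------
    mirna_hits: list = []
    interactome = pd.DataFrame()
    mir_path = input_dir / "mirna.fasta"
    if mir_path.exists():
        mirnas = [
            mirna.MatureMiRNA(mirna_id=rec.id, seq=str(rec.seq))
            for rec in SeqIO.parse(str(mir_path), "fasta")
        ]
        import numpy as np

        rng = np.random.default_rng(seed_for(config.seed, "mirna_scan"))
        transcripts: dict[str, str] = {}
        nonr_scanned: dict[str, set[str]] = {}
        for sp in species:
            seqs = {
                rec.id: str(rec.seq)
                for rec in SeqIO.parse(
                    str(input_dir / f"{sp}.transcripts.fasta"), "fasta"
                )
            }
            r_here = sorted(set(seqs) & r_ids_all)
            non_r = sorted(set(seqs) - r_ids_all)
            if len(non_r) > config.nonr_scan_sample:
                idx = rng.choice(
                    len(non_r), size=config.nonr_scan_sample, replace=False
                )
                non_r = [non_r[i] for i in sorted(idx)]
            nonr_scanned[sp] = set(non_r)
            for gid in r_here + non_r:
                transcripts[gid] = seqs[gid]
        mirna_hits = mirna.scan_targets(
            mirnas,
            transcripts,
            threshold=config.mirna_score,
            strict=config.mirna_strict,
        )
        manifest_path = input_dir / "manifest.yaml"
        wgd_rounds = None
        if manifest_path.exists():
            with open(manifest_path) as fh:
                manifest = yaml.safe_load(fh) or {}
            rounds = 1 if manifest.get("sim_config", {}).get("wgd", False) else 0
            wgd_rounds = {sp: rounds for sp in species}
        interactome = mirna.interactome_summary(
            mirna_hits,
            records,
            conserved_ids=conserved_ids,
            clustered_ids=clustered_ids,
            nonr_scanned=nonr_scanned,
            wgd_rounds=wgd_rounds,
        )
        hit_rows = [
            {
                "mirna_id": h.mirna_id,
                "gene_id": h.gene_id,
                "site_start": h.site_start,
                "score": h.score,
            }
            for h in mirna_hits
        ]
        _write_tsv(
            pd.DataFrame(
                hit_rows, columns=["mirna_id", "gene_id", "site_start", "score"]
            ),
            outdir / "mirna_hits.tsv",
            config,
            "mirna",
        )
        _write_tsv(interactome, outdir / "interactome.tsv", config, "mirna")
        logger.info("stage=mirna mirnas=%d hits=%d", len(mirnas), len(mirna_hits))

    # --- stage: report -------------------------------------------------------
    summary1, summary2 = make_summary_tables(
        species,
        records,
        conservation,
        mirna_hits,
        conserved_ids,
        genomes,
        reference,
    )
    _write_tsv(summary1, outdir / "summary_catalog.tsv", config, "report")
    _write_tsv(summary2, outdir / "summary_interactome.tsv", config, "report")
    config.to_yaml(outdir / "pipeline_config.yaml")

    return PipelineResult(
        config=config,
        genomes=genomes,
        catalog_records=records,
        clusters_by_species=clusters_by_species,
        singletons=singletons,
        conservation=conservation,
        founder_pool=founder,
        block_scan=block_scan,
        regression=regression,
        dup_calls=dup_calls,
        hotspots=hotspots,
        mirna_hits=mirna_hits,
        interactome=interactome,
        trend=trend,
        summary1=summary1,
        summary2=summary2,
    )


def make_summary_tables(
    species: Sequence[str],
    records: Sequence,
    conservation: Mapping,
    mirna_hits: Sequence,
    conserved_ids: set[str],
    genomes: Mapping[str, Sequence[io_formats.GeneModel]],
    reference: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species catalog/conservation and miRNA-target summary tables."""
    targeted = {h.gene_id for h in mirna_hits}
    rows1, rows2 = [], []
    for sp in species:
        recs = [r for r in records if r.gene.species == sp]
        r_ids = {r.gene.gene_id for r in recs}
        n_annot = sum(1 for r in recs if "annotation" in r.sources)
        n_pfam = sum(1 for r in recs if "pfam" in r.sources)
        n_prgdb = sum(1 for r in recs if "prgdb" in r.sources)
        cons = conservation.get(sp)
        rows1.append(
            {
                "species": sp,
                "n_gene": len(genomes[sp]),
                "n_annot": n_annot,
                "n_pfam": n_pfam,
                "n_prgdb": n_prgdb,
                "n_nonredundant": len(recs),
                "n_ortho_rgene": cons.n_rgene_conserved if cons else None,
                "conservation_pct": (
                    round(cons.pct_rgene, 2) if cons else None
                ),
            }
        )
        cons_here = r_ids & conserved_ids
        noncons_here = r_ids - conserved_ids
        rows2.append(
            {
                "species": sp,
                "cons_targets": len(cons_here & targeted),
                "cons_total": len(cons_here),
                "noncons_targets": len(noncons_here & targeted),
                "noncons_total": len(noncons_here),
            }
        )
    return pd.DataFrame(rows1), pd.DataFrame(rows2)
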