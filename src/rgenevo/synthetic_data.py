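"""Synthetic multi-species cohort with ground truth for every pipeline stage.

The generator emulates the history the pipeline is built to dissect: an
ancestral genome with a minority of R-genes carrying domain architectures, a
whole-genome duplication followed by biased diploidization (the sensitive
block copy loses more duplicates than the dominant one), lineage-specific
gene loss, tandem-array growth (clusterization), single-gene transpositions
(SSD), and planted miRNA target sites enriched toward duplicated R-genes.

Sequence evolution is deliberately minimal: homology is emitted directly as
HSP tables whose identities decay with configured divergence (the pipeline
only ever consumes HSP tables), and nucleotide sequences are generated only
where the miRNA scorer needs them. Every stochastic choice flows from one
seed; the same seed yields byte-identical cohort files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import seed_for
from .catalog import FAMILIES, DomainHit, Hsp, HspSet
from .io_formats import (
    BLAST_COLUMNS,
    GeneModel,
    assign_ranks,
    write_blast_tab,
    write_domtblout,
    write_gff3,
)
from .mirna import MatureMiRNA, revcomp
from .paleo import AncestralMap, DuplicatedBlockPair

_DEFAULT_DOMAIN_FREQS = {
    # marginal probability that an R-gene carries each family; draws are
    # independent per family, redrawn if empty. LRR-heavy, kinase-rich,
    # TIR rare, mirroring grass-like repertoires.
    "LRR": 0.62,
    "PKinase": 0.45,
    "NBS": 0.28,
    "TIR": 0.07,
    "LysM": 0.05,
    "WRKY": 0.09,
    "RG": 0.06,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a grass-like clade: ~1000 ancestral genes on 5
    protochromosomes, ~8% R-genes, one shared WGD with modest retention and
    a clear deletion bias toward the sensitive block copy, recent tandem
    arrays (geometric sizes, mostly pairs), occasional transpositions, and a
    miRNA interactome tilted toward duplicated R-genes.
    """

    seed: int = 0
    n_anc_chr: int = 5
    genes_per_chr: int = 200
    r_fraction: float = 0.08
    domain_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DOMAIN_FREQS)
    )
    wgd: bool = True
    retention_rate: float = 0.22  # background genes, duplicate co-retention
    r_retention_rate: float = 0.06  # R-genes are diploidization-sensitive
    dominance_bias: float = 0.35
    tandem_rate: float = 0.25
    tandem_geom_p: float = 0.55
    ssd_rate: float = 0.15
    species_loss: float = 0.08
    n_species: int = 4
    divergence: Mapping[str, float] | None = None
    n_mirna: int = 12
    targets_per_mirna: int = 8
    target_bias_duplicated: float = 0.75

    def __post_init__(self) -> None:
        fracs = {
            "r_fraction": self.r_fraction,
            "retention_rate": self.retention_rate,
            "r_retention_rate": self.r_retention_rate,
            "dominance_bias": self.dominance_bias,
            "tandem_rate": self.tandem_rate,
            "tandem_geom_p": self.tandem_geom_p,
            "ssd_rate": self.ssd_rate,
            "species_loss": self.species_loss,
            "target_bias_duplicated": self.target_bias_duplicated,
            **{f"domain_freqs[{k}]": v for k, v in self.domain_freqs.items()},
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_anc_chr * self.genes_per_chr <= 0:
            raise ValueError("degenerate config: no ancestral genes")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"SP{i + 1}" for i in range(self.n_species))

    @property
    def reference(self) -> str:
        return self.species[0]

    def species_divergence(self) -> dict[str, float]:
        if self.divergence is not None:
            return dict(self.divergence)
        # evenly spread expected identity loss, 3-12%
        return {
            sp: 0.03 + 0.09 * i / max(1, self.n_species - 1)
            for i, sp in enumerate(self.species)
        }


@dataclass(frozen=True)
class AncGene:
    anc_id: str
    anc_chr: str  # A1..Ak
    idx: int
    is_r: bool
    domains: frozenset[str]
    length: int  # transcript length, nt


@dataclass
class SpeciesGene:
    """One gene in one modern genome, with its true lineage."""

    gene_id: str
    species: str
    chromosome: str
    anc_locus: str  # ancestral gene id, or parent locus for duplicates
    copy: int  # WGD copy (1 dominant, 2 sensitive; 0 if no WGD)
    origin: str  # wgd | tandem | ssd
    is_r: bool
    domains: frozenset[str]
    length: int


@dataclass
class EvolvedCohort:
    config: SimConfig
    genomes: dict[str, list[GeneModel]]
    genes: dict[str, SpeciesGene]  # by gene id, all species
    r_ids: dict[str, set[str]]
    anc_r_loci: dict[str, frozenset[str]]  # ancestral R locus -> domains
    truth_orthology: dict[str, dict[str, list[str]]]  # locus -> sp -> ids
    truth_clusters: list[tuple[str, tuple[str, ...]]]
    truth_dup_class: dict[frozenset, str]
    truth_block_labels: dict[tuple[str, str], str]  # (species, chrom) -> status
    anc_map: AncestralMap
    homology: dict[tuple[str, str], pd.DataFrame]
    annotation_ids: dict[str, list[str]]
    pfam_hits: dict[str, list[DomainHit]]
    prgdb_pairs: dict[str, list[HspSet]]
    transcripts: dict[str, str]
    mirnas: list[MatureMiRNA]
    truth_targets: list[tuple[str, str, int, float]]

    @property
    def species(self) -> tuple[str, ...]:
        return self.config.species

    def duplicated_r_ids(self, species: str) -> set[str]:
        """R-genes that are part of any duplication (tandem, SSD, or a
        retained WGD pair)."""
        dup: set[str] = set()
        for pair in self.truth_dup_class:
            dup |= set(pair)
        for _, members in self.truth_clusters:
            dup |= set(members)
        return dup & {g for g in self.r_ids[species]}


# ---------------------------------------------------------------------------
# stage 1: ancestor
# ---------------------------------------------------------------------------

def simulate_ancestor(config: SimConfig) -> list[AncGene]:
    """Draw the ancestral genome: genes in order on protochromosomes, each
    independently an R-gene with probability ``r_fraction``."""
    rng = np.random.default_rng(seed_for(config.seed, "ancestor"))
    genes: list[AncGene] = []
    fams = [f for f in FAMILIES if f in config.domain_freqs]
    probs = np.array([config.domain_freqs[f] for f in fams])
    for k in range(config.n_anc_chr):
        is_r = rng.random(config.genes_per_chr) < config.r_fraction
        lengths = rng.integers(150, 601, size=config.genes_per_chr)
        for i in range(config.genes_per_chr):
            domains: frozenset[str] = frozenset()
            if is_r[i]:
                while not domains:
                    draw = rng.random(len(fams)) < probs
                    domains = frozenset(f for f, d in zip(fams, draw) if d)
            genes.append(
                AncGene(
                    anc_id=f"ANC{k + 1:02d}_{i:04d}",
                    anc_chr=f"A{k + 1}",
                    idx=i,
                    is_r=bool(is_r[i]),
                    domains=domains,
                    length=int(lengths[i]),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# stage 2: WGD + biased diploidization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtoGene:
    anc: AncGene
    copy: int  # 1 dominant, 2 sensitive, 0 no WGD
    chromosome: str


def apply_wgd_and_diploidize(
    ancestor: Sequence[AncGene], config: SimConfig
) -> tuple[list[ProtoGene], dict[str, str]]:
    """Duplicate the ancestor and delete one copy of most genes.

    Each gene survives as a retained pair with probability
    ``retention_rate`` (``r_retention_rate`` for R-genes, which behave as
    diploidization-sensitive); otherwise one copy is deleted — the sensitive
    one with probability 0.5 + dominance_bias/2. Returns the diploidized
    proto-genome (the cohort's common ancestor) and the chromosome ->
    dominant/sensitive truth labels.
    """
    if not config.wgd:
        proto = [
            ProtoGene(anc=g, copy=0, chromosome=g.anc_chr.replace("A", "c"))
            for g in ancestor
        ]
        labels = {g.chromosome: "unknown" for g in proto}
        return proto, labels

    rng = np.random.default_rng(seed_for(config.seed, "wgd"))
    p_lose_sensitive = 0.5 + config.dominance_bias / 2.0
    proto: list[ProtoGene] = []
    labels: dict[str, str] = {}
    for g in ancestor:
        k = g.anc_chr[1:]
        chrom_d, chrom_s = f"c{k}d", f"c{k}s"
        labels[chrom_d] = "dominant"
        labels[chrom_s] = "sensitive"
        retain = config.r_retention_rate if g.is_r else config.retention_rate
        if rng.random() < retain:
            proto.append(ProtoGene(anc=g, copy=1, chromosome=chrom_d))
            proto.append(ProtoGene(anc=g, copy=2, chromosome=chrom_s))
        elif rng.random() < p_lose_sensitive:
            proto.append(ProtoGene(anc=g, copy=1, chromosome=chrom_d))
        else:
            proto.append(ProtoGene(anc=g, copy=2, chromosome=chrom_s))
    return proto, labels


# ---------------------------------------------------------------------------
# stage 3: speciation, tandem arrays, transpositions
# ---------------------------------------------------------------------------

def apply_tandem_duplications(
    ordered: list[SpeciesGene], config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, tuple[str, ...]]]:
    """Grow tandem arrays in place: each R-gene seeds an array with
    probability ``tandem_rate``; the array size is 1 + Geometric(p).
    Returns the planted arrays (size >= 2) as ground truth."""
    planted: list[tuple[str, tuple[str, ...]]] = []
    i = 0
    while i < len(ordered):
        g = ordered[i]
        if g.is_r and g.origin == "wgd" and rng.random() < config.tandem_rate:
            n_copies = int(rng.geometric(config.tandem_geom_p))
            copies = []
            for c in range(n_copies):
                copies.append(
                    SpeciesGene(
                        gene_id=f"{g.gene_id}t{c + 1}",
                        species=g.species,
                        chromosome=g.chromosome,
                        anc_locus=g.anc_locus,
                        copy=g.copy,
                        origin="tandem",
                        is_r=True,
                        domains=g.domains,
                        length=g.length,
                    )
                )
            ordered[i + 1: i + 1] = copies
            planted.append((g.species, tuple([g.gene_id] + [c.gene_id for c in copies])))
            i += 1 + n_copies
        else:
            i += 1
    return planted


def apply_transpositions(
    by_chrom: dict[str, list[SpeciesGene]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Copy some R-genes to random distant positions (single-gene
    duplications). Returns (parent, copy) gene-id pairs.

    Destinations exclude the parent's WGD-partner chromosome: a copy landing
    inside the paralogous block would carry genuinely segmental-like
    flanking context, and the generator's planted single-gene duplications
    are meant to be unambiguous ground truth for the flanking-window
    classifier."""
    pairs: list[tuple[str, str]] = []
    chroms = sorted(by_chrom)
    swap = {"d": "s", "s": "d"}
    parents = [
        g
        for chrom in chroms
        for g in by_chrom[chrom]
        if g.is_r and g.origin == "wgd"
    ]
    for g in parents:
        if rng.random() >= config.ssd_rate:
            continue
        partner = g.chromosome[:-1] + swap.get(g.chromosome[-1], g.chromosome[-1])
        allowed = [c for c in chroms if c != partner] or chroms
        dest = allowed[int(rng.integers(len(allowed)))]
        pos = int(rng.integers(len(by_chrom[dest]) + 1))
        copy = SpeciesGene(
            gene_id=f"{g.gene_id}x",
            species=g.species,
            chromosome=dest,
            anc_locus=g.anc_locus,
            copy=g.copy,
            origin="ssd",
            is_r=True,
            domains=g.domains,
            length=g.length,
        )
        by_chrom[dest].insert(pos, copy)
        pairs.append((g.gene_id, copy.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# homology emission
# ---------------------------------------------------------------------------

def _hsp_row(
    q: SpeciesGene, s: SpeciesGene, identity: float, aln_frac: float
) -> dict:
    aln = max(30, int(round(aln_frac * min(q.length, s.length))))
    n_id = int(round(identity / 100.0 * aln))
    evalue = 10.0 ** -(max(identity - 20.0, 3.0))
    return {
        "query": q.gene_id,
        "subject": s.gene_id,
        "pct_identity": round(100.0 * n_id / aln, 2),
        "aln_length": aln,
        "mismatches": aln - n_id,
        "gapopen": 0,
        "qstart": 1,
        "qend": aln,
        "sstart": 1,
        "send": aln,
        "evalue": evalue,
        "bitscore": round(2.0 * n_id, 1),
    }


def emit_homology_tables(
    genes: Mapping[str, SpeciesGene],
    truth_orthology: Mapping[str, Mapping[str, list[str]]],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Emit BLAST-tabular-like HSP tables per species pair (and within
    species).

    True same-locus pairs receive identities well above the calling
    thresholds, decaying with configured divergence; a sprinkling of
    unrelated pairs receives sub-threshold noise rows.
    """
    div = config.species_divergence()
    species = config.species
    rows: dict[tuple[str, str], list[dict]] = {}

    def add(key: tuple[str, str], q: SpeciesGene, s: SpeciesGene, ident: float):
        if ident >= 100.0:  # undiverged pair: exact full-length perfect HSP
            ident, aln_frac = 100.0, 1.0
        else:
            ident = float(np.clip(ident + rng.normal(0, 1.0), 35.0, 100.0))
            aln_frac = float(rng.uniform(0.93, 1.0))
        rows.setdefault(key, []).append(_hsp_row(q, s, ident, aln_frac))

    # extra divergence accumulated by a copy since leaving the shared path
    def extra(g: SpeciesGene) -> float:
        if g.origin == "tandem":
            return 0.035
        if g.origin == "ssd":
            return 0.05
        return 0.0

    for locus in sorted(truth_orthology):
        per_sp = truth_orthology[locus]
        # cross-species: divergence of both species plus copy-specific extras
        for i, sp_a in enumerate(species):
            for sp_b in species[i + 1:]:
                for qa in per_sp.get(sp_a, []):
                    for sb in per_sp.get(sp_b, []):
                        q, s = genes[qa], genes[sb]
                        ident = 100.0 * (
                            1.0 - div[sp_a] - div[sp_b] - extra(q) - extra(s)
                        )
                        add((sp_a, sp_b), q, s, ident)
        # within-species: identity reflects time since the duplication event
        for sp in species:
            ids = per_sp.get(sp, [])
            for a_i, ga in enumerate(ids):
                for gb in ids[a_i + 1:]:
                    q, s = genes[ga], genes[gb]
                    if q.origin == "tandem" or s.origin == "tandem":
                        ident = 100.0 * (1.0 - rng.uniform(0.03, 0.10))
                    elif q.origin == "ssd" or s.origin == "ssd":
                        ident = 100.0 * (1.0 - rng.uniform(0.08, 0.18))
                    else:  # retained WGD pair, duplicated before speciation
                        ident = 100.0 * (1.0 - rng.uniform(0.12, 0.20))
                    add((sp, sp), q, s, ident)

    # unrelated-pair noise, guaranteed sub-threshold for calling (CIP < 60)
    all_ids = sorted(genes)
    n_noise = max(10, len(all_ids) // 20)
    for _ in range(n_noise):
        qa, sb = rng.choice(len(all_ids), size=2, replace=False)
        q, s = genes[all_ids[qa]], genes[all_ids[sb]]
        key = tuple(sorted((q.species, s.species)))
        if q.species == key[1] and q.species != s.species:
            q, s = s, q
        ident = float(rng.uniform(25.0, 40.0))
        aln_frac = float(rng.uniform(0.2, 0.5))
        row = _hsp_row(q, s, ident, aln_frac)
        row["evalue"] = 10.0 ** -float(rng.uniform(2.0, 8.0))
        rows.setdefault(key, []).append(row)

    out = {}
    for key in sorted(rows):
        df = pd.DataFrame(rows[key], columns=list(BLAST_COLUMNS))
        out[key] = df.sort_values(["query", "subject"], kind="stable").reset_index(
            drop=True
        )
    return out


# ---------------------------------------------------------------------------
# evidence streams
# ---------------------------------------------------------------------------

def _emit_evidence(
    genes: Mapping[str, SpeciesGene],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[str]], dict[str, list[DomainHit]], dict[str, list[HspSet]]]:
    """Emit the three catalog evidence streams with realistic imperfection:
    PFAM misses a small fraction of domains and includes sub-threshold
    decoys; annotation and database coverage are partial."""
    from .catalog import PFAM_TO_FAMILY

    fam_to_pfam: dict[str, str] = {}
    for acc, fam in PFAM_TO_FAMILY.items():
        fam_to_pfam.setdefault(fam, acc)

    annotation: dict[str, list[str]] = {sp: [] for sp in config.species}
    pfam: dict[str, list[DomainHit]] = {sp: [] for sp in config.species}
    prgdb: dict[str, list[HspSet]] = {sp: [] for sp in config.species}
    prg_counter = 0
    for gid in sorted(genes):
        g = genes[gid]
        if not g.is_r:
            continue
        pfam_fams = [f for f in sorted(g.domains) if f != "RG"]
        for fam in pfam_fams:
            if rng.random() < 0.92:
                pfam[g.species].append(
                    DomainHit(
                        gene_id=gid,
                        family=fam,
                        source="pfam",
                        evalue=10.0 ** -float(rng.uniform(15.0, 60.0)),
                        profile=fam_to_pfam[fam],
                    )
                )
            if rng.random() < 0.03:  # weak extra hit, removed by the 1e-10 cut
                pfam[g.species].append(
                    DomainHit(
                        gene_id=gid,
                        family=fam,
                        source="pfam",
                        evalue=10.0 ** -float(rng.uniform(3.0, 9.0)),
                        profile=fam_to_pfam[fam],
                    )
                )
        rg_only = not pfam_fams
        p_annot = 0.8 if rg_only else 0.4
        p_prg = 0.5 if rg_only else 0.3
        if rng.random() < p_annot:
            annotation[g.species].append(gid)
        if rng.random() < p_prg:
            prg_counter += 1
            qlen = int(rng.integers(150, 400))
            aln = int(round(qlen * rng.uniform(0.85, 1.0)))
            ident = rng.uniform(0.75, 0.95)
            prgdb[g.species].append(
                HspSet(
                    query=f"PRG{prg_counter:04d}",
                    subject=gid,
                    hsps=(
                        Hsp(
                            n_identities=int(round(ident * aln)),
                            aln_len=aln,
                            qstart=1,
                            qend=aln,
                        ),
                    ),
                    query_len=qlen,
                    best_evalue=1e-40,
                )
            )
    return annotation, pfam, prgdb


# ---------------------------------------------------------------------------
# miRNA planting
# ---------------------------------------------------------------------------

_DNA = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_DNA, size=length).tobytes().decode()


def _mutate_site(
    site: list[str], mir: str, budget: float, rng: np.random.Generator
) -> float:
    """Apply mutations worth exactly ``budget`` penalty units to a perfect
    site (non-seed miRNA positions only, so each mismatch costs 1.0 and
    each wobble 0.5). Site is 5'->3'; miRNA position p pairs site index
    len-p. Returns the realized score."""
    m = len(mir)
    non_seed = [p for p in range(1, m + 1) if not (2 <= p <= 13)]
    rng.shuffle(non_seed)
    spent = 0.0
    for p in non_seed:
        if spent >= budget:
            break
        si = m - p  # 0-based site index pairing miRNA position p
        base = mir[p - 1]
        want_wobble = (budget - spent == 0.5) or (
            base in "GU" and rng.random() < 0.4 and budget - spent >= 0.5
        )
        if want_wobble and base == "G":
            site[si] = "T"  # G:U wobble
            spent += 0.5
        elif want_wobble and base == "U":
            site[si] = "G"
            spent += 0.5
        elif budget - spent >= 1.0:
            # mismatch: any base that is neither complement nor wobble
            bad = {"A": "AG", "C": "CT", "G": "AG", "U": "CT"}[base]
            site[si] = bad[int(rng.integers(len(bad)))]
            spent += 1.0
    return spent


def plant_mirna_targets(
    genes: Mapping[str, SpeciesGene],
    transcripts: dict[str, str],
    duplicated: set[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[MatureMiRNA], list[tuple[str, str, int, float]]]:
    """Generate mature miRNAs and insert target sites into transcripts.

    Each planted site is the reverse complement of its miRNA carrying 0-3
    penalty units of mutations; targets fall on duplicated R-genes with
    probability ``target_bias_duplicated``, otherwise uniformly on R-genes.
    """
    r_ids = sorted(gid for gid, g in genes.items() if g.is_r)
    dup_ids = sorted(set(r_ids) & duplicated)
    mirnas = [
        MatureMiRNA(mirna_id=f"miR{i + 1:03d}", seq=_random_seq(21, rng).replace("T", "U"))
        for i in range(config.n_mirna)
    ]
    occupied: dict[str, list[tuple[int, int]]] = {}
    truth: list[tuple[str, str, int, float]] = []
    for mir in mirnas:
        chosen: set[str] = set()
        for _ in range(config.targets_per_mirna):
            pool = dup_ids if (dup_ids and rng.random() < config.target_bias_duplicated) else r_ids
            for _attempt in range(20):
                gid = pool[int(rng.integers(len(pool)))]
                if gid in chosen:
                    continue
                seq = transcripts[gid]
                m = len(mir.seq)
                if len(seq) < m + 10:
                    continue
                start0 = int(rng.integers(len(seq) - m + 1))
                span = (start0, start0 + m)
                if any(a < span[1] and span[0] < b for a, b in occupied.get(gid, [])):
                    continue
                site = list(revcomp(mir.seq).replace("U", "T"))
                budget = 0.5 * int(rng.integers(0, 7))  # 0.0 .. 3.0
                score = _mutate_site(site, mir.seq, budget, rng)
                transcripts[gid] = (
                    seq[:start0] + "".join(site) + seq[start0 + m:]
                )
                occupied.setdefault(gid, []).append(span)
                chosen.add(gid)
                truth.append((mir.mirna_id, gid, start0 + 1, score))
                break
    return mirnas, truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig | None = None) -> EvolvedCohort:
    """Run the full forward simulation and collect every ground truth."""
    config = config or SimConfig()
    ancestor = simulate_ancestor(config)
    proto, block_labels = apply_wgd_and_diploidize(ancestor, config)

    genes: dict[str, SpeciesGene] = {}
    genomes: dict[str, list[GeneModel]] = {}
    r_ids: dict[str, set[str]] = {}
    truth_orthology: dict[str, dict[str, list[str]]] = {}
    truth_clusters: list[tuple[str, tuple[str, ...]]] = []
    truth_dup_class: dict[frozenset, str] = {}
    truth_block_labels: dict[tuple[str, str], str] = {}
    anc_rows: list[dict] = []

    for sp in config.species:
        rng = np.random.default_rng(seed_for(config.seed, f"species:{sp}"))
        counter = 0
        by_chrom: dict[str, list[SpeciesGene]] = {}
        present: dict[tuple[str, int], SpeciesGene] = {}
        for pg in proto:
            if rng.random() < config.species_loss:
                continue
            counter += 1
            sg = SpeciesGene(
                gene_id=f"{sp}_{counter:05d}",
                species=sp,
                chromosome=pg.chromosome,
                anc_locus=pg.anc.anc_id,
                copy=pg.copy,
                origin="wgd",
                is_r=pg.anc.is_r,
                domains=pg.anc.domains,
                length=pg.anc.length,
            )
            by_chrom.setdefault(pg.chromosome, []).append(sg)
            present[(pg.anc.anc_id, pg.copy)] = sg

        # retained WGD pairs of R-genes are the segmental-duplication truth
        for (locus, copy), sg in present.items():
            if sg.is_r and copy == 1 and (locus, 2) in present:
                truth_dup_class[
                    frozenset((sg.gene_id, present[(locus, 2)].gene_id))
                ] = "segmental"

        for chrom in sorted(by_chrom):
            truth_clusters.extend(
                apply_tandem_duplications(by_chrom[chrom], config, rng)
            )
        for parent, copy_id in apply_transpositions(by_chrom, config, rng):
            truth_dup_class[frozenset((parent, copy_id))] = "single_gene"

        # lay out coordinates and freeze gene models
        models: list[GeneModel] = []
        for chrom in sorted(by_chrom):
            pos = 1
            for sg in by_chrom[chrom]:
                genes[sg.gene_id] = sg
                models.append(
                    GeneModel(
                        gene_id=sg.gene_id,
                        species=sp,
                        chromosome=chrom,
                        start=pos,
                        end=pos + sg.length - 1,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                pos += sg.length + 500
                truth_orthology.setdefault(sg.anc_locus, {}).setdefault(
                    sp, []
                ).append(sg.gene_id)
                # only syntenic (WGD-path) genes have an ancestral placement;
                # lineage-specific tandem/SSD copies do not
                if sg.origin == "wgd":
                    anc_chr = "A" + str(int(sg.anc_locus[3:5]))
                    anc_rows.append(
                        {
                            "species": sp,
                            "gene_id": sg.gene_id,
                            "anc_chr": anc_chr,
                            "block_id": (
                                f"{anc_chr}.{sg.copy}" if sg.copy else anc_chr
                            ),
                            "block_status": block_labels.get(
                                sg.chromosome, "unknown"
                            ),
                        }
                    )
        genomes[sp] = assign_ranks(models)
        r_ids[sp] = {sg.gene_id for sg in genes.values() if sg.species == sp and sg.is_r}
        for chrom, status in block_labels.items():
            truth_block_labels[(sp, chrom)] = status

    rng_hom = np.random.default_rng(seed_for(config.seed, "homology"))
    homology = emit_homology_tables(genes, truth_orthology, config, rng_hom)

    rng_ev = np.random.default_rng(seed_for(config.seed, "evidence"))
    annotation_ids, pfam_hits, prgdb_pairs = _emit_evidence(genes, config, rng_ev)

    rng_tx = np.random.default_rng(seed_for(config.seed, "transcripts"))
    transcripts = {
        gid: _random_seq(genes[gid].length, rng_tx) for gid in sorted(genes)
    }
    duplicated: set[str] = set()
    for pair in truth_dup_class:
        duplicated |= set(pair)
    for _, members in truth_clusters:
        duplicated |= set(members)
    rng_mir = np.random.default_rng(seed_for(config.seed, "mirna"))
    mirnas, truth_targets = plant_mirna_targets(
        genes, transcripts, duplicated, config, rng_mir
    )

    anc_r_loci = {
        g.anc_id: g.domains for g in ancestor if g.is_r
    }
    return EvolvedCohort(
        config=config,
        genomes=genomes,
        genes=genes,
        r_ids=r_ids,
        anc_r_loci=anc_r_loci,
        truth_orthology=truth_orthology,
        truth_clusters=truth_clusters,
        truth_dup_class=truth_dup_class,
        truth_block_labels=truth_block_labels,
        anc_map=AncestralMap(pd.DataFrame(anc_rows, columns=list(AncestralMap.COLUMNS))),
        homology=homology,
        annotation_ids=annotation_ids,
        pfam_hits=pfam_hits,
        prgdb_pairs=prgdb_pairs,
        transcripts=transcripts,
        mirnas=mirnas,
        truth_targets=truth_targets,
    )


def simulate_block_pairs(
    n_pairs: int,
    n_anc: int,
    retention_rate: float,
    dominance_bias: float,
    seed: int | None = None,
) -> list[DuplicatedBlockPair]:
    """Simulate duplicated block pairs directly (no genome context): each of
    ``n_anc`` ancestral R-genes is retained as a pair with probability
    ``retention_rate`` or loses its sensitive copy with probability
    0.5 + dominance_bias/2. Used for calibration and power studies of the
    retention test."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_pairs):
        both = rng.random(n_anc) < retention_rate
        lose_sensitive = rng.random(n_anc) < 0.5 + dominance_bias / 2.0
        n1 = int(both.sum() + (~both & lose_sensitive).sum())  # dominant copy
        n2 = int(both.sum() + (~both & ~lose_sensitive).sum())
        out.append(
            DuplicatedBlockPair(
                anc_chr_pair=(f"B{i}.1", f"B{i}.2"),
                n_anc=n_anc,
                n1=n1,
                n2=n2,
                status_pair=("dominant", "sensitive"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cohort(cohort: EvolvedCohort, outdir: str | Path) -> Path:
    """Write the cohort as the pipeline's on-disk input layout.

    Per species: GFF3, transcript FASTA, annotation id list, PFAM domtblout
    and database-alignment TSV; per species pair: HSP TSV; plus ancestral
    map, miRNA FASTA, truth tables, and a manifest recording the config.
    Deterministic: same cohort, byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in cohort.species:
        write_gff3(cohort.genomes[sp], outdir / f"{sp}.gff3")
        with open(outdir / f"{sp}.transcripts.fasta", "w") as fh:
            for g in cohort.genomes[sp]:
                fh.write(f">{g.gene_id}\n{cohort.transcripts[g.gene_id]}\n")
        with open(outdir / f"{sp}.annotation_rgenes.txt", "w") as fh:
            fh.writelines(f"{gid}\n" for gid in cohort.annotation_ids[sp])
        write_domtblout(cohort.pfam_hits[sp], outdir / f"{sp}.domtblout")
        prg_rows = []
        for pair in cohort.prgdb_pairs[sp]:
            h = pair.hsps[0]
            prg_rows.append(
                {
                    "query": pair.query,
                    "subject": pair.subject,
                    "pct_identity": round(100.0 * h.n_identities / h.aln_len, 2),
                    "aln_length": h.aln_len,
                    "mismatches": h.aln_len - h.n_identities,
                    "gapopen": 0,
                    "qstart": h.qstart,
                    "qend": h.qend,
                    "sstart": 1,
                    "send": h.aln_len,
                    "evalue": pair.best_evalue,
                    "bitscore": round(2.0 * h.n_identities, 1),
                }
            )
        write_blast_tab(
            pd.DataFrame(prg_rows, columns=list(BLAST_COLUMNS)),
            outdir / f"{sp}.prgdb.tsv",
        )
        with open(outdir / f"{sp}.prgdb_query_lengths.tsv", "w") as fh:
            fh.write("query\tlength\n")
            for pair in cohort.prgdb_pairs[sp]:
                fh.write(f"{pair.query}\t{pair.query_len}\n")
    for (a, b), df in sorted(cohort.homology.items()):
        write_blast_tab(df, outdir / f"homology.{a}-{b}.tsv")
    cohort.anc_map.write_tsv(outdir / "ancestral_map.tsv")
    with open(outdir / "mirna.fasta", "w") as fh:
        for mir in cohort.mirnas:
            fh.write(f">{mir.mirna_id}\n{mir.seq}\n")

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {"anc_locus": locus, "species": sp, "gene_id": gid}
            for locus in sorted(cohort.truth_orthology)
            for sp in sorted(cohort.truth_orthology[locus])
            for gid in cohort.truth_orthology[locus][sp]
        ]
    ).to_csv(truth_dir / "orthology.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"species": sp, "members": ",".join(members)}
            for sp, members in cohort.truth_clusters
        ]
    ).to_csv(truth_dir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_a": min(p), "gene_b": max(p), "class": c}
            for p, c in sorted(
                cohort.truth_dup_class.items(), key=lambda kv: sorted(kv[0])
            )
        ]
    ).to_csv(truth_dir / "dup_class.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"mirna_id": m, "gene_id": g, "site_start": s, "score": sc}
            for m, g, s, sc in cohort.truth_targets
        ]
    ).to_csv(truth_dir / "targets.tsv", sep="\t", index=False)

    cfg = dataclasses.asdict(cohort.config)
    cfg["domain_freqs"] = dict(cfg["domain_freqs"])
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"sim_config": cfg}, fh, sort_keys=True)
    return outdir
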