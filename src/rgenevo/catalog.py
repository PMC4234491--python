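"""Non-redundant R-gene catalog construction and domain-architecture classing.

Three evidence streams are merged: public genome annotation, PFAM domain
scans (hmmsearch hits at an independent-E-value cut of 1e-10), and alignments
of a curated resistance-gene database accepted at CIP/CALP >= 70/70. Each
catalog entry carries its R-domain set and is classified into a structural
class (TNL, CNL, RLK, RLP, RGA) and a functional group (PTI, ETI,
R-combination, R-pathway).

CIP (cumulative identity percentage) and CALP (cumulative alignment-length
percentage) summarize all HSPs of one query/subject pair:

    CIP  = 100 * sum(identities) / sum(alignment lengths)
    CALP = 100 * sum(alignment lengths) / query length

HSPs overlapping an already-retained HSP on the query by more than 10% of
their own span are discarded before summation, which keeps repeated local
alignments from inflating CALP past 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

#: The seven R-domain families tracked by the pipeline. ``RG`` marks genes
#: supported only by database/annotation evidence, with no PFAM domain.
FAMILIES = ("LRR", "NBS", "TIR", "LysM", "PKinase", "WRKY", "RG")

#: PFAM profile accession -> R-domain family.
PFAM_TO_FAMILY = {
    "PF00560": "LRR",
    "PF07723": "LRR",
    "PF07725": "LRR",
    "PF12799": "LRR",
    "PF01463": "LRR",
    "PF08263": "LRR",
    "PF00931": "NBS",  # NB-ARC
    "PF01582": "TIR",
    "PF01476": "LysM",
    "PF00069": "PKinase",
    "PF03106": "WRKY",
}

R_CLASSES = ("TNL", "CNL", "RLK", "RLP", "RGA", "none")
GROUPS = ("PTI", "ETI", "R-combination", "R-pathway")


@dataclass(frozen=True)
class DomainHit:
    """One domain-evidence row for a gene (PFAM scan, annotation, or the
    resistance-gene database)."""

    gene_id: str
    family: str
    source: str  # pfam | annotation | prgdb
    evalue: float | None = None
    profile: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown R-domain family {self.family!r}")
        if self.source not in {"pfam", "annotation", "prgdb"}:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if self.source == "pfam" and self.evalue is None:
            raise ValueError("pfam hits must carry an E-value")


@dataclass(frozen=True)
class Hsp:
    """One local alignment block (identities over an aligned span)."""

    n_identities: int
    aln_len: int
    qstart: int
    qend: int

    def __post_init__(self) -> None:
        if not (self.aln_len >= self.n_identities > 0):
            raise ValueError(
                f"HSP requires aln_len >= n_identities > 0, "
                f"got {self.n_identities}/{self.aln_len}"
            )


@dataclass(frozen=True)
class HspSet:
    """All HSPs of one query/subject pair, the unit CIP/CALP is computed on."""

    query: str
    subject: str
    hsps: tuple[Hsp, ...]
    query_len: int
    best_evalue: float = 0.0


@dataclass(frozen=True)
class RGeneRecord:
    """A cataloged R-gene: gene model, domain set, evidence sources, class."""

    gene: GeneModel
    domains: frozenset[str]
    sources: frozenset[str]
    r_class: str
    group: str

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"{self.gene.gene_id}: empty domain set")


# ---------------------------------------------------------------------------
# CIP / CALP
# ---------------------------------------------------------------------------

def compute_cip_calp(
    hspset: HspSet, max_overlap_frac: float = 0.1
) -> tuple[float, float]:
    """Compute (CIP, CALP) for one query/subject HSP set, both on a 0-100
    scale.

    HSPs are considered in input order (BLAST emits best-first); an HSP whose
    query-span overlap with any previously retained HSP exceeds
    ``max_overlap_frac`` of its own span is discarded. CALP is clamped at 100
    (with a logged warning) if residual overlaps still push it over.
    """
    if not hspset.hsps:
        raise ValueError(f"{hspset.query}/{hspset.subject}: empty HSP list")
    if hspset.query_len <= 0:
        raise ValueError(f"{hspset.query}: non-positive query length")
    retained: list[Hsp] = []
    for h in hspset.hsps:
        span = h.qend - h.qstart + 1
        overlap_ok = True
        for kept in retained:
            ov = min(h.qend, kept.qend) - max(h.qstart, kept.qstart) + 1
            if ov > max_overlap_frac * span:
                overlap_ok = False
                break
        if overlap_ok:
            retained.append(h)
    tot_id = sum(h.n_identities for h in retained)
    tot_len = sum(h.aln_len for h in retained)
    cip = 100.0 * tot_id / tot_len
    calp = 100.0 * tot_len / hspset.query_len
    if calp > 100.0:
        logger.warning(
            "%s/%s: CALP %.2f > 100 after overlap filtering; clamped",
            hspset.query,
            hspset.subject,
            calp,
        )
        calp = 100.0
    return cip, calp


def hspsets_from_blast(
    df: pd.DataFrame, query_lengths: Mapping[str, int]
) -> list[HspSet]:
    """Group raw BLAST tabular rows into per-(query, subject) HSP sets.

    Identity counts are recovered from ``pct_identity * aln_length``
    (rounded), which is exact for the integer counts BLAST reports.
    """
    sets: list[HspSet] = []
    for (q, s), grp in df.groupby(["query", "subject"], sort=True):
        if q not in query_lengths:
            raise KeyError(f"no query length for {q}")
        hsps = tuple(
            Hsp(
                n_identities=int(round(r.pct_identity * r.aln_length / 100.0)),
                aln_len=int(r.aln_length),
                qstart=int(r.qstart),
                qend=int(r.qend),
            )
            for r in grp.itertuples(index=False)
        )
        sets.append(
            HspSet(
                query=q,
                subject=s,
                hsps=hsps,
                query_len=int(query_lengths[q]),
                best_evalue=float(grp["evalue"].min()),
            )
        )
    return sets


# ---------------------------------------------------------------------------
# evidence streams
# ---------------------------------------------------------------------------

def filter_pfam_hits(
    hits: Iterable[DomainHit], evalue_cut: float = 1e-10
) -> list[DomainHit]:
    """Keep PFAM hits at or below the independent-E-value cut (default 1e-10)."""
    out = []
    for h in hits:
        if h.evalue is None:
            raise ValueError(f"{h.gene_id}: pfam hit without E-value")
        if h.evalue <= evalue_cut:
            out.append(h)
    return out


def filter_prgdb_hits(
    pairs: Iterable[HspSet],
    cip_min: float = 70.0,
    calp_min: float = 70.0,
    target_side: str = "subject",
) -> set[str]:
    """Accept target genes hit by a database R-protein at CIP/CALP >= 70/70.

    Acceptance is per query/subject pair: HSPs are never pooled across
    different database proteins. ``target_side`` names which side of the pair
    is the proteome gene (database searches put the R-protein on the query).
    """
    if target_side not in {"query", "subject"}:
        raise ValueError("target_side must be 'query' or 'subject'")
    accepted: set[str] = set()
    for pair in pairs:
        cip, calp = compute_cip_calp(pair)
        if cip >= cip_min and calp >= calp_min:
            accepted.add(pair.subject if target_side == "subject" else pair.query)
    return accepted


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_rgene(domains: frozenset[str] | set[str]) -> tuple[str, str]:
    """Map a domain set to (structural class, functional group).

    Precedence:

    1. NBS and LRR         -> ETI; TNL when TIR is present, else CNL
       (the coiled-coil domain has no PFAM profile in the vocabulary, so
       CNL is operationalized as NBS-LRR without TIR).
    2. LysM                -> PTI; RLK with PKinase, else RLP.
    3. LRR without NBS     -> PTI; RLK with PKinase, else RLP.
    4. any NBS/TIR/RG left -> R-combination, class RGA.
    5. only WRKY/PKinase   -> R-pathway, no structural class.
    """
    d = set(domains)
    if not d:
        raise ValueError("empty domain set")
    unknown = d - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    if "NBS" in d and "LRR" in d:
        return ("TNL" if "TIR" in d else "CNL", "ETI")
    if "LysM" in d:
        return ("RLK" if "PKinase" in d else "RLP", "PTI")
    if "LRR" in d:  # no NBS here
        return ("RLK" if "PKinase" in d else "RLP", "PTI")
    if d & {"NBS", "TIR", "RG"}:
        return ("RGA", "R-combination")
    return ("none", "R-pathway")  # only WRKY and/or PKinase


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def merge_evidence(
    annotation_ids: Iterable[str],
    pfam_hits: Iterable[DomainHit],
    prgdb_ids: Iterable[str],
    genes: Mapping[str, GeneModel],
) -> list[RGeneRecord]:
    """Union the three evidence streams into a non-redundant catalog.

    Keyed by gene id; sources are recorded per gene. Genes with no PFAM
    domain (annotation/database evidence only) receive the ``RG`` family.
    Ids that do not resolve to a gene model are skipped with a warning.
    Idempotent: merging a catalog's own streams again reproduces it.
    """
    domains: dict[str, set[str]] = {}
    sources: dict[str, set[str]] = {}

    def _touch(gid: str, source: str) -> bool:
        if gid not in genes:
            logger.warning("%s: id not in annotation; skipped", gid)
            return False
        domains.setdefault(gid, set())
        sources.setdefault(gid, set()).add(source)
        return True

    for gid in annotation_ids:
        _touch(gid, "annotation")
    for hit in pfam_hits:
        if _touch(hit.gene_id, "pfam"):
            domains[hit.gene_id].add(hit.family)
    for gid in prgdb_ids:
        _touch(gid, "prgdb")

    records = []
    for gid in domains:
        dset = domains[gid] or {"RG"}
        r_class, group = classify_rgene(dset)
        records.append(
            RGeneRecord(
                gene=genes[gid],
                domains=frozenset(dset),
                sources=frozenset(sources[gid]),
                r_class=r_class,
                group=group,
            )
        )
    records.sort(key=lambda r: (r.gene.species, r.gene.chromosome, r.gene.rank))
    return records


def family_counts(records: Sequence[RGeneRecord]) -> dict[str, int]:
    """Per-family gene counts (a gene counts once per family it carries)."""
    counts = dict.fromkeys(FAMILIES, 0)
    for r in records:
        for fam in r.domains:
            counts[fam] += 1
    return counts
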