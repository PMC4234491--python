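"""Readers/writers for the external formats the pipeline touches.

Covers GFF3 gene models (via :mod:`gffutils`), 12-column BLAST tabular
(outfmt 6), HMMER3 ``--domtblout`` tables (via :mod:`Bio.SearchIO`), the
catalog TSV produced by :mod:`rgenevo.catalog`, and the two packaged summary
tables of published per-species counts that the acceptance checks rely on.

Coordinates are kept 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SearchIO

from ._util import FixtureError, ParseError

if TYPE_CHECKING:  # avoid a circular import at runtime
    from .catalog import DomainHit, RGeneRecord

logger = logging.getLogger(__name__)

#: Column names of NCBI BLAST tabular output, ``-outfmt 6`` defaults.
BLAST_COLUMNS = (
    "query",
    "subject",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

_FIXTURE_SHA256 = {
    "table1.tsv": "0abebe5967243033ee51a631955606dfa3365b2c75b99f65516154ce6b3906d8",
    "table2.tsv": "c5cdbf09bed4eed45e915e5d5b09f06100331f450b141cfc9eab248fce82043b",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GeneModel:
    """One annotated gene: location plus its within-chromosome rank.

    ``rank`` is the dense 0-based order of ``start`` within the chromosome
    (ties broken by ``gene_id``); gene order, not physical distance, drives
    cluster calling and flanking-window analyses downstream.
    """

    species: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    gene_id: str
    strand: str = "."
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ParseError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Table1Row:
    """Per-species published catalog counts (reference rows carry no
    conservation figures)."""

    species: str
    lineage: str
    n_chr: int
    n_gene: int
    n_annot: int
    n_pfam: int
    n_prgdb: int
    n_nonredundant: int
    n_ortho_rgene: int | None = None
    conservation_pct: float | None = None

    def __post_init__(self) -> None:
        if self.lineage not in {"monocot", "eudicot"}:
            raise ValueError(f"bad lineage {self.lineage!r}")
        if self.n_nonredundant > self.n_annot + self.n_pfam + self.n_prgdb:
            raise ValueError(
                f"{self.species}: non-redundant count exceeds stream sum"
            )
        if self.n_ortho_rgene is not None and self.n_ortho_rgene > self.n_nonredundant:
            raise ValueError(f"{self.species}: orthologs exceed catalog size")


@dataclass(frozen=True)
class Table2Row:
    """Per-species published miRNA-target counts, split by R-gene
    conservation, with the species' lineage-specific WGD round count."""

    species: str
    lineage: str
    wgd_rounds: int
    cons_targets: int
    cons_total: int
    noncons_targets: int
    noncons_total: int

    def __post_init__(self) -> None:
        if self.wgd_rounds not in {0, 1, 2}:
            raise ValueError(f"bad wgd_rounds {self.wgd_rounds}")
        if self.cons_targets > self.cons_total:
            raise ValueError(f"{self.species}: conserved targets exceed total")
        if self.noncons_targets > self.noncons_total:
            raise ValueError(f"{self.species}: non-conserved targets exceed total")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Assign dense 0-based ranks per chromosome, ordering by start
    (ties by gene_id). Returns a new list sorted by (chromosome, rank)."""
    out: list[GeneModel] = []
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault((g.species, g.chromosome), []).append(g)
    for key in sorted(by_chrom):
        ordered = sorted(by_chrom[key], key=lambda g: (g.start, g.gene_id))
        out.extend(replace(g, rank=i) for i, g in enumerate(ordered))
    return out


def _validate_gff3_lines(path: Path) -> int:
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end {end} < start {start}")
            n_features += 1
    return n_features


def read_gff3(path: str | Path, species: str | None = None) -> list[GeneModel]:
    """Read gene features from a GFF3 file into ranked :class:`GeneModel`\\ s.

    ``species`` defaults to the file stem. mRNA/transcript features are
    collapsed to their parent gene; only ``gene`` features produce records.
    Duplicate gene IDs within the file are an error.
    """
    path = Path(path)
    species = species if species is not None else path.stem
    if _validate_gff3_lines(path) == 0:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types
        raise ParseError(f"{path}: {exc}") from exc
    genes = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise ParseError(f"{path}: duplicate gene id {gid}")
        seen.add(gid)
        genes.append(
            GeneModel(
                gene_id=gid,
                species=species,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else ".",
            )
        )
    return assign_ranks(genes)


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene features as minimal GFF3 (one ``gene`` line per model)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\trgenevo\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read 12-column BLAST tabular output (``-outfmt 6``) into a typed frame."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=BLAST_COLUMNS,
            comment="#",
            dtype={
                "query": str,
                "subject": str,
                "pct_identity": float,
                "aln_length": "int64",
                "mismatches": "int64",
                "gapopen": "int64",
                "qstart": "int64",
                "qend": "int64",
                "sstart": "int64",
                "send": "int64",
                "evalue": float,
                "bitscore": float,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] != 12 or (len(df) and df["bitscore"].isna().any()):
        raise ParseError(f"{path}: expected 12 tab-separated columns")
    return df


def write_blast_tab(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(BLAST_COLUMNS))


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

def read_domtblout(path: str | Path, strict: bool = False) -> "list[DomainHit]":
    """Read an hmmsearch ``--domtblout`` table into per-domain hits.

    One :class:`~rgenevo.catalog.DomainHit` per domain row, carrying the
    independent (per-domain) E-value. Profiles outside the R-domain PFAM
    vocabulary are skipped (or rejected when ``strict``). No E-value filter
    is applied here; see :func:`rgenevo.catalog.filter_pfam_hits`.
    """
    from .catalog import PFAM_TO_FAMILY, DomainHit

    path = Path(path)
    hits: list[DomainHit] = []
    try:
        queries = list(SearchIO.parse(str(path), "hmmsearch3-domtab"))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for qres in queries:
        acc = (qres.accession or qres.id).split(".")[0].upper()
        family = PFAM_TO_FAMILY.get(acc)
        if family is None:
            if strict:
                raise ParseError(f"{path}: unknown PFAM profile {acc}")
            logger.debug("skipping non-R profile %s", acc)
            continue
        for hit in qres.hits:
            for hsp in hit.hsps:
                hits.append(
                    DomainHit(
                        gene_id=hit.id,
                        family=family,
                        source="pfam",
                        evalue=float(hsp.evalue),
                        profile=acc,
                    )
                )
    return hits


def write_domtblout(hits: "Iterable[DomainHit]", path: str | Path) -> None:
    """Write domain hits as a minimal, re-readable hmmsearch domtblout table.

    Alignment coordinates are placeholders; the fields the pipeline consumes
    (target gene, profile accession, independent E-value) are faithful.
    """
    header = (
        "#                                                               "
        "--- full sequence --- -------------- this domain -------------   "
        "hmm coord   ali coord   env coord\n"
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
        "i-Evalue  score  bias  from    to  from    to  from    to  acc "
        "description of target\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        grouped: dict[str, list] = {}
        for h in hits:
            grouped.setdefault(h.profile or "PF00000", []).append(h)
        for profile, rows in grouped.items():
            for h in rows:
                ev = h.evalue if h.evalue is not None else 1e-30
                fh.write(
                    f"{h.gene_id:<20s} -          100 {h.family:<20s} "
                    f"{profile}.1 100 {ev:9.2g} 100.0 0.0 1 1 "
                    f"{ev:9.2g} {ev:9.2g} 100.0 0.0 1 100 1 100 1 100 0.99 -\n"
                )


# ---------------------------------------------------------------------------
# catalog TSV
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = (
    "gene_id",
    "species",
    "chromosome",
    "start",
    "end",
    "strand",
    "rank",
    "domains",
    "sources",
    "r_class",
    "group",
)


def write_catalog_tsv(records: "Iterable[RGeneRecord]", path: str | Path) -> None:
    rows = []
    for r in records:
        g = r.gene
        rows.append(
            {
                "gene_id": g.gene_id,
                "species": g.species,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "rank": g.rank,
                "domains": ",".join(sorted(r.domains)),
                "sources": ",".join(sorted(r.sources)),
                "r_class": r.r_class,
                "group": r.group,
            }
        )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> "list[RGeneRecord]":
    from .catalog import RGeneRecord

    df = pd.read_csv(path, sep="\t", dtype=str)
    if tuple(df.columns) != CATALOG_COLUMNS:
        raise ParseError(f"{path}: unexpected catalog columns {tuple(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        gene = GeneModel(
            gene_id=row.gene_id,
            species=row.species,
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            rank=int(row.rank),
        )
        records.append(
            RGeneRecord(
                gene=gene,
                domains=frozenset(str(row.domains).split(",")),
                sources=frozenset(str(row.sources).split(",")),
                r_class=row.r_class,
                group=row.group,
            )
        )
    return records


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_bytes(name: str) -> bytes:
    data = resources.files("rgenevo.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureError(
            f"packaged fixture {name} failed its checksum "
            f"({digest} != {_FIXTURE_SHA256[name]})"
        )
    return data


def load_table_fixtures() -> tuple[list[Table1Row], list[Table2Row]]:
    """Load the packaged per-species published count tables.

    Returns 13 catalog/conservation rows and 13 miRNA-target rows; ``nd``
    entries in the source are stored as 0 and reference-species rows carry
    no conservation figures. Integrity is checked by SHA-256.
    """
    import io

    t1 = pd.read_csv(io.BytesIO(_fixture_bytes("table1.tsv")), sep="\t")
    t2 = pd.read_csv(io.BytesIO(_fixture_bytes("table2.tsv")), sep="\t")
    rows1 = [
        Table1Row(
            species=r.species,
            lineage=r.lineage,
            n_chr=int(r.n_chr),
            n_gene=int(r.n_gene),
            n_annot=int(r.n_annot),
            n_pfam=int(r.n_pfam),
            n_prgdb=int(r.n_prgdb),
            n_nonredundant=int(r.n_nonredundant),
            n_ortho_rgene=None if pd.isna(r.n_ortho_rgene) else int(r.n_ortho_rgene),
            conservation_pct=(
                None if pd.isna(r.conservation_pct) else float(r.conservation_pct)
            ),
        )
        for r in t1.itertuples(index=False)
    ]
    rows2 = [
        Table2Row(
            species=r.species,
            lineage=r.lineage,
            wgd_rounds=int(r.wgd_rounds),
            cons_targets=int(r.cons_targets),
            cons_total=int(r.cons_total),
            noncons_targets=int(r.noncons_targets),
            noncons_total=int(r.noncons_total),
        )
        for r in t2.itertuples(index=False)
    ]
    return rows1, rows2
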