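"""Positional R-gene cluster calling and within-cluster domain profiling.

A cluster is a maximal run of R-genes on one chromosome in which consecutive
members are separated by at most ``max_gap`` (default 8) intervening non-R
annotated genes. The gap is counted in genes (rank difference minus one),
not base pairs, and chaining is transitive: if A links to B and B to C, all
three form one cluster even if A and C alone would not link.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import RGeneRecord
from .io_formats import GeneModel

DEFAULT_MAX_GAP = 8


@dataclass(frozen=True)
class RCluster:
    cluster_id: str
    species: str
    chromosome: str
    members: tuple[str, ...]  # gene ids ordered by rank
    span_ranks: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


def call_clusters(
    genes: Iterable[GeneModel],
    r_ids: set[str],
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[RCluster], list[str]]:
    """Chain R-genes into clusters; return (clusters, singleton gene ids).

    ``genes`` must carry dense per-chromosome ranks (0..n-1); chains of a
    single R-gene are reported as singletons, chains of two or more as
    clusters. Chromosome boundaries are never spanned.
    """
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault((g.species, g.chromosome), []).append(g)

    clusters: list[RCluster] = []
    singletons: list[str] = []
    for (species, chrom), models in sorted(by_chrom.items()):
        models.sort(key=lambda g: g.rank)
        ranks = [g.rank for g in models]
        if ranks != list(range(len(models))):
            raise ValueError(
                f"{species}/{chrom}: ranks are not dense 0..{len(models) - 1}"
            )
        r_genes = [g for g in models if g.gene_id in r_ids]
        chain: list[GeneModel] = []
        for g in r_genes:
            if chain and g.rank - chain[-1].rank - 1 <= max_gap:
                chain.append(g)
            else:
                _emit(chain, species, chrom, clusters, singletons)
                chain = [g]
        _emit(chain, species, chrom, clusters, singletons)
    return clusters, singletons


def _emit(
    chain: list[GeneModel],
    species: str,
    chrom: str,
    clusters: list[RCluster],
    singletons: list[str],
) -> None:
    if not chain:
        return
    if len(chain) == 1:
        singletons.append(chain[0].gene_id)
        return
    clusters.append(
        RCluster(
            cluster_id=f"{species}:{chrom}:c{chain[0].rank}",
            species=species,
            chromosome=chrom,
            members=tuple(g.gene_id for g in chain),
            span_ranks=(chain[0].rank, chain[-1].rank),
        )
    )


@dataclass(frozen=True)
class ClusterTypology:
    species: str
    n_rgenes: int
    n_in_clusters: int
    size_histogram: tuple[tuple[int, int], ...]  # (size, count) sorted

    @property
    def pct_in_clusters(self) -> float:
        return 100.0 * self.n_in_clusters / self.n_rgenes if self.n_rgenes else 0.0

    @property
    def pct_size2(self) -> float:
        hist = dict(self.size_histogram)
        total = sum(hist.values())
        return 100.0 * hist.get(2, 0) / total if total else 0.0


def cluster_typology(
    clusters: Sequence[RCluster], catalog: Sequence[RGeneRecord]
) -> dict[str, ClusterTypology]:
    """Per-species clusterization statistics: share of R-genes in clusters
    and the cluster-size histogram."""
    n_r = Counter(r.gene.species for r in catalog)
    in_clusters: Counter[str] = Counter()
    sizes: dict[str, Counter[int]] = {}
    for c in clusters:
        in_clusters[c.species] += c.size
        sizes.setdefault(c.species, Counter())[c.size] += 1
    return {
        s: ClusterTypology(
            species=s,
            n_rgenes=n_r[s],
            n_in_clusters=in_clusters.get(s, 0),
            size_histogram=tuple(sorted(sizes.get(s, Counter()).items())),
        )
        for s in sorted(n_r)
    }


@dataclass(frozen=True)
class DomainComboProfile:
    combo_counts: tuple[tuple[tuple[str, ...], int], ...]
    pct_with_lrr: float
    lrr_partner_shares: tuple[tuple[str, float], ...]  # PKinase vs NBS


def domain_combination_profile(
    clusters: Sequence[RCluster],
    records_by_id: Mapping[str, RGeneRecord],
) -> DomainComboProfile:
    """Tally member domain combinations across clusters.

    Each clustered gene contributes its full domain combination (one multiset
    entry per member). Reports the share of combinations containing LRR and,
    among those, the relative preference for a PKinase vs an NBS partner —
    the "LRR as glue" pattern.
    """
    combos: Counter[tuple[str, ...]] = Counter()
    for c in clusters:
        for gid in c.members:
            rec = records_by_id.get(gid)
            if rec is None:
                continue
            combos[tuple(sorted(rec.domains))] += 1
    total = sum(combos.values())
    with_lrr = sum(n for combo, n in combos.items() if "LRR" in combo)
    lrr_pk = sum(
        n for combo, n in combos.items() if "LRR" in combo and "PKinase" in combo
    )
    lrr_nbs = sum(
        n for combo, n in combos.items() if "LRR" in combo and "NBS" in combo
    )
    partnered = lrr_pk + lrr_nbs
    shares = (
        ("PKinase", 100.0 * lrr_pk / partnered if partnered else 0.0),
        ("NBS", 100.0 * lrr_nbs / partnered if partnered else 0.0),
    )
    return DomainComboProfile(
        combo_counts=tuple(sorted(combos.items())),
        pct_with_lrr=100.0 * with_lrr / total if total else 0.0,
        lrr_partner_shares=shares,
    )
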