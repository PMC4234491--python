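"""Ortholog/paralog calling from HSP tables and conservation statistics.

Homologs are called on CIP/CALP thresholds (60/70 by default, inclusive);
no reciprocal-best-hit filtering is applied — every threshold-passing pair
counts, so one gene may have several orthologs. Conservation percentages use
the species' own gene counts as denominators, and enrichment of R-gene
conservation over background gene conservation is assessed with Fisher's
exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from scipy import stats

from .catalog import HspSet, compute_cip_calp


@dataclass(frozen=True)
class HomologyPair:
    query: str
    subject: str
    cip: float
    calp: float
    best_evalue: float
    relation: str  # ortholog | paralog | none


@dataclass(frozen=True)
class ConservationSummary:
    species: str
    n_rgene: int
    n_rgene_conserved: int
    n_gene: int
    n_gene_conserved: int
    fisher_p: float
    odds_ratio: float

    @property
    def pct_rgene(self) -> float:
        return 100.0 * self.n_rgene_conserved / self.n_rgene

    @property
    def pct_gene(self) -> float:
        return 100.0 * self.n_gene_conserved / self.n_gene


def _species_of(species: Mapping[str, str] | Callable[[str], str]):
    return species.__getitem__ if isinstance(species, Mapping) else species


def _call(
    pairs: Iterable[HspSet],
    cip_min: float,
    calp_min: float,
    relation: str,
    species: Mapping[str, str] | Callable[[str], str],
) -> list[HomologyPair]:
    sp = _species_of(species)
    out = []
    for pair in pairs:
        if pair.query == pair.subject:
            raise ValueError(f"self pair {pair.query} passed to homolog calling")
        same = sp(pair.query) == sp(pair.subject)
        if relation == "ortholog" and same:
            raise ValueError(
                f"same-species pair {pair.query}/{pair.subject} passed to "
                "ortholog calling"
            )
        if relation == "paralog" and not same:
            raise ValueError(
                f"cross-species pair {pair.query}/{pair.subject} passed to "
                "paralog calling"
            )
        cip, calp = compute_cip_calp(pair)
        rel = relation if (cip >= cip_min and calp >= calp_min) else "none"
        out.append(
            HomologyPair(
                query=pair.query,
                subject=pair.subject,
                cip=cip,
                calp=calp,
                best_evalue=pair.best_evalue,
                relation=rel,
            )
        )
    return out


def call_orthologs(
    pairs: Iterable[HspSet],
    species: Mapping[str, str] | Callable[[str], str],
    cip_min: float = 60.0,
    calp_min: float = 70.0,
) -> list[HomologyPair]:
    """Call orthologs among cross-species pairs at CIP/CALP >= 60/70
    (inclusive). Same-species input is an error."""
    return _call(pairs, cip_min, calp_min, "ortholog", species)


def call_paralogs(
    pairs: Iterable[HspSet],
    species: Mapping[str, str] | Callable[[str], str],
    cip_min: float = 60.0,
    calp_min: float = 70.0,
) -> list[HomologyPair]:
    """Call paralogs among same-species, non-self pairs at CIP/CALP >= 60/70."""
    return _call(pairs, cip_min, calp_min, "paralog", species)


def fisher_conservation_test(
    a: int, b: int, c: int, d: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p). The odds ratio is the sample ratio (a*d)/(b*c)
    with the 0/inf conventions for empty cells.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else (0.0 if a * d == 0 else math.inf)
    else:
        odds = (a * d) / (b * c)
    return odds, float(p)


def conservation_summary(
    rgene_ids: Mapping[str, set[str]],
    gene_ids: Mapping[str, set[str]],
    rgene_orthologs: Iterable[HomologyPair],
    gene_orthologs: Iterable[HomologyPair],
    reference: str,
    species: Mapping[str, str] | Callable[[str], str],
) -> dict[str, ConservationSummary]:
    """Per-species conservation of R-genes vs all genes against a reference.

    A species gene is conserved when it appears in at least one
    threshold-passing ortholog pair with the reference. Percentages use the
    species' own totals as denominators; the Fisher test contrasts the
    R-gene conservation rate with the background gene rate.
    """
    sp = _species_of(species)

    def _conserved(pairs: Iterable[HomologyPair]) -> dict[str, set[str]]:
        by_species: dict[str, set[str]] = {}
        for p in pairs:
            if p.relation == "none":
                continue
            for gid in (p.query, p.subject):
                s = sp(gid)
                if s != reference:
                    by_species.setdefault(s, set()).add(gid)
        return by_species

    cons_r = _conserved(rgene_orthologs)
    cons_g = _conserved(gene_orthologs)
    out: dict[str, ConservationSummary] = {}
    for s in sorted(rgene_ids):
        if s == reference:
            continue
        n_r, n_g = len(rgene_ids[s]), len(gene_ids[s])
        if n_r == 0 or n_g == 0:
            raise ValueError(f"{s}: zero denominator in conservation summary")
        rc = len(cons_r.get(s, set()) & rgene_ids[s])
        gc = len(cons_g.get(s, set()) & gene_ids[s])
        odds, p = fisher_conservation_test(rc, n_r - rc, gc, n_g - gc)
        out[s] = ConservationSummary(
            species=s,
            n_rgene=n_r,
            n_rgene_conserved=rc,
            n_gene=n_g,
            n_gene_conserved=gc,
            fisher_p=p,
            odds_ratio=odds,
        )
    return out
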