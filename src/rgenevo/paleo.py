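"""Paleogenomic analyses: ancestral founder-pool reconstruction, the WGD
retention-bias permutation Z-test, dominance/cluster regression, segmental vs
single-gene duplication classification, and duplication hotspots.

The retention test asks whether the split of surviving R-genes between the
two descendant copies of a duplicated (post-WGD) block is compatible with
unbiased gene deletion. With ancestral content N and observed copies n1, n2,
the total deletions D = 2N - n1 - n2 are redistributed at random (each
deletion hits either copy with probability 1/2, capped at N per copy), the
replicate differences X_i - Y_i form the null, and the observed difference
X = n1 - n2 is standardized against it:

    z = (X - u) / sigma        (default; u, sigma = null mean and sd)

The closed form for this null is z ~ (n1 - n2) / sqrt(D). A literal variant
dividing by sigma/sqrt(reps) is kept for comparison but is not calibrated
(it inflates |z| by sqrt(reps) for any nonzero X).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import FAMILIES, HspSet, RGeneRecord, compute_cip_calp
from .homology import HomologyPair, fisher_conservation_test
from .io_formats import GeneModel

logger = logging.getLogger(__name__)

BLOCK_STATUSES = ("dominant", "sensitive", "unknown")


# ---------------------------------------------------------------------------
# ancestral map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralMap:
    """Placement of modern genes on ancestral (proto)chromosomes.

    One row per gene: (species, gene_id, anc_chr, block_id, block_status).
    The karyotype reconstruction itself is an input, not recomputed here.
    """

    rows: pd.DataFrame

    COLUMNS = ("species", "gene_id", "anc_chr", "block_id", "block_status")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"ancestral map missing columns {sorted(missing)}")
        dup = self.rows.duplicated(subset=["species", "gene_id"])
        if dup.any():
            bad = self.rows.loc[dup, "gene_id"].iloc[0]
            raise ValueError(f"gene {bad} mapped to more than one ancestral position")
        bad_status = set(self.rows["block_status"]) - set(BLOCK_STATUSES)
        if bad_status:
            raise ValueError(f"unknown block status {sorted(bad_status)}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AncestralMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, columns=list(self.COLUMNS))

    def lookup(self, species: str, gene_id: str) -> pd.Series | None:
        hit = self.rows[
            (self.rows["species"] == species) & (self.rows["gene_id"] == gene_id)
        ]
        return None if hit.empty else hit.iloc[0]


# ---------------------------------------------------------------------------
# retention permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicatedBlockPair:
    """Two descendant copies of one ancestral block with R-gene counts.

    ``n_anc`` is the ancestral R-gene content N; the unbiased-deletion null
    starts from 2N post-duplication copies.
    """

    anc_chr_pair: tuple[str, str]
    n_anc: int
    n1: int
    n2: int
    species: str = ""
    status_pair: tuple[str, str] = ("unknown", "unknown")

    def __post_init__(self) -> None:
        if not (0 <= self.n1 <= self.n_anc and 0 <= self.n2 <= self.n_anc):
            raise ValueError(
                f"{self.anc_chr_pair}: retained counts ({self.n1}, {self.n2}) "
                f"exceed ancestral content {self.n_anc}"
            )


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: int
    null_mean: float
    null_sd: float
    reps: int
    z: float
    p_two_sided: float
    p_exact: float
    seed: int | None
    mode: str


def retention_permutation_test(
    block: DuplicatedBlockPair,
    reps: int = 1000,
    seed: int | None = None,
    mode: str = "sd",
) -> PermutationResult:
    """Permutation Z-test for biased R-gene retention between block copies.

    Each replicate redistributes the D = 2N - n1 - n2 deletions over the two
    copies independently with probability 1/2 (capped at N per copy;
    overflowing draws are redrawn). ``p_two_sided`` comes from the standard
    normal on z; ``p_exact`` is the rank of |X| in the |null| sample with the
    add-one correction.
    """
    if mode not in {"sd", "sd_over_sqrt_n"}:
        raise ValueError(f"unknown mode {mode!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n, n1, n2 = block.n_anc, block.n1, block.n2
    d_total = 2 * n - n1 - n2
    x = n1 - n2
    rng = np.random.default_rng(seed)

    d1 = rng.binomial(d_total, 0.5, size=reps)
    # cap deletions at N per copy, redrawing overflow (only possible if D > N)
    while True:
        bad = (d1 > n) | (d_total - d1 > n)
        if not bad.any():
            break
        d1[bad] = rng.binomial(d_total, 0.5, size=int(bad.sum()))
    diffs = d_total - 2 * d1  # (N - d1) - (N - d2)

    u = float(diffs.mean())
    sigma = float(diffs.std(ddof=1)) if reps > 1 else 0.0
    if sigma == 0.0:
        if x == u:
            z, p = 0.0, 1.0
        else:
            raise ValueError(
                f"{block.anc_chr_pair}: degenerate null (sd = 0) with "
                f"observed difference {x} != {u}"
            )
    else:
        denom = sigma if mode == "sd" else sigma / math.sqrt(reps)
        z = (x - u) / denom
        p = float(2.0 * stats.norm.sf(abs(z)))
    p_exact = float((1 + np.sum(np.abs(diffs) >= abs(x))) / (reps + 1))
    return PermutationResult(
        observed_diff=x,
        null_mean=u,
        null_sd=sigma,
        reps=reps,
        z=z,
        p_two_sided=p,
        p_exact=p_exact,
        seed=seed,
        mode=mode,
    )


def build_block_pairs(
    anc_map: AncestralMap,
    r_ids: set[str],
    n_anc: Mapping[tuple[str, str], int] | None = None,
) -> list[DuplicatedBlockPair]:
    """Assemble per-species duplicated block pairs from the ancestral map.

    For each (species, ancestral chromosome) with exactly two descendant
    blocks, count mapped R-genes per block. Without external ancestral
    content, N is taken as n1 + n2 (no co-retention information in the map);
    pass ``n_anc`` keyed by (species, anc_chr) to override.
    """
    df = anc_map.rows[anc_map.rows["gene_id"].isin(r_ids)]
    pairs: list[DuplicatedBlockPair] = []
    for (species, anc_chr), grp in df.groupby(["species", "anc_chr"], sort=True):
        blocks = grp.groupby(["block_id", "block_status"]).size()
        if len(blocks) != 2:
            logger.debug(
                "%s/%s: %d blocks, expected 2; skipped", species, anc_chr, len(blocks)
            )
            continue
        (b1, s1), (b2, s2) = blocks.index.tolist()
        # dominant block first when labeled
        if (s1, s2) == ("sensitive", "dominant"):
            (b1, s1), (b2, s2) = (b2, s2), (b1, s1)
        n1, n2 = int(blocks[(b1, s1)]), int(blocks[(b2, s2)])
        n = (n_anc or {}).get((species, anc_chr), n1 + n2)
        pairs.append(
            DuplicatedBlockPair(
                anc_chr_pair=(b1, b2),
                n_anc=n,
                n1=n1,
                n2=n2,
                species=species,
                status_pair=(s1, s2),
            )
        )
    return pairs


def block_retention_scan(
    blocks: Sequence[DuplicatedBlockPair],
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "sd",
) -> pd.DataFrame:
    """Run the retention test over block pairs; label each biased/balanced.

    Per-block seeds are spawned from ``seed`` so the scan is deterministic
    and order-independent in its labels.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for block, child in zip(blocks, ss.spawn(len(blocks))):
        res = retention_permutation_test(
            block, reps=reps, seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            mode=mode,
        )
        rows.append(
            {
                "species": block.species,
                "block1": block.anc_chr_pair[0],
                "block2": block.anc_chr_pair[1],
                "status1": block.status_pair[0],
                "status2": block.status_pair[1],
                "n_anc": block.n_anc,
                "n1": block.n1,
                "n2": block.n2,
                "z": res.z,
                "p": res.p_two_sided,
                "p_exact": res.p_exact,
                "label": "biased" if res.p_two_sided < alpha else "balanced",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# founder pool
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FounderLocus:
    ref_gene: str
    anc_chr: str
    block_id: str
    n_species: int
    domains: frozenset[str]


@dataclass(frozen=True)
class FounderPool:
    loci: tuple[FounderLocus, ...]
    family_totals: tuple[tuple[str, int], ...]

    @property
    def size(self) -> int:
        return len(self.loci)


def reconstruct_founder_pool(
    catalog: Sequence[RGeneRecord],
    orthologs: Iterable[HomologyPair],
    anc_map: AncestralMap,
    reference: str,
    min_species: int = 2,
) -> FounderPool:
    """Reconstruct the minimal ancestral (founder) R-locus pool.

    An ortholog group is keyed by its reference-species member; it founds an
    ancestral locus when R-genes from at least ``min_species`` species
    (reference included) belong to it and the reference member has an
    ancestral placement. The locus inherits the union of member domain sets.
    """
    by_id = {r.gene.gene_id: r for r in catalog}
    ref_rows = anc_map.rows[anc_map.rows["species"] == reference]
    placement = {
        r.gene_id: (r.anc_chr, r.block_id) for r in ref_rows.itertuples(index=False)
    }

    groups: dict[str, set[str]] = {}
    for p in orthologs:
        if p.relation != "ortholog":
            continue
        q_rec, s_rec = by_id.get(p.query), by_id.get(p.subject)
        if q_rec is None or s_rec is None:
            continue
        if q_rec.gene.species == reference:
            ref_gid, other = p.query, s_rec
        elif s_rec.gene.species == reference:
            ref_gid, other = p.subject, q_rec
        else:
            continue
        groups.setdefault(ref_gid, set()).add(other.gene.gene_id)

    loci: list[FounderLocus] = []
    for ref_gid in sorted(groups):
        members = groups[ref_gid]
        species_set = {reference} | {by_id[m].gene.species for m in members}
        if len(species_set) < min_species:
            continue
        if ref_gid not in placement:
            logger.warning("%s: reference member unplaced; locus skipped", ref_gid)
            continue
        domains: set[str] = set(by_id[ref_gid].domains)
        for m in members:
            domains |= by_id[m].domains
        anc_chr, block_id = placement[ref_gid]
        loci.append(
            FounderLocus(
                ref_gene=ref_gid,
                anc_chr=anc_chr,
                block_id=block_id,
                n_species=len(species_set),
                domains=frozenset(domains),
            )
        )
    totals = dict.fromkeys(FAMILIES, 0)
    for locus in loci:
        for fam in locus.domains:
            totals[fam] += 1
    return FounderPool(loci=tuple(loci), family_totals=tuple(totals.items()))


# ---------------------------------------------------------------------------
# dominance / cluster regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def dominance_cluster_regression(
    points: Iterable[tuple[float, float, str]],
) -> dict[str, RegressionResult]:
    """OLS of conserved R-gene count on clustered R-gene count per block,
    stratified by dominant/sensitive status.

    Input triples are (n_clustered, n_conserved, block_status); each stratum
    needs at least 3 blocks and non-degenerate predictor variance.
    """
    strata: dict[str, list[tuple[float, float]]] = {}
    for x, y, status in points:
        strata.setdefault(status, []).append((float(x), float(y)))
    out: dict[str, RegressionResult] = {}
    for status, pts in sorted(strata.items()):
        if len(pts) < 3:
            raise ValueError(f"stratum {status}: need >= 3 blocks, got {len(pts)}")
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        if np.ptp(xs) == 0:
            raise ValueError(f"stratum {status}: zero variance in predictor")
        fit = stats.linregress(xs, ys)
        out[status] = RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r2=float(fit.rvalue**2),
            p=float(fit.pvalue),
            n=len(pts),
        )
    return out


# ---------------------------------------------------------------------------
# duplication classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationCall:
    locus_a: str
    locus_b: str
    n_flank_hits: int
    call: str  # segmental | single_gene


def flank_evalue_map(df: pd.DataFrame) -> dict[frozenset[str], float]:
    """Collapse a BLAST tabular frame to the best E-value per unordered
    gene pair (used as the flanking-similarity lookup)."""
    out: dict[frozenset[str], float] = {}
    for r in df.itertuples(index=False):
        if r.query == r.subject:
            continue
        key = frozenset((r.query, r.subject))
        ev = float(r.evalue)
        if ev < out.get(key, math.inf):
            out[key] = ev
    return out


def classify_duplication(
    rgene_pairs: Iterable[HspSet],
    genes: Sequence[GeneModel],
    cluster_of: Mapping[str, str],
    flank_evalues: Mapping[frozenset[str], float],
    window: int = 40,
    flank_evalue: float = 1e-10,
    cip_min: float = 70.0,
    calp_min: float = 70.0,
) -> list[DuplicationCall]:
    """Classify non-syntenic R-gene pairs as segmental or single-gene
    duplications from flanking-gene similarity.

    Pairs must pass CIP/CALP >= 70/70 (others are dropped); R-genes in one
    cluster collapse to a single locus, and same-locus pairs are skipped.
    Each locus contributes a window of ``window`` flanking annotated genes
    (half per side by rank, truncated at chromosome ends, locus members
    excluded). A pair is segmental iff at least one cross-window gene pair
    aligns at E <= ``flank_evalue``; otherwise it is a single-gene
    duplication. The call is symmetric in the two loci.
    """
    by_id = {g.gene_id: g for g in genes}
    order: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        order.setdefault((g.species, g.chromosome), []).append(g)
    for models in order.values():
        models.sort(key=lambda g: g.rank)

    def locus_id(gid: str) -> str:
        return cluster_of.get(gid, gid)

    locus_members: dict[str, set[str]] = {}
    for gid in by_id:
        locus_members.setdefault(locus_id(gid), set()).add(gid)

    half = window // 2

    def _span(locus: str) -> tuple[tuple[str, str], int, int]:
        members = [by_id[m] for m in locus_members[locus] if m in by_id]
        if not members:
            raise ValueError(f"locus {locus}: no located members")
        chrom_key = (members[0].species, members[0].chromosome)
        return chrom_key, min(m.rank for m in members), max(m.rank for m in members)

    def flank_window(locus: str, partner: str) -> list[str]:
        # Flanking context excludes the members of BOTH loci; when the two
        # loci sit on one chromosome closer than the window span, each
        # window stops at the midpoint so the neighborhoods stay disjoint
        # (otherwise any local gene family between them would masquerade as
        # conserved flanking synteny).
        chrom_key, lo, hi = _span(locus)
        p_chrom, p_lo, p_hi = _span(partner)
        track = order[chrom_key]
        left_bound, right_bound = 0, len(track)
        if p_chrom == chrom_key:
            if p_hi < lo:
                left_bound = (p_hi + lo) // 2 + 1
            elif p_lo > hi:
                right_bound = (hi + p_lo + 1) // 2
        excluded = locus_members[locus] | locus_members[partner]
        left = [
            g.gene_id
            for g in track[max(left_bound, lo - half): lo]
            if g.gene_id not in excluded
        ]
        right = [
            g.gene_id
            for g in track[hi + 1: min(right_bound, hi + 1 + half)]
            if g.gene_id not in excluded
        ]
        return left + right

    seen: set[frozenset[str]] = set()
    calls: list[DuplicationCall] = []
    for pair in rgene_pairs:
        if pair.query == pair.subject:
            continue
        cip, calp = compute_cip_calp(pair)
        if cip < cip_min or calp < calp_min:
            continue
        la, lb = sorted((locus_id(pair.query), locus_id(pair.subject)))
        if la == lb:
            continue
        key = frozenset((la, lb))
        if key in seen:
            continue
        seen.add(key)
        wa, wb = flank_window(la, lb), flank_window(lb, la)
        hits = sum(
            1
            for fa in wa
            for fb in wb
            if fa != fb
            and flank_evalues.get(frozenset((fa, fb)), math.inf) <= flank_evalue
        )
        calls.append(
            DuplicationCall(
                locus_a=la,
                locus_b=lb,
                n_flank_hits=hits,
                call="segmental" if hits >= 1 else "single_gene",
            )
        )
    return calls


def detect_hotspots(
    calls: Sequence[DuplicationCall],
    related_pairs: set[frozenset[str]],
) -> set[str]:
    """Find single-gene-duplication hotspots.

    A locus is a hotspot when it has single-gene-duplication matches to at
    least two partner loci that are not themselves related (no
    threshold-passing match between the partners, as given by
    ``related_pairs``). Output is independent of input order.
    """
    partners: dict[str, set[str]] = {}
    for c in calls:
        if c.call != "single_gene":
            continue
        partners.setdefault(c.locus_a, set()).add(c.locus_b)
        partners.setdefault(c.locus_b, set()).add(c.locus_a)
    hotspots: set[str] = set()
    for locus, ps in partners.items():
        plist = sorted(ps)
        for i, p in enumerate(plist):
            for q in plist[i + 1:]:
                if frozenset((p, q)) not in related_pairs:
                    hotspots.add(locus)
                    break
            if locus in hotspots:
                break
    return hotspots


# ---------------------------------------------------------------------------
# PTI/ETI trend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    group: str
    anc_share: float
    modern_share: float
    direction: str  # gain | loss | flat (modern relative to ancestor)
    odds_ratio: float
    p: float


def pti_eti_trend_test(
    anc_counts: Mapping[str, int],
    modern_counts: Mapping[str, int],
    groups: Sequence[str] = ("PTI", "ETI"),
) -> dict[str, TrendResult]:
    """Fisher exact test of each group's share, ancestor vs one modern
    species (group count vs rest of the repertoire)."""
    anc_total = sum(anc_counts.values())
    mod_total = sum(modern_counts.values())
    if anc_total == 0 or mod_total == 0:
        raise ValueError("zero total in trend test")
    out = {}
    for grp in groups:
        a = anc_counts.get(grp, 0)
        c = modern_counts.get(grp, 0)
        odds, p = fisher_conservation_test(a, anc_total - a, c, mod_total - c)
        anc_share = a / anc_total
        mod_share = c / mod_total
        if mod_share > anc_share:
            direction = "gain"
        elif mod_share < anc_share:
            direction = "loss"
        else:
            direction = "flat"
        out[grp] = TrendResult(
            group=grp,
            anc_share=anc_share,
            modern_share=mod_share,
            direction=direction,
            odds_ratio=odds,
            p=p,
        )
    return out
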