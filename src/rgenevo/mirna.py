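"""miRNA/R-gene interactome: complementarity mismatch scoring and summaries.

A mature miRNA is slid along the transcript (antiparallel, so the miRNA is
compared against the reversed target) and each candidate duplex is scored
with Targetfinder-style penalties:

* mismatch 1.0, G:U wobble 0.5, single-nucleotide bulge (either strand) 1.0;
* every penalty is doubled when it falls at miRNA positions 2-13 from the
  5' end (the seed-extended region); for a target bulge the charged position
  is the miRNA position immediately 3' of the bulge, for a miRNA bulge the
  unpaired miRNA position itself.

At most one bulge per duplex is considered. Scores are sums of these
penalties (hence quantized to 0.5); a transcript site is reported when its
score is below the threshold (default: strictly below 4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import FAMILIES, RGeneRecord

_ALPHA = "ACGU"
_IDX = {c: i for i, c in enumerate(_ALPHA)}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# penalty[mirna_base, target_base]; row/col 4 pads sequence boundaries
_PEN = np.ones((5, 5), dtype=float)
for _m, _t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PEN[_IDX[_m], _IDX[_t]] = 0.0
_PEN[_IDX["G"], _IDX["U"]] = 0.5
_PEN[_IDX["U"], _IDX["G"]] = 0.5
_PEN[4, :] = _PEN[:, 4] = 9.0

SEED_START, SEED_END = 2, 13  # 1-based miRNA positions with doubled penalties
DEFAULT_THRESHOLD = 4.0


def _encode(seq: str, what: str) -> np.ndarray:
    s = seq.upper().replace("T", "U")
    try:
        return np.array([_IDX[c] for c in s], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"{what}: non-nucleotide character {exc.args[0]!r}") from exc


def revcomp(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class MatureMiRNA:
    mirna_id: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper().replace("T", "U")
        if not (19 <= len(s) <= 24):
            raise ValueError(f"{self.mirna_id}: length {len(s)} outside 19-24 nt")
        if set(s) - set(_ALPHA):
            raise ValueError(f"{self.mirna_id}: non-RNA characters")
        object.__setattr__(self, "seq", s)


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    gene_id: str
    site_start: int  # 1-based on the transcript
    site_len: int
    score: float
    alignment: tuple[str, str, str]  # miRNA 5'->3', pairing, target 3'->5'


def _position_weights(m: int) -> np.ndarray:
    w = np.ones(m)
    w[SEED_START - 1: SEED_END] = 2.0
    return w


def _windows(arr: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(arr, m)


def _site_alignment(mir: str, site: str) -> tuple[float, tuple[str, str, str]]:
    """Score one candidate duplex explicitly and build its alignment strings.

    ``site`` is the target site read 3'->5' (i.e. already reversed), with
    length m-1, m, or m+1 relative to the miRNA; the length selects the
    bulge variant. Used to annotate reported hits.
    """
    m, n = len(mir), len(site)
    w = _position_weights(m)
    mir_i = _encode(mir, "miRNA")
    site_i = _encode(site, "site")

    def pair_char(a: int, b: int) -> str:
        p = _PEN[a, b]
        return "|" if p == 0 else ("o" if p == 0.5 else " ")

    best: tuple[float, tuple[str, str, str]] | None = None
    if n == m:
        score = float((_PEN[mir_i, site_i] * w).sum())
        pairing = "".join(pair_char(a, b) for a, b in zip(mir_i, site_i))
        best = (score, (mir, pairing, site))
    elif n == m + 1:  # one unpaired target base after miRNA position k
        for k in range(1, m):
            score = float(
                (_PEN[mir_i[:k], site_i[:k]] * w[:k]).sum()
                + w[k]
                + (_PEN[mir_i[k:], site_i[k + 1:]] * w[k:]).sum()
            )
            if best is None or score < best[0]:
                top = mir[:k] + "-" + mir[k:]
                mid = (
                    "".join(pair_char(a, b) for a, b in zip(mir_i[:k], site_i[:k]))
                    + " "
                    + "".join(
                        pair_char(a, b) for a, b in zip(mir_i[k:], site_i[k + 1:])
                    )
                )
                best = (score, (top, mid, site))
    elif n == m - 1:  # miRNA position k unpaired
        for k in range(1, m - 1):
            score = float(
                (_PEN[mir_i[:k], site_i[:k]] * w[:k]).sum()
                + w[k]
                + (_PEN[mir_i[k + 1:], site_i[k:]] * w[k + 1:]).sum()
            )
            if best is None or score < best[0]:
                mid = (
                    "".join(pair_char(a, b) for a, b in zip(mir_i[:k], site_i[:k]))
                    + " "
                    + "".join(
                        pair_char(a, b) for a, b in zip(mir_i[k + 1:], site_i[k:])
                    )
                )
                best = (score, (mir, mid, site[:k] + "-" + site[k:]))
    else:
        raise ValueError(f"site length {n} incompatible with miRNA length {m}")
    assert best is not None
    return best


def score_target(
    mirna: MatureMiRNA,
    transcript: str,
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
    gene_id: str = "",
) -> list[TargetHit]:
    """Score all candidate sites of one miRNA on one transcript.

    Returns passing sites best-first; overlapping candidates are collapsed
    to the best-scoring one. The transcript may be DNA or RNA, 5'->3'.
    """
    m = len(mirna.seq)
    tgt = _encode(transcript, f"transcript {gene_id or '?'}")
    ell = len(tgt)
    if ell < m:
        raise ValueError("transcript shorter than miRNA")
    mir_i = _encode(mirna.seq, mirna.mirna_id)
    w = _position_weights(m)
    rev = tgt[::-1]

    cands: list[tuple[float, int, int]] = []  # (score, start0, site_len)
    cutoff = threshold + 0.25  # scores are multiples of 0.5: keeps <= threshold

    # perfect-register duplexes
    p0 = _PEN[mir_i[None, :], _windows(rev, m)] * w  # (ell-m+1, m)
    score0 = p0.sum(axis=1)
    for o in np.flatnonzero(score0 < cutoff):
        cands.append((float(score0[o]), ell - int(o) - m, m))

    # one unpaired target base (site m+1 long), bulge after miRNA pos k
    if ell >= m + 1:
        c0 = np.cumsum(p0, axis=1)  # prefix sums of in-register penalties
        p1 = p0[1:, :]  # penalties against the site shifted by one
        suff1 = np.cumsum(p1[:, ::-1], axis=1)[:, ::-1]
        n_off = ell - m
        ks = np.arange(1, m)
        bulge = c0[:n_off, ks - 1] + w[ks] + suff1[:, ks]
        best_k = bulge.min(axis=1)
        for o in np.flatnonzero(best_k < cutoff):
            cands.append((float(best_k[o]), ell - int(o) - (m + 1), m + 1))

    # one unpaired miRNA base (site m-1 long)
    if m >= 3 and ell >= m - 1:
        rev_pad = np.concatenate(([np.int8(4)], rev))
        q = _PEN[mir_i[None, :], _windows(rev_pad, m)] * w  # row o: site rev[o-1..]
        n_off = ell - m + 2  # offsets 0..ell-m+1
        pref = np.cumsum(
            _PEN[mir_i[None, :], _windows(np.concatenate((rev, [np.int8(4)])), m)] * w,
            axis=1,
        )  # pref[o, i]: in-register pairs, rows 0..ell-m+1
        suffm = np.cumsum(q[:, ::-1], axis=1)[:, ::-1]  # suffix over shifted pairs
        ks = np.arange(1, m - 1)
        # score(o, k) = pref[o, k-1] + w[k] + sum_{i>k} pen(mir[i], rev[o+i-1])
        scorem = pref[:n_off, ks - 1] + w[ks] + suffm[:n_off, ks + 1]
        best_k = scorem.min(axis=1)
        for o in np.flatnonzero(best_k < cutoff):
            start0 = ell - int(o) - (m - 1)
            if 0 <= start0 <= ell - (m - 1):
                cands.append((float(best_k[o]), start0, m - 1))

    # collapse overlapping candidates, best first
    cands.sort(key=lambda c: (c[0], c[1]))
    hits: list[TargetHit] = []
    taken: list[tuple[int, int]] = []
    cmp = (lambda s: s < threshold) if strict else (lambda s: s <= threshold)
    for score, start0, site_len in cands:
        if not cmp(score):
            continue
        end0 = start0 + site_len
        if any(start0 < e and s < end0 for s, e in taken):
            continue
        taken.append((start0, end0))
        site = transcript[start0:end0].upper().replace("T", "U")[::-1]
        exact, aln = _site_alignment(mirna.seq, site)
        hits.append(
            TargetHit(
                mirna_id=mirna.mirna_id,
                gene_id=gene_id,
                site_start=start0 + 1,
                site_len=site_len,
                score=exact,
                alignment=aln,
            )
        )
    hits.sort(key=lambda h: (h.score, h.site_start))
    return hits


def scan_targets(
    mirnas: Sequence[MatureMiRNA],
    transcripts: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> list[TargetHit]:
    """Scan every miRNA against every transcript; keep the best site per
    (miRNA, gene) pair."""
    best: dict[tuple[str, str], TargetHit] = {}
    for mir in mirnas:
        for gid in sorted(transcripts):
            hits = score_target(
                mir, transcripts[gid], threshold=threshold, strict=strict,
                gene_id=gid,
            )
            if hits:
                key = (mir.mirna_id, gid)
                if key not in best or hits[0].score < best[key].score:
                    best[key] = hits[0]
    return sorted(best.values(), key=lambda h: (h.mirna_id, h.gene_id))


# ---------------------------------------------------------------------------
# interactome statistics
# ---------------------------------------------------------------------------

def interactome_summary(
    hits: Sequence[TargetHit],
    catalog: Sequence[RGeneRecord],
    conserved_ids: set[str] = frozenset(),
    clustered_ids: set[str] = frozenset(),
    nonr_scanned: Mapping[str, set[str]] | None = None,
    wgd_rounds: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-species targeting percentages over the R-gene catalog.

    ``nonr_scanned`` gives, per species, the non-R gene ids whose transcripts
    were scanned (denominator for the non-R percentage). Domain percentages
    are computed over R-genes carrying each family; categories with zero
    denominators are reported as NaN.
    """
    targeted = {h.gene_id for h in hits}
    by_species: dict[str, list[RGeneRecord]] = {}
    for r in catalog:
        by_species.setdefault(r.gene.species, []).append(r)

    def pct(hit_ids: set[str], pool: set[str]) -> float:
        return 100.0 * len(hit_ids & pool) / len(pool) if pool else float("nan")

    rows = []
    for species in sorted(by_species):
        recs = by_species[species]
        r_ids = {r.gene.gene_id for r in recs}
        cons = r_ids & set(conserved_ids)
        row: dict[str, object] = {
            "species": species,
            "n_rgene": len(r_ids),
            "pct_r_targeted": pct(targeted, r_ids),
            "pct_conserved_targeted": pct(targeted, cons),
            "pct_nonconserved_targeted": pct(targeted, r_ids - cons),
            "pct_cluster_targeted": pct(targeted, r_ids & set(clustered_ids)),
            "pct_singleton_targeted": pct(targeted, r_ids - set(clustered_ids)),
        }
        if nonr_scanned is not None:
            row["pct_nonr_targeted"] = pct(targeted, set(nonr_scanned.get(species, set())))
        for fam in FAMILIES:
            pool = {r.gene.gene_id for r in recs if fam in r.domains}
            row[f"pct_{fam}_targeted"] = pct(targeted, pool)
        if wgd_rounds is not None:
            row["wgd_rounds"] = wgd_rounds.get(species)
        rows.append(row)
    return pd.DataFrame(rows)


def overall_targeted_fraction(
    cons_targets: int, cons_total: int, noncons_targets: int, noncons_total: int
) -> float:
    """Pooled targeted fraction over conserved + non-conserved R-genes."""
    return (cons_targets + noncons_targets) / (cons_total + noncons_total)


def wgd_correlation(
    points: Iterable[tuple[float, float]],
) -> tuple[float, float]:
    """Pearson correlation of (WGD rounds, targeted fraction) across species,
    with the two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2)."""
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 species")
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant input to correlation")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Standard paired t-test; degenerate (zero-variance) differences are an
    error rather than a silent nan/inf."""
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    diffs = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.ptp(diffs) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)
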