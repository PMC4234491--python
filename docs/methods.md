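# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the package. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Catalog construction

Three evidence streams are unioned per gene id:

1. **Annotation** — gene ids flagged as resistance-related in the source
   annotation (a plain id list).
2. **PFAM** — hmmsearch domain hits, keyed by profile accession
   (LRR: PF00560/PF07723/PF07725/PF12799/PF01463/PF08263; NBS: PF00931;
   TIR: PF01582; LysM: PF01476; PKinase: PF00069; WRKY: PF03106), retained
   at independent E-value ≤ 1e−10. Profiles outside this vocabulary are
   skipped by the reader.
3. **Database alignments** — a curated R-protein set aligned to the
   proteome; a gene is accepted when some single database protein reaches
   CIP ≥ 70 and CALP ≥ 70 against it. HSPs are never pooled across database
   proteins: pooling would let two unrelated partial matches manufacture an
   acceptance.

A gene supported only by streams 1/3 carries the `RG` family (resistance
gene analog without a recognized PFAM domain). The catalog is idempotent
under re-merging and is written as a plain TSV.

**CIP/CALP conventions.** CIP's denominator is the summed HSP alignment
length; CALP's is the query length. HSPs are processed in input order
(BLAST emits best-first) and an HSP whose query-span overlap with an
already-retained HSP exceeds 10% of its own span is dropped; residual CALP
above 100 (gappy alignments) is clamped with a logged warning. Identity
counts are reconstructed from `pct_identity × aln_length` rounded to the
nearest integer, which is exact for BLAST's integer identity counts.

**Classification precedence.** NBS∧LRR → ETI (TNL if TIR, else CNL — the
coiled-coil domain has no profile in the vocabulary, so CNL is
operationalized as NBS-LRR without TIR); then LysM → PTI; then LRR without
NBS → PTI (RLK with PKinase, else RLP); then any remaining NBS/TIR/RG →
R-combination (class RGA); WRKY/PKinase alone → R-pathway. The precedence
is total over all 127 non-empty domain sets and is pinned by a golden test.
One consequence of applying the precedence literally: {LRR, TIR} without
NBS classifies as PTI/RLP, not R-combination.

## Cluster calling

A cluster is a maximal chain of R-genes on one chromosome where consecutive
members have ≤ 8 intervening non-R annotated genes. Gaps are measured in
gene ranks (dense 0-based order of start coordinates, ties broken by gene
id), not base pairs; chaining is transitive; chromosome boundaries are never
spanned; chains of length 1 are reported as singletons. The caller is
checked for exact agreement against an exhaustive interval oracle on 1000
random R/non-R strings, including the gap-8 vs gap-9 boundary.

At realistic R-gene densities the rule chains well beyond tandem arrays:
in the default synthetic cohort ~80–87% of R-genes are in clusters although
only ~40% sit in planted arrays. This mirrors the behaviour on real
genomes, where clustered fractions near 70% reflect proximity, not only
tandem descent; recovery tests therefore compare against the gap-rule
clusterization of the *true* R layout, isolating catalog-detection error.

## Conservation and orthology

Orthologs (cross-species) and paralogs (within-species, non-self) are
called at CIP ≥ 60 and CALP ≥ 70, inclusive, with no reciprocal-best
constraint — a gene may have several orthologs. Conservation percentages
use the species' own catalog size as denominator (this convention, not the
reference-set denominator, reproduces the published per-species values).
Enrichment of R-gene conservation over the background gene rate uses the
two-sided Fisher exact test (scipy), validated against full hypergeometric
enumeration on small tables.

## Founder pool

An ortholog group is anchored at its reference-species member. It founds an
ancestral locus when it contains R-genes from ≥ 2 species (configurable)
and the reference member has a placement in the ancestral-karyotype map
(an input, not recomputed). The locus inherits the union of member domain
families. Reference members without placement — typically lineage-specific
tandem/transposed copies — are skipped with a warning. When a reference
WGD pair survives, each placed copy anchors its own group, so the pool
counts ancestral *placements*; the recovery test tolerance (±10%) covers
this convention.

## Retention permutation test

Under unbiased diploidization, the D = 2N − n1 − n2 deletions fall on
either block copy with probability ½. Each replicate draws the copy-1
deletion count from Binomial(D, ½), capped at N per copy with overflowing
draws redrawn (the cap only binds when D > N). The observed difference
X = n1 − n2 is standardized by the replicate null: z = (X − u)/σ, p from
the standard normal (two-sided); the exact permutation rank p is reported
alongside. The closed form is z ≈ (n1 − n2)/√D since Var(X₁ − X₂) = D.

A literal σ/√n standardization (n = 1000 replicates), sometimes printed for
this style of test, is available as `mode="sd_over_sqrt_n"` but inflates
|z| by √n for any non-zero X and is not calibrated. The default (`mode="sd"`) has measured type-I error 0.0485
at α = 0.05 (2000 simulated null block pairs). At the 100-pair study size
used in calibration runs, the observed rejection rate fluctuates binomially
(± ~0.02 at 1 s.e.).

When block pairs are built from an ancestral map alone, the ancestral
content N is unknown and is taken as n1 + n2 (zero co-retention), which
overstates D and makes the test slightly conservative; a true N can be
supplied where known.

## Duplication classification and hotspots

Candidate pairs pass CIP/CALP ≥ 70/70; genes in one cluster collapse to a
single locus and same-locus pairs are skipped. Each locus contributes a
40-gene flanking window (20 per side by rank, truncated at chromosome
ends). Two implementation details the rule itself does not fix: the windows
exclude the members of *both* loci, and when the two loci sit on one
chromosome closer than the window span, each window stops at the midpoint
between them — otherwise the pair itself, or a local gene family between
the loci, would masquerade as conserved flanking synteny. A pair is
segmental iff ≥ 1 cross-window gene pair aligns at E ≤ 1e−10; calls are
symmetric in the loci. A hotspot is a locus with single-gene-duplication
matches to ≥ 2 partners that have no threshold-passing match between
themselves; the implementation is order-independent and is checked against
a graph-based oracle.

## miRNA scoring

The duplex score sums: mismatch 1.0, G:U wobble 0.5, single-nucleotide
bulge 1.0 (at most one bulge per duplex, on either strand), each doubled at
miRNA positions 2–13 from the 5′ end. For a target bulge the doubled-region
test uses the miRNA position immediately 3′ of the bulge; for a miRNA bulge,
the unpaired position itself. Scores are therefore multiples of 0.5. The
scanner evaluates every offset and bulge placement (vectorized prefix/suffix
sums over penalty matrices), collapses overlapping candidates to the best
one, and reports sites strictly below the threshold (default 4.0; a flag
switches to ≤ for the alternative published reading). Agreement with an
exhaustive enumeration oracle is under test, as is monotonicity: adding a
mutation to a site never lowers its score. Secondary-structure validation
of miRNA precursors is out of scope; inputs are assumed to be curated
mature miRNAs.

The published WGD correlation is reproduced from the packaged per-species
table using the pooled targeted fraction
(cons_targets + noncons_targets)/(cons_total + noncons_total) over the nine
eudicot rows; this definition gives r = 0.7127 against the printed 0.7133
(the source's exact fraction definition is ambiguous; other plausible
definitions differ at the 1e−2 level).

## The synthetic cohort

The generator emulates the history the pipeline dissects, with defaults
chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_anc_chr × genes_per_chr | 5 × 200 | ancestral genome size |
| r_fraction | 0.08 | ancestral R-gene density (rice-like ~6–8%) |
| retention_rate | 0.22 | post-WGD duplicate co-retention, background genes |
| r_retention_rate | 0.06 | co-retention of R-genes (diploidization-sensitive) |
| dominance_bias | 0.35 | excess deletion probability on the sensitive copy |
| tandem_rate / tandem_geom_p | 0.25 / 0.55 | array seeding; sizes 1+Geometric (mostly pairs, tail to ~6) |
| ssd_rate | 0.15 | transposition events per R-gene |
| species_loss | 0.08 | per-species lineage-specific gene loss |
| n_species | 4 | grass-like cohort; SP1 is the reference |
| divergence | 0.03–0.12 | expected identity loss per species |
| n_mirna / targets_per_mirna | 12 / 8 | planted interactome size |
| target_bias_duplicated | 0.75 | planted-target preference for duplicated R-genes |

Splitting the retention rate is deliberate: the background genome retains
far more post-WGD duplicates than R-genes do, and that background supplies
the conserved flanking context the duplication classifier relies on.

Homology is emitted directly as HSP tables — identities decay with the two
species' divergences (plus small extras for tandem/transposed copies),
within-species pair identities reflect time since the duplication event
(WGD ≈ 80–88%, transposition ≈ 82–92%, tandem ≈ 90–97%), and unrelated
pairs receive only sub-threshold noise rows. No nucleotide-level evolution
is simulated; transcripts are random sequences used only by the miRNA
scanner, with planted sites built as mutated reverse complements carrying
an exactly known penalty (0–3 units, placed outside the doubled region).
When configured divergence is zero the emitted HSPs are exactly perfect
(CIP = CALP = 100).

Two generator choices keep the planted truth separable: transposition
destinations exclude the parent's WGD-partner chromosome (a copy landing in
the paralogous block genuinely carries segmental-like flanking context and
would make the truth label meaningless), and only WGD-path genes appear in
the ancestral map (lineage-specific copies have no ancestral placement).

**What passing tests do and do not show.** The cohort has clean block
structure, no gene-order rearrangement beyond transposition, no nucleotide
alignment noise, and homology identities well separated from the calling
thresholds. Passing recovery tests therefore demonstrates correctness of
the inference logic at the configured conditions — not robustness to
borderline identities, fragmented annotations, assembly error, or
reference-bias effects present in real proteome comparisons.

All randomness flows from one seed; per-stage streams are split by hashing
the stage name, so adding a stage does not perturb earlier draws, and a
rerun is byte-identical (under test).

## Problem sizes

The default cohort (4 species × ~1200 genes) generates in ~2 s and runs the
full pipeline in ~12 s on one CPU. Calibration studies use 100 simulated
block pairs at N = 60 with 1000 permutation replicates (5000 where the
closed-form comparison needs tighter Monte-Carlo error); oracle comparisons
use 1000 fuzzed inputs each. These sizes were chosen so the whole suite and
the acceptance script each complete in a few minutes while keeping
binomial/Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The ancestral map is an input; karyotype reconstruction is out of scope.
* The founder pool counts reference-anchored placements, not deduplicated
  ancestral loci (see above).
* HMM scanning and BLAST are not run by the package; it parses their
  outputs (or the simulator's equivalents).
* The miRNA scorer allows at most one bulge per duplex and no target-side
  secondary-structure model.
* Conservation summaries assume the reference species is one of the cohort;
  cross-cohort references are not supported.
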