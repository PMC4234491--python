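# rgenevo

Evolutionary plasticity of plant disease-resistance (R-) genes: a tested,
reusable re-implementation of a comparative-genomics analysis that builds a
non-redundant R-gene catalog from three evidence streams, classifies domain
architectures, calls positional gene clusters, reconstructs an ancestral
founder pool on protochromosome maps, tests biased duplicate retention after
whole-genome duplication (WGD), separates segmental from single-gene
duplications, and computes a miRNA/R-gene interactome.

It is written for comparative genomicists who want to run this style of
analysis on their own annotations — or audit it — without one-off scripts.
Genome-scale inputs for this analysis (a dozen-plus proteomes plus external
HMMER/BLAST runs) are not redistributable, so the package ships a forward
simulator (`rgenevo.synthetic_data`) that generates a multi-species cohort
with full ground truth, and every stage is exercised and tested end-to-end
at desk scale.

## The models and statistics at the core

**Homology calling (CIP/CALP).** All HSPs of one query–subject pair are
summarized as

```
CIP  = 100 · Σ identities / Σ alignment lengths
CALP = 100 · Σ alignment lengths / query length
```

with HSPs overlapping an already-retained HSP on the query by >10% of their
span discarded. Database hits are accepted at CIP/CALP ≥ 70/70; orthologs
and paralogs at ≥ 60/70 (inclusive, no reciprocal-best filtering).

**Domain classification.** Seven R-domain families (LRR, NBS, TIR, LysM,
PKinase, WRKY, RG) map each gene to a structural class (TNL, CNL, RLK, RLP,
RGA) and a functional group (PTI, ETI, R-combination, R-pathway) by a fixed
precedence: NBS∧LRR → ETI (TNL with TIR, else CNL); then LysM or LRR → PTI
(RLK with PKinase, else RLP); then any NBS/TIR/RG → R-combination; else
R-pathway.

**Cluster rule.** A cluster is a maximal run of R-genes in which consecutive
members are separated by at most 8 intervening non-R annotated genes (gap in
gene ranks, not base pairs; transitive chaining).

**Retention permutation Z-test.** For a duplicated block pair with ancestral
R content N and surviving counts n1, n2, the D = 2N − n1 − n2 deletions are
redistributed 1000× with probability ½ per copy; the observed X = n1 − n2 is
standardized against the replicate null, z = (X − u)/σ, whose closed form is
z ≈ (n1 − n2)/√D. Biased retention is declared at p < 0.05 (two-sided
normal; an exact permutation p is also reported).

**Duplication classes.** CIP/CALP ≥ 70/70 R-gene pairs (cluster members
collapsed to one locus) are *segmental* if at least one pair of genes from
the two 40-gene flanking windows aligns at E ≤ 1e−10, else *single-gene*
duplications; a locus matching ≥2 mutually unrelated partners is a hotspot.

**miRNA targeting.** A Targetfinder-style mismatch score (mismatch 1, G:U
wobble 0.5, 1-nt bulge 1, all doubled at miRNA positions 2–13); sites with
score < 4 count as predicted targets.

## Worked example

The analysis is organised as numbered drivers over the library:

```
python analysis/01_simulate_cohort.py   # cohort + truth -> scratch/cohort/
python analysis/02_build_catalog.py     # evidence union -> results/02_*
python analysis/03_call_clusters.py
python analysis/04_conservation.py
python analysis/05_retention_bias.py
python analysis/06_duplication_classes.py
python analysis/07_mirna_interactome.py
```

`02_build_catalog.py` prints, for the default cohort (seed 0):

```
species  n_annot  n_pfam  n_prgdb  n_nonredundant  n_PTI  n_ETI  n_R-combination  n_R-pathway
    SP1       44     118       33             123     65     19               28           11
    SP2       61     134       36             140     73     28               24           15
    SP3       57     129       38             134     73     29               18           14
    SP4       41     117       35             119     63     29               17           10
```

— per species, the three evidence-stream counts, their non-redundant union,
and the functional-group breakdown. `03_call_clusters.py` then reports
79–87% of R-genes in clusters (the gap rule chains aggressively at this
R-gene density, as it does in real genomes) with LRR in 70% of clustered
domain combinations; `05_retention_bias.py` reconstructs an 80-locus founder
pool, flags 7 of 20 block pairs as biased, and finds conservation strongly
predicted by clusterization inside sensitive blocks (r² = 0.73,
p = 1.9e−06); `07_mirna_interactome.py` prints
the interactome table and reproduces the packaged-table correlation between
WGD rounds and targeted fraction over nine eudicot species:

```
WGD rounds vs targeted fraction over 9 eudicots: r = 0.7127, p = 0.031
```

The same stages are available behind one entry point
(`rgenevo simulate|run|catalog|clusters|conserve|paleotest|dupclass|mirna|report`).

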