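# Methods

## The assay being modelled

NlaIII DGE tag profiling sequences a single 21-nt tag per transcript
molecule: the CATG restriction site closest to the 3′ end plus the 17
following bases. Tag counts per library are proxies for transcript
abundance; there is one pooled library per biological stage (MP, HP, PT),
with no replicates. All statistics in this package are exact count
statistics appropriate to that design — no dispersion parameter is
estimable from single pooled libraries, and none is modelled.

## Virtual-tag reference

`reference.scan_catg_tags` indexes **all** CATG+17 sites of every
transcript, not only the 3′-most one: a sequenced tag with an internal
error, an incomplete digest, or an alternative 3′ end can originate from
any site, so the reference must be exhaustive. The 3′-site bias of the
chemistry lives in the simulator instead (`simulate.canonical_tags`).
Both strands are indexed so antisense transcription is detectable.
Ambiguity is defined over distinct gene ids: a tag occurring twice in one
gene still identifies that gene uniquely and is kept. Reference 21-mers
containing N can never match a clean tag and are skipped, but tallied in a
diagnostics field. Sense coordinates are 0-based; antisense tags carry
offsets on the reverse-complement coordinate system so every tag is
recoverable by slicing the stated strand.

The summary reports the unambiguous-tag percentage with the total-tag
denominator and also the raw counts, because historical reports of this
statistic are ambiguous about the denominator.

## Tag QC

Filter order is N-containing → adaptor-identical → copy number < 2, with
copy numbers evaluated after the first two removals. This makes the three
removal classes disjoint, so the ledger identities

```
raw.distinct − N.distinct − adaptor.distinct − singleton.distinct = clean.distinct
raw.total    − N.total    − adaptor.total    − singleton.total    = clean.total
```

hold exactly (they are asserted on every run). Adaptor matching is exact
full-length equality against a configurable list, empty by default.
Spectrum thresholds are ≥ 2 (the clean library itself) and then strictly
greater than 5/10/20/50/100 — the asymmetry follows the conventional
presentation, where only the first bound is written inclusively. FASTQ
input takes the 21-mer at the first CATG of each read; reads without an
anchor are counted as a `no_anchor` diagnostic before the raw tally, which
makes FASTQ support deterministic without modelling read quality.

## Mapping and quantification

Each clean tag is looked up exactly; only tags with no exact hit are
checked against their 63 Hamming-1 neighbours. Exact beats one-mismatch
absolutely; ambiguity (≥ 2 distinct genes) is evaluated within the winning
class only. A tag matching one gene on both strands counts to that gene,
strand recorded sense-first. Tags with no hit are `unknown`; a separate
genomic (non-transcript) mapping class is out of scope, so tags a genome
aligner would capture also land in `unknown`. Gene counts sum the copy
numbers of uniquely assigned tags (both strands pooled; per-strand tallies
are kept in the assignment table) and TPM = count / clean total × 10⁶.
Detection is ≥ `min_tags` unambiguous tags (default 1). Antisense activity
is reported both per distinct tag and per gene-level transcript call,
because the two ratios answer different questions (tag diversity vs how
many genes are bidirectionally transcribed).

Saturation analysis subsamples the clean multiset without replacement;
each replicate's depths are prefixes of one random permutation, which
makes both curves non-decreasing within every replicate by construction.
The closed-form expectation Σᵢ (1 − C(T−cᵢ, d)/C(T, d)) is provided for
verification.

## Differential expression

The Audic–Claverie conditional distribution of *y* given *x* is negative
binomial with *x*+1 successes and success probability N₁/(N₁+N₂); tails
are evaluated through the regularized incomplete beta function
(`scipy.stats.nbinom`), which stays exact in log space at library sizes of
10⁶ and beyond. The two-sided p doubles the smaller of P[Y ≤ y] and
P[Y ≥ y], capped at 1. Doubling a discrete tail is not exactly symmetric
under swapping the libraries — the conditional pmf is, the tail sums are
not — and the doubled p-values for (x, y) and (y, x) can differ by up to a
factor of 2; the test is switchable to one-sided.

Genes with zero counts in both libraries carry no contrast and are not
tested. FDR control is Benjamini–Hochberg step-up by default
(Benjamini–Yekutieli available); a gene is called at q ≤ 0.001 **and**
p < 0.0005 **and** |log₂ ratio| ≥ 1, applied conjunctively — the p
threshold is largely redundant next to the q threshold but is kept because
the convention applies both. Log ratios use a pseudo-TPM of 0.001 on both
sides so stage-exclusive genes get large finite ratios; the significance
test itself uses raw counts and needs no pseudo-count.

## Enrichment

The upper tail P(X ≥ k) is summed term-by-term in log space (lgamma
binomials, `fsum` after rescaling by the largest term), which keeps ≥ 6
significant digits even for p ≈ 10⁻⁷ at backgrounds of ~20,000 genes; it
is verified against exact rational arithmetic in the tests. The background
N is the set of genes carrying any annotation of the ontology, not the
whole reference (both conventions are available). BH correction runs
across all tested terms of one comparison — terms with k = 0 are excluded
by default, matching how pathway lists are reported. The ≥-k (not ≥ k+1)
convention is validated by exact reproduction of published pathway
contingencies in the acceptance tests.

## Clustering

The cluster set is the intersection: expressed in all three stages, and
q ≤ 0.001 with |log₂ ratio| ≥ 1 in *both* transitions. The clustered
quantity defaults to the two log₂ ratios per gene (germination and tube
growth), matching the red/green up-down encoding of the historical Cluster
program, with log₂(TPM+1) per stage as an option. Distance is 1 − centered
Pearson correlation; rows with zero variance have undefined correlation
and are assigned distance 1 to everything. Linkage is average (UPGMA) —
the defaults of the Eisen Cluster program. Gene order is fixed (sorted by
id) before linkage, so the dendrogram is deterministic; merge heights are
checked against a naive O(n³) agglomerative oracle. Output is Eisen CDT +
GTR (node scores = 1 − merge height, i.e. the correlation at each join).

## qPCR

ΔCt normalises the target's mean Ct to the arithmetic mean of the
reference genes' mean Cts (equivalent to a geometric mean of linear
quantities); ΔΔCt then normalises to the calibrator sample, and the ratio
is 2^−ΔΔCt with amplification efficiency fixed at 2. Replicate SEs
propagate through the linear combination of means. Per-reference output is
available where the combined pseudo-reference is not wanted. Concordance
with DGE is sign agreement of log₂ ratios under the same orientation.

## Synthetic study generator

Defaults (all overridable in `SimulationConfig`) and what they emulate:

| parameter | default | why |
|---|---|---|
| `n_genes` | 1,000 | desk-scale stand-in for a ~41k-gene reference |
| `min_len`/`max_len` | 300–1,500 nt | typical transcript lengths |
| `catg_fraction` | 0.90 | ~90% of genes carry a usable CATG site |
| `frac_specific` | MP 0.17, HP 0.05, PT 0.10 | stage-exclusive fractions of a pollen series |
| `frac_de` / `frac_de_both` | 0.10 / 0.03 | ~10% DEGs per transition; overlap feeds the clustering intersection |
| `log2_effect` | 2 (4-fold) | planted effect size, identifiable at this depth |
| `de_min_base_tpm` | 100 | DE planted on moderately expressed genes, as called DEGs are in practice |
| `depth` | 500,000 | scaled-down analogue of 2.5–4.7 M tags/library |
| `error_rate` | 0.005/base | ~10% of 21-mers carry ≥ 1 error |
| `n_read_rate` | 0.012 | N-read fraction of raw libraries |
| `adaptor_rate` | 0 | adaptor reads are typically absent |
| `singleton_noise_rate` | 0.02 | unique junk tags, removed by the copy < 2 filter |
| `antisense_gene_fraction` | 0.24 | minority of genes transcribed bidirectionally → sense:antisense transcript calls ≈ 4:1 |
| `antisense_fraction` | 0.4 | per-read antisense probability within those genes |

Stage-exclusive and DE gene sets are disjoint deterministic slices of a
seeded permutation, so planted counts are exact. Base abundances are
lognormal(log 50, 1.2); each stage column is renormalised to 10⁶ TPM and
the recorded true log₂ ratios are post-normalisation. Ground-truth DE
labels mark every gene whose true ratio reaches |log₂| ≥ 1 — including
stage-exclusive genes, whose ratios are infinite — while `planted` marks
the explicit-effect subset; false-discovery proportions are measured
against the former, sensitivity against the latter.

Sampling is multinomial per library (see above on overdispersion). Each
gene emits its 3′-most sense tag — the tag the chemistry actually
produces — while the reference indexes all sites; per-base errors are
independent substitutions; N-reads are signal-shaped reads with one base
replaced by N; noise tags are unique random CATG-anchored 21-mers.

What the generator does **not** emulate: PCR duplication, quality-score
structure, position-dependent error profiles, incomplete digestion,
overdispersion between biological replicates, genomic (non-transcript)
tag sources, and annotation structure beyond flat gene→term sets (no GO
DAG propagation). Passing tests therefore demonstrate correctness of the
accounting and statistics under the stated generative model, not
robustness to every artefact of real libraries.

## Problem sizes and numerical choices

The default synthetic study (1,000 genes, 5×10⁵ tags per stage) was chosen
as the smallest scale at which every phenomenon of interest — singleton
floors, one-mismatch recovery, antisense calls, planted-DEG recovery at
q ≤ 0.001, planted-term enrichment — is comfortably identifiable; the test
suite uses a 300-gene/10⁵-tag version of the same conditions for speed.
Percentages in published-style summary tables are rounded half-away-from-
zero to the stated decimals via decimal arithmetic, so printed values
reproduce exactly. Tail computations are performed in log space
throughout; cross-implementation agreement is required to 10⁻¹⁰ relative
(Audic–Claverie) and against exact rational arithmetic (hypergeometric).

## Known limitations

* No genome-level mapping class: tags from unannotated genomic loci land
  in `unknown`.
* One-mismatch lookup assumes fixed-length (21-nt) tags; indels are not
  modelled on either side.
* The Audic–Claverie test, like all single-library exact tests, treats
  sampling as the only noise source; with biological replicates a
  dispersion-modelling framework would be preferable.
* BH correction assumes independence/PRDS across genes and terms;
  BY is available where that is doubted.
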