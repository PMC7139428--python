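# Methods

This package implements a small-RNA-to-validated-target pipeline for
two-group animal studies: differential expression of mature miRNA
counts, integration of multi-source miRNA–target predictions, signed
bipartite network analysis with hub detection, GO over-representation,
a hub-selection rule, and 2^−ΔΔCp qRT-PCR statistics. This note
records the models, the defaults and why, and what the synthetic
benchmark does and does not establish.

## Differential expression

Counts for miRNA *i* in sample *j* are modelled as negative binomial,

    y_ij ~ NB(mu_ij, phi),    log mu_ij = beta_{i,g(j)} + log(N_j f_j)

with library size N_j, TMM scaling factor f_j, group g(j) ∈ {control,
treated} and a single common dispersion phi shared across miRNAs.

**TMM.** Scaling factors are trimmed means of per-miRNA log2 ratios
(M-values) against a reference sample (the one whose 75th-percentile
count fraction is closest to the across-sample mean), double-trimmed
(30% on M, 5% on A) with inverse asymptotic-variance weights, then
rescaled to geometric mean 1. This follows the standard TMM recipe for
count libraries.

**Dispersion.** The common phi maximises the Cox–Reid adjusted profile
likelihood summed over miRNAs: for each candidate phi the two group
means are fitted per miRNA by Newton iteration on the one-parameter
score equation (cell-means coding makes the information matrix
diagonal, so the adjustment is half the log of the per-group summed
working weights), a coarse log-grid (0 and 10^-4…10, 21 points) is
scanned and the maximiser refined by bounded scalar optimisation. A
common dispersion, rather than tagwise empirical-Bayes shrinkage, is a
deliberate simplification: the scientific output of this stage is the
set of significance/sign calls, and at the scale of this design
(hundreds of miRNAs, a handful of strong effects) the common-dispersion
likelihood-ratio test reproduces the calls of the full
empirical-Bayes machinery. On random matrices the TMM factors agree
with an independently coded reference to 1e-10, and the null
type-I fraction at raw p < 0.05 stays within 0.05 ± 0.02 (measured in
the test suite over 50 simulated null datasets).

**Testing.** Each miRNA is tested by a likelihood-ratio test of the
group coefficient (full two-mean model vs pooled single-mean model,
both at the estimated common phi) against chi-square(1). logFC is
computed from group-mean CPM with a pseudo-count of 0.5 per group so
that zero counts give finite values. BH step-up correction is applied
over all tested miRNAs; directions are called at FDR < alpha
(default 0.05). Non-finite fits fall back to p = 1, logFC = 0 and are
flagged.

**Detectability.** A miRNA is "detectable" when its total count across
all samples reaches `min_total` (default 1). The threshold is
configurable because detectability criteria vary between studies and
are rarely reported.

## Target integration

Three evidence tables are merged: a predicted-score source (0–100
scale, kept when score **> 80.0**), a regression-score source
(mirSVR-style, more negative = stronger repression, kept when score
**< −1.2**) and a curated source of experimentally validated
interactions (kept unconditionally, since curation is itself the
filter). Both cutoffs are strict inequalities and configurable.
Integration is the union of the filtered sources (no cross-source
agreement requirement), restricted to significantly DE miRNAs, with
(miRNA, gene) pairs deduplicated keeping the union of their sources.
miRNA names are canonicalised (species prefix and id lower-case, stem
`miR`, arm suffix preserved); gene symbols are matched
case-insensitively and stored upper-case. No ortholog mapping is
attempted: gene identifiers are opaque symbols.

## Signed network and hubs

The network is bipartite: DE miRNAs on one side, target genes on the
other, one edge per integrated interaction, weighted +1 if the miRNA
is upregulated and −1 if downregulated. For a target gene t,

    deg(t) = number of incident edges,
    s(t)   = sum of incident weights  (node strength),

so |s| ≤ deg and s ≡ deg (mod 2). Hubs are, by default, the genes at
the maximal observed degree — the most densely co-regulated targets,
and hence the most likely to shift in expression. The maximal degree
is data-dependent, not a constant; a fixed-threshold policy
(degree ≥ k) is available for reuse. Strengths are reported for gene
nodes; miRNA-side strength is derivable from the graph but plays no
role in the rule set.

## GO over-representation

For a target list of size n from a universe of N annotated genes, a
term with K annotated genes and k overlapping targets gets

    fold enrichment = (k/n)/(K/N),
    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

with either BH (default) or Bonferroni correction across all tested
terms (k ≥ 1). Both corrections exist because published analyses use
either, sometimes inconsistently within one study; the choice is a
parameter, not a hidden constant. The annotation is taken flat from a
GMT file — no DAG propagation or term pruning — and the universe
defaults to the union of annotated genes.

## Candidate selection

The selection rule mirrors the two-part logic of strength plus
pathway context:

1. every hub with **negative** node strength is selected
   unconditionally (the stated rule names strength −1; since hubs in
   the motivating data all have strength ±1 the generalisation to
   s < 0 is behaviour-preserving, and it is the sensible extension for
   deeper networks);
2. positive-strength hubs are ranked by the **maximum fold enrichment
   over significant terms annotating them** and the top `n_positive`
   (default 3) are added. Ties break by smaller term p, then gene
   symbol, so the selection is deterministic and invariant to input
   order. The scoring is configurable because the original selection
   may have involved expert judgement; ranking by best-term fold is
   the most direct quantitative reading.

## qPCR quantification

Duplicate wells are averaged **on the Cp scale**; per sample,
ΔCp = Cp(target) − Cp(reference); ΔΔCp = ΔCp − mean(ΔCp over control
samples); expression = 2^−ΔΔCp in arbitrary units. Anchoring on the
Cp scale means the *geometric* mean of control expressions is exactly
1 (the arithmetic control mean is 1 on noiseless data only). The chain
is invariant to adding a constant to every Cp. Groups are compared by
an unpaired Student's t-test on the per-sample expressions
(equal-variance by default, Welch optional); results are reported as
mean ± SEM. Degenerate inputs are handled explicitly: samples missing
the reference gene are dropped with a warning, groups with fewer than
two samples yield no test, and zero variance in both groups with equal
means reports p = 1 with a warning rather than NaN.

**Amplicons.** In-silico PCR is exact-string matching of the forward
primer and the reverse complement of the reverse primer on the spliced
transcript sense strand; the product is the 1-based inclusive span
from the forward site's first base to the reverse site's last base.
Multiple possible products report the smallest with a warning. No
mismatch tolerance, dimer or self-priming checks are attempted — those
are primer-design-time concerns.

## Synthetic data: what it emulates, what it does not

The generator plants ground truth at every stage so recovery is
checkable end to end:

- **Counts**: NB with per-miRNA baseline log2 abundance uniform on
  (0, 12), library sizes uniform on [1M, 2M), dispersion 0.1, 6
  samples/group, 500 miRNAs with 5 planted DE at |log2FC| = 2 — the
  shape of a small-animal cardiac small-RNA study. phi = 0
  degenerates to Poisson exactly.
- **Interaction tables**: each planted hub edge lands in exactly one
  source with a passing score; decoys carry failing scores (curated
  decoys involve only non-DE miRNAs). Planted hub degrees/strengths
  are therefore recovered exactly by integration — by construction,
  which is the point: it isolates failures to the code, not the draw.
- **GO annotation**: configured enriched blocks plus random background
  terms plus a root term covering the whole universe.
- **Cp tables**: per-gene baselines, per-sample offsets (RNA input;
  they cancel exactly in ΔCp), a −log2(fold) treated-group shift, and
  Gaussian well noise (sd 0.1 by default, duplicates, n = 7/group).

Each generator draws from its own seed-derived stream, so generators
are independently reproducible. What the synthetic benchmark does
*not* show: robustness to mapping/counting artefacts, compositional
extremes, batch effects, database inconsistencies (synonyms, retired
symbols), or qPCR efficiency differences — real-data concerns outside
the statistical contract tested here.

Power note: with baselines uniform on (0, 12), the weakest planted
miRNAs sit at means of a few counts where power at n = 6/group is
below 1; around 1% of planted miRNAs are missed (never with the wrong
sign). The recovery tests assert zero sign errors with a 95% power
floor.

## Numerical choices

- Newton fits are damped (step clipped to ±5) and started at the
  closed-form Poisson solution; zero-count groups use the exact
  mu = 0 limit.
- BH is the standard step-up with cumulative-minimum enforcement; ties
  need no special-casing.
- The LRT statistic is clipped at 0 before chi-square evaluation.
- All orderings (interactions, hubs, enrichment, selection) have
  total, documented tie-breaks so byte-identical reruns are guaranteed.
- Problem sizes in tests (500 miRNAs × 12 samples, 20 + 50 simulation
  seeds, exhaustive hypergeometric enumeration at N ≤ 20) were chosen
  to exercise the asymptotics that matter while keeping the suite
  fast on one CPU.

## Known limitations

- Common dispersion only; designs with strong tagwise dispersion
  heterogeneity will be mis-calibrated at the extremes.
- Two-group designs only; no covariates or paired structures.
- The selection rule's positive-hub scoring is one defensible reading
  of a rule that may originally have involved judgement.
- Amplicon checks require a user-supplied transcript FASTA; no
  accession fetching.
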