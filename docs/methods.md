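# Methods

## Problem and model

Tumor genomes carry many promoter methylation alterations, but only a
minority are *drivers* — alterations that change the tumor's expression
program — while the rest are *passengers*. `methdriver` identifies
driver alterations from paired promoter methylation (beta values) and
expression profiles of a tumor cohort with matched normal samples, under
the working assumption that a driver alteration (a) changes its own
gene's expression in cis, anti-correlated with promoter methylation, and
(b) changes the expression of a downstream gene program enriched in
cancer-associated pathways.

### Discretization

For each CpG locus, the mean μ and standard deviation σ of the beta
value across the normal samples define a reference. Each tumor's beta
value is converted to z = (β − μ)/σ and tested two-sided against the
standard normal; p-values are BH-adjusted and a state is assigned:

    state = sign(z)  if q < q_discretize (default 0.05),  else 0

yielding a ternary matrix with +1 = hypermethylated, −1 =
hypomethylated, 0 = no differential methylation. The BH family is each
tumor sample's own locus profile (discretization is defined per
individual sample; each sample's profile is its own multiple-testing
family). A single global family over all (locus, tumor) pairs is
available via `discretize_scope="global"`. Loci with zero normal-sample
standard deviation have no defined z-score and are dropped with a logged
count. Normal samples are never discretized. Tightening the threshold
(0.05 → 0.01) can only remove nonzero states, since the q-values are
fixed given the scope — this monotonicity is asserted in the tests.

### Candidate filter

A locus is a candidate, separately per direction, when at least 10% of
tumors (inclusive boundary) carry that state. A gene with a hyper
candidate and a hypo candidate among its loci is excluded entirely —
such bidirectional patterns are uninterpretable under the cis model.
Tumors carrying the opposite state at a locus belong to neither
comparison group at any later stage.

### The three driver conditions

1. **Cis effect.** Welch's two-sided t-test on the candidate's own gene
   expression, altered vs zero-state tumors; BH across all candidates
   tested; pass iff q < 0.05 *and* the direction is concordant
   (hypermethylation → lower expression in altered tumors, hypomethylation
   → higher). Student's pooled test is available via `equal_var=True`.
2. **Downstream effect.** Downstream genes are the DE genes (Welch
   t-test, BH q < 0.05) between altered and zero-state tumors over the
   whole expression matrix, excluding the candidate's own gene. The
   observed count is compared with a permutation null: B random draws of
   two *disjoint* tumor groups of the same sizes, each scored the same
   way (the candidate's own gene excluded identically). The empirical
   p is the fraction of replicates whose count is at least the observed
   one (≥, the conservative convention for discrete statistics); BH
   across candidates; pass at q < 1.00E-04.
3. **Pathway disturbance.** Upper-tail hypergeometric enrichment of the
   downstream set in each cancer-associated pathway, with the background
   being all genes in the expression matrix (the universe on which
   downstream genes are defined); pathways intersected with the
   background first. BH across the pathways tested for the candidate
   (one family per candidate by default; a single family across all
   candidate × pathway tests via `pathway_fdr_scope`); pass iff any
   pathway q < 1.00E-04.

A locus passing all three is a driver alteration; a gene with ≥ 1 driver
locus is a driver gene. Full provenance (every candidate with its
per-stage statistics) is always emitted. Stage nesting — drivers ⊆
condition-2 survivors ⊆ condition-1 survivors ⊆ candidates — holds by
construction.

**Empirical p estimator.** The default is the plain fraction r/B. The
permutation pass threshold of 1.00E-04 implies a required p resolution
finer than 1/B whenever B ≤ 10⁴: the add-one estimator (r+1)/(B+1),
whose smallest attainable value is 1/(B+1), can then never clear the
threshold at reduced replicate counts, although it is otherwise the
better-behaved choice (it cannot return 0). The plain fraction keeps the
threshold meaningful at any B and is the convention the test suite and
acceptance runs use; `permutation_estimator="add_one"` switches to the
conservative estimator for full-scale runs (B = 100,000), where its
floor of ~1e-5 is well below the threshold.

**Shared null cache.** The permutation null depends only on the two
group sizes, so replicate counts are generated once per
(n_altered, n_zero) pair under a seed derived deterministically from the
base seed and the sizes, and reused across candidates. Per-candidate
own-gene exclusion subtracts the per-replicate indicator of that gene
being DE, so semantics are identical to independent per-candidate runs
of the same null; fully independent draws are available via
`share_permutation_null=False`.

**Minimum group size.** Any t-test stage requires ≥ 3 tumors per group;
smaller candidates are skipped and reported with a reason rather than
tested.

### Validation statistics

* Known-cancer-gene enrichment: overlap of the driver list with a
  curated cancer-gene set, percentage and upper-tail hypergeometric p.
  The default background is the set of genes with ≥ 1 analyzable
  promoter locus (the universe actually tested); published analyses of
  this kind rarely state their background, so the p-value is reported
  but only the counts/percentages are comparable across studies.
* PPI neighbor enrichment: the novel drivers (drivers minus known cancer
  genes, restricted to network nodes) tested against the direct
  interaction neighbors of the known cancer genes, background = network
  nodes minus the cancer genes. Reported as not-applicable when the test
  set is empty.
* POG (percentage of overlapping genes) between two driver lists:
  reported directionally (100·k/|A|, 100·k/|B|) and symmetrized as their
  mean. The symmetrized form is used because it is the only simple
  definition that reproduces published pairs of POG values from the
  corresponding list sizes at integer overlap counts. Significance is an
  upper-tail hypergeometric test of the overlap against a stated
  background.

### Subtype analysis

Tumors are clustered on their ternary states over the driver loci.
Distance is a ternary Jaccard: similarity = |positions with equal
nonzero state| / |positions nonzero in either profile| (two all-zero
profiles are identical, distance 0). Hyper and hypo are distinct
categories — a +1/−1 pair is a mismatch — preserving the biological
asymmetry of the two directions; a binarized variant (any nonzero → 1)
is available via `jaccard_binarize`. Agglomeration is average linkage
(UPGMA) with the dendrogram cut at k clusters (default k = 3, a config
parameter; no automatic selection). Tumor columns are put in sorted-id
order before the linkage is computed, which fixes tie-breaking and makes
the result invariant to input column order; merge heights are
non-decreasing by the UPGMA property. The dendrogram is exported as
Newick text.

Subtype specificity is tested per driver locus in its driver direction:
for each subtype, k altered tumors among the n subtype members, against
K altered among all N labeled tumors, p = P(X ≥ k) hypergeometric; BH
across all (locus, subtype) pairs; specific iff q < 0.05 and the
in-subtype frequency exceeds the out-of-subtype frequency. Gene-level
rollup is "any significant locus". Unlabeled tumors are excluded with a
logged count.

## Synthetic cohorts

The generator produces complete input bundles with known truth. Study
conditions (defaults): 20 normals, 60 tumors, 500 promoter loci (one per
gene), 2,000 genes, 20 pathways of 50 genes, 10 planted drivers and 50
planted passengers altered in 30% of tumors, methylation shift ±0.3 beta
units on a per-locus Gaussian baseline (mean in [0.2, 0.8], sd 0.05,
truncated to (0, 1)), cis effect 1.5 and downstream effect 1.0 in units
of the unit expression noise sd, downstream programs of 40 genes drawn
from 1–2 designated pathways, 3 tumor subtypes with the first three
drivers concentrating ≥ 80% of their altered tumors in one subtype, and
a cancer-gene list wired to the planted drivers through a network of
driver–cancer-gene edges over an Erdős–Rényi background.

Truncated-Gaussian beta values make the Z-score model exactly correct
under the null, so calibration tests have clean expectations (null
nonzero fraction far below the 5% FDR level); a moment-matched
Beta-distributed mode exists to probe robustness and carries no
calibration guarantee. One locus per gene avoids gene-level ambiguity in
truth scoring; a multi-locus mode exercises the both-direction exclusion
rule. The generator does not emulate real array probe distributions,
beta bimodality, batch effects, or correlated expression noise —
passing recovery tests demonstrate the machinery is correct under its
own assumptions, not performance on real cohorts.

With these conditions the planted downstream effects sit deliberately
near the BH detection boundary (per-gene t ≈ 3.5 at 18 vs 42 tumors), so
the observed downstream counts — and occasionally the pathway-q of a
weak driver — vary noticeably between seeds; locus-level recall is
typically 0.8–1.0 with precision at or near 1.0.

## Problem sizes and numerical choices

Recovery and calibration runs use B = 1,000 permutation replicates on
the 500-locus/2,000-gene cohort, a size chosen so the full suite and the
acceptance script each complete in minutes on one CPU while leaving the
permutation p-value enough resolution for the 1.00E-04 threshold under
the plain-fraction estimator; a full-scale analysis would use the
default B = 100,000. Zero-variance genes get p = 1 everywhere a t-test
is undefined. Hypergeometric tails use the survival function at k − 1
(P(X ≥ k)); k = 0 gives p = 1 exactly. Degenerate Jaccard comparisons
(two silent profiles) count as identical. All randomness flows from a
single base seed: the permutation cache derives per-size seeds from it,
and the generator is bit-reproducible given its seed.

## Known limitations

* The discretization Z-test treats the normal-reference mean and sd as
  known; with few normals the reference is noisy and the test anti-
  conservative. At least 2 normal samples are required, more are better.
* Expression must arrive normalized and log-scale; no renormalization,
  batch correction, or missing-value imputation is performed (loci with
  missing values are to be dropped upstream).
* The enrichment background (all genes in the expression matrix) and the
  BH family scopes are analysis choices; both are configurable and both
  materially affect absolute p-values.
* Copy number, mutation and microRNA integration are out of scope, as is
  any mapping between methylation array platforms.
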