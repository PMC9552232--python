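# Methods

This note documents the statistical procedures implemented in
`prepmatrix`, the choices made where the underlying analysis admits
more than one reading, and what the synthetic-data generator does and
does not emulate.

## Preprocessing model

LFQ intensities are treated as linear-scale, nonnegative values with
zero meaning "not quantified in this run". The quantitative path
applies, in order: row filtering (reverse hits, potential
contaminants, groups identified only by a modified peptide, groups
with fewer than `min_razor_unique = 2` razor+unique peptides, and iRT
retention-time standards matched by accession substring, defaults
`"iRT"` / `"Biognosys"`); per-cell masking of identifications not made
by MS/MS fragmentation (match-between-runs transfers are kept in the
table for audit but never enter quantification); log2 transformation;
a valid-value cutoff requiring at least `min_valid = 3` valid cells in
at least one method group (= the replicate count, so at least one
method must have observed the protein in every replicate); and
constant imputation at `⌊min over valid log2 cells⌋`.

Choices worth noting:

* **Razor+unique cutoff is global**, not per sample; the dialect
  reports a single per-group count and the filter is a row filter.
* **"Only identified by site"** and "only by a modified peptide" are
  treated as the same flag — the dialect has exactly one such column.
* **Groups for the valid-value cutoff are methods** (16 groups of 3),
  the grouping used everywhere else in the analysis. The MS/MS
  restriction is applied per sample (it defines cell validity); a
  protein-level interpretation is available via `msms_scope`
  configuration if a user wants it.
* **Constant imputation** deliberately places censored values at the
  detection floor. On data with intensity-dependent dropout this is a
  conservative stand-in for the missing low-abundance signal; it also
  means imputed cells distort centered profiles of proteins near the
  detection limit (see Limitations).

The overlap (Venn/UpSet) analysis uses its own clearing path —
contaminants, reverse hits, only-by-site and iRT rows removed, but no
peptide-count cutoff and no valid-value filter — and counts a protein
for a method when at least `min_reps = 2` of 3 replicates identified
it by MS/MS. Overlap percentage is |intersection| / |union| × 100.

## Clustering

Clustering operates on method-level profiles: replicate-averaged,
per-protein mean-centered log2 intensities (16 columns). Centering
(no variance scaling) preserves the units of the heatmap — deviations
in log2 LFQ intensity — which a z-score would destroy. Sample-level
(48-column) clustering is available behind `cluster_level`.

k-means uses the Euclidean objective with k-means++ initialization and
25 restarts per k (best restart by SSW kept), k = 2…15 by default,
seeded and fully reproducible. The SSW curve is monotone by
construction; in the rare event a larger k lands above a smaller one,
one extra run initialized from the previous solution plus its
worst-served point restores monotonicity.

The number of clusters is selected at the **elbow**: the k maximizing
the second forward difference `ssw[k−1] − 2·ssw[k] + ssw[k+1]`. This
is a deterministic operationalization of "where the SSW curve stops
dropping"; it is exposed with an override because no elbow rule is
canonical. A curve whose largest relative per-step drop is below 1%
is reported as having no elbow (smallest k returned, flagged).

The cluster dendrogram is UPGMA (average linkage) on Euclidean
distances between cluster mean profiles; UPGMA is used precisely
because its cophenetic distances are ultrametric. Trees are emitted
as Newick with leaf heights at the merge heights.

PCA is computed at sample level (48 observations, proteins as
variables, mean-centered, unscaled) on the imputed matrix.

## Enrichment and the guide matrix

For feature f and cluster c over the clustered universe of N proteins
(cluster size n_c, feature total K_f):

    expected = n_c · K_f / N
    EF       = observed / expected
    p        = P(X ≥ observed),  X ~ Hypergeometric(N, K_f, n_c)

The p-value is the one-sided (enrichment-direction) Fisher exact
test. No multiple-testing correction is applied by default — cells
are flagged on raw p < 0.05, with EF ≥ 2 marking strong enrichment —
matching how such guide matrices are read (per-cell flags, not a
family-wise claim); Benjamini–Hochberg is available behind
`bh_correction`. Proteins missing from the annotation table count as
feature-negative members of the universe, so expected counts refer to
all clustered proteins (`drop_unannotated` restricts the universe
instead). Protein groups map to annotations via their first listed
accession.

## ID statistics

**Bridging.** Two measurement blocks (in-solution-digest batches 1–3,
cleanup batches 4–6) are bridged via re-measured samples of one method
from each block (defaults SDC-A and EasyPep), all bridge runs acquired
in a single sequence. The relative median change factor is

    f = (median(bridge_a) − median(bridge_b)) / median(bridge_b)

and the corrected block-a anchor median is `m* = median(b original
samples) · (1 + f)`. Every method group in block a is rescaled so its
median m_g maps to `m* · (m_g / m_a)` — i.e. the whole block is
scaled by `m* / m_a`, preserving within-block proportions. The
correction is applied to ID counts only, whenever bridge samples are
provided, and the corrected counts are kept as reals (not re-rounded).
Original-run medians (not bridge re-measurements) define `m_a` and the
anchor. Note that f = 0 forces group a's median to group b's — the
correction is the identity exactly when the bridge ratio equals the
original ratio, the consistent no-drift case.

**Linear model.** Over the 30 in-solution-digest runs, each response
(protein IDs, peptide IDs, zero-missed-cleavage peptide IDs) is fitted
by OLS on treatment-coded factors `batch + precipitation + buffer`
(SPEED coded buffer = TFA, precipitation = none). The ANOVA is
sequential (Type I) in formula order by default, with Type II
available for the unbalanced design. Per-level predictions are
population-marginal means — the fitted model averaged over the
observed covariate distribution with the factor set to each level —
with t-based 95% confidence intervals on the residual degrees of
freedom. Partial residuals (residual + term contribution) support
effect plots. Interaction terms are deliberately out of scope: with
3 replicates per condition they are not resolvable.

## Modification artifacts

Open-search PSM counts are summed over each method's replicates and
expressed as percentages of that method's total PSMs (unmodified
included, so columns sum to 100). A modification is flagged
method-specific when its maximum per-method percentage is ≥ 0.05%
**and** ≥ 2× the median across methods. Both thresholds are invented
operationalizations of "method-specific and low-abundance" and are
configurable; flagged and unflagged rows carry the percentages needed
to judge them. A built-in list annotates known preparation artifacts
by mass shift within ±0.01 Da: +40.0313 (acetone/propionaldehyde),
+26.0157 (acetaldehyde), +12.00 (formaldehyde), +151.9966 (DTT adduct),
±57.0215 (alkylation-related), +43.0058 (carbamylation).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis
assumes, with one seeded RNG stream per output table (integer spawn
keys; a seed fully determines every byte of every file):

* **Design**: 16 methods × 3 replicates, ISD in batches 1–3, cleanup
  in 4–6.
* **Intensities**: `log2 x = baseline_i + effect[cluster_i, method] +
  ε`, baselines N(30, 3²) log2 units (≈ 4 orders of magnitude of
  linear dynamic range), replicate noise σ = 0.3. Five planted
  clusters with exact sizes (700/500/350/300/150 at n = 2000). The
  default effect matrix is a fixed ±1.5 log2-unit pattern whose rows
  mimic realistic protein classes (a large "every method works"
  cluster; chloroform/methanol-sensitive; SDC-favored/GnHCl-depleted;
  device-favored; ISD-favored/kit-depleted). The pattern gives each
  cluster a separation commensurate with its size so the SSW elbow is
  attainable; non-default cluster counts fall back to sparse random
  ±effect patterns.
* **Missingness**: logistic intensity-dependent dropout with midpoint
  `baseline_mean − 2·sd` and slope 1.5 per log2 unit, plus 0.5%
  completely-random dropout. Match-between-runs transfers are also
  intensity-dependent (midpoint 1.5 log2 units above the dropout
  midpoint) plus a 2% random component — transfers concentrate where
  fragmentation fails, as in real data.
* **Decoys**: 5% contaminants (`CON_`), 5% reverse (`REV_`), 2%
  only-by-site, one iRT row; 5% of real rows get razor+unique = 1 so
  the evidence filter has work to do.
* **Features**: five binary features, each with prevalence 0.5 inside
  one planted cluster and 0.1 elsewhere.
* **ID counts**: method means in the 3550–4400 range (SDC highest,
  GnHCl lowest), batch offsets of tens of counts, noise sd 40, a −1%
  block drift by default (−10% in the bridging stress test), and three
  drift-free bridge replicates per bridge group.
* **Modifications**: multinomial PSM draws (50 000 per sample) over a
  ten-entry menu with planted method-specific excesses (carbamylation
  in urea, +40.03 in acetone-precipitated, +26.02 in EasyPep, +12.00
  in FASP, +151.997 in SDC/S-Trap).

Not emulated: spectrum- or peptide-level identification, retention
time and chromatography, correlated (protein-complex) abundance
structure, shared-peptide ambiguity in protein grouping, batch effects
on intensities (only on ID counts), and annotation noise. Passing
tests therefore demonstrate the correctness and calibration of the
computations under the assumed generative structure — not robustness
to everything real data can do.

## Test and acceptance problem sizes

The pipeline's recovery checks run at the study scale: 2000 proteins ×
48 runs, k swept 2–15 with 25 restarts, 20 seeded repetitions for the
elbow/ARI check; 1000 null datasets for F-test calibration; 100
permutations for enrichment calibration; 100 runs for CI coverage.
Unit tests use smaller fixtures (500-protein tables, 6-sample toy
designs). `scripts/acceptance.py` repeats the main computations at
the same scale and finishes in well under a minute.

## Known limitations

* Constant imputation biases centered profiles of near-detection-limit
  proteins; in recovery tests this is the dominant source of
  misassignment (adjusted Rand ≈ 0.91–0.95, not 1.0).
* The elbow rule needs the successive SSW drops up to the true k to be
  of comparable size; very unequal cluster sizes with weak signatures
  can pull the elbow below the planted k. The override exists for
  exactly this reason.
* The Fisher universe is the clustered proteome; if annotations cover
  only part of it, unannotated proteins dilute expected counts unless
  `drop_unannotated` is set.
* Bridging assumes the bridge runs of both groups are exchangeable
  with their original runs up to the block-level drift; replicate
  noise in the four medians propagates directly into the correction.
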