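# Methods

This note documents the statistical model, the numerical and design choices
made where the workflow was genuinely open, and what the synthetic-data
generator does and does not establish.

## Preprocessing

Raw read counts from a targeted-sequencing exposure study are processed as
counts per million (CPM, each library scaled to sum 10^6), then ratioed
against the matched vehicle-control library on the log2 scale, and finally
averaged across the surviving replicates of each compound.

**Pseudocount.** Log2 ratios use `log2((cpm_t + c) / (cpm_ctrl + c))` with
`c = 0.5` on both sides.  The offset keeps zero counts finite and is
symmetric: a gene absent in both treated and control reads exactly 0.
The value is the field's conventional small offset; results are insensitive
to it for genes with tens of counts or more.

**Negative-control QC.** The share of total counts carried by water-only
libraries must stay strictly below 0.3%; a share of exactly 0.3% fails.
Duplicated reference-RNA libraries are correlated (Pearson, on
log2(CPM + 0.5)) within and between batches; log scale makes the check
invariant to sequencing depth.

**Outlier replicates.** A replicate's dissimilarity is 1 − Pearson *r*
between its log2 profile and the mean of the *other* replicates of the same
compound; replicates with dissimilarity strictly above 0.2 are removed.
Two deliberate choices here:

* *Leave-one-out, not leave-one-in.*  If the candidate sample is included
  in the group mean, the mean is dominated by that sample exactly when its
  noise is largest, so the correlation is driven back toward 1 and a noisy
  outlier can never cross a 0.2 cutoff.  The leave-one-out form detects
  both a grossly noisy replicate and an anticorrelated one (dissimilarity
  ≈ 2).
* *Greedy one-at-a-time removal.*  A single gross outlier contaminates its
  groupmates' leave-one-out means; removing only the worst offender per
  pass and recomputing prevents faithful replicates from being dragged out
  with it.

The rule is correlation-based rather than dendrogram-height-based because a
tree cutoff depends on the linkage chosen; an average-linkage, Euclidean
full-cohort dendrogram is still emitted for visual inspection.

## The shrunken-centroid classifier

Standard NSC estimator: class centroids and overall centroid are plain
means; the pooled within-class SD uses denominator (n − K); the fudge factor
s0 is the median of the pooled SDs; the class-size factor is
m_k = sqrt(1/n_k − 1/n); standardized contrasts are soft-thresholded by the
shrinkage Δ; classification uses the standardized squared distance to each
shrunken centroid minus 2 log π_k, with class probabilities given by a
softmax of −δ_k/2 (computed with a log-sum-exp shift, since scores can
differ by hundreds of units).

**Priors** default to uniform (0.5, 0.5), matching the balanced 10 + 10
reference design; empirical priors are available by flag.

**The probability rule is strict and binary**: a compound is HDACi only if
P(HDACi) > 0.90; a probability of exactly 0.90, or anything lower, yields
non-HDACi.  This asymmetry is intentional — the call asserts a specific
mechanism, so the burden of evidence is on the positive class.

**Cross-validation** is performed at the compound level (all replicates of
a compound enter one fold — replicate leakage across folds would inflate
accuracy), stratified by class, with a caller-supplied seed.  With 20
compounds and 10 folds every fold holds exactly one compound of each class.
Held-out compounds are called with the same strict 0.9 rule, so an HDACi
compound that fails the cutoff counts as an error.

**Shrinkage selection**: the default grid is 30 evenly spaced Δ values from
0 to the smallest Δ that extinguishes every gene.  Among grid points with
CV accuracy ≥ 0.95 and a surviving panel of 50–100 genes, the largest Δ
(smallest panel) is chosen; if no point satisfies both, the accurate point
nearest the size window is returned with a warning, and if no point reaches
the accuracy floor at all the selection is a hard error.

## PCA and clustering prongs

The probability rule is the formal classifier; PCA and hierarchical
clustering corroborate it.  The combined call always equals the probability
call, with a `concordant` flag instead of voting — when the prongs disagree,
the quantitative rule should win.

* PCA is fitted on centered (not rescaled) reference profiles only; queries
  are projected with the reference loadings, so reference geometry never
  shifts.  PC1 is oriented so the HDACi class mean is positive and the
  threshold is the midpoint of the two class means — a reconstruction of a
  visual separator, documented as such.
* Clustering is average-linkage on Euclidean distance, cut at two clusters,
  over the references plus ONE query at a time (queries never influence each
  other's calls); the call is the majority reference class in the query's
  cluster.  A singleton query cluster or a tied majority makes the prong
  unclassifiable and the combined call falls back to the probability rule
  with a warning.  A joint all-compounds tree is available for display.

## The frozen 19-gene panel

The packaged asset stores, for each of the 19 genes, an HDACi centroid, a
non-HDACi centroid, and an SD.  The asset is interpreted as a complete,
self-contained classifier: the centroid columns are used directly as the
shrunken standardized centroids and the SD column as the per-gene
denominator (s_i + s0), with uniform priors and the 0.9 cutoff.  Under this
convention the panel behaves as expected: its own HDACi centroid vector is
classified HDACi with probability > 0.999, and the zero (no-response)
profile is decisively non-HDACi.  The asset file records a SHA-256 checksum
over its canonical JSON payload; a mismatch at load time is a hard error.
Missing panel genes in an incoming profile are a hard error by default
(`max_missing` permits explicit zero-imputation, loudly) because a biomarker
call on a partial panel is a weaker claim.

## Synthetic data

The generator emulates the classifier's own generative assumptions so that
parameter-recovery and calibration tests are meaningful:

* a compound's mean log2 profile is `overall_mean + effect_scale * class
  centroid + N(0, gene_sd)` per gene, with `gene_sd` defaulting to the
  panel's SD column — i.e. the SD is interpreted as between-compound,
  within-class variability, which is what the classifier's pooled SD
  estimates;
* replicates add `N(0, replicate_sd)` (default 0.5, a typical technical
  spread for targeted sequencing at moderate depth) and are averaged;
* `overall_mean` defaults to the zero profile, so the null model
  (`effect_scale = 0`) draws compounds around *no transcriptional
  response*.  This is the scientifically meaningful null — an inactive
  compound leaves expression at control levels — and under it the 0.9 rule
  is strongly conservative (the zero profile's HDACi log-odds are ≈ −26).
  A null centered between the two classes would instead sit on the decision
  boundary and say nothing about specificity.
* the count layer draws control expected CPM log-normal (rescaled to sum
  10^6), sets treated expected CPM to `control * 2^fc`, and observes Poisson
  counts at a configurable library size (negative-binomial overdispersion
  via `phi`, default off, for an exact mean–variance contract).  The design
  includes matched vehicle controls per replicate index, two water-only
  libraries at 0.1% of a library's depth (negative-control QC passes by
  construction) and duplicated reference-RNA libraries, in one batch.

**What a green test does not establish.**  The generator produces Gaussian,
gene-independent noise on the log2 scale with no batch effects, no probe
artifacts and no gene–gene correlation.  Perfect synthetic classification
(31/31) demonstrates internal consistency of the pipeline under the model's
own assumptions at the published effect sizes — not performance on real
exposure data.  Note also that CPM is compositional: absolute log2 ratios
are recoverable from the count layer only when the perturbed panel is a
small fraction of library mass, which is why count-level tests include a
large unperturbed background gene set.

## Numerical notes

* Probabilities are computed with a log-sum-exp shift and sum to 1 within
  1e-12.
* Tabular writers emit floats at `%.17g`, and readers parse with
  round-trip precision, so write→read is the identity on doubles.
* Tie-breaks: equal-accuracy shrinkage candidates resolve toward more
  shrinkage; a tied clustering majority is unclassifiable rather than
  arbitrarily broken.
* Degenerate inputs fail loudly: classes with fewer than two members,
  all-zero pooled SDs, fully shrunken models at prediction time, zero-total
  count columns, unresolvable vehicle controls.

## Known limitations

* Binary classification only; the estimator generalizes to K > 2 but the
  strict probability rule is defined for the HDACi-vs-rest question.
* No between-batch harmonization (the workflow only reports between-batch
  correlations; it never corrects for them).
* The 81-gene parent panel is supported by the asset schema but not
  bundled; supply it as a JSON asset to use it.
* Gene identity is the case-sensitive symbol string; no alias resolution.
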