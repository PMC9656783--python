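# Methods

This note documents the models and procedures implemented in genesift,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect
results.

## Literature mining

Mining is dictionary-based named-entity matching, not statistical NER.
Text is split into alphanumeric tokens with intra-token hyphens retained
(so `HLA-DRB1` survives), stop phrases are removed case-insensitively,
and runs of consecutive duplicate tokens are collapsed
(case-insensitive comparison, original case kept). A token matches a
gene iff it equals a catalog symbol or alias **case-sensitively**;
aliases resolve to the canonical symbol. Case-sensitivity is deliberate:
gene symbols are case-significant, and a dictionary matcher has no
disambiguation model to justify case folding. The residual ambiguity —
symbols that are also English words (`SET`, `CAT`, `IMPACT`, …) — is
handled with a configurable blacklist; the shipped default is a small
conservative list, and real-corpus users should extend it.

The counting unit is the **article**: a gene mentioned five times in one
abstract counts once. The frequency filter is strict (`count >
min_articles`, default 50), so a gene in exactly 50 articles is
excluded. Frequency-table ties break lexicographically for reproducible
output.

## Expression meta-analysis

Each dataset contributes one effect size per gene: Hedges' g (case
minus control) with the small-sample correction
J = 1 − 3/(4(n₁+n₂−2)−1) and sampling variance
(n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). Genes measured on multiple markers are
collapsed per dataset to the maximum-variance marker (configurable:
mean); max-variance is a common convention when probe annotation quality
is unknown. Genes with zero pooled standard deviation in a dataset are
skipped for that dataset.

Effects are pooled with the DerSimonian–Laird moment estimator:
fixed-effect weights 1/v give Q and C = Σw − Σw²/Σw, then
τ² = max(0, (Q − df)/C), random-effects weights 1/(v+τ²), and a
two-sided normal z-test on the weighted mean. A fixed-effects mode
(τ² ≡ 0) is available; random effects is the default because
heterogeneity across expression platforms is the norm. Genes measured in
fewer than `min_datasets` datasets (default 2) are excluded — pooling a
single study is vacuous, though the minimum is configurable to 1.

Multiple testing uses Benjamini–Hochberg (via
`statsmodels.stats.multitest`), shared by the meta-analysis and
enrichment modules. DEG selection is **inclusive** at the threshold
(fdr ≤ α, default α = 0.001), ranked by FDR then |pooled effect|.

Input matrices are assumed log-scale; a `log_transform` flag applies
log2(x+1) for count-scale input.

## TMM normalization

Used only on the machine-learning feature path. The implementation
follows the published calcNormFactors recipe: the reference sample is
the one whose 75th percentile of count fractions is closest to the mean
across samples; for each sample, M = log2 ratio and A = mean log2
abundance of count fractions against the reference are computed over
markers nonzero in both; markers are doubly trimmed by rank (30% each
tail on M, 5% each tail on A); the factor is 2 to the precision-weighted
mean of the surviving M values (delta-method weights); factors are
rescaled to geometric mean 1. Two numerical details matter: A is
computed as (log2 p_obs + log2 p_ref)/2 — not 0.5·log2 of the product —
because the rank-based trim is sensitive to exact ties between markers
with identical count pairs; and a sample whose M values are all below
1e−6 in magnitude gets factor 1. The test suite checks the
implementation against an independent step-by-step oracle (1e−8) and,
when `Rscript` is present, against Bioconductor edgeR (1e−6).

A note on the uniform-scaling limit: if one sample is another scaled ×2
with no composition change, the *composition* factors of the pair
coincide (TMM divides by library size first); the quantity whose
closed-form limit is 2 is the effective scaling, library size × factor.
The acceptance script reports that effective-scale ratio.

Applying TMM to microarray-scale intensities rather than counts is
scientifically debatable; the package supports it on the ML path
(clipping negatives to zero before factor computation) and provides
`normalize=None` to skip it. The
count-scale generator mode exists to exercise TMM on its natural input.

## Co-expression network

Pearson r with the two-sided t-distribution p-value
(t = r√((n−2)/(1−r²)), df = n−2, via `scipy.stats.pearsonr` semantics).
An edge is kept iff |r| ≥ r_min (default 0.5) **and** p ≤ p_max (default
0.01); both boundaries are as stated (an |r| of 0.49 is discarded, a p
of 0.02 is discarded). The filter uses |r| because negative
correlations are biologically meaningful and are displayed in this kind
of analysis; a signed rule would silently remove them. Edge p-values are
not multiplicity-adjusted — the cutoff is a raw operating point, not an
error-rate guarantee. Zero-variance genes cannot carry edges and are
skipped with a log message while remaining in the node set. Samples are
pooled within a platform group before correlation (per-dataset
correlation with meta-combination would be an alternative; pooling is
the default because group members share a platform).

## Enrichment

Share and intersection ratios satisfy the exact identity
share·|L| = intersection·|T| = 100·|L∩T| at full precision; rounding to
two decimals happens only at serialization. Significance is the
one-sided hypergeometric upper tail P(X ≥ overlap) — equivalent to
one-sided Fisher — with BH adjustment across all size-eligible tested
terms; rows are emitted for terms with overlap ≥ 1 and sorted by
−log₁₀(adjusted p). The background is the supplied annotation
collection's universe restricted to the catalog; list genes outside the
background are dropped with a warning and the effective list size is
always reported. Adjusted p-values are floored at 1e−300 before the
log so the reported column stays finite.

## List comparison

Distance is start-to-start: the catalog carries a single coordinate per
gene, which makes any other inter-gene distance ill-defined. The
proximity boundary is strict (< 1 Mbp default). A gene present in both
lists yields a distance-0 pair; this is configurable because whether
"close to each other" includes identity is genuinely ambiguous — the
report therefore exposes both the pair count and the per-list counts of
distinct genes involved. A "locus" is a fixed-width bin
(floor(start/bin_size), default 1 Mbp) occupied by at least one gene
from each list; the bin width is a parameter since no finer definition
is available. Shared-term comparison requires both enrichments to agree
on every common term's category — disagreement indicates they were run
against different annotation collections and is refused.

## Biomarker ranking

Features are assembled per platform group: samples of member datasets
are concatenated and the marker set is the intersection across members
of markers mapping to a selected gene (markers missing from any member
are dropped and logged). The selected-gene input is the union of
literature-frequent genes and meta-analysis DEGs.

The 70/30 split is stratified: the train budget is ⌈0.7n⌉, allocated
across classes by largest remainder so each class's train count is
within one sample of 0.7 × its size, with at least one test sample per
class; the per-class shuffle is seeded.

Three algorithms run per group: a CART decision tree, a random forest,
and an extra-trees **regressor** fitted to a 0/1 label encoding with
predictions thresholded at 0.5 — a regressor applied to a classification
task is unusual, but it is supported deliberately and its
impurity-based importances feed the same ranking machinery. Forest size
defaults to 500 trees (the pipeline demo uses fewer for speed).
Accuracy is reported with a 95% Wilson score interval — a method had to
be fixed and Wilson behaves well at the small test sizes this design
produces (bounds are clamped to contain the point estimate, which
matters at accuracy 0 or 1 where the Wilson bound can land one ulp
inside). Importances are rescaled to sum to 100 per model — raw
impurity importances are on arbitrary, algorithm-dependent scales, so a
common reporting scale is adopted and the raw values are also kept.

Recurrence tallies count marker appearances in each report's top-k;
gene tallies aggregate marker-level appearances (a gene represented by
two top-k markers in one report counts twice), so a gene's tally is
always ≥ its best marker's tally.

Local explanations are the standard local-surrogate recipe: Gaussian
perturbations around the instance scaled by background per-feature SDs,
model predictions queried on the perturbations, and a ridge fit on
standardized coordinates weighted by exp(−d²/κ²) with κ = 0.75·√d by
default (the conventional kernel width). Zero-variance background
features are excluded and logged. Because perturbation and
standardization are relative to the instance and the SDs, explanations
are invariant to location shifts of the background — a property the
tests check.

## Synthetic data: what it does and does not emulate

The generator produces every input the pipeline consumes, with truth
recorded: a catalog (symbols, aliases, chromosomes, positions, with a
guaranteed sub-1-Mbp pair and a distant pair so proximity logic always
has both instance types); a corpus (bag of decoy sentences from a fixed
common-English vocabulary with gene symbols inserted as standalone
tokens, exact planted article counts per gene, and optional
decoys that collide with catalog names, recorded separately for
blacklist testing); expression datasets (Gaussian log2-like values
around per-gene baselines shared across datasets, planted DEGs with
identical signed shifts of `effect_size` in every dataset, correlation
blocks driven by one latent factor per block with loading √r so the
expected pairwise correlation is r, and an optional negative-binomial
count mode with dispersion 0.1); and annotation sets of bounded sizes
with an optionally planted enriched term.

Default study conditions: three datasets on two platform groups
totalling 44 cases and 57 controls, effect size
2.5, unit noise, 5% DEGs, a >50-article mining cutoff, and the
thresholds listed in the README. Where no value was available the
defaults are ordinary for the field (300-gene demo catalog, 400-article
demo corpus, per-gene baselines N(8, 1) on the log2 scale) and are
fixed once in `RunConfig`.

What passing tests show is therefore internal validity: the pipeline
recovers exactly what was planted, at the stated thresholds, under
token-level text and Gaussian/NB expression models. They do not show
robustness to what real data adds: morphological variants and
punctuation-glued gene names in prose, probe-level artifacts, batch and
platform effects, correlated noise beyond single-factor blocks, or
annotation collections with hierarchical (GO-graph) structure. The
mining match rate on real abstracts in particular depends on the
blacklist and alias list supplied.

## Pipeline and reproducibility

A single `RunConfig` holds every threshold and generator setting; its
SHA-256 hash is written into each stage's provenance record. Reruns with
the same configuration reuse cached stage outputs; outputs from a
different configuration in the same directory are refused rather than
mixed. All randomness flows from the configured seed through
`numpy.random.default_rng`, and all writers are deterministic (sorted
orders, fixed float formats), so two runs of one configuration are
byte-identical. Stage problem sizes in the demo configuration (300
genes, 400 articles, 200 trees) are chosen to keep a full run in the
seconds-to-minutes range while leaving every recovery property
measurable.

## Known limitations

- Dictionary mining cannot resolve genuinely ambiguous symbols; the
  blacklist trades recall for precision and is not corpus-adaptive.
- DerSimonian–Laird underestimates τ² with very few studies (here
  k = 3); the z-test does not propagate τ² estimation error
  (a Hartung–Knapp adjustment is not implemented).
- TMM on microarray-scale intensities is supported because this style
  of workflow applies between-sample normalization before ML; it is not
  a recommendation (`normalize=None` skips it).
- The locus definition (fixed bins) makes shared-locus counts depend on
  bin phase; a pair spanning a bin boundary is not a shared locus even
  if closer than the bin width (the proximity-pair section catches
  those).
- Tree-ensemble importances are impurity-based and biased toward
  high-cardinality features; with standardized synthetic markers this
  is immaterial, but permutation importance would be preferable on real
  data.
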