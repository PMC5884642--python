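# Methods

## Data model and normalization

The unit of data is a kinase-by-sample table of label-free MS intensities
from multiplexed-inhibitor-bead capture, with per-entry unique-peptide
counts. Missingness is explicit (NaN), never conflated with zero: a kinase
absent from a run may be unexpressed, inactive, or simply below detection,
and downstream consumers decide how to treat that. An optional ingest flag
(`zeros_as_missing`) reinterprets explicit zeros as missing for tables that
encode non-detection that way.

Two identification filters precede quantitative work:

- **Peptide rule** — a kinase is kept if its *maximum* unique-peptide count
  over samples reaches 3 (inclusive). The rule is per dataset, not per
  sample: identification is a property of the experiment.
- **Presence rule** — a kinase must be observed in at least
  `ceil(0.30 × n_samples)` samples (inclusive ceiling; "at least 30%" is a
  lower bound, so the conservative literal reading applies: 30% of 32
  samples means 10).

Surviving intensities are log2-transformed and autoscaled **per sample**
over observed entries only (mean 0, SD 1 with the n−1 denominator; the
denominator is a config switch). Missing entries stay masked. Samples with
fewer than two observed values or zero variance are rejected by name rather
than silently propagated. Replicates are collapsed to cell-line profiles by
the observed-value mean; an averaged entry is missing only when every
replicate is missing.

## Distinguishing-kinase selection

Two complementary routes feed the composed feature list:

- **Pan-subtype (PCA)** — the column-centred sample×kinase matrix is
  decomposed by SVD; per component, kinases whose |loading| ranks in the
  top `ceil(0.10 K)` are taken from PC1, then PC2, then PC3, each block
  ordered by descending |loading|, duplicates kept at first occurrence.
  Absolute loadings are used because PCA sign is arbitrary. PCA requires a
  complete matrix, so missing entries are mean-imputed per kinase
  (PCA only; ranking operations always use observed values).
- **Subtype-specific (Bhattacharyya)** — per subtype, each kinase is scored
  by the closed-form Gaussian Bhattacharyya distance between its
  one-vs-rest group distributions (group means and n−1 variances over
  observed values). "Pairwise classification between subtypes" is realized
  as one-vs-rest. Kinases with fewer than two observed values or zero
  variance in either group are scored missing and ranked last. Ties break
  lexicographically by kinase id for reproducibility.

The closed form assumes per-group Gaussians with unpooled variances — the
documented behavior of the standard feature-ranking implementations this
criterion comes from; a histogram-based estimator is out of scope. The
tests verify the closed form against −ln ∫√(pq) by numerical integration.

**Composition** — the top `ceil(0.05 K)` of each subtype ranking (fixed
subtype order: basal-like, claudin-low, HER2-enriched, luminal),
deduplicated keeping first occurrence, then pan-subtype kinases in PC order
until the 50-kinase cap. If the subtype-specific entries alone exceed the
cap, they are truncated by round-robin interleaving over subtypes by rank so
every subtype keeps its best features. Provenance
(`subtype-specific:<name>` / `pan-subtype:PC<i>`) travels with each entry.

Two-group volcano statistics use Welch's t-test per kinase on observed
values, raw p-values by default (p < 0.05 is the headline readout) with a
Benjamini–Hochberg switch.

## Subtype classification

A linear soft-margin SVM (C = 1, config-exposed) is trained on
feature-restricted, training-mean-imputed profiles. The default task is the
two clinical groups — TNBC (basal-like + claudin-low) vs HER2+/Luminal
(HER2-enriched + luminal); a four-class one-vs-rest mode sits behind a flag.
The kernel is linear because nothing in the problem demands more and 50
features on ~32 samples punish anything more flexible.

Query (tumor) profiles are autoscaled on their own observed values, then
missing features are filled with training per-feature means; predictions
record how many features were imputed and warn above 60%. A profile whose
best decision value falls below the threshold τ (default 0 on the signed
margin) is labelled "other" — a calibrated-margin rule rather than
probability calibration, since "other" has no operational definition beyond
low confidence. With τ = −∞ every query receives a group call (the setting
used for leave-one-out evaluation).

## MIB ↔ RNA concordance

Per kinase, Pearson *r* across cell lines between the cell-line-averaged
MIB profile and log2(count + 1) RNA abundance; the +1 handles genuine zeros
below detection, and the log is the scale on which RSEM-style counts are
approximately Gaussian. Kinases with fewer than 3 shared observed lines or
a constant vector in either modality are flagged (r undefined), not
dropped; the summary reports the mean over defined r values together with
how many kinases that covers, since the alternative denominators differ.
RNA detection is called at ≥ 50 counts (inclusive). The joint MIB+RNA
matrix autoscales RNA columns per sample onto the shared Z-score scale so
both data types can be clustered together with a data-type tag per column.

## Kinome networks

- **Union network** — interaction sources are merged on unordered pairs
  restricted to the profiled kinase universe; self-loops are dropped,
  source tags unioned, and universe nodes without edges reported (the
  typical few-of-254 stragglers) and excluded from partitioning.
- **Spectral partition** — symmetric-normalized-Laplacian embedding into
  the k smallest eigenvectors, row-normalized, then k-means with a fixed
  seed (n_init = 10). Disconnected components are handled first: each
  receives a share of k proportional to its size (min 1, max its node
  count, largest-remainder rounding) and is clustered independently,
  because Laplacian eigenvectors are degenerate across components. k = 16
  is a fixed input, matching the subnetwork count this analysis targets;
  an eigengap diagnostic is attached but never auto-applied.
- **Lasso linkages** — each kinase's profile in turn is the response,
  all others the (standardized) predictors; the penalty is chosen by
  10-fold cross-validation minimizing MSE with a fixed fold seed, and
  predictors with nonzero coefficients at the optimum are the linkages.
  CV-minimum (not one-SE) is the documented default of the fitting stack
  this mirrors. No coefficient-magnitude cutoff beyond nonzero is applied.
- **Ego subnetworks** — around an understudied center: regression edges to
  the predictors it selected and to every kinase that selected it; known
  interactions incident to the center or any regression partner layered on
  top; members are the endpoints.
- **Enrichment** — upper-tail hypergeometric p per annotation term against
  the kinase universe, BH-adjusted across terms. This is a local
  replacement for web enrichment services: reproducible, offline, and
  pinned to a user-supplied annotation table rather than a drifting
  database.

## Perturbation response

Fold change is computed on raw replicate-averaged intensities —
autoscaling would destroy ratio semantics — as FC = log2(treated/untreated)
per kinase per cell line, defined only where both conditions observed the
kinase (never ±∞; appearance/disappearance belongs to detection logic, not
imputation). Replicate-averaged-first is the implemented default.
Subnetwork summaries report per-kinase mean and SD (n−1) across cell lines
grouped by community (SD = 0 and flagged at n = 1), "top" subnetworks
ranked by member count, and per-line distributions as median and IQR.

## Synthetic cohorts

The generator emulates the statistical shape the analysis assumes, in the
space the analysis works in: intensities are Gaussian in log2 and
exponentiated, so planted effects are exact on the analysis scale.

Defaults (the study conditions of every test and of the acceptance script):

| parameter | default | meaning |
|---|---|---|
| n_kinases | 254 | post-filter kinase universe scale |
| subtypes | 4 × 4 lines × 2 reps | 32 samples over 16 cell lines |
| n_pan_kinases | 10 | kinases with inflated cross-subtype variance |
| n_specific_per_subtype | 5 | kinases with a one-vs-rest mean shift |
| effect_size | 3.0 | planted shift in within-group SD units |
| baseline_log2_mean / kinase_spread_sd | 20 / 2 | log2 intensity scale of label-free MS |
| line_sd / noise_sd | 0.5 / 0.3 | biological and replicate variation (log2) |
| dropout_rate | 0.10 | missing-at-detection rate (MCAR default) |
| frac_low_peptides | 0.05 | kinases held under the 3-peptide rule |
| rna_coupling | (0.2, 0.15) | per-kinase target MIB↔RNA Pearson r |
| network_k, p_within, p_between | 16, 0.5, 0.02 | planted-partition graph |
| fc_communities, fc_magnitude | 2, 1.0 | planted drug-response shift (log2) |

Within-group SD is √(line_sd² + noise_sd²) ≈ 0.58 log2 units; the planted
one-vs-rest shift is `effect_size ×` that, with random sign. Pan-subtype
kinases draw independent per-subtype shifts of the same scale. Kinase
baselines are a property of the kinase and are shared by the tumor-query
generator — tumors differ by fresh line effects and noise, not by a new
abundance landscape. Dropout is missing-completely-at-random by default; an
intensity-dependent mode (logistic in log2 intensity, rescaled to the
requested overall rate) models preferential loss of low-abundance kinases.
Unique-peptide counts are 3 + Poisson(4), with a controlled fraction of
kinases capped below 3 to exercise the identification filter. RNA counts
are real-valued (RSEM-style), built as 2^(9 + 1.5·y) − 1 where y mixes the
standardized cell-line-averaged MIB profile with noise at the target
correlation — exact on the log2(count+1) scale the concordance module uses.
Replicate-level variance magnitudes are not calibrated against any real
cohort; they are tunable orders of magnitude chosen to look like label-free
MS data.

What passing tests do **not** show about real data: real MIB dropout is
neither MCAR nor purely intensity-logistic; real subtype effects are
correlated across kinases (pathways), not independent shifts; real
interaction networks are scale-free-ish, not planted partitions; and real
tumor heterogeneity is not captured by fresh Gaussian line effects. The
synthetic recovery rates certify the machinery, not field performance.

## Numerical choices and degenerate inputs

- SDs use n−1 throughout (config switch at autoscaling).
- Ceilings make every "at least X%" threshold inclusive.
- Ranking ties break lexicographically by kinase id; unscorable kinases
  rank last rather than being dropped.
- PCA completeness is the caller's job (`impute_kinase_mean`); passing a
  matrix with NaN raises.
- Constant columns, undersized groups and constant Lasso responses raise
  named errors instead of producing NaN downstream.
- KMeans and CV folds take explicit seeds; every generator draws from
  `default_rng([seed, stream])` so stages are independent but jointly
  reproducible.

## Problem sizes

Tests and the acceptance script run at the default cohort scale (254
kinases × 32 samples), 10 cohort replicates for stochastic recovery rates,
5 replicates for network/perturbation summaries, 240-node graphs for
partition recovery, and 30-sample/50-predictor designs for Lasso checks —
sizes at which every planted signal is comfortably identifiable and the
whole suite stays interactive.

## Known limitations

- The exact identity of a real 50-kinase panel depends on the full
  experimental tables and unstated tie handling; this package reproduces
  the *procedure* and its recovery behavior, not a specific published list.
- Live interaction databases and web enrichment services are deliberately
  out of scope; users supply edge lists and annotation tables.
- The "other" threshold τ is a free calibration with no principled default
  beyond 0; users classifying real biopsies should calibrate it on held-out
  profiles.
- Four-class classification is supported but under-determined at 32
  training samples; the binary clinical task is the default for a reason.
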