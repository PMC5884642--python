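# kinotax

Functional kinome taxonomy from multiplexed-inhibitor-bead mass-spectrometry
(MIB/MS) profiles of breast cancer cells.

Genomic taxonomies classify breast tumors into subtypes (basal-like,
claudin-low, HER2-enriched, luminal), but mRNA says little about which
kinases are actually active: MIB affinity capture quantifies *functional*
kinase binding, and its per-kinase agreement with transcript abundance is
weak. `kinotax` implements the analysis chain that turns kinase-by-sample
MIB/MS quantification tables into:

- a **distinguishing kinase set** (≤ 50 features): subtype-specific kinases
  ranked per subtype by the Gaussian Bhattacharyya distance between
  one-vs-rest group distributions,
  `D_B = ¼ ln(¼(σ₁²/σ₂² + σ₂²/σ₁² + 2)) + ¼ (μ₁−μ₂)²/(σ₁²+σ₂²)`,
  composed (top 5% per subtype) with pan-subtype kinases taken from the top
  10% of absolute PCA loadings on PC1–PC3;
- an **SVM subtype classifier** (linear, soft margin) that calls unseen
  tumor profiles TNBC, HER2+/Luminal or "other", tolerating the 15–27 of 50
  feature kinases that typically go unmeasured in needle biopsies;
- **MIB↔RNA concordance**: per-kinase Pearson *r* across cell lines between
  cell-line-averaged MIB log2 profiles and log2(RSEM + 1) transcript
  abundance, with detection-overlap sets at the 50-count RNA threshold;
- **kinome subnetworks**: the union of curated kinase–kinase interaction
  sources partitioned by normalized-Laplacian spectral clustering (k = 16),
  plus Lasso regression of each kinase's MIB profile on all others to build
  ego "functional subnetworks" around understudied kinases, scored for
  annotation-term enrichment with a hypergeometric test (BH-adjusted);
- **drug-response summaries**: per-kinase log2 fold change of treated over
  untreated intensities, aggregated per subnetwork (mean, SD across cell
  lines) and per line (median, IQR).

A first-class synthetic-cohort generator (`kinotax.synthetic_cohort`)
produces MIB-like log-normal cohorts with planted subtype effects, tunable
MIB↔RNA coupling, planted-partition interaction networks and planted
fold-change shifts, with the ground truth returned for recovery testing.

## Worked example

```python
from kinotax import io_filter, taxonomy, subtype_classifier as sc
from kinotax.synthetic_cohort import CohortSpec, generate_mib_cohort

spec = CohortSpec(seed=1)                     # 254 kinases, 4x4x2 = 32 samples
quant, meta, truth = generate_mib_cohort(spec)

q = io_filter.filter_by_peptides(quant)       # >= 3 unique peptides
q = io_filter.filter_by_presence(q)           # observed in >= 30% of samples
norm = io_filter.log2_autoscale(q)            # per-sample Z-scores

pca = taxonomy.run_pca(taxonomy.impute_kinase_mean(norm))
pan = taxonomy.pan_subtype_features(pca)      # top 10% |loading|, PC1-PC3
rankings = {s: taxonomy.rank_subtype_features(norm, meta, s)
            for s in sorted(meta["subtype"].unique())}
dset = taxonomy.compose_distinguishing_set(rankings, pan)   # <= 50 kinases

conf = sc.loo_evaluate(norm, meta, dset)
print(f"LOO accuracy: {100 * sc.loo_accuracy(conf):.1f}%")
```

Output:

```
254 kinases quantified; 241 pass the 3-peptide rule
241 observed in >=30% of 32 samples
PC1/PC2 explain 15.5% / 11.8% of variance
distinguishing set: 50 kinases (38 subtype-specific)
leave-one-out accuracy (TNBC vs HER2+/Luminal): 100.0%
```

The 3-peptide rule removes the generator's planted low-evidence kinases; the
distinguishing set mixes one-vs-rest Bhattacharyya winners (provenance
`subtype-specific:<name>`, e.g. `KIN0083` at D_B ≈ 3.15) with high-variance
PCA features (`pan-subtype:PC1..PC3`); and the leave-one-out confusion table
shows the two clinical groups separate cleanly at the default planted effect
size of 3 within-group SDs.

The same stages are scriptable from a shell:

```sh
kinotax simulate --out cohort --seed 1
kinotax normalize --quant cohort/quant.tsv --meta cohort/meta.tsv --out norm
kinotax select --norm norm/normalized.tsv --meta cohort/meta.tsv
kinotax run --out full_run --seed 1        # every stage + manifest.json
```

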