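# nitromics

Multi-omic integration pipeline for nitric-oxide-dependent remodeling in
macrophages.

Classically activated (LPS/IFNγ-stimulated) macrophages produce large
amounts of nitric oxide through inducible NO synthase (iNOS), and NO in
turn reshapes both the proteome and the transcriptome — suppressing
electron-transport-chain complexes, inducing antioxidant programs. The
standard experimental design for dissecting this crosses genotype
(WT vs `iNOS_KO`), stimulation (`unstim` vs `stim`) and an exogenous
NO-donor rescue arm (DETA-NONOate), and measures label-free or
isobaric-label proteomes alongside RNA-seq. `nitromics` implements the
analysis chain for such designs as a tested, reusable library with a CLI:

- **preprocessing** — per-channel normalization to 100% total signal
  (isobaric path), valid-value filtering (default: ≥16 of 32 samples),
  log₂ transform, down-shifted normal imputation
  (𝒩(μ−1.8σ, (0.3σ)²), per column), row z-scoring;
- **differential statistics** — two-tailed Welch *t*-tests on linear
  intensities with log₂FC = log₂(mean KO-stim / mean WT-stim); a
  simplified negative-binomial Wald test for counts (median-of-ratios
  size factors, moment dispersions shrunk to a trend, normal-reference
  Wald *p*); Benjamini–Hochberg FDR everywhere;
- **structure** — PCA over samples with variance explained
  (σᵢ²/Σσ²·100%), principal-component contributor selection at
  mean ± 2 SD of the loadings, Ward.D2 clustering on 1−Pearson-*r*
  distance, and a four-way NO-dependence classifier on condition-mean
  z-scores (`WT_stim_effect`, `iNOS_stim_effect`,
  `NO_effect = WT_stim_effect − iNOS_stim_effect`, thresholds 0.4/0.5);
- **concordance** — cross-model and cross-omic agreement in five
  categories, Pearson *r* with *t*-test, strong-responder quadrants
  (|log₂FC| > 0.5 and padj < 0.05 in both datasets), and
  triple-concordance ranking of genes significantly down in two
  proteomes and one transcriptome;
- **enrichment** — local hypergeometric over-representation over GMT
  libraries with an explicit universe (curated mouse ETC/denitrosylase
  sets ship with the package);
- **synthetic data** — a first-class generator of coupled
  proteome/transcriptome factorial datasets with planted
  NO-dependent-up/down, NO-independent and null feature classes,
  left-censored missingness and NB counts, so the whole chain is
  testable against known ground truth.

## Worked example

Run the full pipeline on an 800-feature synthetic dataset (32-sample
proteome with donor arm, 16-sample complete-matrix proteome, 12-sample
RNA-seq, one shared planted truth):

```python
from nitromics.pipeline import RunConfig, run, report

results = run(RunConfig(n_features=800, seed=7), "demo_run")
print(results["pc1_stim_silhouette"])   # 0.742
print(results["cross_model_r"])         # 0.880
print(results["cross_omic_r"])          # 0.394
print(results["recovery"]["precision_NO_dep_up"],
      results["recovery"]["recall_NO_dep_up"])   # 1.0 0.897
report("demo_run")                      # demo_run/report.md + plots
```

What these numbers mean: stimulated and unstimulated samples separate
cleanly on PC1 (silhouette 0.742 > 0.5), reproducing the expected
decomposition in which stimulation dominates the first component and the
NO-dependent shift the second (here PC1 22.8%, PC2 13.6% of variance).
The two proteomes, which measure the same planted truth with independent
noise, agree at *r* = 0.880 on the genotype-contrast fold changes; the
protein–RNA agreement is *r* = 0.394, attenuated from the generator's
true-effect coupling (0.568) by measurement noise on both axes. The
pipeline's recovered NO-dependent-up gene set (z-score classifier
category intersected with robust-responder evidence, padj < 0.05 and
|log₂FC| > 0.5 in at least one proteome) has precision 1.0 and recall
0.897 against the planted truth, and the planted marker gene set ranks
first in the enrichment stage.

The same run is available from the shell:

```sh
nitromics run --seed 7 --n-features 800 --out demo_run
nitromics report demo_run
```

Each stage is also independently invokable on intermediate TSVs
(`nitromics simulate|preprocess|diff|classify|concord|enrich`); see
`nitromics --help`.

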