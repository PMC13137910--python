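# Methods

This note documents the models, defaults, and numerical choices behind
`nitromics`, and what the synthetic-data validation does and does not
establish about behavior on real data.

## The factorial design

All operations assume samples annotated by genotype (`WT`, `iNOS_KO`),
stimulation (`unstim`, `stim`) and NO-donor treatment (`none`, `DETA`).
"NO present" means endogenous production (WT and stimulated) or exogenous
donor (DETA in any cell): the donor arm exists precisely so that
NO-dependent effects can be rescued in the knockout. Two reference
layouts are built in: a 32-sample full factorial
(2 genotypes × 2 stimulation × 2 donor × 4 replicates), emulating a
primary-macrophage label-free proteome, and a 16-sample donor-free
factorial (2 × 2 × 4), emulating a complete-matrix cell-line proteome;
RNA-seq uses the donor-free layout with 3 replicates per cell.

## Synthetic data generator

Per feature *f* and sample *j*, the latent log₂ abundance is

    x_fj = b_f + δ_f · a(f, j) + ε_fj

with baseline b_f ~ 𝒩(20, 2²) (typical label-free log₂ intensities),
measurement noise ε ~ 𝒩(0, σ_m²), σ_m = 0.25 by default, and a planted
effect δ_f whose magnitude is |𝒩(effect_size_mean, effect_size_sd²)|
(defaults 1.5 and 0.3 log₂ units — strong but realistic regulation).
The activation indicator a(f, j) encodes the feature's class:
NO-dependent features (up or down) respond wherever NO is present;
NO-independent features respond to stimulation in both genotypes; null
features never respond. Reported intensities are 2^x.

**Class proportions.** The default is (0.10, 0.10, 0.25, 0.55) for
(NO-dep-up, NO-dep-down, NO-independent, null). The NO-independent
stimulation program is deliberately the largest regulated class: with
that mix the sample-space structure reproduces the canonical
decomposition of activated-macrophage proteomes — stimulated vs
unstimulated samples separate on PC1 and the NO axis appears on PC2
(PC1-stim silhouette ≈ 0.72, PC2-NO ≈ 0.53 across seeds). With equal
10% classes the first component becomes a stim/NO mixture, which does
not resemble the real systems this generator emulates.

**Missingness** is left-censoring-like: a cell goes missing with
probability proportional to Φ(censor_strength · (μ_low − x)), where
μ_low is the 20th percentile of latent values, rescaled so the average
rate equals `missing_rate` (default 0.10). This produces the
abundance-dependent missingness that motivates down-shifted imputation.
The complete-matrix (isobaric-label-like) arm is generated with
`missing_rate = 0`.

**RNA coupling.** True RNA effects are
`rna = ρ·prot + sqrt(1−ρ²)·sd(prot)·ε` among non-null features, so the
population correlation of true effects equals ρ exactly; null features
are exactly 0 in both. The default ρ = 0.568 matches the protein–RNA
fold-change correlation reported for this biology; measured-lfc
correlations are attenuated below ρ by noise on both axes. Counts are
negative binomial with gene base means log-normal(log 100, 1.2²),
per-sample library factors uniform on [0.7, 1.4], and dispersion 0.05
(Poisson in the dispersion → 0 limit).

**Determinism.** One RNG stream per matrix, derived from the single
seed via fixed offsets, so the proteome, the transcriptome and the
synthetic gene-set library are each independently reproducible.

What the generator does **not** emulate: peptide-level quantification,
batch/run effects, isobaric reporter interference, mean–variance trends
in intensity noise, count outliers. Passing tests establish correctness
of the statistical machinery under the stated model, not robustness to
those artifacts.

## Preprocessing

Two paths mirror the two acquisition styles. The complete-matrix path:
per-channel normalization so each sample column totals 100 (proportions
preserved; idempotent and scale-invariant), then an all-valid filter.
The label-free path: minimum-valid filter (default ≥16 observed of 32),
log₂ transform, then imputation of each missing cell in column *j* from
𝒩(μ_j − 1.8σ_j, (0.3σ_j)²) using the column's observed mean and sample
SD — the down-shifted-normal convention for left-censored proteomics
data. Columns need ≥3 observed values for a stable σ. Statistical
testing happens on the linear scale, so the matrix is back-transformed
(2^x) after imputation. Row z-scoring (mean 0, SD 1, sample SD
throughout) feeds classification and heat-map rendering; z-capping at
±2 is applied only at display time, never to analyzed values.

One caveat measured during development: total-signal normalization is
compositional — when regulation is directionally unbalanced it imprints
a small opposite-sign fold-change shift (~0.16 log₂ units at default
conditions) on unregulated features. This is a property of the
normalization itself and is one reason the pipeline's high-confidence
calls require a fold-change magnitude cutoff (below).

## Differential statistics

**Intensities.** Per feature, a two-tailed Welch *t*-test on linear
intensities with Welch–Satterthwaite degrees of freedom;
log₂FC = log₂(mean_contrast / mean_ref); BH adjustment across all
tested features. Testing linear-scale values follows the convention of
the workflows this pipeline mirrors; because linear intensities are
heavy-tailed, the effective df at n = 4 per group is small and marginal
true effects can miss the FDR threshold — a config option (non-default)
allows log-scale testing. Degenerate rows (zero variance in both
groups, equal means) return p = 1 by convention; zero pooled SE with
unequal means is an error.

**Counts.** A deliberately simple NB Wald engine, validated by
parameter recovery and calibration rather than by replicating any
specific published tool: (1) median-of-ratios size factors (per-gene
geometric-mean reference over all-zero-free genes; each sample's factor
is the median of count/reference — the median of the ratios, not the
exponentiated median of log-ratios, which differs when the median
interpolates); (2) per-gene moment dispersions
α̂ = max((v − μ·E[1/s])/μ², 0) from pooled within-group variances of
normalized counts, averaged 50/50 with an a₀ + a₁/μ trend fitted across
genes and floored at 1e-8; (3) two-group log-link means = group means
of normalized counts; (4) Wald statistic lfc/SE with SE from the NB
Fisher information (group means floored at 0.5 inside the SE only —
never in the reported lfc), two-sided normal *p*, BH across genes.
Genes with one zero group mean report a sign-correct lfc capped at ±10
with a flag; all-zero genes are excluded. Omitted relative to
full-featured NB frameworks: profile-likelihood dispersions, lfc
shrinkage, outlier refitting, multi-factor designs. Measured behavior:
null rejection at the 5% level within [0.03, 0.08] for 3, 4 and 8
replicates per group; planted lfc = 1 recovered with ≈0.01 mean bias at
n = 8/group. Note that median-of-ratios normalization absorbs
directionally unbalanced regulation (an all-up transcriptome would
estimate lfc ≈ 0 by construction); recovery simulations therefore use a
directionally balanced regulated background.

## Structure: PCA, contributors, clustering, classification

PCA treats samples as observations; features are centered and scaled to
unit sample variance, zero-variance features dropped first. Variance
explained is σᵢ²/Σσ² · 100. Components are oriented so the feature with
the largest |loading| is positive — the orientation is otherwise
arbitrary, and a fixed convention makes "positive/negative contributor"
labels reproducible. Contributors on a component are features beyond
mean ± k·SD of that component's loadings (k = 2 default). This rule is
intentionally liberal: it admits ~2% of features under pure noise at
any scale (the rule is scale-free), so contributor sets should be read
as enriched-for-signal, not pure.

Row clustering uses 1 − Pearson *r* distance with the Ward.D2 update
(the convention of the clustering software this mirrors; Ward linkage
on a non-Euclidean dissimilarity is a heuristic). The implementation is
the nearest-neighbor-chain algorithm; merge order for exactly tied
distances is implementation-defined, which is immaterial for
continuous-valued data. Dendrograms export as Newick.

The NO-dependence classifier computes, per feature, condition means of
row z-scores over the four donor-free cells and the three effects
`WT_stim_effect`, `iNOS_stim_effect`, and their difference `NO_effect`,
then labels: NO-dep-up (WT effect > 0.4 and NO effect > 0.5),
NO-dep-down (both negated thresholds), NO-independent (both |stim
effects| > 0.4, |NO effect| < 0.5), else under-threshold. The four
rules partition effect space (fuzz-tested). Whether condition means are
taken over replicate z-scores (default) or re-standardized after
averaging is exposed as a flag, as the two readings are not
distinguishable from the source convention.

**Why classification alone is not a detector.** Row z-scoring
normalizes variance away, so for a flat feature the condition means are
noise with SD ≈ 1/√n_rep regardless of how small the raw noise is; at
4 replicates/cell roughly 20% of null features cross the 0.4/0.5
thresholds in each direction. The thresholds describe *pattern shape*,
not statistical significance. The pipeline's recovered NO-dependent
sets therefore intersect the classifier category with robust-responder
evidence: padj < α with a sign-consistent |log₂FC| > 0.5 in at least
one of the two proteome genotype contrasts. The magnitude cutoff also
suppresses the compositional normalization shift noted above. At the
reference recovery conditions (2,000 features, 10%/10%/10%/70% classes,
effect 1.5, 4 replicates/cell, 5 seeds) this yields precision 0.91–1.0
and recall 0.90–0.95 per direction; classifier-only precision is ~0.25
under those conditions and is reported alongside as a diagnostic.

## Concordance

Gene matching is a case-insensitive inner join on symbols (tables must
be gene-collapsed first; isoform collapse averages linear intensities
over observed isoform values, a cell staying missing only if all
contributors are missing). Five agreement categories partition matched
pairs by (significance in each dataset, fold-change sign agreement); a
fold change of exactly 0 in a significant pair — possible only through
capping conventions — counts as agreeing with the other dataset's sign.
Pearson *r* on paired fold changes carries a two-sided *t*-test
(t = r√(n−2)/√(1−r²)). Strong-responder quadrants require |lfc| > 0.5
and padj < 0.05 in both datasets, ranked by |lfc_a| + |lfc_b| with the
top 20 flagged. Triple concordance keeps genes with padj < α and
lfc < 0 in two proteomes and the transcriptome (the high-confidence
NO-induced targets: loss of iNOS lowers them everywhere), ranked most-
to-least downregulated by a configurable dataset (ties broken by
symbol), and flags genes also significantly induced by stimulation in
WT. Dataset roles are configuration, not hard-coded model names.

## Enrichment

Over-representation is the exact hypergeometric upper tail
P(X ≥ k) for overlap k between a query of size n and a set of size K in
a universe of size N, BH-adjusted across the sets of one library,
filtered at padj < 0.05 and truncated to the top 15. The universe is
always explicit — by default the genes quantified in the analyzed
dataset — and sets are trimmed to the universe before testing
(conditional-on-measured convention). This is the main place local
results will diverge numerically from web-service enrichment, whose
per-library backgrounds are not reproducible; the choice is logged with
every run. Curated mouse sets ship in
`nitromics/datasets/macrophage_no_response.gmt`: ETC complexes I–V
(structural subunits), COX assembly chaperones as a separate set, the
13 mtDNA-encoded subunits, V-ATPase subunits, and denitrosylase
enzymes. Discrete hypergeometric *p*-values make the BH filter
conservative for small sets: under 100 null queries against a 20-set
library, ≤ ~4% of queries produce any discovery.

## Numerical conventions

Sample (n−1) standard deviations everywhere. BH is the monotone-capped
step-up form (q ≥ p pointwise). Dispersion floor 1e-8; lfc cap ±10 with
flag; SE pseudo-level 0.5 on normalized counts. PCA via full SVD.
Correlation-distance matrices are clipped at 0 before condensing to
absorb rounding noise. All stochastic operations take explicit seeds;
pipeline runs are bit-reproducible from their config, and every output
table carries the config hash in a provenance header.

## Validation problem sizes

The test suite and `scripts/acceptance.py` exercise: oracle equivalence
of BH / hypergeometric tail / Pearson / Welch / size factors / Ward.D2
on ≥1000 random instances each (hypergeometric exhaustively for
universes up to 60); classification partition over 10⁵ fuzzed triples;
planted-class recovery on 2,000-feature runs across 5 seeds; NB
recovery on 500 scored genes over a 3,000-gene balanced background at
8 per group; null calibration at 2,000 features; enrichment FDR over
100 null queries; and PCA/contributor recovery at the 4,000-feature
default conditions. These sizes keep the full suite under a minute of
compute while leaving Monte-Carlo error well inside the asserted
margins.

## Known limitations

- The Welch test on linear intensities is faithful to the stated
  convention but inefficient at n = 4; expect reduced power for
  moderate effects rather than inflated error.
- The NB engine's normal-reference Wald *p* is a large-sample
  approximation; at 2–3 replicates per group it runs mildly liberal
  (within the measured [0.03, 0.08] band but above 0.05).
- Ward.D2 on correlation distance has no variance-decomposition
  interpretation; cluster heights are comparative only.
- The classifier thresholds (0.4/0.5 z-units) are conventions inherited
  from the analyses this package mirrors; they are exposed as
  configuration and their error behavior is documented above rather
  than optimized.
- Imputation adds irreducible noise to downstream tests on the
  label-free path; the null-calibration guarantees are stated for
  complete data, and the imputed path is mildly conservative.
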