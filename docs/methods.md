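# Methods

## The sigmoid transition model

Per-gene log2 expression over developmental time *t* (days post
conception) is modelled as

X(t) = B + A / (1 + e^{f(T)·(L−t)}),  f(T) = 2·ln 9 / T.

The model assumes a single monotone transition between two plateaus with
i.i.d. Gaussian noise on the log2 scale. The rate sub-function f is an
open design choice: any positive calibration leaves the curve shape
unchanged while rescaling T. We fix f(T) = 2·ln 9/T so that T is exactly
the 10%→90% rise (or fall) time in days — the most directly interpretable
calibration in which T "can be expressed in days". Alternative
calibrations can be substituted by replacing `transition_rate`.

**Fitting.** Bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective) minimises the residual sum of squares.
Because the RSS surface is multimodal in L, fits start from a small grid
of candidate inflexion times (the 0.1/0.3/0.5/0.7/0.9 quantiles of the
observed times), with B initialised from the earliest tertile of the data,
A from the latest-minus-earliest tertile difference and T at a quarter of
the time span. Bounds: L within the observed span padded by half a span,
T in [0.1 d, 3·span], B and A within the data range padded by 2 log2
units. Among converged starts the lowest RSS wins; RSS ties (relative
1e-9) break towards smaller |A|, then earlier L — the most parsimonious
transition consistent with the data. The parameter covariance is the
Gauss–Newton estimate s²(JᵀJ)⁻¹. Degenerate inputs (fewer than five
distinct times, all-identical times, non-finite values) are rejected with
errors rather than guessed at.

**Model selection.** The only nested simplification retained is the
constant model (B alone): fits are compared by BIC under a Gaussian
likelihood (k = 2 vs k = 5 including the noise variance). ΔBIC is
reported so callers can apply stricter evidence thresholds.

**Uncertainty.** Random-walk Metropolis on (B, A, L, log T, log σ²):
Gaussian proposals with covariance (2.4²/5)·Σ̂, where Σ̂ extends the
least-squares covariance (delta method for log T) with the asymptotic
2/n variance of log σ²; flat priors over the fit's parameter box; by
default 4 chains × 5000 iterations with 1000 burn-in, pooled after
burn-in, seeded and fully reproducible. Under simulation at the atlas
noise level (σ = 0.25, 30 time points) the central 95% interval for L
covers the true value in ≈92% of replicates; with σ = 0.05 its width
falls below 2 days.

**Classification.** A selected sigmoid with |A| < 0.58 log2 units
(≈1.5-fold) is called *flat*. A transition whose core (L ± T/2) lies
inside the observation window and with T no longer than the window is a
*switch* (up or down by sign of A); anything still in progress at the
window edge is *curvilinear/incomplete* — the SOX9-like case, in which T
is only weakly identified. The L ± T/2 criterion is this package's
operationalisation of the switch/curvilinear distinction; reference
matching therefore compares only L (with doubled tolerance) for
curvilinear references.

## Differential expression

Two-group contrasts on log2 values: log2FC is the difference of group
means, s² the pooled within-group variance on nA+nB−2 df. Variances are
moderated by the standard empirical-Bayes scheme: the scaled
inverse-chi-square prior (d₀, s₀²) is estimated by moment matching on log
s² (digamma/trigamma identities, with a Newton inverse-trigamma), the
posterior variance is the df-weighted blend, and moderated t uses df + d₀
degrees of freedom. d₀ = 0 recovers the ordinary t exactly; d₀ = ∞ uses
the common variance everywhere; estimation failure falls back to d₀ = 0
with a warning. P-values are two-sided; only pairwise contrasts are
supported (every comparison in the workflow is pairwise), with no
covariates. BH adjustment implements the step-up definition directly and
is property-tested against brute force and against
`statsmodels.multipletests`.

"Absolute fold change" is 2^log2FC for up-regulated contrasts (2^|log2FC|
with a direction flag otherwise), reported to one decimal where tables are
quoted.

## Preprocessing

* **Quantile normalisation** maps every sample onto the across-sample
  mean of sorted columns (ties averaged). It exists for consuming
  non-normalised input; the pipeline assumes its input matrix is already
  log2-normalised and does not renormalise by default.
* **Batch adjustment**: `meanvar` standardises each batch per gene and
  rescales to the gene's pooled mean/variance — it removes pure location
  (and scale) batch effects exactly and is the pipeline default. `eb`
  shrinks per-gene batch location estimates toward the batch-wide mean
  with inverse-variance weights (the spread of true offsets is estimated
  by subtracting the mean sampling variance) and moderates scales on the
  log; it is gentler at small batch sizes but retains a residual
  batch-mean noise floor of order σ/√n. Full ComBat parity (covariates,
  parametric priors) is not attempted: the structural property downstream
  stages need is batch-mean equalisation.
* **Outlier flagging** is correlation-based (no criterion is fixed by
  convention): within each tissue of ≥4 samples, a sample whose median
  Pearson correlation to its peers falls below Q1 − k·IQR (default k = 3)
  of the tissue's distribution is flagged. Smaller groups are skipped
  with a warning. Flagged samples are reported, not removed.
* **PCA** projects per-gene-centred samples onto top-k axes
  (`sklearn.decomposition.PCA`, full SVD).
* **Clustering** is Ward linkage on Euclidean distances over the 500 (by
  default) most-variable genes; samples are processed in sorted-id order
  so the tree is invariant to input column order; variance ties break by
  gene id.

## Screens

Gene symbols are upper-cased before any set operation. The early/late
split places samples strictly before the boundary stage (default CS23) in
the early group and strictly after it in the late group; samples *at* the
boundary sit on neither side of the modelled onset and are excluded from
both, which is what makes the pre-/post-onset contrast sharp. Venn
partitions support 2–3 sets with exact region membership. The
steroidogenesis candidate screen intersects adrenal-up (log2FC ≥ 2 vs
control) with late-testis-up (log2FC ≥ 1 vs early) genes, warning if the
input sets lack matching threshold provenance. The chromosome-Y screen
restricts significant up-regulated genes to annotated chrY
(protein-coding when a biotype column is present); the secreted screen is
a pure annotation filter on a signal-peptide flag — no prediction is
performed. Uncategorised candidates fall into a "Novel" category.

## The synthetic atlas generator

The generator emulates the study design the pipeline targets: 53 samples
(17 adrenal, 20 testis, 10 ovary, 6 one-organ 46,XY controls), staged
CS17–F3 and mapped to midpoint ages via a configurable stage map
(defaults CS17→42 … CS23→56.5 … F3→73 dpc, spanning the 42–74 dpc
window; the exact midpoints of the original staging table are not public,
so these are representative values). The testis allocation places 9
samples in CS18–CS22, 3 at CS23 and 8 in F1–F3 so the early/late split
reproduces the 9-vs-8 contrast. Two batches are interleaved within each
tissue (never confounded with it).

Planted profiles and defaults:

* **steroidogenic sigmoids** (6 genes, shared adrenal+testis): B=6, A=3,
  T=4 d, L=55.5 dpc in testis. In adrenal the same genes use L=42 dpc — a
  per-tissue localisation override — because adrenal steroidogenesis is
  already established before the window opens, so the adrenal profile is
  effectively a high plateau. Without this the adrenal contrast would sit
  below the log2FC≥2 screen threshold and carry inflated within-group
  variance, which is not how these genes behave in the real tissue.
* **SRY-like pulse** (chrY): Gaussian bump b=5, h=1.5, μ=45 dpc, w=6 d —
  high at the window start, fading by ~57 dpc. A Gaussian bump is the
  simplest shape with that phenomenology; the pipeline deliberately does
  not fit this transient class, only detects it by contrast.
* **SOX9-like curvilinear** (3 genes): B=6, A=1, L=70, T=25 — a slow
  ~2-fold rise still incomplete at 74 dpc.
* **secreted late-testis genes** (AMH, INHA, INSL3): B=6, A=2, L=57,
  T=6, flagged secreted in the generated annotation.
* **tissue-identity marker blocks** (44 genes): constant per-tissue
  offsets of 1.5–3 log2 units for adrenal, testis (Sertoli-lineage),
  ovary (including a germ-cell expansion signature) and shared-gonad
  genes. These give each organ the broad expression signature that makes
  real atlases cluster by tissue first; without them the within-testis
  developmental transition would dominate the sample dendrogram, which is
  not what whole-transcriptome data do.
* **background**: 143 flat genes with baselines cycling over 4–10 log2
  units; total panel 200 genes.

Noise is additive Gaussian on the log2 scale (default sd 0.25, matching
array-scale residual noise); batch effects are additive per-(batch, gene)
offsets drawn Normal(0, 0.3). Everything is driven by one
`numpy.random.default_rng(seed)`, so a seed reproduces the matrix
bit-for-bit.

**What the generator does not emulate:** probe-level intensities,
realistic gene–gene correlation beyond the planted blocks, heterogeneity
among the six control organs, mean–variance trends, or missingness.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under the stated generative model, not performance on raw
array data.

## Problem sizes and numerical choices

The default simulated atlas is 200 genes × 53 samples — large enough that
variance-moderation hyperparameters, FDR behaviour and clustering are
exercised, small enough that the full pipeline (including ~200 sigmoid
fits with multi-start) completes in well under a minute. Simulation-based
tests use 8–50 seeded replicates per claim; MCMC tests use shortened
chains (1–2 × 1500–2500) where the full default (4 × 5000) would add
nothing but runtime. Tolerances: noiseless parameter recovery to 1e-4;
exact identities to 1e-10–1e-12; stochastic claims at the replicate
counts stated in the tests.

## Known limitations

* The model family is {constant, full sigmoid}; other nested
  simplifications (e.g. fixed-T or shared-L variants) are not enumerated.
* Transient (pulse-shaped) dynamics are simulated but not fitted.
* The eb batch mode implements location/scale shrinkage without
  covariates; it is not a drop-in ComBat replacement.
* Multi-factor DE designs, limma-trend/robust variants and array weights
  are out of scope.
* The CS17–F3 stage midpoints are representative defaults, configurable
  via `DesignConfig.stage_map` / the metadata reader, not authoritative
  staging values.
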