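# Methods

## The problem

In chronically inflamed barrier tissue, cell-type composition is itself an
outcome of disease: immune cells infiltrate the tissue, and any bulk
methylation difference between inflamed and uninflamed biopsies mixes
(i) composition shift and (ii) genuine methylation change within resident
compartments. `ctewas` implements an analysis chain whose estimand is (ii):
the inflammation effect on the non-immune tissue compartment, net of
immune admixture.

## Synthetic cohorts

The generator emulates a paired-biopsy study of periodontitis-inflamed
versus clinically uninflamed gingiva. Defaults (the study conditions used
throughout the tests):

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 48 | each donates one inflamed + one uninflamed biopsy (96 samples); `paired_fraction < 1` drops one biopsy for the remainder |
| `ic_params` | U 0.22 ± 0.06, I 0.58 ± 0.13 | immune-fraction mean ± SD per status, Beta-distributed by moment matching (the gated cohort's moments; pre-gating moments 0.28 ± 0.15 / 0.52 ± 0.18 are provided as `PRE_GATING_IC`) |
| `fib_params` | U 0.21 ± 0.07, I 0.17 ± 0.07 | fibroblast fraction per status |
| epithelial fraction | `1 − ic − fib` | complement; structurally reproduces the near-perfect Epi–IC anticorrelation of real gingival deconvolution (r ≈ −0.93) |
| `noise_sd` | 0.03 | additive Gaussian noise on the beta scale, clipped to [10⁻³, 1−10⁻³] |
| `batch_sd` | 0.1 | per-slide random offset on the M scale; slides hold 8 samples with statuses interleaved so batch is never confounded with status |
| `smoking_rate` | 0.43 | per-subject smoker flag; `n_smoking_probes` labels a random probe subset "smoking-associated" so exclusion logic is exercisable |

The reference methylome (`generate_reference`) lays probes on a toy genome
with exponential inter-probe gaps (mean 700 bp — close enough to array
spacing that both 500-bp smoothing clusters and 2-kb co-methylation
clusters are non-trivial), draws a bimodal base methylome, and engineers
10 % of probes to be *discriminatory* (maximum pairwise centroid
separation ≥ 0.5) — the signature probes deconvolution relies on.
Consecutive probes are grouped into gene territories; ~8 % of annotated
probes carry two gene symbols and ~10 % are intergenic, so fractional gene
counting has something to count.

Observed betas are `clip(C(status)·w + ε)` with planted effects applied to
the affected compartment's centroid in inflamed samples only, batch
offsets added on the M scale. Everything is bit-deterministic given the
design seed (numpy `SeedSequence` fan-out). What the generator does **not**
emulate: array chemistry (type I/II probes, dye bias), realistic
genome-wide methylation landscapes, within-subject correlation of
measurement error, and immune-cell subtypes. Passing tests therefore
validate the statistical machinery under a linear mixture model, not
performance on real arrays.

## Deconvolution

`estimate_fractions` solves `beta ≈ C·w` per sample. The default `rpc`
mode uses iteratively reweighted robust regression (statsmodels RLM,
Huber t = 1.345, ≤ 50 iterations, tol 10⁻⁶), truncates negative
coefficients at zero and renormalises to sum 1; `nnls` (scipy) is the
cross-check. Probes are intersected by id (≥ 30 required, warning
below 100). On noiseless centroid mixtures both modes recover weights to
10⁻⁶; on the default noisy cohort mean per-sample RMSE is ~0.002–0.004.

## Gating and MDS

Thresholds are inclusive (`IC ≤ 0.35` uninflamed, `IC ≥ 0.40` inflamed);
exclusion reasons are recorded. The MDS is classical metric scaling
(PCoA): Euclidean distances over the 1000 most-variable probes, Gower
double-centring, eigendecomposition; axis signs fixed by the first
sample, numerically-zero eigenvalue axes zeroed, so the embedding is
deterministic.

## Per-CpG model

On M-values (`beta_to_m`, boundary clip ε = 10⁻³):

```
M = μ + δ·status + γ·IC_c + u_batch + ε
```

with IC centred at the mean of the uninflamed samples, and IC dropped when
constant. Two engines:

- `fit_dmp` (per probe): MixedLM random slide intercept (REML, Wald z on
  δ) when ≥ 3 slides and the batch variance estimate is positive;
  otherwise exact OLS with centred slide fixed effects (Wald t). Singular
  status/batch designs raise, naming the probe.
- `run_ewas` (genome-wide, default `engine="fixed"`): the OLS-with-slide-
  fixed-effects model solved in closed form for all probes at once (the
  design matrix is shared), which makes a 20k-probe EWAS a sub-second
  operation; `engine="mixed"` runs the per-probe mixed model. With slides
  balanced over status the two treatments of batch estimate the same
  contrast; a test asserts their agreement on a small panel. The fixed
  engine is the default because desk-scale runs are ~10³× faster and
  exactly reproducible.

Stage 2 (`paired_stage`) refits stage-1 significant probes (q < 0.05) on
subjects with both biopsies retained, adding a per-subject intercept
(within-subject fixed-effect OLS by default — for two samples per subject
this is the classic paired estimator — or MixedLM), and Bonferroni-corrects
over the stage-1 selection size, mirroring a two-stage design correcting
over the stage-1 test count.

### Intercept-method effect sizes

`Δβ_adj = f(m₀+δ) − f(m₀)` with `f(m) = 2^m/(2^m+1)`. The reference level
`m₀` is the fitted M of an uninflamed sample with the batch effect at its
mean (slide dummies are centred, so the intercept already sits there) and
immune content at a configurable reference: `zero` (default — the estimand
is the effect in the non-immune compartment) or `uninflamed-mean`. In the
homogeneous limit (constant IC, constant per-group betas) `Δβ_adj` equals
the raw group difference exactly; this identity is tested. Under
confounded admixture the adjusted estimate approaches the planted
compartment effect while the raw difference is diluted several-fold.

## Calibration scenarios

The generator's defaults contain two things the IC-only model cannot fully
absorb: a fibroblast-fraction shift between statuses (a second,
unadjusted composition axis) and the nonlinearity of the M transform in
IC (exact only at small composition variance). Both are genuine
limitations of the modelling approach — bulk-tissue EWAS are known for
inflated test statistics — not of the estimator/SE/BH machinery. The
calibration checks therefore isolate the machinery:

- **Null calibration** (λ, KS uniformity, empirical FDR): composition
  drawn identically for both statuses in the small-variance regime
  (IC 0.30 ± 0.03, Fib 0.19 ± 0.03) with true fractions as covariate, so
  the model is correctly specified and status is fully exchangeable.
  Under these conditions λ ≈ 1.00 and p-values pass KS at 20k probes.
  Empirical FDR is measured with 200 planted effects among 20k probes
  (so false discoveries are identifiable and the ratio is stable) and
  averaged over 3 cohorts.
- **De-confounding** runs under the study's confounded IC (0.22/0.58)
  with status-independent fibroblasts and *estimated* immune fractions —
  the realistic pipeline.

## Spatial filter

Single-linkage chaining of stage-1 significant DMPs along each chromosome
with an inclusive 2000-bp gap; the stringent filter keeps clusters with
≥ 2 members, max member |Δβ_adj| > 0.1 (strict), and min member paired
p_adj < 0.05 (strict); members missing a paired p cannot satisfy
criterion 3. "Supporting DMPs" are cluster co-members excluding the index
probe. Clustering is verified against a brute-force transitive-closure
oracle; the filter against fixtures with known pass/fail patterns. Both
pre- and post-filter cluster counts are reported, since singleton
counting conventions differ between studies.

## Bump hunting

Coefficients are per-probe beta-scale status effects adjusted for IC by
linear regression (the 0.02 cutoff is only meaningful on the beta scale).
Probes are pre-clustered at a 500-bp gap; within clusters of ≥ 3 probes a
centred running mean (window 3, truncated at cluster edges — region areas
are therefore edge-attenuated, which the tests assert by oracle
recomputation) smooths the coefficients; candidates are maximal
sign-consistent runs beyond ±cutoff.

Significance uses **Freedman–Lane residual permutation** rather than label
permutation: because δ is estimated jointly with IC, shuffling labels
destroys the status–IC collinearity of the observed design and produces a
null distribution far too narrow (measured: every null cohort produced
false FWER hits under label permutation). Instead the residuals of the
status-free model `beta ~ 1 + IC` are permuted and projected onto the
observed design's status contrast (algebraically identical to refitting
the full model on the reconstructed null response). The permutation group
respects pairing twice over: paired residual 2-vectors travel across
subjects as units (in original or swapped order), and unpaired samples
shuffle freely — a group that remains valid when a subject's two samples
are correlated. With add-one counting, `p_perm` pools all null region
areas and `fwer` uses the per-permutation maximum area; the smallest
attainable FWER with B permutations is 1/(B+1). Desk-scale runs use
B = 200 (floor ≈ 0.005); the conventional production setting is B = 1000.
Measured null familywise error across 96 simulated null cohorts: 0.04.

## Enrichment

A probe annotated to k genes contributes 1/k to each gene's probe and
significance counts; a gene's differential-methylation weight is
min(1, fractional significant count), which produces the half-integer
gene tallies characteristic of fractional counting. Per set, the rounded
(half-away-from-zero) DM-gene count is tested against a Wallenius
noncentral hypergeometric draw (scipy) with odds = mean probes-per-gene
inside the set / outside. With constant probe coverage the odds are
exactly 1 and the central hypergeometric is used directly, so the no-bias
reduction is exact to machine precision. Under simulated probe-count bias
(per-probe significance, sets sampled toward probe-rich genes) the plain
hypergeometric rejects ~2–3× the nominal rate while the adjusted test
holds level. Per-gene weighting curves (beyond the single set-level odds)
are out of scope. FDR over sets is Benjamini–Hochberg.

## Orchestration

`run_all` executes simulate/load → deconvolve → gate → EWAS (full +
paired) → filter → DMR → enrich, writing every stage's tables before the
next begins (later failures preserve earlier outputs, wrapped in a
`StageError` naming the stage). One master seed fans out to one child seed
per stage via `SeedSequence`, so stages are independently reproducible;
all thresholds are echoed into the JSON run report. `B = 0` skips the DMR
stage; without a GMT file, simulated runs test random gene sets as a
negative control.

## Numerical notes and limitations

- Beta→M boundary clip ε = 10⁻³ (configurable); emitted synthetic betas
  clipped to the same bounds.
- Zero residual variance (noise-free fixtures) yields p = 0 for a nonzero
  effect and p = 1 otherwise, rather than NaN.
- BH is an in-package 6-line step-up pinned by an exhaustive oracle over
  all short inputs and cross-checked against statsmodels.
- λ uses the median-χ²₁ estimator (the EWAS/GWAS convention).
- The λ ≈ 5.97 reported for real gingival data is expected to arise from
  intra-individual variation and residual composition axes that the
  IC-only model does not absorb; the simulator reproduces the mechanism
  qualitatively (unadjusted fibroblast shifts inflate λ) but makes no
  quantitative claim about real-data inflation.
- MixedLM with very few batch groups can fail to converge; such fits fall
  back to the fixed-effect path and are logged in the fit's `method`.
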