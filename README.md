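# ctewas — cell-type-informed EWAS of inflamed mucosal tissue

Bulk biopsies of inflamed tissue are mixtures: in periodontitis-inflamed
gingiva roughly half of the cells are infiltrating immune cells, against
~20 % at clinically healthy sites. An epigenome-wide association study
(EWAS) that compares such biopsies therefore measures two things at once —
true methylation changes within the resident tissue compartments, and the
shift in cell-type composition. `ctewas` implements the full analysis chain
for separating the two, for epigenomics analysts working with paired
inflamed/uninflamed solid-tissue methylomes (Illumina-style beta matrices):

- **reference-based cell-type deconvolution** — per sample, solve
  `beta ≈ C·w` for non-negative weights `w = (Epi, Fib, IC)` over reference
  centroids `C`, by Huber-loss robust regression (`rpc`, default) or NNLS;
- **immune-fraction gating** — keep uninflamed samples with IC ≤ 0.35 and
  inflamed samples with IC ≥ 0.40 (both inclusive), pair subjects whose two
  biopsies both survive; classical-MDS diagnostics;
- **per-CpG association** on M-values, `M = log2(β/(1−β))`:
  `M ~ μ + δ·status + γ·IC + u_batch + ε`, with a slide random intercept
  (per-probe mixed model) or a vectorised exact fixed-effect fit for
  genome-wide runs; Benjamini–Hochberg q-values and the genomic inflation
  factor λ (median-χ² estimator);
- **intercept-method effect sizes** — the confounder-adjusted beta-scale
  effect `Δβ_adj = f(m₀+δ) − f(m₀)`, `f(m) = 2^m/(2^m+1)`, with the baseline
  `m₀` evaluated for an uninflamed sample at zero immune content, so the
  estimand is the effect in the non-immune tissue compartment;
- **two-stage testing** — stage-1 significant probes (q < 0.05) are refit on
  the paired subset with a per-subject intercept and Bonferroni-corrected
  over the stage-1 selection size;
- **stringent spatial filtering** — 2-kb single-linkage clusters of
  significant DMPs, kept when ≥ 2 members, max |Δβ_adj| > 0.1, and at least
  one member paired-significant;
- **bump-hunting DMR detection** — running-mean smoothing of IC-adjusted
  beta-scale coefficients within 500-bp probe clusters, candidate regions
  beyond a ±0.02 cutoff, permutation p-values and family-wise error rates
  from Freedman–Lane residual permutation that respects pairing;
- **probe-bias-aware enrichment** — fractional probe-to-gene counting and a
  Wallenius noncentral hypergeometric test whose odds parameter corrects
  the probe-number bias of methylation arrays;
- **a synthetic-cohort generator** with planted compartment-specific
  effects, batch effects, and full truth tables, used by the test suite to
  validate every stage against known ground truth.

## Worked example

`examples/03_ewas_intercept_method.py` plants an epithelial-compartment
effect of Δβ = −0.2 at 40 CpGs in a simulated 48-subject paired cohort in
which immune content is strongly confounded with inflammation (IC
0.22 ± 0.06 uninflamed vs 0.58 ± 0.13 inflamed), then runs deconvolution
and the two-stage EWAS:

```
stage-1 significant (q<0.05): 40 probes
planted probes recovered at q<0.05: 95%
genomic inflation lambda: 1.05
mean raw delta-beta at planted probes:      -0.051
mean adjusted delta-beta at planted probes: -0.140  (planted: -0.200)
adjusted closer to truth than raw: 100% of planted probes
planted probes significant after paired-stage Bonferroni: 35
```

The raw group difference (−0.05) is a quarter of the planted effect —
immune admixture dilutes it, because inflamed samples contain mostly
immune cells that do not carry the epithelial change. The intercept-method
estimate (−0.14) recovers most of the compartment effect; the residual gap
is the fibroblast share of the non-immune compartment, which also does not
carry the planted epithelial change. The other examples cover simulation +
deconvolution, gating + MDS, and DMR detection + enrichment; each prints
its numbers with a note on what they mean.

## Command line

A thin CLI mirrors the library stages:

```bash
ctewas simulate   --n-subjects 48 --n-probes 20000 --seed 7 --outdir sim/
ctewas deconvolve --betas sim/betas.tsv --reference sim/reference.tsv \
                  --manifest sim/manifest.tsv --out fractions.tsv
ctewas gate       --fractions fractions.tsv --sheet sim/sample_sheet.csv \
                  --u-max 0.35 --i-min 0.40 --out-prefix gating
ctewas ewas       --betas ... --sheet ... --fractions ... --manifest ... --out dmps.tsv
ctewas filter     --dmps dmps.tsv --max-gap 2000 --min-effect 0.1 --out retained.tsv
ctewas dmr        --betas ... --cutoff 0.02 --permutations 1000 --seed 7 --out dmrs.tsv
ctewas enrich     --dmps dmps.tsv --manifest ... --gmt sets.gmt --out enrichment.tsv
ctewas run-all    --config config.yaml --outdir run/
```

File dialects (TSV tables, CSV sample sheet, plain-text blacklists, GMT
gene sets, BED region export) are documented in `ctewas.io`; every
reader/writer pair round-trips exactly.

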