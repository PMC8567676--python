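"""Two-stage EWAS with confounder-adjusted effect sizes.

Plants epithelial hypomethylation (delta-beta -0.2) at 40 probes in a
cohort whose immune content is confounded with inflammation, runs the
per-CpG model (M-values, status + immune-content covariates), and shows
that the intercept-method effect size recovers the compartment effect far
better than the raw group difference.
"""

import numpy as np

import ctewas as ct
from ctewas.synthetic import auto_effects

reference = ct.generate_reference(8000, seed=3)
effects = auto_effects(reference, n_dmps=40, n_dmrs=0, dmp_delta=-0.2, seed=3)
design = ct.CohortDesign(n_subjects=48, seed=3)
cohort = ct.simulate_cohort(design, reference=reference, effect_spec=effects)

ic = ct.estimate_fractions(cohort.betas, reference)["ic"]
dmps = ct.run_ewas(cohort.betas, cohort.sheet, ic,
                   manifest=reference.manifest)
stage2 = ct.paired_stage(dmps, cohort.betas, cohort.sheet, ic)
dmps = dmps.join(stage2)

planted = [e.probe_id for e in effects]
sub = dmps.loc[planted]
print(f"stage-1 significant (q<0.05): {(dmps['q_full'] < 0.05).sum()} probes")
print(f"planted probes recovered at q<0.05: {(sub['q_full'] < 0.05).mean():.0%}")
print(f"genomic inflation lambda: "
      f"{ct.genomic_inflation(dmps['p_full'].to_numpy()):.2f}")
print(f"mean raw delta-beta at planted probes:      "
      f"{sub['raw_delta_beta'].mean():+.3f}")
print(f"mean adjusted delta-beta at planted probes: "
      f"{sub['adj_delta_beta'].mean():+.3f}  (planted: -0.200)")
closer = ((sub["adj_delta_beta"] + 0.2).abs()
          < (sub["raw_delta_beta"] + 0.2).abs())
print(f"adjusted closer to truth than raw: {closer.mean():.0%} of planted probes")
# the raw difference is diluted to a fraction of the planted effect by
# immune admixture; the intercept method, evaluated at zero immune
# content, approaches the true epithelial-compartment effect
paired_sig = (sub["p_adj_paired"] < 0.05).sum()
print(f"planted probes significant after paired-stage Bonferroni: {paired_sig}")
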