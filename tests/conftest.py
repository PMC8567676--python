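"""Shared fixtures: small synthetic references and cohorts.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive cohorts to one build per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ctewas as ct
from ctewas.synthetic import INFLAMED, UNINFLAMED

#: status moments used by calibration scenarios: composition identical
#: across statuses and in the linear (small-variance) regime, so the
#: per-CpG model is correctly specified and status is fully exchangeable
EQ_IC = {UNINFLAMED: (0.30, 0.03), INFLAMED: (0.30, 0.03)}
EQ_FIB = {UNINFLAMED: (0.19, 0.03), INFLAMED: (0.19, 0.03)}

#: study-condition immune confounding with status-independent fibroblasts
CONF_IC = {UNINFLAMED: (0.22, 0.06), INFLAMED: (0.58, 0.13)}
EQMEAN_FIB = {UNINFLAMED: (0.19, 0.07), INFLAMED: (0.19, 0.07)}


@pytest.fixture(scope="session")
def small_reference() -> ct.CellTypeReference:
    return ct.generate_reference(2000, seed=3)


@pytest.fixture(scope="session")
def effect_cohort(small_reference):
    """24-subject paired cohort with 30 planted epithelial DMPs (-0.2)."""
    from ctewas.synthetic import auto_effects

    effects = auto_effects(
        small_reference, n_dmps=30, n_dmrs=0, dmp_delta=-0.2, seed=11
    )
    design = ct.CohortDesign(n_subjects=24, seed=11, n_smoking_probes=20)
    cohort = ct.simulate_cohort(design, reference=small_reference,
                                effect_spec=effects)
    return cohort, effects


@pytest.fixture(scope="session")
def estimated_fractions(effect_cohort):
    cohort, _ = effect_cohort
    return ct.estimate_fractions(cohort.betas, cohort.reference)


def make_sheet(statuses, subjects=None, slides=None):
    """Minimal sample sheet from parallel lists."""
    n = len(statuses)
    if subjects is None:
        subjects = [f"S{i:03d}" for i in range(n)]
    if slides is None:
        slides = ["slide01"] * n
    return pd.DataFrame(
        {
            "subject": subjects,
            "status": statuses,
            "slide": slides,
            "position": np.arange(n) % 8 + 1,
            "smoker": False,
        },
        index=pd.Index([f"samp{i:03d}" for i in range(n)], name="sample_id"),
    )
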