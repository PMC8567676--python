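"""Synthetic cohort generator: references, fractions, planted effects."""

import numpy as np
import pandas as pd
import pytest

import ctewas as ct
from ctewas.synthetic import (
    CELL_TYPES,
    INFLAMED,
    UNINFLAMED,
    auto_effects,
    beta_params_from_moments,
    draw_fractions,
    generate_reference,
    plant_effects,
    simulate_cohort,
    synthesize_cohort,
)


class TestGenerateReference:
    def test_minimal_single_probe(self):
        ref = generate_reference(1, n_chromosomes=1, seed=0)
        assert ref.n_probes == 1
        assert ref.centroids.shape == (1, 3)
        assert ((ref.centroids >= 0) & (ref.centroids <= 1)).all().all()

    def test_discriminatory_margin(self):
        ref = generate_reference(500, seed=1, margin=0.5)
        disc = ref.manifest["discriminatory"]
        assert disc.any()
        cent = ref.centroids[disc]
        spread = cent.max(axis=1) - cent.min(axis=1)
        assert (spread >= 0.5 - 1e-12).all()

    def test_same_seed_identical(self):
        a = generate_reference(300, seed=7)
        b = generate_reference(300, seed=7)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        pd.testing.assert_frame_equal(a.centroids, b.centroids)

    def test_positions_sorted_within_chromosome(self):
        ref = generate_reference(1000, n_chromosomes=4, seed=2)
        for _, grp in ref.manifest.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            generate_reference(0)
        with pytest.raises(ValueError):
            generate_reference(10, mean_gap=-1)


class TestDrawFractions:
    def test_moments_match_design_at_large_n(self):
        # inflamed immune fraction Beta-matched to mean 0.58, SD 0.13
        design = ct.CohortDesign(n_subjects=1000, seed=5)
        frac = draw_fractions(design)
        sheet = design.sample_sheet()
        ic_inf = frac.loc[sheet["status"] == INFLAMED, "ic"]
        n = len(ic_inf)
        assert ic_inf.mean() == pytest.approx(0.58, abs=3 * 0.13 / np.sqrt(n))
        assert ic_inf.std() == pytest.approx(0.13, abs=3 * 0.13 / np.sqrt(n))
        ic_un = frac.loc[sheet["status"] == UNINFLAMED, "ic"]
        assert ic_un.mean() == pytest.approx(0.22, abs=3 * 0.06 / np.sqrt(n))

    def test_zero_sd_degenerates_to_mean(self):
        design = ct.CohortDesign(
            n_subjects=10, seed=0,
            ic_params={UNINFLAMED: (0.2, 0.0), INFLAMED: (0.6, 0.0)},
            fib_params={UNINFLAMED: (0.2, 0.0), INFLAMED: (0.2, 0.0)},
        )
        frac = draw_fractions(design)
        sheet = design.sample_sheet()
        assert (frac.loc[sheet["status"] == INFLAMED, "ic"] == 0.6).all()

    def test_rows_sum_to_one(self):
        frac = draw_fractions(ct.CohortDesign(n_subjects=200, seed=1))
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-12)
        assert (frac >= 0).all().all()

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_params_from_moments(0.5, 0.6)
        with pytest.raises(ValueError):
            ct.CohortDesign(
                n_subjects=4,
                ic_params={UNINFLAMED: (1.2, 0.1), INFLAMED: (0.5, 0.1)},
            )


class TestPlantEffects:
    def test_null_cohort_statuses_identical(self, small_reference):
        design = ct.CohortDesign(n_subjects=4, seed=0, noise_sd=0.0, batch_sd=0.0,
                                 ic_params={UNINFLAMED: (0.3, 0.0), INFLAMED: (0.3, 0.0)},
                                 fib_params={UNINFLAMED: (0.2, 0.0), INFLAMED: (0.2, 0.0)})
        truth = plant_effects(small_reference, design, [])
        betas, sheet = synthesize_cohort(
            small_reference, draw_fractions(design), truth, design
        )
        u = betas.loc[:, sheet["status"] == UNINFLAMED].to_numpy()
        i = betas.loc[:, sheet["status"] == INFLAMED].to_numpy()
        np.testing.assert_allclose(u.mean(axis=1), i.mean(axis=1), atol=1e-12)

    def test_pure_compartment_shift_is_exact(self, small_reference):
        cent = small_reference.centroids["epi"]
        probe = cent[(cent > 0.4) & (cent < 0.8)].index[0]
        design = ct.CohortDesign(
            n_subjects=4, seed=0, noise_sd=0.0, batch_sd=0.0,
            ic_params={UNINFLAMED: (1e-9, 0.0), INFLAMED: (1e-9, 0.0)},
            fib_params={UNINFLAMED: (1e-9, 0.0), INFLAMED: (1e-9, 0.0)},
        )
        truth = plant_effects(
            small_reference, design, [ct.ProbeEffect(probe, "epi", -0.2)]
        )
        betas, sheet = synthesize_cohort(
            small_reference, draw_fractions(design), truth, design
        )
        diff = (
            betas.loc[probe, sheet["status"] == INFLAMED].mean()
            - betas.loc[probe, sheet["status"] == UNINFLAMED].mean()
        )
        assert diff == pytest.approx(-0.2, abs=1e-8)

    def test_region_spec_expands_to_shared_region_id(self, small_reference):
        man = small_reference.manifest
        grp = man[man["chrom"] == "chr1"]
        pos = grp["pos"].to_numpy()
        fib = small_reference.centroids["fib"]
        # find 5 consecutive probes within 1.5 kb with headroom for -0.05
        i = next(
            i for i in range(len(grp) - 4)
            if pos[i + 4] - pos[i] <= 1500
            and (fib.loc[grp.index[i : i + 5]] > 0.1).all()
        )
        span = int(pos[i + 4] - pos[i])
        spec = ct.RegionEffect("chr1", int(pos[i]), span, "fib", -0.05)
        truth = plant_effects(
            small_reference, ct.CohortDesign(n_subjects=2, seed=0), [spec]
        )
        assert len(truth.effects) == 5
        assert truth.effects["region_id"].nunique() == 1
        assert set(truth.effects.index) == set(grp.index[i : i + 5])

    def test_out_of_range_delta_rejected(self, small_reference):
        cent = small_reference.centroids["epi"]
        probe = cent[cent < 0.1].index[0]
        with pytest.raises(ValueError, match="outside"):
            plant_effects(
                small_reference,
                ct.CohortDesign(n_subjects=2),
                [ct.ProbeEffect(probe, "epi", -0.5)],
            )

    def test_unknown_probe_and_compartment_rejected(self, small_reference):
        with pytest.raises(ValueError, match="not in the reference"):
            plant_effects(small_reference, ct.CohortDesign(n_subjects=2),
                          [ct.ProbeEffect("cg99999999", "epi", -0.1)])
        probe = small_reference.probe_ids[0]
        with pytest.raises(ValueError, match="compartment"):
            plant_effects(small_reference, ct.CohortDesign(n_subjects=2),
                          [ct.ProbeEffect(probe, "tcell", -0.1)])


class TestSynthesizeCohort:
    def _noiseless_design(self, **frac_kw):
        return ct.CohortDesign(n_subjects=3, seed=0, noise_sd=0.0, batch_sd=0.0,
                               **frac_kw)

    def test_identity_mixture_equals_centroid(self, small_reference):
        design = self._noiseless_design(
            ic_params={UNINFLAMED: (1e-9, 0.0), INFLAMED: (1e-9, 0.0)},
            fib_params={UNINFLAMED: (1e-9, 0.0), INFLAMED: (1e-9, 0.0)},
        )
        truth = plant_effects(small_reference, design, [])
        betas, _ = synthesize_cohort(
            small_reference, draw_fractions(design), truth, design
        )
        expected = small_reference.centroids["epi"].to_numpy()
        for col in betas.columns:
            np.testing.assert_allclose(betas[col], expected, atol=1e-8)

    def test_half_half_mixture_is_linear(self, small_reference):
        design = self._noiseless_design(
            ic_params={UNINFLAMED: (1e-9, 0.0), INFLAMED: (1e-9, 0.0)},
            fib_params={UNINFLAMED: (0.5, 0.0), INFLAMED: (0.5, 0.0)},
        )
        truth = plant_effects(small_reference, design, [])
        betas, _ = synthesize_cohort(
            small_reference, draw_fractions(design), truth, design
        )
        expected = small_reference.centroids[["epi", "fib"]].mean(axis=1)
        np.testing.assert_allclose(betas.iloc[:, 0], expected, atol=1e-8)

    def test_zero_noise_mixture_to_machine_precision(self, small_reference):
        design = self._noiseless_design()
        frac = draw_fractions(design)
        truth = plant_effects(small_reference, design, [])
        betas, _ = synthesize_cohort(small_reference, frac, truth, design)
        expected = small_reference.centroids.to_numpy() @ frac.to_numpy().T
        np.testing.assert_allclose(betas.to_numpy(), expected, atol=1e-14)

    def test_betas_bounded_and_complete(self, effect_cohort):
        cohort, _ = effect_cohort
        vals = cohort.betas.to_numpy()
        assert not np.isnan(vals).any()
        assert vals.min() > 0 and vals.max() < 1

    def test_same_seed_bit_identical(self, small_reference):
        design = ct.CohortDesign(n_subjects=6, seed=42, n_smoking_probes=10)
        a = simulate_cohort(design, reference=small_reference)
        b = simulate_cohort(design, reference=small_reference)
        pd.testing.assert_frame_equal(a.betas, b.betas)
        pd.testing.assert_frame_equal(a.sheet, b.sheet)
        pd.testing.assert_frame_equal(a.truth.effects, b.truth.effects)
        assert a.truth.smoking_probes == b.truth.smoking_probes

    def test_paired_fraction_controls_pairing(self):
        design = ct.CohortDesign(n_subjects=10, paired_fraction=0.6, seed=0)
        sheet = design.sample_sheet()
        per_subject = sheet.groupby("subject").size()
        assert (per_subject == 2).sum() == 6
        assert (per_subject == 1).sum() == 4

    def test_status_not_confounded_with_slide(self):
        sheet = ct.CohortDesign(n_subjects=24, seed=0).sample_sheet()
        # every slide carries both statuses
        mix = sheet.groupby("slide")["status"].nunique()
        assert (mix == 2).all()


class TestAutoEffects:
    def test_effects_are_feasible_and_deterministic(self, small_reference):
        a = auto_effects(small_reference, n_dmps=10, n_dmrs=1, seed=4)
        b = auto_effects(small_reference, n_dmps=10, n_dmrs=1, seed=4)
        assert a == b
        design = ct.CohortDesign(n_subjects=2, seed=0)
        truth = plant_effects(small_reference, design, a)  # no ValueError
        assert (truth.effects["region_id"] != "").sum() == 5
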