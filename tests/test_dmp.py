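"""Per-CpG association model, intercept-method effect sizes, two stages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ctewas as ct
from ctewas.dmp import (
    DmpFit,
    exclude_probes,
    fit_dmp,
    intercept_delta_beta,
    paired_stage,
    raw_delta_beta,
    run_ewas,
)
from ctewas.methcore import beta_to_m
from ctewas.synthetic import INFLAMED, UNINFLAMED

from conftest import make_sheet


class TestExcludeProbes:
    @staticmethod
    def _manifest(n=10, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos": np.arange(1, n + 1) * 100, "gene": ""},
            index=pd.Index([f"cg{i:02d}" for i in range(n)], name="probe_id"),
        )

    def test_empty_blacklists_identity(self):
        man = self._manifest()
        retained, counts = exclude_probes(man, {})
        assert list(retained) == list(man.index)
        assert counts["retained"] == 10

    def test_partial_blacklist_with_unknown_id_warns(self):
        man = self._manifest()
        with pytest.warns(UserWarning, match="not in manifest"):
            retained, counts = exclude_probes(
                man, {"smoking": ["cg00", "cg03", "cg07", "cgXX"]}
            )
        assert len(retained) == 7
        assert counts["smoking"] == 3

    def test_sex_chromosomes_removed(self):
        man = pd.concat([self._manifest(5), self._manifest(3, "chrX")
                         .rename(index=lambda s: s + "X")])
        retained, counts = exclude_probes(man, {})
        assert counts["sex_chromosomes"] == 3
        assert len(retained) == 5

    def test_categories_overlap_counted_once(self):
        man = self._manifest()
        retained, counts = exclude_probes(
            man, {"a": ["cg00", "cg01"], "b": ["cg01", "cg02"]}
        )
        assert len(retained) == 7
        assert counts["a"] == 2 and counts["b"] == 1  # cg01 already gone


def _two_group_m(values_u, values_i, ic=None, slides=None):
    """Build (m_series, sheet, ic_series) for explicit per-group M-values."""
    vals = np.concatenate([values_u, values_i])
    statuses = [UNINFLAMED] * len(values_u) + [INFLAMED] * len(values_i)
    sheet = make_sheet(statuses, slides=slides)
    m = pd.Series(vals, index=sheet.index, name="cg_test")
    ic_vals = np.full(len(vals), 0.3) if ic is None else np.asarray(ic)
    return m, sheet, pd.Series(ic_vals, index=sheet.index)


class TestFitDmp:
    def test_ols_reduction_matches_pooled_t_test(self):
        rng = np.random.default_rng(0)
        u, i = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        m, sheet, ic = _two_group_m(u, i)
        fit = fit_dmp(m, sheet, ic)
        assert fit.method == "ols_fixed_batch"
        assert fit.delta_m == pytest.approx(i.mean() - u.mean(), abs=1e-10)
        t, p = stats.ttest_ind(i, u)  # pooled-variance two-sample test
        assert fit.p == pytest.approx(p, abs=1e-12)
        assert fit.mu0 == pytest.approx(u.mean(), abs=1e-10)

    def test_closed_form_two_covariate_regression(self):
        rng = np.random.default_rng(1)
        n = 30
        status = np.repeat([0.0, 1.0], n // 2)
        ic = rng.random(n)
        y = 1.0 - 0.5 * status + 2.0 * ic + rng.normal(0, 0.1, n)
        sheet = make_sheet([UNINFLAMED] * (n // 2) + [INFLAMED] * (n // 2))
        m = pd.Series(y, index=sheet.index)
        fit = fit_dmp(m, sheet, pd.Series(ic, index=sheet.index))
        X = np.column_stack([np.ones(n), status, ic - ic[status == 0].mean()])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.delta_m == pytest.approx(coef[1], abs=1e-8)
        assert fit.mu0 == pytest.approx(coef[0], abs=1e-8)

    def test_mixed_model_used_with_enough_batches(self):
        rng = np.random.default_rng(2)
        n_per = 4
        slides, y, statuses = [], [], []
        offsets = {"slide01": 0.5, "slide02": -0.4, "slide03": 0.1,
                   "slide04": -0.2}
        for s, off in offsets.items():
            for j in range(n_per):
                slides.append(s)
                st_lab = UNINFLAMED if j % 2 == 0 else INFLAMED
                statuses.append(st_lab)
                y.append(off + (0.7 if st_lab == INFLAMED else 0)
                         + rng.normal(0, 0.2))
        sheet = make_sheet(statuses, slides=slides)
        m = pd.Series(y, index=sheet.index)
        ic = pd.Series(0.3, index=sheet.index)
        fit = fit_dmp(m, sheet, ic)
        assert fit.method == "lmm"
        assert fit.sigma_batch > 0
        assert fit.delta_m == pytest.approx(0.7, abs=0.3)

    def test_singular_design_names_probe(self):
        # status perfectly confounded with slide
        sheet = make_sheet(
            [UNINFLAMED] * 4 + [INFLAMED] * 4,
            slides=["s1"] * 4 + ["s2"] * 4,
        )
        m = pd.Series(np.random.default_rng(0).random(8), index=sheet.index,
                      name="cg_bad")
        ic = pd.Series(0.3, index=sheet.index)
        with pytest.raises(ValueError, match="cg_bad"):
            fit_dmp(m, sheet, ic)

    def test_p_decreases_with_effect_at_fixed_noise(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, 24)
        ps = []
        for effect in (0.5, 1.0, 2.0):
            u = noise[:12]
            i = noise[12:] + effect
            m, sheet, ic = _two_group_m(u, i)
            ps.append(fit_dmp(m, sheet, ic).p)
        assert ps[0] > ps[1] > ps[2]


class TestInterceptMethod:
    def test_zero_delta_gives_zero(self):
        fit = DmpFit(mu0=1.2, delta_m=0.0, se=0.1, p=1.0, gamma_ic=2.0,
                     ic_center=0.3, sigma_batch=0, sigma_resid=0.1,
                     method="ols_fixed_batch", n_used=10)
        assert intercept_delta_beta(fit) == 0.0

    def test_homogeneous_limit_equals_raw_delta_beta(self):
        # constant per-group betas 0.87 / 0.80, constant IC: the adjusted
        # effect must equal the raw difference -0.07 exactly
        u_beta, i_beta = 0.87, 0.80
        m_u, m_i = beta_to_m(u_beta), beta_to_m(i_beta)
        m, sheet, ic = _two_group_m([m_u] * 5, [m_i] * 5)
        fit = fit_dmp(m, sheet, ic)
        adj = intercept_delta_beta(fit)
        assert adj == pytest.approx(i_beta - u_beta, abs=1e-10)
        assert adj == pytest.approx(-0.07, abs=1e-10)

    def test_reference_level_switch(self):
        fit = DmpFit(mu0=1.0, delta_m=-0.5, se=0.1, p=0.01, gamma_ic=2.0,
                     ic_center=0.25, sigma_batch=0, sigma_resid=0.1,
                     method="ols_fixed_batch", n_used=10)
        from ctewas.methcore import m_to_beta

        at_zero = intercept_delta_beta(fit, ic_reference="zero")
        at_mean = intercept_delta_beta(fit, ic_reference="uninflamed-mean")
        m0 = 1.0 - 2.0 * 0.25
        assert at_zero == pytest.approx(m_to_beta(m0 - 0.5) - m_to_beta(m0))
        assert at_mean == pytest.approx(m_to_beta(0.5) - m_to_beta(1.0))
        with pytest.raises(ValueError):
            intercept_delta_beta(fit, ic_reference="nonsense")

    def test_non_finite_rejected(self):
        fit = DmpFit(mu0=np.nan, delta_m=0.1, se=0.1, p=0.5, gamma_ic=0,
                     ic_center=0, sigma_batch=0, sigma_resid=0.1,
                     method="ols_fixed_batch", n_used=10)
        with pytest.raises(ValueError):
            intercept_delta_beta(fit)


class TestRawDeltaBeta:
    def test_worked_group_means(self):
        sheet = make_sheet([UNINFLAMED] * 2 + [INFLAMED] * 2)
        betas = pd.Series([0.87, 0.87, 0.80, 0.80], index=sheet.index)
        assert raw_delta_beta(betas, sheet) == pytest.approx(-0.07)

    def test_identical_groups_zero(self):
        sheet = make_sheet([UNINFLAMED, INFLAMED])
        betas = pd.Series([0.5, 0.5], index=sheet.index)
        assert raw_delta_beta(betas, sheet) == 0.0

    def test_large_effect_group_means(self):
        # means 0.64 vs 0.18 differ by -0.46 on the raw scale
        sheet = make_sheet([UNINFLAMED] * 3 + [INFLAMED] * 3)
        betas = pd.Series([0.64] * 3 + [0.18] * 3, index=sheet.index)
        assert raw_delta_beta(betas, sheet) == pytest.approx(-0.46)

    def test_missing_group_rejected(self):
        sheet = make_sheet([UNINFLAMED, UNINFLAMED])
        betas = pd.Series([0.5, 0.6], index=sheet.index)
        with pytest.raises(ValueError, match="inflamed"):
            raw_delta_beta(betas, sheet)


class TestRunEwas:
    def test_fixed_engine_matches_fit_dmp_without_batch_variance(
        self, small_reference
    ):
        design = ct.CohortDesign(n_subjects=10, seed=5, batch_sd=0.0)
        cohort = ct.simulate_cohort(design, reference=small_reference)
        betas = cohort.betas.iloc[:40]
        ic = cohort.fractions["ic"]
        table = run_ewas(betas, cohort.sheet, ic)
        M = beta_to_m(betas.to_numpy())
        for k, pid in enumerate(betas.index[:10]):
            fit = fit_dmp(
                pd.Series(M[k], index=betas.columns, name=pid),
                cohort.sheet, ic,
            )
            if fit.method == "lmm":
                continue  # fell to LMM only if variance appeared
            row = table.loc[pid]
            assert row["delta_m"] == pytest.approx(fit.delta_m, abs=1e-8)
            assert row["p_full"] == pytest.approx(fit.p, abs=1e-8)

    def test_mixed_engine_agrees_with_fixed_on_small_panel(
        self, small_reference
    ):
        # random- and fixed-effect treatments of slide estimate the same
        # status contrast; agreement is close for the bulk of probes (the
        # mixed fit shrinks batch offsets, so exact equality is not expected)
        design = ct.CohortDesign(n_subjects=24, seed=6, batch_sd=0.1,
                                 samples_per_slide=6)
        cohort = ct.simulate_cohort(design, reference=small_reference)
        betas = cohort.betas.iloc[:30]
        ic = cohort.fractions["ic"]
        fixed = run_ewas(betas, cohort.sheet, ic, engine="fixed")
        mixed = run_ewas(betas, cohort.sheet, ic, engine="mixed")
        diff = (fixed["delta_m"] - mixed["delta_m"]).abs()
        assert diff.median() < 0.05
        assert np.quantile(diff, 0.9) < 0.15
        r = np.corrcoef(np.log10(fixed["p_full"]), np.log10(mixed["p_full"]))
        assert r[0, 1] > 0.95

    def test_retained_restricts_and_q_over_tested_set(self, effect_cohort):
        cohort, _ = effect_cohort
        ic = cohort.fractions["ic"]
        keep = cohort.betas.index[:500]
        table = run_ewas(cohort.betas, cohort.sheet, ic, retained=keep)
        assert len(table) == 500
        from ctewas.methcore import bh_adjust

        np.testing.assert_allclose(
            table["q_full"], bh_adjust(table["p_full"].to_numpy()), atol=1e-12
        )

    def test_planted_effects_recovered_with_sign(self, effect_cohort,
                                                 estimated_fractions):
        cohort, effects = effect_cohort
        table = run_ewas(
            cohort.betas, cohort.sheet, estimated_fractions["ic"]
        )
        planted = [e.probe_id for e in effects]
        assert (table.loc[planted, "delta_m"] < 0).mean() > 0.95
        assert (table.loc[planted, "adj_delta_beta"] < -0.05).mean() > 0.9


class TestPairedStage:
    def test_selection_contract_and_bonferroni_count(self, effect_cohort):
        cohort, effects = effect_cohort
        ic = cohort.fractions["ic"]
        table = run_ewas(cohort.betas, cohort.sheet, ic)
        stage2 = paired_stage(table, cohort.betas, cohort.sheet, ic)
        selected = table.index[table["q_full"] < 0.05]
        assert set(stage2.index) == set(selected)
        np.testing.assert_allclose(
            stage2["p_adj_paired"],
            np.minimum(1.0, stage2["p_paired"] * len(selected)),
        )
        # planted probes significant in stage 1 mostly survive pairing
        planted = stage2.index.intersection([e.probe_id for e in effects])
        if len(planted):
            assert (stage2.loc[planted, "p_adj_paired"] < 0.05).mean() > 0.5

    def test_explicit_n_tests_arithmetic(self, effect_cohort):
        cohort, _ = effect_cohort
        ic = cohort.fractions["ic"]
        table = run_ewas(cohort.betas.iloc[:300], cohort.sheet, ic)
        stage2 = paired_stage(
            table, cohort.betas, cohort.sheet, ic, n_tests=15507
        )
        if len(stage2):
            row = stage2.iloc[0]
            assert row["p_adj_paired"] == pytest.approx(
                min(1.0, row["p_paired"] * 15507)
            )

    def test_too_few_pairs_aborts(self):
        sheet = make_sheet(
            [UNINFLAMED, INFLAMED, UNINFLAMED, INFLAMED],
            subjects=["A", "A", "B", "B"],
        )
        betas = pd.DataFrame(
            np.random.default_rng(0).uniform(0.2, 0.8, (5, 4)),
            index=[f"cg{i}" for i in range(5)],
            columns=sheet.index,
        )
        ic = pd.Series(0.3, index=sheet.index)
        stage1 = pd.DataFrame({"q_full": 0.01}, index=betas.index)
        with pytest.raises(ValueError, match="paired"):
            paired_stage(stage1, betas, sheet, ic)

    def test_mixed_engine_runs(self, effect_cohort):
        cohort, _ = effect_cohort
        ic = cohort.fractions["ic"]
        table = run_ewas(cohort.betas.iloc[:150], cohort.sheet, ic)
        if (table["q_full"] < 0.05).sum() == 0:
            pytest.skip("no stage-1 hits in this slice")
        fixed = paired_stage(table, cohort.betas, cohort.sheet, ic)
        mixed = paired_stage(table, cohort.betas, cohort.sheet, ic,
                             engine="mixed")
        assert set(fixed.index) == set(mixed.index)
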