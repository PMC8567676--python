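"""Per-CpG association of methylation with inflammation status.

The model, fit on M-values, is

    M = mu + delta * status + gamma * IC_c + u_batch + e,
    u_batch ~ N(0, sigma_b^2),  e ~ N(0, sigma_e^2)

with status coded 0 = uninflamed, 1 = inflamed and IC_c the immune fraction
centred at the mean IC of the uninflamed samples.  ``delta`` is the
status effect on the M scale at fixed immune content — i.e. net of the
compositional confounding that dominates raw group differences in
immune-infiltrated tissue.

Effect sizes on the beta scale come from the intercept method: the fitted
baseline M of an uninflamed sample at a reference immune content (IC = 0 by
default: the estimand is the effect in the non-immune tissue compartment)
is pushed through the inverse M transform with and without ``delta``:

    adj_delta_beta = f(m0 + delta) - f(m0),  f(m) = 2^m / (2^m + 1).

Two fitting engines exist.  ``fit_dmp`` is the per-probe contract: a linear
mixed model with a batch (slide) random intercept, falling back to OLS with
batch as a (centred) fixed effect when there are fewer than 3 batches or the
batch variance estimate collapses to 0.  ``run_ewas`` is the genome-wide
engine; its default "fixed" mode fits the batch-fixed-effect OLS for every
probe at once in closed form (the design matrix is shared across probes),
while "mixed" runs the per-probe mixed model.  A two-stage design refits
stage-1 significant probes on the paired subset with a per-subject
intercept and Bonferroni-corrects over the stage-1 selection size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .methcore import beta_to_m, bh_adjust, bonferroni_adjust, m_to_beta
from .synthetic import INFLAMED, UNINFLAMED

__all__ = [
    "DmpFit",
    "exclude_probes",
    "fit_dmp",
    "intercept_delta_beta",
    "raw_delta_beta",
    "run_ewas",
    "paired_stage",
]

_IC_CONST_TOL = 1e-12


def exclude_probes(
    manifest: pd.DataFrame,
    blacklists: Mapping[str, Iterable[str]] | None = None,
    exclude_sex_chromosomes: bool = True,
) -> tuple[pd.Index, dict]:
    """Remove blacklisted and sex-chromosome probes from the manifest.

    ``blacklists`` maps a category name (e.g. "smoking", "snp_proximal",
    "cross_reactive") to an iterable of probe ids.  Ids absent from the
    manifest are reported with a warning, not an error.  Returns the
    retained probe index and a per-category removal count dict.
    """
    retained = manifest.index
    counts: dict = {"initial": len(retained)}
    for name, ids in (blacklists or {}).items():
        ids = pd.Index(ids)
        unknown = ids.difference(manifest.index)
        if len(unknown):
            warnings.warn(
                f"blacklist {name!r}: {len(unknown)} id(s) not in manifest "
                f"(e.g. {list(unknown[:3])})",
                stacklevel=2,
            )
        hit = retained.intersection(ids)
        counts[name] = len(hit)
        retained = retained.difference(hit)
    if exclude_sex_chromosomes:
        sex = manifest["chrom"].isin(["chrX", "chrY", "X", "Y"])
        hit = retained.intersection(manifest.index[sex])
        counts["sex_chromosomes"] = len(hit)
        retained = retained.difference(hit)
    counts["retained"] = len(retained)
    # preserve manifest order
    return manifest.index[manifest.index.isin(retained)], counts


@dataclass(frozen=True)
class DmpFit:
    """Single-probe model fit.

    ``mu0`` is the fitted M for an uninflamed sample at the centred
    covariate level with the batch effect at its mean; ``ic_center`` the
    centring constant (mean IC of uninflamed samples); ``gamma_ic`` the IC
    slope (0 when IC was constant and dropped).
    """

    mu0: float
    delta_m: float
    se: float
    p: float
    gamma_ic: float
    ic_center: float
    sigma_batch: float
    sigma_resid: float
    method: str
    n_used: int


def _design_pieces(sheet: pd.DataFrame, ic: pd.Series):
    status = (sheet["status"] == INFLAMED).to_numpy(float)
    if not {UNINFLAMED, INFLAMED} >= set(sheet["status"]):
        raise ValueError("unknown status labels in sample sheet")
    for lab, mask in ((UNINFLAMED, status == 0), (INFLAMED, status == 1)):
        if mask.sum() < 2:
            raise ValueError(f"need >= 2 samples with status {lab!r}")
    ic = ic.loc[sheet.index].to_numpy(float)
    ic_center = float(ic[status == 0].mean())
    ic_c = ic - ic_center
    use_ic = ic_c.std() > _IC_CONST_TOL
    return status, ic_c, ic_center, use_ic


def _batch_dummies(groups: pd.Series) -> np.ndarray:
    """Centred treatment-coded dummies; empty when a single batch."""
    d = pd.get_dummies(groups, drop_first=True, dtype=float)
    return d.to_numpy() - d.to_numpy().mean(axis=0, keepdims=True)


def fit_dmp(
    m_probe: pd.Series,
    sheet: pd.DataFrame,
    ic: pd.Series,
    batch_col: str = "slide",
    probe_id: str | None = None,
) -> DmpFit:
    """Fit the per-CpG mixed model at one probe.

    Uses a batch random intercept (REML via statsmodels MixedLM) when >= 3
    batches are present and the estimated batch variance is positive;
    otherwise falls back to OLS with batch as a centred fixed effect.  The
    p value is a Wald z test on ``delta`` for the mixed model and the exact
    t test for the OLS fallback.
    """
    label = probe_id or (m_probe.name if m_probe.name is not None else "<probe>")
    sheet = sheet.loc[m_probe.index]
    status, ic_c, ic_center, use_ic = _design_pieces(sheet, ic)
    y = m_probe.to_numpy(float)
    n = y.size

    cols = [np.ones(n), status]
    if use_ic:
        cols.append(ic_c)
    X = np.column_stack(cols)
    groups = sheet[batch_col]
    n_batches = groups.nunique()

    dummies = _batch_dummies(groups)
    full = np.column_stack([X, dummies]) if dummies.size else X
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            f"probe {label}: status is confounded with batch (singular design)"
        )

    if n_batches >= 3:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
            sigma_b2 = float(np.squeeze(fit.cov_re))
        except (np.linalg.LinAlgError, ValueError):
            sigma_b2 = 0.0  # degenerate fit -> fixed-effect fallback
        if sigma_b2 > 1e-10:
            delta, se = float(fit.fe_params[1]), float(fit.bse_fe[1])
            p = float(2 * stats.norm.sf(abs(delta / se)))
            gamma = float(fit.fe_params[2]) if use_ic else 0.0
            return DmpFit(
                mu0=float(fit.fe_params[0]),
                delta_m=delta,
                se=se,
                p=p,
                gamma_ic=gamma,
                ic_center=ic_center,
                sigma_batch=float(np.sqrt(sigma_b2)),
                sigma_resid=float(np.sqrt(fit.scale)),
                method="lmm",
                n_used=n,
            )
    # fallback: OLS with centred batch fixed effects (intercept = batch mean)
    coef, se_all, dof, sigma = _ols(full, y[None, :])
    delta, se = float(coef[0, 1]), float(se_all[0, 1])
    # se == 0 on exactly noise-free data: the test degenerates
    z = abs(delta) / se if se > 0 else (np.inf if delta != 0 else 0.0)
    p = float(2 * stats.t.sf(z, dof))
    gamma = float(coef[0, 2]) if use_ic else 0.0
    return DmpFit(
        mu0=float(coef[0, 0]),
        delta_m=delta,
        se=se,
        p=p,
        gamma_ic=gamma,
        ic_center=ic_center,
        sigma_batch=0.0,
        sigma_resid=float(sigma[0]),
        method="ols_fixed_batch",
        n_used=n,
    )


def _wald_t_p(delta: np.ndarray, se: np.ndarray, dof: int) -> np.ndarray:
    """Two-sided t p values, tolerating se == 0 on degenerate noise-free data."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(delta) / se
    z = np.where(se > 0, z, np.where(delta != 0, np.inf, 0.0))
    return 2 * stats.t.sf(z, dof)


def _ols(X: np.ndarray, Y: np.ndarray):
    """Closed-form OLS of every row of Y on the shared design X.

    Returns (coefficients, standard errors, residual df, residual SD), with
    coefficient/SE arrays of shape (n_rows, n_params).
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    H = X @ xtx_inv  # n x p
    coef = Y @ H
    resid = Y - coef @ X.T
    dof = n - p
    sigma2 = np.einsum("ij,ij->i", resid, resid) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    return coef, se, dof, np.sqrt(sigma2)


def intercept_delta_beta(
    fit: DmpFit, ic_reference: str = "zero"
) -> float:
    """Confounder-adjusted beta-scale effect size for a single-probe fit.

    ``ic_reference`` chooses the immune content at which the baseline is
    evaluated: "zero" (effect in the non-immune compartment, default) or
    "uninflamed-mean" (baseline at the uninflamed cohort's mean IC).
    """
    if not np.isfinite([fit.mu0, fit.delta_m, fit.gamma_ic]).all():
        raise ValueError("non-finite fit coefficients")
    m0 = _reference_m0(fit.mu0, fit.gamma_ic, fit.ic_center, ic_reference)
    return float(m_to_beta(m0 + fit.delta_m) - m_to_beta(m0))


def _reference_m0(mu0, gamma, ic_center, ic_reference):
    if ic_reference == "zero":
        return mu0 + gamma * (0.0 - ic_center)
    if ic_reference == "uninflamed-mean":
        return mu0
    raise ValueError(
        f"ic_reference must be 'zero' or 'uninflamed-mean', got {ic_reference!r}"
    )


def raw_delta_beta(betas_probe: pd.Series, sheet: pd.DataFrame) -> float:
    """Unadjusted effect size: mean beta(inflamed) - mean beta(uninflamed)."""
    sheet = sheet.loc[betas_probe.index]
    groups = betas_probe.groupby(sheet["status"])
    means = groups.mean()
    for lab in (UNINFLAMED, INFLAMED):
        if lab not in means.index or groups.size()[lab] == 0:
            raise ValueError(f"no samples with status {lab!r}")
    return float(means[INFLAMED] - means[UNINFLAMED])


def run_ewas(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    ic: pd.Series,
    manifest: pd.DataFrame | None = None,
    retained: pd.Index | None = None,
    engine: str = "fixed",
    batch_col: str = "slide",
    ic_reference: str = "zero",
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Genome-wide per-CpG association; returns the full DMP table.

    Columns: delta_m, se, p_full, q_full, raw_delta_beta, adj_delta_beta,
    n_used (+ chrom/pos when a manifest is given).  ``retained`` restricts
    the probes tested (e.g. after blacklist exclusion); BH q values are
    computed over exactly the tested set.
    """
    if engine not in ("fixed", "mixed"):
        raise ValueError(f"unknown engine {engine!r}")
    if retained is not None:
        betas = betas.loc[betas.index.intersection(retained)]
    sheet = sheet.loc[betas.columns]
    ic = ic.loc[betas.columns]
    M = beta_to_m(betas.to_numpy(), epsilon=epsilon)

    status, ic_c, ic_center, use_ic = _design_pieces(sheet, ic)
    n = len(sheet)

    if engine == "mixed":
        rows = []
        for i, pid in enumerate(betas.index):
            fit = fit_dmp(
                pd.Series(M[i], index=betas.columns, name=pid),
                sheet, ic, batch_col=batch_col, probe_id=pid,
            )
            rows.append(
                (fit.delta_m, fit.se, fit.p, fit.mu0, fit.gamma_ic)
            )
        delta, se, p, mu0, gamma = map(np.asarray, zip(*rows))
    else:
        cols = [np.ones(n), status]
        if use_ic:
            cols.append(ic_c)
        X = np.column_stack(cols + [_batch_dummies(sheet[batch_col])]) \
            if sheet[batch_col].nunique() > 1 else np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("status is confounded with batch (singular design)")
        coef, se_all, dof, _ = _ols(X, M)
        delta, se = coef[:, 1], se_all[:, 1]
        p = _wald_t_p(delta, se, dof)
        mu0 = coef[:, 0]
        gamma = coef[:, 2] if use_ic else np.zeros_like(delta)

    m0 = _reference_m0(mu0, gamma, ic_center, ic_reference)
    adj = m_to_beta(m0 + delta) - m_to_beta(m0)

    B = betas.to_numpy()
    raw = B[:, status == 1].mean(axis=1) - B[:, status == 0].mean(axis=1)

    out = pd.DataFrame(
        {
            "delta_m": delta,
            "se": se,
            "p_full": p,
            "q_full": bh_adjust(p),
            "raw_delta_beta": raw,
            "adj_delta_beta": adj,
            "n_used": n,
        },
        index=betas.index,
    )
    if manifest is not None:
        out = out.join(manifest[["chrom", "pos"]])
        out = out[["chrom", "pos"] + [c for c in out.columns if c not in ("chrom", "pos")]]
    return out


def paired_stage(
    stage1: pd.DataFrame,
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    ic: pd.Series,
    n_tests: int | None = None,
    q_threshold: float = 0.05,
    engine: str = "fixed",
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Refit stage-1 significant probes on the paired subset.

    Selection = probes with ``q_full < q_threshold`` in ``stage1``.  The
    paired subset is every subject with one sample of each status in
    ``sheet``; the model adds a per-subject intercept (random intercept for
    engine="mixed" via MixedLM grouped by subject; exact within-subject
    fixed-effect OLS for the default engine).  ``p_adj_paired`` is
    Bonferroni-corrected over ``n_tests`` (defaults to the stage-1
    selection size).  Returns p_paired and p_adj_paired per selected probe.
    """
    selected = stage1.index[stage1["q_full"] < q_threshold]
    if len(selected) == 0:
        return pd.DataFrame(columns=["p_paired", "p_adj_paired"])
    if n_tests is None:
        n_tests = len(selected)

    per_subject = sheet.groupby("subject")["status"].agg(set)
    paired = per_subject[per_subject == {UNINFLAMED, INFLAMED}].index
    if len(paired) < 3:
        raise ValueError(
            f"paired stage needs >= 3 paired subjects, found {len(paired)}"
        )
    psheet = sheet[sheet["subject"].isin(paired)]
    pbetas = betas.loc[selected, psheet.index]
    pic = ic.loc[psheet.index]
    M = beta_to_m(pbetas.to_numpy(), epsilon=epsilon)
    status, ic_c, _, use_ic = _design_pieces(psheet, pic)

    if engine == "mixed":
        import statsmodels.api as sm

        cols = [np.ones(len(psheet)), status]
        if use_ic:
            cols.append(ic_c)
        X = np.column_stack(cols)
        p = np.empty(len(selected))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(selected)):
                fit = sm.MixedLM(M[i], X, groups=psheet["subject"]).fit(reml=True)
                p[i] = 2 * stats.norm.sf(abs(fit.fe_params[1] / fit.bse_fe[1]))
    else:
        subj = pd.get_dummies(psheet["subject"], dtype=float).to_numpy()
        cols = [status]
        if use_ic:
            cols.append(ic_c)
        X = np.column_stack(cols + [subj])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("paired design is singular")
        coef, se_all, dof, _ = _ols(X, M)
        p = _wald_t_p(coef[:, 0], se_all[:, 0], dof)

    return pd.DataFrame(
        {"p_paired": p, "p_adj_paired": bonferroni_adjust(p, n_tests)},
        index=selected,
    )
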