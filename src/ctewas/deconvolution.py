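"""Reference-based cell-type deconvolution of bulk methylomes.

Each bulk sample's raw beta profile is modelled as a convex combination of
compartment centroid methylomes (epithelial, fibroblast, immune):

    beta_sample ~= C @ w,   w >= 0,  sum(w) = 1

Two solvers are provided.  "rpc" (robust partial correlations, the default)
regresses the sample betas on the centroids with iteratively reweighted
robust regression (Huber loss), truncates negative coefficients to zero and
renormalises to sum 1.  "nnls" solves the non-negative least-squares problem
directly and renormalises.  Both are deterministic given the inputs and
agree to numerical precision on noiseless mixtures.

Deconvolution runs on raw betas, not M-values: the mixture model is linear
on the beta scale only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .synthetic import CELL_TYPES, INFLAMED, UNINFLAMED, CellTypeReference

__all__ = ["estimate_fractions", "fraction_summary"]

MIN_SHARED_PROBES = 30
WARN_SHARED_PROBES = 100
HUBER_T = 1.345
RPC_MAX_ITER = 50
RPC_TOL = 1e-6


def _solve_rpc(centroids: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = sm.RLM(y, centroids, M=sm.robust.norms.HuberT(t=HUBER_T))
    fit = model.fit(maxiter=RPC_MAX_ITER, tol=RPC_TOL)
    return np.asarray(fit.params, dtype=float)

def _solve_nnls(centroids: np.ndarray, y: np.ndarray) -> np.ndarray:
    w, _ = optimize.nnls(centroids, y)
    return w


def estimate_fractions(
    betas: pd.DataFrame,
    reference: CellTypeReference,
    method: str = "rpc",
) -> pd.DataFrame:
    """Estimate per-sample (epi, fib, ic) fractions from raw betas.

    Parameters
    ----------
    betas
        Probes x samples beta matrix (raw scale).
    reference
        Compartment centroids; probes are intersected with ``betas`` by id.
    method
        "rpc" (robust regression, default) or "nnls".

    Returns
    -------
    DataFrame indexed by sample id with columns epi, fib, ic; rows are
    non-negative and sum to 1.
    """
    if method not in ("rpc", "nnls"):
        raise ValueError(f"unknown method {method!r}; expected 'rpc' or 'nnls'")
    shared = reference.probe_ids.intersection(betas.index)
    if len(shared) < MIN_SHARED_PROBES:
        raise ValueError(
            f"only {len(shared)} probes shared between matrix and reference; "
            f"need >= {MIN_SHARED_PROBES}"
        )
    if len(shared) < WARN_SHARED_PROBES:
        warnings.warn(
            f"only {len(shared)} shared probes; fraction estimates may be "
            "unstable below 100",
            stacklevel=2,
        )
    C = reference.centroids.loc[shared, list(CELL_TYPES)].to_numpy()
    Y = betas.loc[shared].to_numpy()
    solve = _solve_rpc if method == "rpc" else _solve_nnls

    out = np.empty((betas.shape[1], len(CELL_TYPES)))
    for j, sample in enumerate(betas.columns):
        y = Y[:, j]
        if np.ptp(y) == 0:
            raise ValueError(
                f"sample {sample!r} has a constant beta vector; cannot deconvolve"
            )
        w = np.clip(solve(C, y), 0.0, None)
        total = w.sum()
        if total == 0:
            raise ValueError(
                f"sample {sample!r}: all fraction coefficients truncated to 0"
            )
        out[j] = w / total
    return pd.DataFrame(out, index=betas.columns, columns=list(CELL_TYPES))


def fraction_summary(fractions: pd.DataFrame, sheet: pd.DataFrame) -> dict:
    """Per-status fraction moments, Epi–IC correlation, paired Wilcoxon.

    Returns a dict with ``by_status`` (DataFrame of mean/sd per cell type),
    ``epi_ic_pearson_r``, and — when subjects with both biopsies exist —
    ``wilcoxon_p`` from a Wilcoxon signed-rank test of IC(inflamed) vs
    IC(uninflamed) over paired subjects, with ``wilcoxon_n_pairs`` and
    ``wilcoxon_variant`` recording what ran.
    """
    if not fractions.index.isin(sheet.index).all():
        raise ValueError("fractions and sample sheet must share sample ids")
    sheet = sheet.loc[fractions.index]
    joined = fractions.join(sheet[["subject", "status"]])

    by_status = joined.groupby("status")[list(CELL_TYPES)].agg(["mean", "std"])
    r = float(np.corrcoef(fractions["epi"], fractions["ic"])[0, 1])
    summary: dict = {"by_status": by_status, "epi_ic_pearson_r": r}

    wide = joined.pivot_table(index="subject", columns="status", values="ic")
    if UNINFLAMED in wide.columns and INFLAMED in wide.columns:
        pairs = wide.dropna()
    else:
        pairs = wide.iloc[0:0]
    if len(pairs) == 0:
        warnings.warn("no paired subjects; Wilcoxon test omitted", stacklevel=2)
        summary["wilcoxon_p"] = None
        summary["wilcoxon_n_pairs"] = 0
        summary["wilcoxon_variant"] = "omitted (no pairs)"
        return summary
    diffs = pairs[INFLAMED] - pairs[UNINFLAMED]
    if np.allclose(diffs, 0):
        # zero-variance convention: no evidence against symmetry
        summary["wilcoxon_p"] = 1.0
    else:
        summary["wilcoxon_p"] = float(
            stats.wilcoxon(pairs[INFLAMED], pairs[UNINFLAMED]).pvalue
        )
    summary["wilcoxon_n_pairs"] = int(len(pairs))
    summary["wilcoxon_variant"] = "paired signed-rank"
    return summary
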