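"""Immune-fraction sample gating and MDS diagnostics.

Bulk biopsies whose estimated immune-cell (IC) fraction contradicts their
clinical label are removed before association testing: clinically
uninflamed samples are kept only when IC <= 0.35 and inflamed samples only
when IC >= 0.40 (both boundaries inclusive).  Subjects whose two biopsies
both survive form the paired subset used by the second analysis stage.

Classical metric MDS (principal-coordinates analysis) over the most
variable probes provides the standard visual check that samples separate
by immune content rather than by technical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .synthetic import INFLAMED, UNINFLAMED

__all__ = ["GatingResult", "apply_ic_thresholds", "mds_embedding"]


@dataclass(frozen=True)
class GatingResult:
    """Outcome of immune-fraction gating.

    ``included``/``excluded``: per-sample tables with status, ic and (for
    exclusions) a reason code; ``paired_subjects``: subjects contributing
    one retained sample per status.
    """

    included: pd.DataFrame
    excluded: pd.DataFrame
    paired_subjects: tuple

    @property
    def included_ids(self) -> pd.Index:
        return self.included.index

    def counts(self) -> dict:
        by = self.included["status"].value_counts()
        return {
            "n_included_uninflamed": int(by.get(UNINFLAMED, 0)),
            "n_included_inflamed": int(by.get(INFLAMED, 0)),
            "n_excluded": int(len(self.excluded)),
            "n_paired_subjects": len(self.paired_subjects),
        }


def apply_ic_thresholds(
    fractions: pd.DataFrame,
    sheet: pd.DataFrame,
    uninflamed_max: float = 0.35,
    inflamed_min: float = 0.40,
) -> GatingResult:
    """Gate samples on their immune fraction, inclusively at both bounds.

    Uninflamed samples are retained iff ic <= ``uninflamed_max``; inflamed
    samples iff ic >= ``inflamed_min``.  Exclusion reasons are recorded
    ("ic_above_max" / "ic_below_min").
    """
    if not fractions.index.isin(sheet.index).all():
        raise ValueError("every fraction row needs a sample-sheet entry")
    sheet = sheet.loc[fractions.index]
    unknown = set(sheet["status"]) - {UNINFLAMED, INFLAMED}
    if unknown:
        raise ValueError(f"unknown status label(s): {sorted(unknown)}")

    table = sheet[["subject", "status"]].copy()
    table["ic"] = fractions["ic"]
    is_uninfl = table["status"] == UNINFLAMED
    keep = np.where(
        is_uninfl, table["ic"] <= uninflamed_max, table["ic"] >= inflamed_min
    )
    excluded = table.loc[~keep].copy()
    excluded["reason"] = np.where(
        excluded["status"] == UNINFLAMED, "ic_above_max", "ic_below_min"
    )
    included = table.loc[keep].copy()

    per_subject = included.groupby("subject")["status"].agg(lambda s: set(s))
    paired = tuple(
        sorted(per_subject[per_subject == {UNINFLAMED, INFLAMED}].index)
    )
    return GatingResult(included=included, excluded=excluded, paired_subjects=paired)


def mds_embedding(
    betas: pd.DataFrame, n_top: int = 1000, n_dims: int = 2
) -> pd.DataFrame:
    """Classical metric MDS (PCoA) of samples over the most variable probes.

    Euclidean distances are computed over the ``n_top`` probes with the
    largest beta variance across samples; the Gower-centred distance matrix
    is eigendecomposed and the top ``n_dims`` coordinates returned.  Axis
    signs are fixed by making the first sample's coordinate non-negative in
    every dimension, so the embedding is fully deterministic.
    """
    if betas.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    if n_top > betas.shape[0]:
        warnings.warn(
            f"n_top={n_top} exceeds the {betas.shape[0]} available probes; "
            "using all probes",
            stacklevel=2,
        )
        n_top = betas.shape[0]
    variances = betas.var(axis=1).to_numpy()
    top = np.argsort(variances)[::-1][:n_top]
    X = betas.to_numpy()[top].T  # samples x probes

    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    np.maximum(d2, 0, out=d2)
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:n_dims]
    lams = np.clip(eigvals[order], 0, None)
    # degenerate axes (numerically zero eigenvalues) carry no signal
    lams[lams < max(lams.max(), 0.0) * 1e-12] = 0.0
    coords = eigvecs[:, order] * np.sqrt(lams)
    flip = np.where(coords[0] < 0, -1.0, 1.0)
    coords = coords * flip
    return pd.DataFrame(
        coords, index=betas.columns, columns=[f"dim{k + 1}" for k in range(n_dims)]
    )
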