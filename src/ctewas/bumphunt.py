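"""Bump-hunting detection of differentially methylated regions.

Per-probe inflammation coefficients on the beta scale (group difference
adjusted for immune content by linear regression) are smoothed with a
running mean inside pre-computed probe clusters; maximal sign-consistent
runs of smoothed coefficients beyond a cutoff become candidate regions.
Significance comes from permutation, Freedman–Lane style: because the
status coefficient is estimated jointly with the immune-content covariate,
naively permuting inflammation labels would break the status–IC
collinearity of the observed design and produce an anti-conservatively
narrow null (the variance of the adjusted coefficient grows with that
collinearity).  Instead the residuals of the status-free null model
(beta ~ 1 + IC) are permuted — within-subject swaps for paired subjects,
free permutation among unpaired samples, so the paired design's
exchangeability is respected — and projected onto the observed design's
status contrast, which is algebraically identical to re-running the full
regression on the reconstructed null response.  Each observed region's
area (sum of |smoothed coefficient|) is compared against the pooled null
areas (per-region p) and against the per-permutation maximum area
(family-wise error rate).  Add-one counting keeps p values off zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse

from .synthetic import INFLAMED, UNINFLAMED

__all__ = [
    "make_probe_clusters",
    "compute_coefficients",
    "find_bumps",
    "permutation_fwer",
    "find_dmrs",
]

DEFAULT_CLUSTER_GAP = 500
DEFAULT_CUTOFF = 0.02
DEFAULT_SMOOTH_SPAN = 3


def make_probe_clusters(
    manifest: pd.DataFrame, cluster_gap: int = DEFAULT_CLUSTER_GAP
) -> pd.Series:
    """Chain *all* analysed probes into clusters (gap <= cluster_gap).

    Same single-linkage rule as DMP clustering, but over the full manifest:
    this is the pre-smoothing grouping bump hunting operates within.
    Returns integer cluster ids in manifest order.
    """
    ids = np.empty(len(manifest), dtype=np.int64)
    k = 0
    for _, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            raise ValueError("manifest must be position-sorted within chromosome")
        new = np.ones(len(grp), dtype=bool)
        if np.isfinite(cluster_gap):
            new[1:] = np.diff(pos) > cluster_gap
        else:
            new[1:] = False
        loc = manifest.index.get_indexer(grp.index)
        ids[loc] = k + np.cumsum(new)
        k = ids[loc].max()
    return pd.Series(ids, index=manifest.index, name="cluster")


def _design(status: np.ndarray, ic: np.ndarray) -> np.ndarray:
    cols = [np.ones(status.size), status]
    ic_c = ic - ic.mean()
    if ic_c.std() > 1e-12:
        cols.append(ic_c)
    return np.column_stack(cols)


def compute_coefficients(
    B: np.ndarray, status: np.ndarray, ic: np.ndarray
) -> np.ndarray:
    """IC-adjusted beta-scale status coefficient per probe (vectorised OLS)."""
    X = _design(status, ic)
    H = X @ np.linalg.inv(X.T @ X)
    return B @ H[:, 1]


def smoothing_matrix(
    clusters: np.ndarray, smooth_span: int = DEFAULT_SMOOTH_SPAN
) -> sparse.csr_matrix:
    """Sparse running-mean operator respecting cluster boundaries.

    Probes in clusters with fewer than ``smooth_span`` members pass through
    unsmoothed; elsewhere each probe is averaged with its in-cluster
    neighbours inside a centred window of ``smooth_span`` probes (truncated
    at cluster edges, hence the documented edge attenuation of region
    areas).  The operator is linear, so doubling all coefficients exactly
    doubles all smoothed values and areas.
    """
    n = clusters.size
    half = smooth_span // 2
    rows, cols, vals = [], [], []
    start = 0
    while start < n:
        end = start
        while end < n and clusters[end] == clusters[start]:
            end += 1
        size = end - start
        if size < smooth_span:
            for i in range(start, end):
                rows.append(i); cols.append(i); vals.append(1.0)
        else:
            for i in range(start, end):
                lo = max(start, i - half)
                hi = min(end, i + half + 1)
                w = 1.0 / (hi - lo)
                for j in range(lo, hi):
                    rows.append(i); cols.append(j); vals.append(w)
        start = end
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _runs(smoothed: np.ndarray, clusters: np.ndarray, cutoff: float):
    """Maximal sign-consistent runs beyond +-cutoff, not crossing clusters.

    Returns (starts, ends, areas, values, signs); starts/ends are inclusive
    index pairs into the probe order.
    """
    n = smoothed.size
    break_before = np.ones(n, dtype=bool)
    break_before[1:] = clusters[1:] != clusters[:-1]
    break_after = np.ones(n, dtype=bool)
    break_after[:-1] = break_before[1:]

    all_starts, all_ends, all_signs = [], [], []
    for sign in (1.0, -1.0):
        mask = smoothed * sign > cutoff
        if not mask.any():
            continue
        prev = np.concatenate(([False], mask[:-1]))
        nxt = np.concatenate((mask[1:], [False]))
        starts = np.flatnonzero(mask & (~prev | break_before))
        ends = np.flatnonzero(mask & (~nxt | break_after))
        all_starts.append(starts)
        all_ends.append(ends)
        all_signs.append(np.full(starts.size, sign))
    if not all_starts:
        empty_i = np.array([], dtype=int)
        empty_f = np.array([], dtype=float)
        return empty_i, empty_i, empty_f, empty_f, empty_f
    starts = np.concatenate(all_starts)
    ends = np.concatenate(all_ends)
    signs = np.concatenate(all_signs)
    areas = np.array(
        [np.abs(smoothed[s : e + 1]).sum() for s, e in zip(starts, ends)]
    )
    values = np.array(
        [smoothed[s : e + 1].mean() for s, e in zip(starts, ends)]
    )
    return starts, ends, areas, values, signs


def find_bumps(
    coefficients: pd.Series,
    clusters: pd.Series,
    manifest: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    smooth_span: int = DEFAULT_SMOOTH_SPAN,
) -> pd.DataFrame:
    """Extract candidate regions from per-probe coefficients.

    ``coefficients`` and ``clusters`` are indexed like ``manifest`` (which
    must be position-sorted within chromosome).  Returns one row per
    candidate with chrom, start/end (bp of first/last probe), n_probes,
    value (mean smoothed coefficient), area (sum |smoothed coefficient|)
    and the probe-order indices of the run.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cl = clusters.to_numpy()
    S = smoothing_matrix(cl, smooth_span)
    sm = S @ coefficients.to_numpy()
    starts, ends, areas, values, signs = _runs(sm, cl, cutoff)
    pos = manifest["pos"].to_numpy()
    chrom = manifest["chrom"].to_numpy()
    return pd.DataFrame(
        {
            "chrom": chrom[starts] if starts.size else np.array([], dtype=object),
            "start": pos[starts] if starts.size else np.array([], dtype=int),
            "end": pos[ends] if ends.size else np.array([], dtype=int),
            "n_probes": (ends - starts + 1) if starts.size else np.array([], dtype=int),
            "value": values,
            "area": areas,
            "sign": signs,
            "first_idx": starts,
            "last_idx": ends,
        }
    )


def _permute_indices(
    status: np.ndarray, subjects: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One sample-index permutation respecting pairing.

    Paired subjects' residual pairs travel as units: the pairs are permuted
    among the pair slots and each lands with its two members in original or
    swapped order (probability 1/2).  Positions of unpaired samples are
    permuted freely among themselves.  The group is valid when errors are
    exchangeable across subjects and within pairs — in particular it
    remains valid when the two samples of a subject are correlated, which
    a fully free permutation would not be.
    """
    perm = np.arange(status.size)
    pairs = []
    unpaired_mask = np.ones(status.size, dtype=bool)
    for subj in pd.unique(subjects):
        idx = np.flatnonzero(subjects == subj)
        if idx.size == 2 and status[idx[0]] != status[idx[1]]:
            unpaired_mask[idx] = False
            # order as (uninflamed slot, inflamed slot)
            pairs.append(idx if status[idx[0]] == 0 else idx[::-1])
    if pairs:
        pairs_arr = np.asarray(pairs)
        source = pairs_arr[rng.permutation(len(pairs))]
        flip = rng.random(len(pairs)) < 0.5
        source[flip] = source[flip, ::-1]
        perm[pairs_arr.ravel()] = source.ravel()
    idx = np.flatnonzero(unpaired_mask)
    if idx.size:
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def permutation_fwer(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    ic: pd.Series,
    candidates: pd.DataFrame,
    clusters: pd.Series,
    B: int = 1000,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    smooth_span: int = DEFAULT_SMOOTH_SPAN,
) -> pd.DataFrame:
    """Attach permutation p values and FWER to candidate regions.

    The null is generated by permuting the residuals of the status-free
    model (beta ~ 1 + IC) over samples (within-subject swaps for pairs,
    free shuffling of unpaired samples) and projecting them onto the
    status contrast of the observed design — the Freedman–Lane scheme,
    which keeps the status–IC collinearity of the design intact.  p_perm
    compares each observed area with the pooled null areas across all
    permutations; fwer compares it with each permutation's maximum area.
    Both use add-one counting, so the smallest attainable fwer with B
    permutations is 1 / (B + 1).  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(
            f"B={B} permutations give coarse FWER resolution (floor {1/(B+1):.3g})",
            stacklevel=2,
        )
    sheet = sheet.loc[betas.columns]
    status = (sheet["status"] == INFLAMED).to_numpy(float)
    subjects = sheet["subject"].to_numpy()
    icv = ic.loc[betas.columns].to_numpy(float)
    Bmat = betas.to_numpy()
    cl = clusters.to_numpy()
    S = smoothing_matrix(cl, smooth_span)

    # status contrast of the observed design; orthogonal to [1, IC], so the
    # null-model fitted values drop out and permuted-residual projection
    # equals the full refit on the reconstructed null response
    X = _design(status, icv)
    h = (X @ np.linalg.inv(X.T @ X))[:, 1]
    Xnull = np.delete(X, 1, axis=1)
    Pnull = Xnull @ np.linalg.inv(Xnull.T @ Xnull) @ Xnull.T
    R = Bmat - Bmat @ Pnull.T  # residuals of beta ~ 1 + IC, per probe

    rng = np.random.default_rng(seed)
    null_areas = []
    max_areas = np.zeros(B)
    for b in range(B):
        perm = _permute_indices(status, subjects, rng)
        coef = R[:, perm] @ h
        sm = S @ coef
        _, _, areas, _, _ = _runs(sm, cl, cutoff)
        if areas.size:
            null_areas.append(areas)
            max_areas[b] = areas.max()
    pooled = np.concatenate(null_areas) if null_areas else np.array([])

    obs = candidates["area"].to_numpy()
    p_perm = np.array(
        [(1 + np.sum(pooled >= a)) / (1 + pooled.size) for a in obs]
    )
    fwer = np.array([(1 + np.sum(max_areas >= a)) / (1 + B) for a in obs])
    out = candidates.copy()
    out["p_perm"] = p_perm
    out["fwer"] = fwer
    return out


def find_dmrs(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    ic: pd.Series,
    manifest: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
    smooth_span: int = DEFAULT_SMOOTH_SPAN,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end DMR detection on a beta matrix."""
    manifest = manifest.loc[betas.index]
    sheet = sheet.loc[betas.columns]
    status = (sheet["status"] == INFLAMED).to_numpy(float)
    if set(sheet["status"]) - {UNINFLAMED, INFLAMED}:
        raise ValueError("unknown status labels")
    icv = ic.loc[betas.columns].to_numpy(float)
    clusters = make_probe_clusters(manifest, cluster_gap)
    coef = pd.Series(
        compute_coefficients(betas.to_numpy(), status, icv), index=betas.index
    )
    candidates = find_bumps(coef, clusters, manifest, cutoff, smooth_span)
    if len(candidates) == 0 or B == 0:
        candidates["p_perm"] = np.nan
        candidates["fwer"] = np.nan
        return candidates
    return permutation_fwer(
        betas, sheet, ic, candidates, clusters, B=B, seed=seed,
        cutoff=cutoff, smooth_span=smooth_span,
    )
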