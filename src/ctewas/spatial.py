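"""Spatial post-processing of significant DMPs.

CpG methylation is spatially correlated on the kb scale, so isolated
significant positions are more likely to be noise than members of
co-methylated clusters.  This module chains stage-1 significant DMPs into
clusters (single linkage along each chromosome, gap <= 2 kb inclusive) and
applies the three-criterion stringent filter: a cluster is kept when it has
(1) >= 2 members, (2) at least one member with |adjusted delta-beta| above
the effect threshold, and (3) at least one member significant in the paired
stage.  All members of a kept cluster are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "cluster_dmps",
    "stringent_filter",
    "nearest_significant_distance",
    "supporting_dmp_counts",
]


def cluster_dmps(dmps: pd.DataFrame, max_gap: int = 2000) -> pd.Series:
    """Assign cluster ids by single-linkage chaining along each chromosome.

    ``dmps`` needs chrom/pos columns; input order is irrelevant (sorted
    internally), duplicate positions land in the same cluster, and a new
    cluster starts when the gap to the previous DMP exceeds ``max_gap``
    (boundary inclusive: exactly ``max_gap`` bp chains).  Returns a Series
    of cluster ids ("<chrom>_c<k>") indexed like ``dmps``; singletons are
    clusters of size 1.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ids = pd.Series(index=dmps.index, dtype=object)
    for chrom, grp in dmps.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        new_cluster = np.ones(len(grp), dtype=bool)
        new_cluster[1:] = np.diff(pos) > max_gap
        k = np.cumsum(new_cluster)
        ids.loc[grp.index] = [f"{chrom}_c{i}" for i in k]
    return ids


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping from the stringent filter."""

    n_clusters_pre: int
    n_clusters_kept: int
    n_dmps_pre: int
    n_dmps_retained: int
    failed: pd.DataFrame  # cluster_id -> reason


def stringent_filter(
    dmps: pd.DataFrame,
    cluster_ids: pd.Series,
    min_effect: float = 0.1,
    paired_alpha: float = 0.05,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three-criterion cluster filter to significant DMPs.

    ``dmps`` must carry ``adj_delta_beta`` and ``p_adj_paired`` (NaN when a
    probe was absent from the paired stage — such members cannot satisfy
    criterion 3).  Returns (retained DMPs with a cluster_id column, report).
    """
    df = dmps.copy()
    df["cluster_id"] = cluster_ids
    reasons = {}
    kept_clusters = []
    for cid, grp in df.groupby("cluster_id", sort=False):
        if len(grp) < 2:
            reasons[cid] = "fewer_than_2_members"
        elif not (grp["adj_delta_beta"].abs() > min_effect).any():
            reasons[cid] = "no_member_above_effect_threshold"
        elif not (grp["p_adj_paired"].dropna() < paired_alpha).any():
            reasons[cid] = "no_member_paired_significant"
        else:
            kept_clusters.append(cid)
    retained = df[df["cluster_id"].isin(kept_clusters)]
    report = FilterReport(
        n_clusters_pre=int(df["cluster_id"].nunique()),
        n_clusters_kept=len(kept_clusters),
        n_dmps_pre=len(df),
        n_dmps_retained=len(retained),
        failed=pd.DataFrame(
            {"reason": pd.Series(reasons, dtype=object)}
        ).rename_axis("cluster_id"),
    )
    return retained, report


def nearest_significant_distance(dmps: pd.DataFrame) -> pd.Series:
    """Per DMP, bp distance to the nearest other significant DMP.

    Same-chromosome neighbours only; a DMP alone on its chromosome reports
    NaN.  ``dmps`` needs chrom/pos columns and should already be the
    significant set.
    """
    out = pd.Series(np.nan, index=dmps.index)
    for _, grp in dmps.groupby("chrom", sort=False):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy(float)
        gaps = np.diff(pos)
        nearest = np.empty(len(pos))
        nearest[0] = gaps[0]
        nearest[-1] = gaps[-1]
        if len(pos) > 2:
            nearest[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        out.loc[grp.index] = nearest
    return out


def supporting_dmp_counts(cluster_ids: pd.Series) -> pd.Series:
    """Co-members per DMP: cluster size minus one (the index DMP itself)."""
    sizes = cluster_ids.map(cluster_ids.value_counts())
    return (sizes - 1).astype(int)
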