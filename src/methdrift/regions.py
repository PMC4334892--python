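"""Regional probe classification and bounded clustering.

Probes are assigned to one of three regional classes by distance to the
nearest CpG island (inside an island -> ``island``; within 4 kb of an
island edge -> ``shore_shelf``, merging the conventional 2 kb shores and
2 kb shelves; beyond -> ``open_sea``).  Within each class, spatially
close probes are collapsed greedily into clusters bounded by a maximum
inter-probe gap and a maximum cluster width; the mean beta value of a
cluster is the unit of all downstream statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ISLAND = "island"
SHORE_SHELF = "shore_shelf"
OPEN_SEA = "open_sea"

REGION_CLASSES = (ISLAND, SHORE_SHELF, OPEN_SEA)

#: distance-to-island thresholds (bp): 0 -> island, <=2000 shore,
#: <=4000 shelf; shores and shelves are merged into one class.
SHORE_BP = 2000
SHELF_BP = 4000


def classify_probes(probes: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    """Assign each probe a regional class by distance to the nearest island.

    Parameters
    ----------
    probes
        DataFrame with columns ``probe_id``, ``chrom``, ``pos`` (1-based bp).
    islands
        DataFrame with columns ``chrom``, ``start``, ``end`` giving CpG
        islands as 1-based inclusive intervals, non-overlapping within
        each chromosome.

    Returns
    -------
    DataFrame
        Copy of ``probes`` with an added ``region_class`` column.
    """
    probes = probes.copy()
    classes = np.empty(len(probes), dtype=object)
    classes[:] = OPEN_SEA

    isl_by_chrom = {c: g.sort_values("start") for c, g in islands.groupby("chrom")}
    for chrom, grp in probes.groupby("chrom"):
        isl = isl_by_chrom.get(chrom)
        if isl is None:
            logger.warning(
                "chromosome %s absent from island track; probes classified open_sea",
                chrom,
            )
            continue
        starts = isl["start"].to_numpy()
        ends = isl["end"].to_numpy()
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"islands overlap on {chrom}")
        pos = grp["pos"].to_numpy()
        dist = _distance_to_intervals(pos, starts, ends)
        cls = np.where(dist == 0, ISLAND, np.where(dist <= SHELF_BP, SHORE_SHELF, OPEN_SEA))
        classes[probes.index.get_indexer(grp.index)] = cls

    probes["region_class"] = pd.Categorical(classes, categories=list(REGION_CLASSES))
    return probes


def _distance_to_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest [start, end] interval (0 if inside)."""
    # nearest interval is either the one ending before pos or starting after
    idx = np.searchsorted(starts, pos, side="right")  # intervals with start <= pos
    dist = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
    has_left = idx > 0
    left = np.clip(idx - 1, 0, None)
    inside = has_left & (pos <= ends[left])
    d_left = np.where(has_left, pos - ends[left], np.iinfo(np.int64).max)
    has_right = idx < len(starts)
    right = np.clip(idx, None, len(starts) - 1)
    d_right = np.where(has_right, starts[right] - pos, np.iinfo(np.int64).max)
    dist = np.minimum(np.abs(d_left), np.abs(d_right))
    dist[inside] = 0
    return dist


def bounded_cluster(
    positions: np.ndarray, max_gap: int = 500, max_width: int = 1500
) -> np.ndarray:
    """Greedy left-to-right bounded clustering of sorted positions.

    A probe extends the current cluster iff its gap to the previous probe
    is <= ``max_gap`` AND the width from the cluster's first probe is
    <= ``max_width``; otherwise it opens a new cluster.

    Parameters
    ----------
    positions
        Sorted 1-based bp positions on one chromosome, one region class.

    Returns
    -------
    ndarray of int
        0-based cluster index per probe.
    """
    positions = np.asarray(positions)
    if positions.ndim != 1:
        raise ValueError("positions must be 1-D")
    if len(positions) == 0:
        return np.array([], dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    ids = np.empty(len(positions), dtype=np.int64)
    ids[0] = 0
    start = positions[0]
    for i in range(1, len(positions)):
        gap = positions[i] - positions[i - 1]
        width = positions[i] - start
        if gap <= max_gap and width <= max_width:
            ids[i] = ids[i - 1]
        else:
            ids[i] = ids[i - 1] + 1
            start = positions[i]
    return ids


def make_clusters(
    annotation: pd.DataFrame, max_gap: int = 500, max_width: int = 1500
) -> pd.DataFrame:
    """Build region clusters from a classified probe annotation.

    Clustering is done per (chromosome, region class); probes of
    different classes are never merged.

    Returns
    -------
    DataFrame
        One row per cluster with columns ``cluster_id``, ``chrom``,
        ``start``, ``end`` (1-based inclusive), ``region_class``,
        ``n_probes``, ``probe_ids`` (list).
    """
    rows = []
    chroms = sorted(annotation["chrom"].unique())
    for chrom in chroms:
        sub_c = annotation[annotation["chrom"] == chrom]
        for cls in REGION_CLASSES:
            sub = sub_c[sub_c["region_class"] == cls].sort_values("pos")
            if len(sub) == 0:
                continue
            ids = bounded_cluster(sub["pos"].to_numpy(), max_gap, max_width)
            for k in range(ids.max() + 1):
                members = sub.iloc[np.flatnonzero(ids == k)]
                rows.append(
                    {
                        "cluster_id": f"{chrom}:{cls}:{members['pos'].iloc[0]}",
                        "chrom": chrom,
                        "start": int(members["pos"].iloc[0]),
                        "end": int(members["pos"].iloc[-1]),
                        "region_class": cls,
                        "n_probes": len(members),
                        "probe_ids": list(members["probe_id"]),
                    }
                )
    clusters = pd.DataFrame(rows)
    return clusters


def summarize_clusters(betas: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Average probe-level beta values within each cluster.

    Parameters
    ----------
    betas
        Probe-level matrix, index = probe_id, columns = sample ids.
    clusters
        Output of :func:`make_clusters`.

    Returns
    -------
    DataFrame
        Cluster-level matrix (index = cluster_id) where each value is
        the arithmetic mean of member-probe betas for that sample.
    """
    missing = set()
    for pids in clusters["probe_ids"]:
        missing.update(p for p in pids if p not in betas.index)
    if missing:
        raise KeyError(f"probes missing from beta matrix: {sorted(missing)[:5]} ...")

    probe_to_cluster = {}
    for cid, pids in zip(clusters["cluster_id"], clusters["probe_ids"]):
        for p in pids:
            probe_to_cluster[p] = cid
    grouping = betas.index.map(probe_to_cluster)
    out = betas.groupby(grouping).mean()
    out.index.name = "cluster_id"
    # keep the cluster table's ordering
    return out.loc[clusters["cluster_id"]]


def islands_from_bed(bed: pd.DataFrame) -> pd.DataFrame:
    """Convert a 0-based half-open BED island track to 1-based inclusive."""
    out = pd.DataFrame(
        {
            "chrom": bed.iloc[:, 0],
            "start": bed.iloc[:, 1].astype(int) + 1,
            "end": bed.iloc[:, 2].astype(int),
        }
    )
    return out
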