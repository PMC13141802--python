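"""Localization of the strongest condition contrasts via DBSCAN.

The voxels carrying the top 1% of BI-minus-NBI power differences (cerebellum
excluded) are clustered with DBSCAN: search radius eps = 0.75 cm, i.e. 1.5x
the 0.5 cm grid spacing, and a minimum of five voxels per cluster.  On a
0.5 cm lattice that radius connects face (0.5 cm) and edge (~0.707 cm)
neighbors but not cube-diagonal ones (~0.866 cm).  Clusters are then mapped
to anatomical region labels via a user-supplied atlas table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

NOISE = -1


@dataclass(frozen=True)
class DbscanParams:
    eps: float = 0.75  # cm; 1.5 x the 0.5 cm grid spacing
    min_pts: int = 5

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


def select_top_voxels(
    diff: np.ndarray,
    pct: float = 1.0,
    direction: str = "positive",
    cerebellum_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel ids of the top ``pct`` percent condition differences.

    ``direction="positive"`` ranks by the difference itself (up-modulations),
    ``"negative"`` by its negation (down-modulations), ``"abs"`` by magnitude.
    Cerebellar voxels are excluded before ranking; k = ceil(pct/100 * n
    eligible); ties at the cutoff break by ascending voxel id.
    """
    diff = np.asarray(diff, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("difference map contains non-finite values")
    if not 0 < pct <= 100:
        raise ValueError("pct must lie in (0, 100]")
    eligible = np.arange(diff.size)
    if cerebellum_mask is not None:
        eligible = eligible[~np.asarray(cerebellum_mask, dtype=bool)]
    if eligible.size == 0:
        raise ValueError("no voxels remain after cerebellum exclusion")
    score = {"positive": diff, "negative": -diff, "abs": np.abs(diff)}.get(direction)
    if score is None:
        raise ValueError("direction must be 'positive', 'negative' or 'abs'")
    k = int(np.ceil(pct / 100.0 * eligible.size))
    # sort by descending score, ascending voxel id on ties
    order = np.lexsort((eligible, -score[eligible]))
    return np.sort(eligible[order[:k]])


def dbscan(points: np.ndarray, params: DbscanParams = DbscanParams()) -> np.ndarray:
    """Classic DBSCAN; returns a label per point (-1 = noise).

    A point is a core point iff its eps-ball, itself included, holds at least
    ``min_pts`` points.  Clusters are the maximal density-reachable sets.
    Core membership is order-invariant; a border point reachable from several
    clusters joins the one whose expansion reaches it first in the ascending-id
    scan (deterministic).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    labels = np.full(n, NOISE, dtype=np.int64)
    if n == 0:
        return labels
    if len(np.unique(points, axis=0)) != n:
        raise ValueError("points must be distinct")
    tree = cKDTree(points)
    neighborhoods = tree.query_ball_point(points, r=params.eps * (1 + 1e-12))
    neighborhoods = [np.sort(nb) for nb in neighborhoods]
    core = np.array([len(nb) >= params.min_pts for nb in neighborhoods])
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cluster
        frontier = list(neighborhoods[i])
        while frontier:
            j = frontier.pop(0)
            if labels[j] == NOISE:
                labels[j] = cluster
                if core[j]:
                    frontier.extend(k for k in neighborhoods[j] if labels[k] == NOISE)
        cluster += 1
    return labels


@dataclass
class LabeledCluster:
    """A DBSCAN cluster with its anatomical label tally."""

    cluster_id: int
    voxel_ids: np.ndarray
    region_counts: list  # (region, count), count descending


def label_clusters(
    labels: np.ndarray, voxel_ids: np.ndarray, atlas: pd.DataFrame
) -> list:
    """Map each cluster's voxels to atlas regions.

    ``atlas`` needs columns voxel_id and region_label; voxels absent from the
    atlas are tallied as "unlabeled", never dropped.
    """
    if not {"voxel_id", "region_label"} <= set(atlas.columns):
        raise ValueError("atlas needs voxel_id and region_label columns")
    region = dict(zip(atlas["voxel_id"].to_numpy(), atlas["region_label"]))
    out = []
    for c in sorted(set(labels) - {NOISE}):
        members = np.asarray(voxel_ids)[labels == c]
        tally: dict[str, int] = {}
        for v in members:
            name = region.get(int(v), "unlabeled")
            tally[name] = tally.get(name, 0) + 1
        counts = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append(LabeledCluster(int(c), members, counts))
    return out


def localize(
    diff: np.ndarray,
    coords: np.ndarray,
    atlas: pd.DataFrame,
    pct: float = 1.0,
    direction: str = "positive",
    params: DbscanParams = DbscanParams(),
) -> tuple[list, np.ndarray, np.ndarray]:
    """Full localization step: top-percent selection, DBSCAN, atlas labels.

    ``atlas`` may carry an is_cerebellum column used for the exclusion.
    Returns (labeled clusters, selected voxel ids, DBSCAN labels).
    """
    mask = None
    if "is_cerebellum" in atlas.columns:
        mask = np.zeros(diff.size, dtype=bool)
        cere = atlas.loc[atlas["is_cerebellum"].astype(bool), "voxel_id"].to_numpy()
        mask[cere] = True
    selected = select_top_voxels(diff, pct, direction, mask)
    labels = dbscan(coords[selected], params)
    return label_clusters(labels, selected, atlas), selected, labels


def read_atlas_tsv(path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    if "voxel_id" not in atlas.columns:
        raise ValueError("atlas TSV must have a voxel_id column")
    return atlas
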