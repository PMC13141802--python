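"""Cluster-based permutation test (CBPT) for paired voxel-wise power contrasts.

Within a group, BI and NBI source power are compared voxel-by-voxel with a
dependent-samples t statistic.  Voxels whose |t| exceeds the cluster-forming
threshold are grouped into spatially connected clusters separately per sign;
each cluster's statistic is the sum of its members' t values (Tsum).  The
family-wise-corrected p value of a cluster comes from a sign-flip permutation
null: each permutation flips every subject's condition labels independently,
and the maximum |Tsum| over clusters of either sign is recorded.  With the
+1/+1 Monte-Carlo convention, p >= 1/(n_perm + 1) always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


@dataclass
class AdjacencyGraph:
    """Symmetric voxel neighborhood structure (no self edges).

    ``edges`` holds each undirected edge once as two aligned index arrays.
    """

    edges: tuple  # (u, v) int arrays
    coords: np.ndarray
    n_voxels: int

    def matrix(self) -> sparse.csr_matrix:
        u, v = self.edges
        i = np.concatenate([u, v])
        j = np.concatenate([v, u])
        return sparse.csr_matrix(
            (np.ones(i.size, dtype=bool), (i, j)), shape=(self.n_voxels, self.n_voxels)
        )

    def neighbor_sets(self) -> list:
        out = [set() for _ in range(self.n_voxels)]
        for a, b in zip(*self.edges):
            out[a].add(int(b))
            out[b].add(int(a))
        return out


def build_adjacency(coords: np.ndarray, rule: str = "lattice",
                    spacing: float | None = None, radius: float | None = None) -> AdjacencyGraph:
    """Neighborhood graph of grid voxels.

    rule="lattice": orthogonal 6-connectivity at the lattice spacing (inferred
    from the smallest nonzero coordinate gap if not given).
    rule="radius": neighbors iff Euclidean distance <= radius.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be (n_voxels, n_dims)")
    n = coords.shape[0]
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("duplicate voxel coordinates")
    if rule == "lattice":
        if spacing is None:
            diffs = np.diff(np.unique(coords.ravel()))
            diffs = diffs[diffs > 1e-12]
            spacing = float(diffs.min()) if diffs.size else 1.0
        pairs = cKDTree(coords).query_pairs(r=spacing * 1.0001, output_type="ndarray")
        if pairs.size:
            d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
            on_axis = (np.abs(d) > spacing * 0.5).sum(axis=1) == 1
            pairs = pairs[on_axis]
    elif rule == "radius":
        if radius is None:
            raise ValueError("radius rule requires a radius")
        pairs = cKDTree(coords).query_pairs(r=radius * (1 + 1e-12), output_type="ndarray")
    else:
        raise ValueError(f"unknown adjacency rule: {rule}")
    if pairs.size == 0:
        u = v = np.empty(0, dtype=np.int64)
    else:
        u, v = pairs[:, 0].astype(np.int64), pairs[:, 1].astype(np.int64)
    return AdjacencyGraph((u, v), coords, n)


def paired_t_map(power_bi: np.ndarray, power_nbi: np.ndarray) -> np.ndarray:
    """Dependent-samples t per voxel: mean(d) / (sd(d)/sqrt(n)), d = BI - NBI.

    Voxels with zero difference variance get t = 0 when the mean difference is
    also 0, else +/- inf.
    """
    power_bi = np.asarray(power_bi, dtype=float)
    power_nbi = np.asarray(power_nbi, dtype=float)
    if power_bi.shape != power_nbi.shape:
        raise ValueError("condition arrays must have equal shapes")
    n = power_bi.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a paired t map")
    d = power_bi - power_nbi
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0
    return t


@dataclass
class SignedCluster:
    """A connected set of same-sign suprathreshold voxels."""

    voxels: np.ndarray
    sign: int  # +1 or -1
    t_sum: float

    @property
    def size(self) -> int:
        return self.voxels.size


@dataclass
class CbptResult:
    clusters: list  # SignedCluster, sorted by |t_sum| descending
    p_values: np.ndarray  # aligned with clusters
    n_perm: int
    seed: int | None
    alpha: float
    cluster_forming_alpha: float
    t_map: np.ndarray = field(repr=False, default=None)
    null_max_tsum: np.ndarray = field(repr=False, default=None)

    def significant(self) -> list:
        return [c for c, p in zip(self.clusters, self.p_values) if p <= self.alpha]


def _components(mask: np.ndarray, eu: np.ndarray, ev: np.ndarray):
    """Connected components of the subgraph induced by a boolean voxel mask.

    Returns (labels over masked nodes, n_components, masked node ids).
    """
    nodes = np.flatnonzero(mask)
    n_sel = nodes.size
    if n_sel == 0:
        return None, 0, nodes
    keep = mask[eu] & mask[ev]
    if not keep.any():
        return np.arange(n_sel), n_sel, nodes
    remap = np.empty(mask.size, dtype=np.int64)
    remap[nodes] = np.arange(n_sel)
    sub = sparse.csr_matrix(
        (np.ones(keep.sum(), dtype=bool), (remap[eu[keep]], remap[ev[keep]])),
        shape=(n_sel, n_sel),
    )
    n_comp, labels = connected_components(sub, directed=False)
    return labels, n_comp, nodes


def form_clusters(
    t_map: np.ndarray, alpha_form: float, adjacency: AdjacencyGraph, df: int
) -> list:
    """Threshold |t| at the two-sided critical value and split suprathreshold
    voxels into connected components, separately per sign."""
    thresh = stats.t.ppf(1 - alpha_form / 2, df)
    eu, ev = adjacency.edges
    clusters: list[SignedCluster] = []
    for sign in (1, -1):
        labels, n_comp, nodes = _components((sign * t_map) > thresh, eu, ev)
        for c in range(n_comp):
            members = nodes[labels == c]
            clusters.append(SignedCluster(members, sign, float(t_map[members].sum())))
    clusters.sort(key=lambda c: abs(c.t_sum), reverse=True)
    return clusters


def _max_abs_tsum(t_map, thresh, eu, ev) -> float:
    """Max |Tsum| over clusters of either sign (0.0 if none suprathreshold)."""
    best = 0.0
    for sign in (1, -1):
        labels, n_comp, nodes = _components((sign * t_map) > thresh, eu, ev)
        if n_comp:
            sums = np.bincount(labels, weights=np.abs(t_map[nodes]), minlength=n_comp)
            best = max(best, float(sums.max()))
    return best


def permutation_test(
    power_bi: np.ndarray,
    power_nbi: np.ndarray,
    adjacency: AdjacencyGraph,
    n_perm: int = 1000,
    alpha: float = 0.05,
    alpha_form: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CbptResult:
    """Paired CBPT with a sign-flip max-statistic permutation null.

    Each permutation flips every subject's BI/NBI labels independently (the
    2^n scheme, sampled).  Cluster p = (1 + #{perm max >= |Tsum|}) / (n_perm + 1),
    two-sided via the max over both signs of |Tsum|; positive and negative
    clusters are reported separately in the result.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    power_bi = np.asarray(power_bi, dtype=float)
    power_nbi = np.asarray(power_nbi, dtype=float)
    n, n_vox = power_bi.shape
    if adjacency.n_voxels != n_vox:
        raise ValueError("adjacency does not match the voxel count")
    d = power_bi - power_nbi
    t_obs = paired_t_map(power_bi, power_nbi)
    df = n - 1
    clusters = form_clusters(t_obs, alpha_form, adjacency, df)
    thresh = stats.t.ppf(1 - alpha_form / 2, df)
    eu, ev = adjacency.edges

    # Sign flips leave sum(d^2) per voxel invariant, so permutation t maps
    # need only the flipped means.
    ssq = np.sum(d * d, axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ d / n
    var = np.maximum(ssq - n * means**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / n)
    t_perm[~np.isfinite(t_perm)] = 0.0

    null_max = np.empty(n_perm)
    for k in range(n_perm):
        null_max[k] = _max_abs_tsum(t_perm[k], thresh, eu, ev)

    if clusters:
        obs = np.array([abs(c.t_sum) for c in clusters])
        exceed = (null_max[None, :] >= obs[:, None]).sum(axis=1)
        p_values = (1.0 + exceed) / (n_perm + 1.0)
    else:
        p_values = np.empty(0)
    return CbptResult(
        clusters, p_values, n_perm, seed, alpha, alpha_form,
        t_map=t_obs, null_max_tsum=null_max,
    )
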