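"""Independent brute-force oracles used to check the package's algorithms.

These deliberately avoid the implementation paths they verify: clustering is
done by explicit flood fill over neighbor sets, DBSCAN by a density-
reachability closure, the paired t by the longhand formula, and the sign-flip
null by exhaustive enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def flood_fill_components(nodes, neighbor_sets):
    """Connected components of ``nodes`` (iterable of ids) via BFS flood fill."""
    nodes = set(int(v) for v in nodes)
    seen: set[int] = set()
    comps = []
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for v in neighbor_sets[u]:
                if v in nodes and v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def longhand_paired_t(diffs) -> float:
    d = [float(x) for x in diffs]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n)


def brute_force_clusters(t_map, thresh, neighbor_sets):
    """Signed suprathreshold clusters by flood fill; returns
    {(sign, frozenset(voxels)): t_sum}."""
    out = {}
    for sign in (1, -1):
        nodes = [v for v, t in enumerate(t_map) if sign * t > thresh]
        for comp in flood_fill_components(nodes, neighbor_sets):
            out[(sign, comp)] = sum(t_map[v] for v in comp)
    return out


def exhaustive_sign_flip_null(diffs, thresh, neighbor_sets):
    """Max |Tsum| for every one of the 2^n sign assignments (paired design)."""
    d = np.asarray(diffs, dtype=float)
    n = d.shape[0]
    values = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = d * np.asarray(signs)[:, None]
        t_map = np.array([longhand_paired_t(flipped[:, v]) if np.std(flipped[:, v]) > 0
                          else 0.0 for v in range(d.shape[1])])
        clusters = brute_force_clusters(t_map, thresh, neighbor_sets)
        values.append(max((abs(s) for s in clusters.values()), default=0.0))
    return np.asarray(values)


def dbscan_reachability_closure(points, eps, min_pts):
    """Brute-force DBSCAN semantics.

    Returns (core partition as a set of frozensets, noise ids, border map
    border_id -> set of admissible core-cluster indices).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    within = d <= eps * (1 + 1e-12)
    core = within.sum(axis=1) >= min_pts  # ball includes the point itself
    core_ids = np.flatnonzero(core)
    neighbor_sets = [set(np.flatnonzero(within[i] & core)) - {i} for i in range(n)]
    comps = flood_fill_components(core_ids, neighbor_sets)
    noise, border = set(), {}
    for i in range(n):
        if core[i]:
            continue
        reachable = {k for k, comp in enumerate(comps) if any(within[i, j] for j in comp)}
        if reachable:
            border[i] = reachable
        else:
            noise.add(i)
    return comps, noise, border


def partition_from_labels(labels):
    """Cluster label array -> (set of frozensets, noise id set)."""
    labels = np.asarray(labels)
    clusters = {}
    noise = set()
    for i, lab in enumerate(labels):
        if lab == -1:
            noise.add(i)
        else:
            clusters.setdefault(int(lab), set()).add(i)
    return {frozenset(v) for v in clusters.values()}, noise
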