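"""Leave-one-out jackknife CBPT metrics and the rank-sum group comparison.

Cluster-level statistics from a single CBPT cannot be compared across groups
directly, so the test is rerun once per omitted group member (n iterations
for n subjects).  Each iteration yields two metrics: the number of
significant voxels (cluster size) and the relative modulation strength
relT_sum = Tsum / size.  The two per-group metric distributions are then
compared with Wilcoxon-Mann-Whitney rank-sum tests, with effect size
r = |Z| / sqrt(n1 + n2).

Caveat: jackknife iterations share n-1 of n subjects and are therefore
statistically dependent; the rank-sum p values are descriptive rather than
strictly valid, which is inherent to this comparison scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cbpt import AdjacencyGraph, CbptResult, permutation_test


@dataclass
class GroupComparison:
    """One rank-sum comparison between per-iteration metric distributions."""

    metric: str
    z: float
    p: float
    r: float  # |z| / sqrt(n1 + n2)
    n1: int
    n2: int
    u: float


def _iteration_metrics(result: CbptResult) -> tuple[int, float]:
    """(size, relT_sum) of the significant clusters of the dominant sign.

    The dominant sign is the one whose significant clusters carry the larger
    total |Tsum|; when several clusters of that sign are significant their
    voxel sets are pooled.  No significant cluster -> (0, 0.0).
    """
    sig = result.significant()
    if not sig:
        return 0, 0.0
    totals = {s: sum(abs(c.t_sum) for c in sig if c.sign == s) for s in (1, -1)}
    dom = max(totals, key=lambda s: totals[s])
    chosen = [c for c in sig if c.sign == dom]
    size = int(sum(c.size for c in chosen))
    t_sum = float(sum(c.t_sum for c in chosen))
    return size, t_sum / size


def loo_cbpt_metrics(
    power_bi: np.ndarray,
    power_nbi: np.ndarray,
    adjacency: AdjacencyGraph,
    n_perm: int = 1000,
    alpha: float = 0.05,
    alpha_form: float = 0.05,
    seed: int | None = None,
    seed_policy: str = "per-iteration",
) -> pd.DataFrame:
    """Jackknife CBPT: one full permutation test per left-out subject.

    Returns one row per iteration with columns ``left_out``, ``size``,
    ``rel_t_sum`` and ``significant``.  ``seed_policy`` chooses whether every
    iteration reuses the same permutation seed ("fixed") or derives an
    iteration-specific one ("per-iteration", default).
    """
    power_bi = np.asarray(power_bi, dtype=float)
    power_nbi = np.asarray(power_nbi, dtype=float)
    n = power_bi.shape[0]
    if n < 3:
        raise ValueError("leave-one-out CBPT needs at least 3 subjects")
    if seed_policy not in ("fixed", "per-iteration"):
        raise ValueError("seed_policy must be 'fixed' or 'per-iteration'")
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        it_seed = seed if seed_policy == "fixed" else _derive_seed(seed, i)
        try:
            res = permutation_test(
                power_bi[keep], power_nbi[keep], adjacency,
                n_perm=n_perm, alpha=alpha, alpha_form=alpha_form, seed=it_seed,
            )
        except Exception as exc:
            raise RuntimeError(f"CBPT failed in leave-one-out iteration {i}") from exc
        size, rel = _iteration_metrics(res)
        rows.append((i, size, rel, size > 0))
    return pd.DataFrame(rows, columns=["left_out", "size", "rel_t_sum", "significant"])


def _derive_seed(seed: int | None, i: int) -> int | None:
    if seed is None:
        return None
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))


def wilcoxon_mann_whitney(x, y, metric: str = "") -> GroupComparison:
    """Rank-sum test with midrank ties and effect size r = |Z|/sqrt(N).

    Z comes from the normal approximation with tie-corrected variance; the
    p value uses exact enumeration for n1 + n2 <= 12 without ties (and the
    normal approximation otherwise).  Identical pooled samples give z = 0,
    p = 1.  Sign convention: z > 0 when x tends to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return GroupComparison(metric, 0.0, 1.0, 0.0, n1, n2, u1)
    z = (u1 - mu) / np.sqrt(var)
    has_ties = np.any(counts > 1)
    if n <= 12 and not has_ties:
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    else:
        p = 2 * stats.norm.sf(abs(z))
    p = min(float(p), 1.0)
    r = abs(z) / np.sqrt(n)
    return GroupComparison(metric, float(z), p, float(r), n1, n2, float(u1))


def compare_group_metrics(
    a: pd.DataFrame, b: pd.DataFrame, magnitude: bool = False
) -> dict:
    """Rank-sum comparison of jackknife metrics between two groups.

    Returns {"size": GroupComparison, "rel_t_sum": GroupComparison}; the z
    sign follows the (a - b) rank ordering.  With ``magnitude=True`` the
    rel_t_sum comparison uses |relT_sum| (down-modulations compared by
    strength rather than signed value).
    """
    for name, g in (("a", a), ("b", b)):
        if len(g) == 0:
            raise ValueError(f"group {name} has no jackknife iterations")
    out = {"size": wilcoxon_mann_whitney(a["size"], b["size"], "size")}
    ra, rb = a["rel_t_sum"].to_numpy(), b["rel_t_sum"].to_numpy()
    if magnitude:
        ra, rb = np.abs(ra), np.abs(rb)
    out["rel_t_sum"] = wilcoxon_mann_whitney(ra, rb, "rel_t_sum")
    return out


def effect_size_r(z: float, n_total: int) -> float:
    """r = |Z| / sqrt(N) for a standardized rank-sum statistic."""
    return abs(z) / np.sqrt(n_total)
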