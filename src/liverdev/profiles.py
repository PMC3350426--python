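"""Model-profile clustering of 7-comparison log2-ratio vectors.

The seven comparisons are treated as an ordered pseudo-series.  Candidate
model profiles are all integer trajectories starting at 0 with successive
steps bounded by a maximum unit change c; a greedy max-min algorithm picks
m mutually distinctive profiles; every gene is assigned to its nearest
profile under the 1 - Pearson correlation distance; and a within-gene
permutation test asks which profiles attract significantly more genes than
expected for randomly ordered data (binomial upper tail on the permutation
expectation, Bonferroni-corrected over profiles).

Zero-variance (flat) gene vectors have no defined correlation; they are
quarantined in a dedicated flat bucket (profile id -1) and excluded from
significance testing.  A hierarchical-clustering utility (average linkage
on the same correlation distance) orders genes and arrays for heat-map
style layouts.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

FLAT_PROFILE = -1


def enumerate_candidates(T: int = 7, c: int = 2) -> np.ndarray:
    """All integer profiles of length T starting at 0 with steps in
    [-c, c], excluding the constant-zero profile; (2c+1)^(T-1) - 1 rows."""
    if T < 2 or c < 1:
        raise ValueError("need T >= 2 and c >= 1")
    steps = itertools.product(range(-c, c + 1), repeat=T - 1)
    out = np.zeros(((2 * c + 1) ** (T - 1), T), dtype=int)
    for i, s in enumerate(steps):
        out[i, 1:] = np.cumsum(s)
    keep = ~(out == 0).all(axis=1)
    return out[keep]


def _unit_rows(x: np.ndarray) -> np.ndarray:
    """Center and L2-normalize rows; zero rows for constant vectors."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms > 0, centered / norms, 0.0)
    return unit


def correlation_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of a and rows of b.

    Pairs involving a constant vector get distance 1 (correlation treated
    as 0), per the package's degenerate-input convention.
    """
    return 1.0 - _unit_rows(np.atleast_2d(a)) @ _unit_rows(np.atleast_2d(b)).T


def select_model_profiles(candidates: np.ndarray, m: int,
                          seed: int | None = None) -> np.ndarray:
    """Greedy max-min selection of m distinctive profiles.

    The first pick maximizes its summed distance to all candidates; each
    later pick maximizes its minimum distance to those already selected.
    Ties break to enumeration order.  Fully deterministic; ``seed`` is
    accepted for interface symmetry only.
    """
    candidates = np.asarray(candidates)
    n = len(candidates)
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}]")
    unit = _unit_rows(candidates)
    # Summed distance to all = n - sum of correlations; argmax via argmin
    # of the correlation sum, computed without the n x n matrix.
    corr_sum = unit @ unit.sum(axis=0)
    selected = [int(np.argmin(corr_sum))]
    min_dist = 1.0 - unit @ unit[selected[0]]
    for _ in range(1, m):
        min_dist[selected] = -np.inf
        pick = int(np.argmax(min_dist))
        selected.append(pick)
        min_dist = np.minimum(min_dist, 1.0 - unit @ unit[pick])
    return candidates[selected]


def assign_genes(ratios: pd.DataFrame, profiles: np.ndarray) -> pd.DataFrame:
    """Assign every gene to its nearest model profile.

    ``ratios`` is genes x comparisons (no missing values).  Returns
    gene_id, profile_id, distance; flat gene vectors go to the flat bucket
    (profile_id -1, distance NaN).  Ties break to the lowest profile id.
    """
    x = ratios.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("ratio matrix contains missing values; exclude upstream")
    flat = x.std(axis=1) == 0
    dist = correlation_distance(x, np.asarray(profiles, dtype=float))
    best = dist.argmin(axis=1)
    out = pd.DataFrame({
        "gene_id": ratios.index,
        "profile_id": np.where(flat, FLAT_PROFILE, best),
        "distance": np.where(flat, np.nan, dist[np.arange(len(x)), best]),
    })
    return out


def profile_significance(
    assignments: pd.DataFrame,
    ratios: pd.DataFrame,
    profiles: np.ndarray,
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test for over-populated profiles.

    For each of B rounds every gene's values are independently shuffled
    (preserving its value multiset) and reassigned; the expected count per
    profile is the mean over rounds.  The observed count is compared to
    Binomial(n_genes, expected/n_genes) via its upper tail, Bonferroni-
    corrected over the number of profiles.  Flat genes are excluded.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    profiles = np.asarray(profiles, dtype=float)
    obs_counts = np.bincount(
        assignments.loc[assignments["profile_id"] != FLAT_PROFILE, "profile_id"],
        minlength=len(profiles),
    )
    x = ratios.to_numpy(dtype=float)
    x = x[x.std(axis=1) > 0]
    n_genes = len(x)
    unit_profiles = _unit_rows(profiles)

    rng = np.random.default_rng(seed)
    perm_counts = np.zeros((B, len(profiles)))
    for b in range(B):
        order = np.argsort(rng.random(x.shape), axis=1)
        shuffled = np.take_along_axis(x, order, axis=1)
        best = (_unit_rows(shuffled) @ unit_profiles.T).argmax(axis=1)
        perm_counts[b] = np.bincount(best, minlength=len(profiles))
    expected = perm_counts.mean(axis=0)

    rate = np.clip(expected / max(n_genes, 1), 0.0, 1.0)
    p = stats.binom.sf(obs_counts - 1, n_genes, rate)
    return pd.DataFrame({
        "profile_id": np.arange(len(profiles)),
        "observed_count": obs_counts,
        "expected_count": expected,
        "p_value": p,
        "significant": p < alpha / len(profiles),
    })


def profile_box_stats(cluster: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary (min, q25, median, q75, max) per comparison for
    the genes of one cluster; quartiles by linear interpolation."""
    if len(cluster) == 0:
        raise ValueError("cluster is empty")
    q = np.percentile(cluster.to_numpy(dtype=float), [0, 25, 50, 75, 100], axis=0)
    return pd.DataFrame(
        q.T, index=cluster.columns, columns=["min", "q25", "median", "q75", "max"]
    )


def hierarchical_cluster(ratios: pd.DataFrame, axis: str = "genes"):
    """Average-linkage agglomerative clustering on 1 - Pearson distance.

    ``axis`` is "genes" (cluster rows) or "arrays" (cluster columns).
    Returns (leaf labels in dendrogram order, scipy linkage matrix).
    Constant vectors sit at distance 1 from everything; leaf order is
    deterministic (ties resolve to input order).
    """
    if axis == "arrays":
        ratios = ratios.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'arrays'")
    x = ratios.to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 items to cluster")
    dist = correlation_distance(x, x)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(x), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(linkage)
    return list(ratios.index[order]), linkage


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths
    from merge heights) for external tree viewers."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
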