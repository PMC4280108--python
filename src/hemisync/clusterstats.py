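"""Cluster-based permutation inference and the permuted-correlation variant.

Mass-univariate tests over sensors (or sensor pairs) x frequency inflate the
family-wise error rate; cluster-based permutation inference controls it by
forming clusters of adjacent supra-threshold elements, summing their test
statistic, and comparing each observed cluster against the distribution of
the largest cluster statistic under within-subject condition-label
permutation.

Two variants are provided: a dependent-samples t-test (condition A vs B per
subject) and a correlation test in which a per-subject scalar (here the
behavioral motion index) is correlated with a per-subject channel map (the
coherence difference between stimulation phases); correlations are converted
to t-values with the Student transform, clusters formed at a liberal 20%
alpha, and only clusters spanning at least two adjacent channels with a
permutation p below 5% are reported as significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ClusterResult",
    "motion_index",
    "r_to_t",
    "cluster_perm_ttest",
    "cluster_perm_correlation",
    "space_freq_adjacency",
]


@dataclass
class Cluster:
    members: Tuple[int, ...]
    stat: float
    p: float
    sign: int  # +1 / -1

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    clusters: List[Cluster]
    n_permutations: int
    cluster_alpha: float
    seed: int
    kind: str  # "dependent_t" | "correlation"
    min_cluster: int = 1

    def __post_init__(self):
        lo = 1.0 / (self.n_permutations + 1)
        for c in self.clusters:
            if not lo - 1e-12 <= c.p <= 1.0 + 1e-12:
                raise ValueError("cluster p outside [1/(n_perm+1), 1]")

    def significant(self, alpha: float = 0.05) -> List[Cluster]:
        return [
            c
            for c in self.clusters
            if c.p < alpha and c.size >= self.min_cluster
        ]


def motion_index(
    mr_in: float, mr_sham_in: float, mr_anti: float, mr_sham_anti: float
) -> float:
    """Sham-corrected motion-ratio difference between stimulation phases.

    MI = (MR_in - MR_sham_in) - (MR_anti - MR_sham_anti); positive values
    mean in-phase stimulation shifted perception toward horizontal motion
    more than anti-phase did, relative to each session's sham baseline.
    """
    for v in (mr_in, mr_sham_in, mr_anti, mr_sham_anti):
        if not 0.0 <= v <= 1.0:
            raise ValueError("motion ratios must lie in [0, 1]")
    return (mr_in - mr_sham_in) - (mr_anti - mr_sham_anti)


def r_to_t(r: float, n: int) -> float:
    """Student transform of a Pearson correlation: t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    return r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)


def space_freq_adjacency(space_adj: np.ndarray, n_freq: int) -> sparse.csr_matrix:
    """Combined adjacency over space x frequency elements.

    Element (s, f) neighbours (s', f) for spatial neighbours s' and (s, f+/-1);
    frequencies adjacent at the grid resolution are linked regardless of band
    boundaries.  Element index = s * n_freq + f.
    """
    space_adj = sparse.csr_matrix(np.asarray(space_adj, dtype=bool))
    eye = sparse.identity(n_freq, dtype=bool, format="csr")
    freq_adj = sparse.diags([True] * (n_freq - 1), 1, shape=(n_freq, n_freq), dtype=bool)
    freq_adj = (freq_adj + freq_adj.T).tocsr()
    n_space = space_adj.shape[0]
    combined = sparse.kron(space_adj, eye, format="csr") + sparse.kron(
        sparse.identity(n_space, dtype=bool, format="csr"), freq_adj, format="csr"
    )
    return combined.tocsr()


def _as_sparse(adjacency, n: int) -> sparse.csr_matrix:
    adj = sparse.csr_matrix(adjacency)
    if adj.shape != (n, n):
        raise ValueError(f"adjacency must be {n}x{n}")
    return adj


def _clusters_from_mask(mask: np.ndarray, adj: sparse.csr_matrix, values: np.ndarray):
    """Connected components of supra-threshold elements -> (members, sum)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for c in range(n_comp):
        members = idx[labels == c]
        out.append((tuple(int(m) for m in members), float(values[members].sum())))
    return out


def _max_cluster_stat(t_row: np.ndarray, thr: float, adj: sparse.csr_matrix) -> float:
    best = 0.0
    for mask in (t_row > thr, t_row < -thr):
        for _, s in _clusters_from_mask(mask, adj, t_row):
            best = max(best, abs(s))
    return best


def _paired_t_matrix(d: np.ndarray) -> np.ndarray:
    """Paired t per column of the difference matrix d (subjects x elements)."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(d.shape[1])
    ok = sd > 1e-12
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return t


def cluster_perm_ttest(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Dependent-samples cluster permutation test.

    ``cond_a``/``cond_b`` are subjects x elements matrices of one condition
    each.  Element-wise paired t-values above the two-sided ``cluster_alpha``
    threshold are clustered by adjacency (positive and negative clusters
    separately); each cluster's summed t is compared against the null
    distribution of the maximum |cluster sum| obtained by randomly switching
    the two condition labels within subjects.  The observed labelling is
    included in the null, so p >= 1/(n_perm + 1).
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must be equal-shape subjects x elements matrices")
    n_subj, n_elem = a.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    adj = _as_sparse(adjacency, n_elem)
    d = a - b
    # exclude degenerate-variance elements from clustering
    sd = d.std(axis=0, ddof=1)
    valid = sd > 1e-12
    t_obs = _paired_t_matrix(d)
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, n_subj - 1)

    observed: List[Cluster] = []
    for sign, mask in ((1, (t_obs > thr) & valid), (-1, (t_obs < -thr) & valid)):
        for members, s in _clusters_from_mask(mask, adj, t_obs):
            observed.append(Cluster(members=members, stat=s, p=1.0, sign=sign))

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    # vectorized permutation t: flipping a subject's label negates its difference
    ss = (d**2).sum(axis=0)
    mean_p = signs @ d / n_subj
    var_p = (ss[None, :] - n_subj * mean_p**2) / (n_subj - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean_p / np.sqrt(var_p / n_subj)
    t_perm[:, ~valid] = 0.0
    t_perm = np.nan_to_num(t_perm)

    null_max = np.fromiter(
        (_max_cluster_stat(t_perm[p], thr, adj) for p in range(n_perm)),
        dtype=float,
        count=n_perm,
    )
    for c in observed:
        exceed = int(np.count_nonzero(null_max >= abs(c.stat)))
        c.p = (1 + exceed) / (n_perm + 1)
    observed.sort(key=lambda c: c.p)
    return ClusterResult(
        clusters=observed,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        seed=seed,
        kind="dependent_t",
        min_cluster=1,
    )


def _corr_t_matrix(mi_c: np.ndarray, maps: np.ndarray, n: int) -> np.ndarray:
    """Per-channel Pearson r between mi and map columns, as t-values."""
    yc = maps - maps.mean(axis=0, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=0))
    sx = np.sqrt((mi_c**2).sum())
    r = np.zeros(maps.shape[1])
    ok = (sy > 1e-12) & (sx > 1e-12)
    r[ok] = (mi_c @ yc[:, ok]) / (sx * sy[ok])
    r = np.clip(r, -0.999999, 0.999999)
    return r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)


def cluster_perm_correlation(
    mi: np.ndarray,
    delta_maps: np.ndarray,
    adjacency,
    cluster_alpha: float = 0.20,
    n_perm: int = 1000,
    min_cluster: int = 2,
    seed: int = 0,
    permute: str = "condition_switch",
) -> ClusterResult:
    """Cluster-based permuted correlation between a scalar and channel maps.

    Per channel, Pearson's r between the per-subject scalar ``mi`` and the
    per-subject map value is transformed to t; channels with two-sided p
    below ``cluster_alpha`` (20%) form clusters by adjacency.  The null
    permutes condition labels within subjects - for a difference map this
    flips the sign of the subject's row (``"condition_switch"``); the
    alternative ``"shuffle_mi"`` permutes the scalar across subjects.  Only
    clusters of at least ``min_cluster`` adjacent channels with p < 0.05 are
    reported by ``.significant()``.
    """
    mi = np.asarray(mi, dtype=float)
    maps = np.asarray(delta_maps, dtype=float)
    n_subj = len(mi)
    if maps.shape[0] != n_subj:
        raise ValueError("mi and delta_maps must agree on subjects")
    if n_subj < 4:
        raise ValueError("need at least 4 subjects")
    if permute not in ("condition_switch", "shuffle_mi"):
        raise ValueError("permute must be 'condition_switch' or 'shuffle_mi'")
    n_elem = maps.shape[1]
    adj = _as_sparse(adjacency, n_elem)
    mi_c = mi - mi.mean()
    t_obs = _corr_t_matrix(mi_c, maps, n_subj)
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, n_subj - 2)

    observed: List[Cluster] = []
    for sign, mask in ((1, t_obs > thr), (-1, t_obs < -thr)):
        for members, s in _clusters_from_mask(mask, adj, t_obs):
            observed.append(Cluster(members=members, stat=s, p=1.0, sign=sign))

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    if permute == "condition_switch":
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
        for p_i in range(n_perm):
            t_p = _corr_t_matrix(mi_c, maps * signs[p_i][:, None], n_subj)
            null_max[p_i] = _max_cluster_stat(t_p, thr, adj)
    else:
        for p_i in range(n_perm):
            perm = rng.permutation(n_subj)
            t_p = _corr_t_matrix(mi_c[perm], maps, n_subj)
            null_max[p_i] = _max_cluster_stat(t_p, thr, adj)

    for c in observed:
        exceed = int(np.count_nonzero(null_max >= abs(c.stat)))
        c.p = (1 + exceed) / (n_perm + 1)
    observed.sort(key=lambda c: c.p)
    return ClusterResult(
        clusters=observed,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        seed=seed,
        kind="correlation",
        min_cluster=min_cluster,
    )
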