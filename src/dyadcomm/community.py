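"""Pairwise community dissimilarity, average-linkage clustering, and ANOSIM.

Bray-Curtis operates on abundance vectors, ``sum |x - y| / sum (x + y)``;
Jaccard on presence/absence sets, ``1 - |A & B| / |A | B|`` (a quantitative
Ruzicka variant, ``1 - sum min / sum max``, is available via
``binary=False``).  Clustering is unweighted average linkage (UPGMA) with a
deterministic tie-break.  ANOSIM contrasts mean between-group and
within-group distance ranks; its permutation P-value uses the convention
that the observed labelling counts as one permutation, so the smallest
achievable P with 999 permutations is 1/1000.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import InputError


# ---------------------------------------------------------------------------
# metrics

def bray_curtis(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    denom = (x + y).sum()
    if denom == 0:
        raise InputError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def jaccard(x, y, binary: bool = True) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    if binary:
        a, b = x > 0, y > 0
        union = (a | b).sum()
        if union == 0:
            raise InputError("Jaccard undefined for two empty presence sets")
        return float(1.0 - (a & b).sum() / union)
    denom = np.maximum(x, y).sum()
    if denom == 0:
        raise InputError("Jaccard undefined for two all-zero vectors")
    return float(1.0 - np.minimum(x, y).sum() / denom)


def _check_pair(x, y) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("vectors must be 1-D and of equal length")
    if (x < 0).any() or (y < 0).any():
        raise InputError("vectors must be non-negative")


_METRICS = ("bray_curtis", "jaccard_binary", "jaccard_quantitative")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with ordered labels."""

    ids: list
    values: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise InputError("distance matrix shape does not match ids")
        if np.isnan(v).any():
            raise InputError("NaN in distance matrix")
        if not np.allclose(v, v.T, atol=1e-12) or not np.allclose(np.diag(v), 0):
            raise InputError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(data: pd.DataFrame, metric: str = "bray_curtis") -> DistanceMatrix:
    """All pairwise dissimilarities between the rows of ``data``.

    Rows are observations (samples or cohort means), columns genera.
    """
    if metric not in _METRICS:
        raise InputError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    X = data.values.astype(float)
    if (X < 0).any():
        raise InputError("abundances must be non-negative")
    n = X.shape[0]
    if metric == "bray_curtis":
        num = np.abs(X[:, None, :] - X[None, :, :]).sum(-1)
        den = (X[:, None, :] + X[None, :, :]).sum(-1)
        if (den == 0).any():
            raise InputError("Bray-Curtis undefined for all-zero row pair")
        d = num / den
    elif metric == "jaccard_binary":
        B = X > 0
        inter = (B[:, None, :] & B[None, :, :]).sum(-1)
        union = (B[:, None, :] | B[None, :, :]).sum(-1)
        if (union == 0).any():
            raise InputError("Jaccard undefined for empty presence-set pair")
        d = 1.0 - inter / union
    else:
        mn = np.minimum(X[:, None, :], X[None, :, :]).sum(-1)
        mx = np.maximum(X[:, None, :], X[None, :, :]).sum(-1)
        d = 1.0 - mn / mx
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(data.index), d, metric)


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class Dendrogram:
    """UPGMA merge sequence: n-1 merges of (left, right, height, members).

    ``left``/``right`` are cluster indices (0..n-1 are leaves in label
    order; merge k creates cluster n+k); ``members`` is the sorted tuple of
    leaf labels of the merged cluster.
    """

    labels: list
    merges: list  # (left, right, height, members)

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def clades(self) -> list[frozenset]:
        return [frozenset(m[3]) for m in self.merges]

    def smallest_clade(self, labels) -> frozenset:
        """Smallest merged cluster containing all the given leaf labels."""
        want = set(labels)
        for cl in self.clades():
            if want <= cl:
                return cl
        raise KeyError(f"labels {sorted(want)} not all present")

    @property
    def last_singleton(self):
        """The leaf joining at the final merge, if the final merge attaches
        a singleton; otherwise None."""
        left, right, _, _ = self.merges[-1]
        n = len(self.labels)
        for side in (left, right):
            if side < n:
                return self.labels[side]
        return None

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        n = len(self.labels)
        node_height = {i: 0.0 for i in range(n)}
        node_str = {i: _escape_newick(l) for i, l in enumerate(self.labels)}
        for k, (a, b, h, _) in enumerate(self.merges):
            idx = n + k
            sa = f"{node_str[a]}:{h - node_height[a]:.10g}"
            sb = f"{node_str[b]}:{h - node_height[b]:.10g}"
            node_str[idx] = f"({sa},{sb})"
            node_height[idx] = h
        return node_str[n + len(self.merges) - 1] + ";"


def _escape_newick(label: str) -> str:
    if any(c in str(label) for c in " (),:;'"):
        return "'" + str(label).replace("'", "''") + "'"
    return str(label)


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) hierarchical clustering.

    Inter-cluster distance is the unweighted mean over all cross pairs of
    leaves.  Ties are broken by the smallest (row, column) cluster-index
    pair, so the merge sequence is fully deterministic.  Heights are
    monotone non-decreasing (average linkage cannot invert).
    """
    n = dm.n
    if n < 2:
        raise InputError("clustering needs at least 2 observations")
    D = dm.values.copy().astype(float)
    sizes = {i: 1 for i in range(n)}
    leaf_members = {i: (dm.ids[i],) for i in range(n)}
    merges = []
    cur = D
    ids = list(range(n))
    for k in range(n - 1):
        m = len(ids)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                d = cur[ai, bi]
                if best is None or d < best[0] - 1e-15:
                    best = (d, ai, bi)
        d, ai, bi = best
        a, b = ids[ai], ids[bi]
        members = tuple(sorted(leaf_members[a] + leaf_members[b]))
        new_id = n + k
        merges.append((a, b, float(d), members))
        # unweighted average update
        na, nb = sizes[a], sizes[b]
        row = (na * cur[ai] + nb * cur[bi]) / (na + nb)
        keep = [i for i in range(m) if i not in (ai, bi)]
        new = np.empty((m - 1, m - 1))
        new[:-1, :-1] = cur[np.ix_(keep, keep)]
        new[-1, :-1] = row[keep]
        new[:-1, -1] = row[keep]
        new[-1, -1] = 0.0
        cur = new
        ids = [ids[i] for i in keep] + [new_id]
        sizes[new_id] = na + nb
        leaf_members[new_id] = members
    return Dendrogram(list(dm.ids), merges)


# ---------------------------------------------------------------------------
# ANOSIM

@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_perm: int
    method: str
    grouping: list
    seed: object = None

    def __repr__(self) -> str:  # compact, statsmodels-ish
        return (f"AnosimResult(R={self.R:.4f}, p={self.p_value:.4g}, "
                f"method={self.method!r}, n_perm={self.n_perm})")


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / denom


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None,
           method: str = "permutation") -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks taken over all n(n-1)/2 distances with mid-rank ties.  The
    permutation P includes the observed statistic:
    ``P = (1 + #{R_perm >= R_obs}) / (1 + n_perm)``.  ``method="exact"``
    enumerates every distinct label assignment instead (small n only) and
    returns the exact fraction with ``R_perm >= R_obs``.
    """
    groups = list(groups)
    if len(groups) != dm.n:
        raise InputError("groups length must match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise InputError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2][0]
        raise InputError(f"group {small!r} has fewer than 2 members")
    g = np.asarray(pd.Categorical(groups).codes)
    n = dm.n
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(dm.values[iu, ju])
    denom = n * (n - 1) / 4.0
    within_obs = g[iu] == g[ju]
    r_obs = _anosim_r(ranks, within_obs, denom)

    if method == "exact":
        perms = sorted(set(itertools.permutations(g)))
        r_perm = np.array([
            _anosim_r(ranks, np.asarray(p)[iu] == np.asarray(p)[ju], denom)
            for p in perms
        ])
        p = float((r_perm >= r_obs - 1e-12).mean())
        return AnosimResult(float(r_obs), p, len(perms), "exact", groups, seed)

    rng = np.random.default_rng(seed)
    perm = np.array([rng.permutation(g) for _ in range(n_perm)])
    within = perm[:, iu] == perm[:, ju]  # (n_perm, n_pairs)
    n_within = within.sum(axis=1).astype(float)
    sum_within = (ranks[None, :] * within).sum(axis=1)
    total = ranks.sum()
    rw = sum_within / n_within
    rb = (total - sum_within) / (len(ranks) - n_within)
    r_perm = (rb - rw) / denom
    p = (1.0 + (r_perm >= r_obs - 1e-12).sum()) / (1.0 + n_perm)
    return AnosimResult(float(r_obs), float(p), n_perm, "permutation", groups, seed)
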