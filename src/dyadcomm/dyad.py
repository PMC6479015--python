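"""Milk-feces association across matched mother-infant dyads.

Four views of the same question — does a mother's milk community predict her
infant's fecal community? —

* a genus-by-genus Spearman screen between the two niches' aggregate genus
  sets, flagged at P < 0.01 and |rs| > 0.3;
* canonical correlation of the logit-transformed abundance blocks (the first
  canonical correlation r1 summarizes community-level association);
* a matched-vs-unmatched similarity test: Bray-Curtis or Jaccard distance of
  every mother to her own infant, against her distance to every other
  infant, compared by a rank-sum test (plus an exact pairing-permutation
  variant — the rank-sum version treats the two overlapping distance sets
  as independent samples, which makes it conservative);
* Spearman correlation of the per-dyad diversity indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from .tables import AbundanceTable, DyadPairing, InputError


# ---------------------------------------------------------------------------
# cross-niche Spearman screen

@dataclass
class CrossCorrelation:
    rs: pd.DataFrame          # milk genera x feces genera
    p_values: pd.DataFrame
    flags: pd.DataFrame       # True iff p < p_max and |rs| > rs_min
    p_max: float = 0.01
    rs_min: float = 0.3


def cross_spearman(milk: AbundanceTable, feces: AbundanceTable,
                   pairs: DyadPairing, p_max: float = 0.01,
                   rs_min: float = 0.3) -> CrossCorrelation:
    """Spearman rs between every (milk genus, feces genus) over matched dyads.

    Mid-rank ties; P-values by the t approximation.  Constant vectors give
    NaN rs (undefined) and are excluded from flagging.
    """
    if len(pairs) < 3:
        raise InputError("cross_spearman requires >= 3 matched dyads")
    M = milk.abund.loc[pairs.milk_ids]
    F = feces.abund.loc[pairs.feces_ids]
    rs, pv = _spearman_blocks(M.values, F.values)
    rs = pd.DataFrame(rs, index=M.columns, columns=F.columns)
    pv = pd.DataFrame(pv, index=M.columns, columns=F.columns)
    flags = (pv < p_max) & (rs.abs() > rs_min)
    return CrossCorrelation(rs, pv, flags.fillna(False), p_max, rs_min)


def _spearman_blocks(X: np.ndarray, Y: np.ndarray):
    """Cross-block Spearman matrix with t-approximation P-values."""
    n = X.shape[0]
    RX = np.apply_along_axis(stats.rankdata, 0, X)
    RY = np.apply_along_axis(stats.rankdata, 0, Y)
    RX = (RX - RX.mean(0)) / RX.std(0, ddof=0)
    RY = (RY - RY.mean(0)) / RY.std(0, ddof=0)
    with np.errstate(invalid="ignore"):
        rho = RX.T @ RY / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


# ---------------------------------------------------------------------------
# logit canonical correlation

class LogitCCA:
    """Canonical correlation of two abundance blocks after logit transform.

    Expects zero-replaced abundances (all entries in (0, 1)); entries equal
    to or above 1 are clipped to 1 - 1e-6.  Columns are standardized after
    the transform, so r1 is invariant to per-variable affine rescaling.
    """

    def __init__(self, milk: AbundanceTable | pd.DataFrame,
                 feces: AbundanceTable | pd.DataFrame,
                 pairs: DyadPairing | None = None):
        M = milk.abund if isinstance(milk, AbundanceTable) else milk
        F = feces.abund if isinstance(feces, AbundanceTable) else feces
        if pairs is not None:
            M = M.loc[pairs.milk_ids]
            F = F.loc[pairs.feces_ids]
        if len(M) != len(F):
            raise InputError("milk and feces blocks must have matching rows")
        self.milk_genera = list(M.columns)
        self.feces_genera = list(F.columns)
        self.X = self._logit(M.values)
        self.Y = self._logit(F.values)
        self.n = len(M)

    @staticmethod
    def _logit(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if (v <= 0).any():
            raise InputError("logit requires strictly positive abundances "
                             "(zero-replace upstream)")
        v = np.minimum(v, 1.0 - 1e-6)
        return logit(v)

    def fit(self, ridge: float = 0.0) -> "CCAResults":
        X = self.X - self.X.mean(0)
        Y = self.Y - self.Y.mean(0)
        sx = X.std(0, ddof=1)
        sy = Y.std(0, ddof=1)
        for s, names in ((sx, self.milk_genera), (sy, self.feces_genera)):
            if (s == 0).any():
                bad = [n for n, v in zip(names, s) if v == 0]
                raise InputError(f"constant variable(s): {bad}")
        X = X / sx
        Y = Y / sy
        n, p = X.shape
        q = Y.shape[1]
        Sxx = X.T @ X / (n - 1) + ridge * np.eye(p)
        Syy = Y.T @ Y / (n - 1) + ridge * np.eye(q)
        Sxy = X.T @ Y / (n - 1)
        wx = _inv_sqrt(Sxx, self.milk_genera, ridge)
        wy = _inv_sqrt(Syy, self.feces_genera, ridge)
        U, s, Vt = np.linalg.svd(wx @ Sxy @ wy)
        r = np.clip(s, 0.0, 1.0)
        a = wx @ U            # x weights, columns per canonical axis
        b = wy @ Vt.T
        x_scores = X @ a
        y_scores = Y @ b
        # unit sample variance of the variates
        x_scores /= x_scores.std(0, ddof=1)
        y_scores /= y_scores.std(0, ddof=1)
        loadings_milk = pd.Series(
            [stats.spearmanr(self.X[:, j], x_scores[:, 0]).statistic
             for j in range(p)], index=self.milk_genera)
        loadings_feces = pd.Series(
            [stats.spearmanr(self.Y[:, j], y_scores[:, 0]).statistic
             for j in range(q)], index=self.feces_genera)
        p_overall = _bartlett_p(r, n, p, q)
        return CCAResults(self, np.asarray(r), x_scores, y_scores,
                          loadings_milk, loadings_feces, p_overall, ridge)


def _inv_sqrt(S: np.ndarray, names, ridge: float, tol: float = 1e-10) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    if (w < tol).any() and ridge == 0.0:
        bad = [names[i] for i in np.argsort(w)[: int((w < tol).sum())]]
        raise InputError(
            f"rank-deficient block (collinear variables, e.g. {bad[:5]}); "
            "enable ridge regularization"
        )
    w = np.maximum(w, tol)
    return V @ np.diag(w ** -0.5) @ V.T


def _bartlett_p(r: np.ndarray, n: int, p: int, q: int) -> float:
    """Bartlett's chi-square approximation for the overall CCA significance."""
    lam = np.prod(1.0 - np.minimum(r, 1.0 - 1e-12) ** 2)
    statistic = -(n - 1 - (p + q + 1) / 2.0) * np.log(lam)
    return float(stats.chi2.sf(statistic, p * q))


@dataclass
class CCAResults:
    model: LogitCCA
    correlations: np.ndarray      # non-increasing, in [0, 1]
    x_scores: np.ndarray          # per-dyad milk variate scores (unit variance)
    y_scores: np.ndarray
    loadings_milk: pd.Series      # Spearman of each milk genus with 1st variate
    loadings_feces: pd.Series
    p_overall: float              # Bartlett chi-square P for the whole set
    ridge: float

    @property
    def r1(self) -> float:
        return float(self.correlations[0])

    def summary(self) -> str:
        lines = [f"Logit canonical correlation (n = {self.model.n}, "
                 f"p = {len(self.model.milk_genera)}, "
                 f"q = {len(self.model.feces_genera)})",
                 "  canonical correlations: "
                 + ", ".join(f"{r:.3f}" for r in self.correlations[:5]),
                 f"  Bartlett P (all axes) = {self.p_overall:.4g}"]
        top_m = self.loadings_milk.abs().sort_values(ascending=False).head(3)
        top_f = self.loadings_feces.abs().sort_values(ascending=False).head(3)
        lines.append("  top milk loadings: "
                     + ", ".join(f"{g} ({self.loadings_milk[g]:+.3f})"
                                 for g in top_m.index))
        lines.append("  top feces loadings: "
                     + ", ".join(f"{g} ({self.loadings_feces[g]:+.3f})"
                                 for g in top_f.index))
        return "\n".join(lines)


def logit_canonical_correlation(milk, feces, pairs=None, ridge: float = 0.0) -> CCAResults:
    """Convenience wrapper: ``LogitCCA(milk, feces, pairs).fit(ridge)``."""
    return LogitCCA(milk, feces, pairs).fit(ridge=ridge)


# ---------------------------------------------------------------------------
# matched-dyad similarity test

@dataclass
class DyadTestResult:
    matched: np.ndarray            # one distance per dyad
    unmatched: np.ndarray          # all i != j mother x infant combinations
    statistic: float               # rank-sum W of the matched set
    z: float
    p_value: float                 # two-sided, normal approximation
    median_difference: float       # median(matched) - median(unmatched)
    metric: str
    p_permutation: float | None = None

    @property
    def n_dyads(self) -> int:
        return len(self.matched)


def dyad_similarity_test(milk: AbundanceTable, feces: AbundanceTable,
                         pairs: DyadPairing, metric: str = "bray_curtis",
                         permutation: int = 0, seed=None) -> DyadTestResult:
    """Compare matched-dyad distances with all non-matched combinations.

    The matched set is d(milk_i, feces_i); the unmatched set d(milk_i,
    feces_j) for all i != j (n^2 - n values).  The two sets are compared by
    a two-sample rank-sum test with mid-rank tie correction and normal
    approximation, two-sided.  A negative median difference means dyads are
    more similar than chance pairings.

    ``permutation > 0`` additionally computes an exact-null alternative:
    shuffle the pairing that many times, recompute the mean matched
    distance, and report the two-sided permutation P (the observed pairing
    counts as one permutation).  Unlike the rank-sum P it is calibrated
    under no-coupling, because it respects the dependence between the two
    distance sets.
    """
    if len(pairs) < 5:
        raise InputError("dyad similarity test requires >= 5 dyads")
    if metric == "jaccard":
        metric = "jaccard_binary"
    if metric == "jaccard_binary" and milk.zero_replaced:
        import logging
        logging.getLogger("dyadcomm").warning(
            "binary Jaccard on zero-replaced abundances: every genus counts "
            "as present, distances degenerate to 0; use pre-fill abundances")
    M = milk.abund.loc[pairs.milk_ids]
    F = feces.abund.loc[pairs.feces_ids]
    common = M.columns.union(F.columns)  # shared genus universe
    M = M.reindex(columns=common, fill_value=0.0)
    F = F.reindex(columns=common, fill_value=0.0)
    D = _cross_distances(M.values, F.values, metric)
    n = len(pairs)
    eye = np.eye(n, dtype=bool)
    matched = D[eye]
    unmatched = D[~eye]
    w, z, p = _ranksum(matched, unmatched)
    med = float(np.median(matched) - np.median(unmatched))
    p_perm = None
    if permutation:
        rng = np.random.default_rng(seed)
        obs = matched.mean()
        perm_stats = np.empty(permutation)
        for i in range(permutation):
            perm_stats[i] = D[np.arange(n), rng.permutation(n)].mean()
        lo = 1 + int((perm_stats <= obs + 1e-15).sum())
        hi = 1 + int((perm_stats >= obs - 1e-15).sum())
        p_perm = min(1.0, 2.0 * min(lo, hi) / (permutation + 1))
    return DyadTestResult(matched, unmatched, w, z, p, med, metric, p_perm)


def _cross_distances(M: np.ndarray, F: np.ndarray, metric: str) -> np.ndarray:
    if metric == "bray_curtis":
        num = np.abs(M[:, None, :] - F[None, :, :]).sum(-1)
        den = (M[:, None, :] + F[None, :, :]).sum(-1)
        return num / den
    if metric == "jaccard_binary":
        A = M > 0
        B = F > 0
        inter = (A[:, None, :] & B[None, :, :]).sum(-1)
        union = (A[:, None, :] | B[None, :, :]).sum(-1)
        return 1.0 - inter / union
    if metric == "jaccard_quantitative":
        mn = np.minimum(M[:, None, :], F[None, :, :]).sum(-1)
        mx = np.maximum(M[:, None, :], F[None, :, :]).sum(-1)
        return 1.0 - mn / mx
    raise InputError(f"unknown metric {metric!r}")


def _ranksum(x: np.ndarray, y: np.ndarray):
    """Two-sample rank-sum: W, z (tie-corrected), two-sided P.

    Complete ties give variance 0, reported as z = 0, P = 1.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = float((counts ** 3 - counts).sum())
    var = n1 * (n - n1) / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return w, 0.0, 1.0
    z = (w - mean) / np.sqrt(var)
    return w, float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# diversity correlations

def diversity_correlation(div_milk: pd.DataFrame, div_feces: pd.DataFrame,
                          pairs: DyadPairing, per_cohort: bool = False,
                          min_dyads: int = 5) -> pd.DataFrame:
    """Spearman r and P between milk and feces diversity, per index.

    ``div_milk``/``div_feces`` are :func:`dyadcomm.diversity.diversity_table`
    outputs.  With ``per_cohort=True`` one row per (cohort, index); scopes
    with fewer than ``min_dyads`` dyads are skipped with a warning.
    """
    import logging
    logger = logging.getLogger("dyadcomm")
    indices = ["richness", "shannon", "inv_simpson", "fisher_alpha"]
    M = div_milk.loc[pairs.milk_ids]
    F = div_feces.loc[pairs.feces_ids]
    scopes = [("overall", np.ones(len(pairs), dtype=bool))]
    if per_cohort:
        cohorts = M["cohort"].values
        scopes = [(k, cohorts == k) for k in sorted(set(cohorts))]
    rows = []
    for scope, mask in scopes:
        if mask.sum() < min_dyads:
            logger.warning("scope %r has %d < %d dyads; skipped",
                           scope, int(mask.sum()), min_dyads)
            continue
        for idx in indices:
            a = M.loc[M.index[mask], idx]
            b = F.loc[F.index[mask], idx]
            res = stats.spearmanr(a, b, nan_policy="omit")
            rows.append({"scope": scope, "index": idx, "n": int(mask.sum()),
                         "r": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
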