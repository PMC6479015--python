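"""One-way group models for relative abundances and diversity indices.

Relative abundances (proportions in (0, 1), zero-replaced upstream) are
modelled with a beta likelihood: y ~ Beta(mu_k * phi, (1 - mu_k) * phi) with
a logit link on the group means mu_k and a common precision phi.  The
overall group effect is a likelihood-ratio test against the intercept-only
model; pairwise contrasts are Wald z-tests on the link scale with a
Bonferroni multiplier equal to the number of pairs, summarized by a
compact-letter display (groups sharing a letter are not significantly
different after adjustment).

Diversity indices use an ordinary one-way ANOVA, optionally on the log
scale with back-transformed group estimates (Shannon is conventionally
analysed untransformed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, expit, gammaln, logit


# ---------------------------------------------------------------------------
# beta one-way model

class BetaOneWay:
    """One-way beta-likelihood model for proportions.

    Parameters
    ----------
    y : array-like of proportions strictly inside (0, 1)
    groups : array-like of group labels, same length; groups are ordered by
        first appearance (so a cohort column order is preserved).
    """

    def __init__(self, y, groups):
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or len(y) == 0:
            raise ValueError("y must be a non-empty 1-D array")
        if (y <= 0).any() or (y >= 1).any():
            raise ValueError("y must lie strictly in (0, 1); zero-replace upstream")
        groups = pd.Series(groups)
        if len(groups) != len(y):
            raise ValueError("groups length must match y")
        self.group_names = list(pd.unique(groups))
        self.codes = groups.map({g: i for i, g in enumerate(self.group_names)}).values
        counts = np.bincount(self.codes)
        if len(self.group_names) >= 2 and (counts < 3).any():
            small = self.group_names[int(np.argmin(counts))]
            raise ValueError(f"group {small!r} has fewer than 3 observations")
        self.y = y
        self.k = len(self.group_names)

    # log-likelihood and gradient in theta = (eta_1..eta_K, log phi)
    def loglike(self, theta) -> float:
        eta, logphi = theta[:-1], theta[-1]
        mu = expit(eta)[self.codes]
        phi = np.exp(logphi)
        a, b = mu * phi, (1 - mu) * phi
        return float(np.sum(gammaln(phi) - gammaln(a) - gammaln(b)
                            + (a - 1) * np.log(self.y)
                            + (b - 1) * np.log1p(-self.y)))

    def score(self, theta) -> np.ndarray:
        eta, logphi = theta[:-1], theta[-1]
        mu_k = expit(eta)
        mu = mu_k[self.codes]
        phi = np.exp(logphi)
        a, b = mu * phi, (1 - mu) * phi
        ly, l1y = np.log(self.y), np.log1p(-self.y)
        dl_dmu = phi * (-digamma(a) + digamma(b) + ly - l1y)
        dmu_deta = mu * (1 - mu)
        g_eta = np.bincount(self.codes, weights=dl_dmu * dmu_deta, minlength=self.k)
        dl_dphi = (digamma(phi) - mu * digamma(a) - (1 - mu) * digamma(b)
                   + mu * ly + (1 - mu) * l1y)
        return np.append(g_eta, dl_dphi.sum() * phi)

    def _start(self) -> np.ndarray:
        """Method-of-moments start: group means, pooled beta precision."""
        means = np.array([self.y[self.codes == i].mean() for i in range(self.k)])
        resid_var = np.var(self.y - means[self.codes]) + 1e-12
        mbar = self.y.mean()
        phi0 = max(mbar * (1 - mbar) / resid_var - 1.0, 1.0)
        return np.append(logit(np.clip(means, 1e-9, 1 - 1e-9)), np.log(phi0))

    def fit(self, maxiter: int = 200) -> "BetaOneWayResults":
        x0 = self._start()
        res = optimize.minimize(
            lambda t: -self.loglike(t), x0, jac=lambda t: -self.score(t),
            method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-14,
                                        "gtol": 1e-10},
        )
        theta = res.x
        # polish to a tight stationary point: damped Newton on the score
        for _ in range(50):
            g = self.score(theta)
            if np.linalg.norm(g) < 1e-10:
                break
            J = self._score_jacobian(theta)
            try:
                step = np.linalg.solve(J, -g)
            except np.linalg.LinAlgError:
                break
            lam, ll0 = 1.0, self.loglike(theta)
            while lam > 1e-6:
                cand = theta + lam * step
                if (np.linalg.norm(self.score(cand)) < np.linalg.norm(g)
                        and np.isfinite(self.loglike(cand))):
                    theta = cand
                    break
                lam /= 2.0
            else:
                break
        grad_norm = float(np.linalg.norm(self.score(theta)))
        converged = grad_norm < 1e-8
        if not converged:
            raise RuntimeError(
                f"beta one-way ML did not converge (||grad|| = {grad_norm:.3g}); "
                f"optimizer message: {res.message}"
            )
        cov = self._covariance(theta)
        return BetaOneWayResults(self, theta, cov, self.loglike(theta),
                                 converged, grad_norm)

    def _score_jacobian(self, theta) -> np.ndarray:
        # Hessian of the log-likelihood by central differences of the score
        p = len(theta)
        H = np.zeros((p, p))
        h = 1e-6 * np.maximum(1.0, np.abs(theta))
        for j in range(p):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] -= h[j]
            H[:, j] = (self.score(tp) - self.score(tm)) / (2 * h[j])
        return (H + H.T) / 2.0

    def _covariance(self, theta) -> np.ndarray:
        return np.linalg.inv(-self._score_jacobian(theta))


@dataclass
class BetaOneWayResults:
    """Fitted beta one-way model (link-scale parameters retained)."""

    model: BetaOneWay
    theta: np.ndarray          # (eta_1..eta_K, log phi)
    cov: np.ndarray            # observed-information covariance, same order
    llf: float
    converged: bool
    grad_norm: float

    @property
    def eta(self) -> pd.Series:
        return pd.Series(self.theta[:-1], index=self.model.group_names, name="eta")

    @property
    def mu(self) -> pd.Series:
        """Group mean estimates on the proportion scale."""
        return pd.Series(expit(self.theta[:-1]), index=self.model.group_names,
                         name="mu")

    @property
    def phi(self) -> float:
        return float(np.exp(self.theta[-1]))

    @property
    def bse_eta(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)[:-1]),
                         index=self.model.group_names, name="se(eta)")

    @property
    def bse_mu(self) -> pd.Series:
        """Delta-method standard errors on the proportion scale."""
        mu = self.mu.values
        return pd.Series(self.bse_eta.values * mu * (1 - mu),
                         index=self.model.group_names, name="se(mu)")

    def lr_test(self):
        """LRT of the group effect against the intercept-only model.

        Returns (statistic, df, p_value).
        """
        if self.model.k < 2:
            raise ValueError("LRT requires >= 2 groups")
        null = BetaOneWay(self.model.y, np.zeros(len(self.model.y), dtype=int)).fit()
        stat = 2.0 * (self.llf - null.llf)
        df = self.model.k - 1
        return float(max(stat, 0.0)), df, float(stats.chi2.sf(max(stat, 0.0), df))

    def pairwise_contrasts(self, alpha: float = 0.05) -> "PairwiseContrasts":
        return pairwise_contrasts(self, alpha=alpha)

    def summary(self) -> str:
        lines = ["Beta one-way model (logit link, common precision)",
                 f"  n = {len(self.model.y)}, groups = {self.model.k}, "
                 f"phi = {self.phi:.3f}, llf = {self.llf:.3f}"]
        tab = pd.DataFrame({"mu": self.mu, "se(mu)": self.bse_mu,
                            "eta": self.eta, "se(eta)": self.bse_eta})
        lines.append(tab.to_string(float_format=lambda v: f"{v:.4f}"))
        if self.model.k >= 2:
            stat, df, p = self.lr_test()
            lines.append(f"  LR test of group effect: chi2({df}) = {stat:.3f}, "
                         f"P = {p:.4g}")
        return "\n".join(lines)


@dataclass
class PairwiseContrasts:
    """All-pairs link-scale Wald contrasts with Bonferroni adjustment."""

    table: pd.DataFrame        # per pair: estimate, se, z, p_raw, p_adj, significant
    letters: dict              # group -> compact letter string
    alpha: float
    m: int                     # Bonferroni multiplier (number of pairs)


def pairwise_contrasts(results: BetaOneWayResults, alpha: float = 0.05) -> PairwiseContrasts:
    """Wald z-tests on all K(K-1)/2 link-scale differences, Bonferroni-adjusted."""
    if not results.converged:
        raise ValueError("fit did not converge")
    names = results.model.group_names
    k = len(names)
    if k < 2:
        raise ValueError("contrasts require >= 2 groups")
    eta = results.theta[:-1]
    cov = results.cov[:-1, :-1]
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        diff = eta[i] - eta[j]
        se = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        z = diff / se
        p_raw = 2 * stats.norm.sf(abs(z))
        p_adj = min(1.0, m * p_raw)
        rows.append({"group_1": names[i], "group_2": names[j],
                     "estimate": diff, "se": se, "z": z,
                     "p_raw": p_raw, "p_adj": p_adj,
                     "significant": p_adj <= alpha})
    table = pd.DataFrame(rows)
    sig = {(r["group_1"], r["group_2"]) for _, r in table.iterrows()
           if r["significant"]}
    letters = compact_letter_display(names, sig)
    return PairwiseContrasts(table, letters, alpha, m)


def compact_letter_display(groups, significant_pairs) -> dict:
    """Insert-and-absorb compact-letter display.

    ``significant_pairs`` is a set of (group, group) tuples (order
    irrelevant) that differ significantly.  Two groups share a letter iff
    they are NOT in ``significant_pairs``.  Letters are assigned
    alphabetically in the given group order.
    """
    groups = list(groups)
    sig = {frozenset(p) for p in significant_pairs}
    sets: list[frozenset] = [frozenset(groups)]
    for pair in sorted(sig, key=lambda s: tuple(sorted(s))):
        a, b = sorted(pair)
        expanded: list[frozenset] = []
        for s in sets:
            if a in s and b in s:
                expanded.extend((s - {a}, s - {b}))  # insert step
            else:
                expanded.append(s)
        # absorb: keep only maximal, non-empty, distinct sets
        expanded = [s for s in expanded if s]
        sets = [s for i, s in enumerate(expanded)
                if not any(s < o for o in expanded)
                and s not in expanded[:i]]
    # order letter sets by first group appearance for stable labelling
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


# ---------------------------------------------------------------------------
# log-normal / identity one-way ANOVA for diversity indices

@dataclass
class OneWayAnovaResults:
    """Ordinary one-way ANOVA, optionally on the log scale."""

    group_names: list
    estimates: pd.Series       # back-transformed group means when log scale
    se: pd.Series              # on the analysis scale
    f_stat: float
    p_value: float
    contrasts: pd.DataFrame
    letters: dict
    log_scale: bool

    def summary(self) -> str:
        scale = "ln(y)" if self.log_scale else "y"
        lines = [f"One-way ANOVA on {scale}: F = {self.f_stat:.3f}, "
                 f"P = {self.p_value:.4g}"]
        tab = pd.DataFrame({"estimate": self.estimates, "se": self.se,
                            "letters": pd.Series(self.letters)})
        lines.append(tab.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def lognormal_anova(y, groups, log_scale: bool = True,
                    alpha: float = 0.05) -> OneWayAnovaResults:
    """One-way ANOVA on ln(y) (or y), pairwise pooled-t contrasts, Bonferroni.

    With ``log_scale=True`` group estimates are back-transformed
    (geometric means ``exp(mean ln y)``); standard errors stay on the
    analysis scale.  Shannon diversity is conventionally analysed with
    ``log_scale=False``.
    """
    y = np.asarray(y, dtype=float)
    groups = pd.Series(groups)
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    if log_scale:
        if (y <= 0).any():
            raise ValueError("non-positive value under log scale")
        v = np.log(y)
    else:
        v = y
    samples = [v[(groups == g).values] for g in names]
    f_stat, p_value = stats.f_oneway(*samples)
    k = len(names)
    n = len(v)
    means = np.array([s.mean() for s in samples])
    ns = np.array([len(s) for s in samples])
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / (n - k)
    se = np.sqrt(mse / ns)
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        diff = means[i] - means[j]
        sed = np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
        t = diff / sed
        p_raw = 2 * stats.t.sf(abs(t), n - k)
        p_adj = min(1.0, m * p_raw)
        rows.append({"group_1": names[i], "group_2": names[j],
                     "estimate": diff, "se": sed, "t": t,
                     "p_raw": p_raw, "p_adj": p_adj,
                     "significant": p_adj <= alpha})
    contrasts = pd.DataFrame(rows)
    sig = {(r["group_1"], r["group_2"]) for _, r in contrasts.iterrows()
           if r["significant"]}
    letters = compact_letter_display(names, sig)
    estimates = pd.Series(np.exp(means) if log_scale else means, index=names)
    return OneWayAnovaResults(names, estimates, pd.Series(se, index=names),
                              float(f_stat), float(p_value), contrasts,
                              letters, log_scale)
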