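"""Rarefaction and alpha-diversity indices (richness, Shannon, inverse
Simpson, Fisher's alpha).

All indices are computed on counts rarefied without replacement to a common
depth (default 1,000 reads), one draw per sample, so richness is comparable
across samples of unequal sequencing depth.  Shannon uses natural log.
Fisher's alpha is the parameter of the log-series relation
``S = alpha * ln(1 + N / alpha)`` linking the number of genera S observed to
the number of reads N; it is obtained by bracketed root finding.  A finite
positive root exists iff ``1 <= S < N``; the degenerate case S = N is
reported missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tables import CountTable, InputError

logger = logging.getLogger("dyadcomm")


def rarefy(t: CountTable, depth: int = 1000, seed=None) -> CountTable:
    """Subsample every sample's reads without replacement to exactly ``depth``.

    Samples already at exactly ``depth`` are returned unchanged.  A sample
    below ``depth`` raises :class:`InputError` naming it (the read filter is
    expected to have removed it).  Reproducible given ``seed`` (an int or a
    ``numpy.random.Generator``).
    """
    rng = np.random.default_rng(seed)
    totals = t.total_reads
    low = totals.index[totals < depth]
    if len(low):
        raise InputError(
            f"sample {low[0]!r} has {totals[low[0]]} < {depth} reads; cannot rarefy"
        )
    out = np.empty_like(t.counts.values)
    for i, (sid, row) in enumerate(t.counts.iterrows()):
        if totals[sid] == depth:
            out[i] = row.values
        else:
            out[i] = rng.multivariate_hypergeometric(row.values, depth)
    rarefied = pd.DataFrame(out, index=t.counts.index, columns=t.counts.columns)
    return CountTable(rarefied, t.meta)


def _props(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise InputError("expected the counts of a single sample")
    if (x < 0).any():
        raise InputError("negative counts")
    total = x.sum()
    if total <= 0:
        raise InputError("all-zero sample")
    p = x[x > 0] / total
    return p


def richness(counts) -> int:
    """Number of genera with a positive count."""
    return int((np.asarray(counts) > 0).sum())


def shannon(counts) -> float:
    """H = -sum p ln p over genera with p > 0 (nats)."""
    p = _props(counts)
    return float(-(p * np.log(p)).sum())


def inverse_simpson(counts) -> float:
    """1 / sum p^2: the effective number of equally abundant genera."""
    p = _props(counts)
    return float(1.0 / (p ** 2).sum())


def fisher_alpha(S: int, N: int) -> float:
    """Solve ``S = alpha * ln(1 + N / alpha)`` for the unique alpha > 0.

    The map alpha -> alpha*ln(1 + N/alpha) increases from 0 (alpha -> 0) to N
    (alpha -> inf), so a finite root exists iff 1 <= S < N.
    """
    if S < 1:
        raise InputError("Fisher alpha requires at least one genus")
    if S > N:
        raise InputError("genus count cannot exceed read count")
    if S == N:
        raise InputError("no finite Fisher alpha when S = N (log-series degenerate)")

    def f(a: float) -> float:
        return a * np.log1p(N / a) - S

    lo = 1e-12
    # near S ~ N the root grows like N^2 / (2 (N - S))
    hi = max(10.0, 4.0 * N * N / max(N - S, 1))
    while f(hi) < 0:  # pragma: no cover - bracket is generous
        hi *= 10
    alpha = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    if abs(f(alpha)) >= 1e-8:
        raise RuntimeError("Fisher alpha root did not converge")
    return float(alpha)


def diversity_table(t: CountTable, depth: int = 1000, seed=None) -> pd.DataFrame:
    """One rarefaction draw per sample, then all four indices.

    Returns a per-sample DataFrame with columns ``richness``, ``shannon``,
    ``inv_simpson``, ``fisher_alpha`` plus the sample metadata; the depth and
    seed are recorded in ``DataFrame.attrs``.  Fisher's alpha is NaN with a
    logged warning for degenerate samples (S = N).
    """
    rare = rarefy(t, depth=depth, seed=seed)
    rows = []
    for sid in rare.sample_ids:
        c = rare.counts.loc[sid].values
        S = richness(c)
        N = int(c.sum())
        try:
            alpha = fisher_alpha(S, N)
        except InputError as exc:
            logger.warning("Fisher alpha undefined for sample %r: %s", sid, exc)
            alpha = np.nan
        rows.append({
            "richness": S,
            "shannon": shannon(c),
            "inv_simpson": inverse_simpson(c),
            "fisher_alpha": alpha,
        })
    out = pd.DataFrame(rows, index=rare.counts.index)
    out = pd.concat([out, rare.meta], axis=1)
    out.attrs["rarefaction_depth"] = depth
    out.attrs["seed"] = seed
    return out


def expected_rarefied_richness(counts, depth: int) -> float:
    """Closed-form E[richness] of rarefaction without replacement.

    For genus i with N_i of the sample's N reads, the probability that a
    without-replacement subsample of size d misses it is hypergeometric:
    C(N - N_i, d) / C(N, d).  Used as an independent oracle for
    :func:`rarefy`.
    """
    from scipy.special import gammaln

    x = np.asarray(counts, dtype=float)
    N = x.sum()
    if depth > N:
        raise InputError("depth exceeds sample total")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    es = 0.0
    for ni in x[x > 0]:
        if N - ni < depth:
            p_miss = 0.0
        else:
            p_miss = np.exp(log_comb(N - ni, depth) - log_comb(N, depth))
        es += 1.0 - p_miss
    return float(es)
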