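"""Core-taxa, unique-taxa, and top-N aggregation rules.

A genus is *core* within a scope (the whole dataset or one cohort) when it is
present (raw count > 0) in at least 90% of the scope's samples and its
scope-mean relative abundance is at least 0.1%.  Both boundaries are
inclusive.  A genus is *unique* to a cohort when it is detected in no other
cohort and in at least 10% of that cohort's samples.  The *aggregate set* is
the union over cohorts of each cohort's top-N genera by within-cohort mean
relative abundance, with everything else summed into an ``other`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, CountTable, InputError


@dataclass
class CoreCriteria:
    """Thresholds of the core rule (both inclusive).

    ``abundance_basis`` selects how "represents >= 0.1% of all identified
    taxa" is measured: ``"mean_relative"`` (default) uses the scope-mean
    per-sample relative abundance; ``"reads"`` uses the genus' share of the
    scope's total reads.
    """

    prevalence_min: float = 0.90
    abundance_min: float = 0.001
    abundance_basis: str = "mean_relative"

    def __post_init__(self) -> None:
        for name in ("prevalence_min", "abundance_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InputError(f"{name} must be in (0, 1]")
        if self.abundance_basis not in ("mean_relative", "reads"):
            raise InputError("abundance_basis must be 'mean_relative' or 'reads'")


@dataclass
class DesignationReport:
    """Per-scope prevalence/abundance screen plus the derived genus sets."""

    per_scope: dict            # scope -> DataFrame(prevalence %, mean_abundance, is_core)
    unique_taxa: dict          # cohort -> sorted genus list
    aggregate_set: list        # union of cohort top-N genera (no 'other')


def _scope_table(t: CountTable, scope: str | None) -> CountTable:
    if scope is None or scope == "overall":
        return t
    return t.subset_cohort(scope)


def prevalence(t: CountTable, scope: str | None = None, decimals: int = 1) -> pd.Series:
    """Percent of the scope's samples in which each genus has count > 0.

    Reported to ``decimals`` decimal places (the printed tables use one).
    """
    sub = _scope_table(t, scope)
    if sub.n_samples == 0:
        raise InputError(f"empty scope {scope!r}")
    pct = 100.0 * (sub.counts.values > 0).mean(axis=0)
    return pd.Series(np.round(pct, decimals), index=sub.genera, name="prevalence")


def mean_relative_abundance(t: CountTable, scope: str | None = None) -> pd.Series:
    """Scope-mean per-sample relative abundance of each genus (proportion)."""
    sub = _scope_table(t, scope)
    rel = sub.counts.div(sub.total_reads, axis=0)
    return rel.mean(axis=0).rename("mean_abundance")


def core_from_screen(prev_pct: pd.Series, abund: pd.Series,
                     criteria: CoreCriteria | None = None) -> list[str]:
    """Apply the core rule to a precomputed prevalence/abundance screen.

    ``prev_pct`` is in percent, ``abund`` a proportion.  Used both on real
    count tables and on the printed prevalence/mean fixtures.  Order:
    descending prevalence, genus name as tie-break.
    """
    c = criteria or CoreCriteria()
    ok = (prev_pct >= 100.0 * c.prevalence_min) & (abund.reindex(prev_pct.index) >= c.abundance_min)
    hits = prev_pct[ok]
    return list(hits.sort_index().sort_values(ascending=False, kind="stable").index)


def designate_core(t: CountTable, scope: str | None = None,
                   criteria: CoreCriteria | None = None) -> list[str]:
    """Genera passing both core thresholds within the scope."""
    c = criteria or CoreCriteria()
    prev = prevalence(t, scope, decimals=10)  # full precision for the decision
    if c.abundance_basis == "mean_relative":
        abund = mean_relative_abundance(t, scope)
    else:
        sub = _scope_table(t, scope)
        abund = sub.counts.sum(axis=0) / sub.counts.values.sum()
    return core_from_screen(prev, abund, c)


def designate_unique(t: CountTable, min_within: float = 0.10) -> dict[str, list[str]]:
    """Genera detected in exactly one cohort at >= ``min_within`` prevalence there."""
    cohorts = sorted(t.meta["cohort"].unique())
    if len(cohorts) < 2:
        raise InputError("unique-taxa designation requires >= 2 cohorts")
    present = {k: (t.subset_cohort(k).counts.values > 0) for k in cohorts}
    n_detected = pd.DataFrame(
        {k: present[k].any(axis=0) for k in cohorts}, index=t.genera
    )
    out: dict[str, list[str]] = {}
    for k in cohorts:
        frac_within = present[k].mean(axis=0)
        only_here = n_detected[k] & (n_detected.drop(columns=k).sum(axis=1) == 0)
        hits = [g for g, o, f in zip(t.genera, only_here, frac_within)
                if o and f >= min_within]
        if hits:
            out[k] = sorted(hits)
    return out


def aggregate_top_n(a: AbundanceTable, n: int = 10):
    """Union of per-cohort top-``n`` genera; the rest summed into ``other``.

    Ranking is by within-cohort mean relative abundance with ties broken by
    genus name.  Returns ``(aggregate_set, aggregated AbundanceTable)``; the
    aggregated rows preserve the original row sums exactly.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    cohorts = sorted(a.meta["cohort"].unique())
    agg: set[str] = set()
    for k in cohorts:
        means = a.subset_cohort(k).abund.mean(axis=0)
        ranked = means.sort_index().sort_values(ascending=False, kind="stable")
        agg.update(ranked.index[: min(n, len(ranked))])
    kept = [g for g in a.genera if g in agg]
    rest = [g for g in a.genera if g not in agg]
    out = a.abund[kept].copy()
    out["other"] = a.abund[rest].sum(axis=1) if rest else 0.0
    table = AbundanceTable(out, a.meta, a.zero_replaced, rowsum_atol=max(a.rowsum_atol, 1e-9))
    return kept, table


def designation_report(t: CountTable, criteria: CoreCriteria | None = None,
                       n_top: int = 10) -> DesignationReport:
    """Full screen: overall + per-cohort core, unique taxa, aggregate set."""
    criteria = criteria or CoreCriteria()
    scopes = ["overall"] + sorted(t.meta["cohort"].unique())
    per_scope = {}
    for scope in scopes:
        sc = None if scope == "overall" else scope
        prev = prevalence(t, sc)
        abund = mean_relative_abundance(t, sc)
        core = set(designate_core(t, sc, criteria))
        per_scope[scope] = pd.DataFrame({
            "prevalence": prev,
            "mean_abundance": abund,
            "is_core": [g in core for g in prev.index],
        })
    unique = designate_unique(t) if t.meta["cohort"].nunique() >= 2 else {}
    from .preprocess import relative_abundance
    agg_set, _ = aggregate_top_n(relative_abundance(t), n_top)
    return DesignationReport(per_scope, unique, agg_set)
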