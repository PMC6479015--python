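"""Sample read filter, relative-abundance transform, rounding, pruning, zero fill.

Canonical stage order (enforced by :func:`preprocess`):

1. drop samples with fewer than ``min_reads`` total reads (inclusive boundary:
   a sample with exactly ``min_reads`` reads is kept);
2. convert counts to per-sample proportions;
3. round proportions half-to-even to ``rounding_digits`` decimals and drop
   genera whose rounded abundance is zero in every sample;
4. replace remaining zeros with ``zero_fill`` so that downstream
   proportion-scale statistics (beta likelihood, logit transform) are defined.

Diversity calculations consume raw counts, never the zero-filled proportions;
zero replacement exists solely for proportion-scale statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tables import AbundanceTable, CountTable, InputError

logger = logging.getLogger("dyadcomm")


@dataclass
class PreprocessConfig:
    """Thresholds for the preprocessing stages.

    ``rounding_digits`` counts decimal digits on the proportion scale: the
    default 10 means granularity 1e-10, which keeps rounding compatible with
    the subsequent 1e-6 zero fill.  (Rounding to one decimal on the percent
    scale would zero out everything the fill is meant to rescue; the digit
    count is configurable for anyone preferring that reading.)
    """

    min_reads: int = 1000
    zero_fill: float = 1e-6
    rounding_digits: int = 10

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise InputError("min_reads must be >= 1")
        if not 0 < self.zero_fill < 1:
            raise InputError("zero_fill must be in (0, 1)")
        if self.rounding_digits < 1:
            raise InputError("rounding_digits must be >= 1")


def filter_min_reads(t: CountTable, cfg: PreprocessConfig | None = None) -> CountTable:
    """Keep samples with ``total_reads >= cfg.min_reads``."""
    cfg = cfg or PreprocessConfig()
    totals = t.total_reads
    keep = totals.index[totals >= cfg.min_reads]
    dropped = totals.index.difference(keep)
    if len(keep) == 0:
        raise InputError("no samples pass read filter")
    if len(dropped):
        logger.info(
            "read filter dropped %d sample(s) (< %d reads): %s; %d retained",
            len(dropped), cfg.min_reads, list(dropped)[:10], len(keep),
        )
    return t.select_samples(keep)


def relative_abundance(t: CountTable) -> AbundanceTable:
    """Divide each sample's counts by its total reads."""
    totals = t.total_reads
    if (totals == 0).any():
        sid = totals.index[totals == 0][0]
        raise InputError(f"sample {sid!r} has zero total reads (filter first)")
    abund = t.counts.div(totals, axis=0)
    return AbundanceTable(abund, t.meta, zero_replaced=False)


def round_and_prune(a: AbundanceTable, cfg: PreprocessConfig | None = None) -> AbundanceTable:
    """Round half-to-even to ``rounding_digits`` decimals; drop all-zero genera."""
    cfg = cfg or PreprocessConfig()
    if a.zero_replaced:
        raise InputError("round_and_prune must run before zero replacement")
    rounded = np.round(a.abund.values, cfg.rounding_digits)
    keep = rounded.sum(axis=0) > 0
    dropped = [g for g, k in zip(a.genera, keep) if not k]
    if dropped:
        logger.info("pruned %d all-zero genera after rounding: %s",
                    len(dropped), dropped[:10])
    out = a.abund.copy()
    out.loc[:, :] = rounded
    out = out.loc[:, keep]
    # per-entry rounding perturbs row sums by up to G * 0.5 * 10^-digits
    atol = max(1e-9, out.shape[1] * 10.0 ** -cfg.rounding_digits)
    return AbundanceTable(out, a.meta, zero_replaced=False, rowsum_atol=atol)


def zero_replace(a: AbundanceTable, cfg: PreprocessConfig | None = None) -> AbundanceTable:
    """Replace every zero proportion with ``cfg.zero_fill``."""
    cfg = cfg or PreprocessConfig()
    vals = a.abund.values.copy()
    n_zero = int((vals == 0).sum())
    vals[vals == 0] = cfg.zero_fill
    logger.info("zero replacement: %d entries set to %g", n_zero, cfg.zero_fill)
    out = a.abund.copy()
    out.loc[:, :] = vals
    return AbundanceTable(out, a.meta, zero_replaced=True)


def preprocess(t: CountTable, cfg: PreprocessConfig | None = None):
    """Run the four canonical stages; returns (AbundanceTable, provenance dict).

    The provenance dict records the sample/genus counts after each stage so a
    run can be audited.
    """
    cfg = cfg or PreprocessConfig()
    prov = {"input": {"samples": t.n_samples, "genera": len(t.genera)}}
    filtered = filter_min_reads(t, cfg)
    prov["filter_min_reads"] = {"samples": filtered.n_samples,
                                "min_reads": cfg.min_reads}
    rel = relative_abundance(filtered)
    pruned = round_and_prune(rel, cfg)
    prov["round_and_prune"] = {"genera": len(pruned.genera),
                               "rounding_digits": cfg.rounding_digits}
    filled = zero_replace(pruned, cfg)
    prov["zero_replace"] = {"zero_fill": cfg.zero_fill,
                            "replaced": int((pruned.abund.values == 0).sum())}
    return filled, prov
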