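"""Count-table data model, delimited-text I/O, dyad pairing, and packaged fixtures.

The pipeline's raw input is a genus-level read-count table (samples x genera,
non-negative integers) together with a sample-metadata table assigning each
sample a cohort, a mother-infant dyad id, and a niche (``milk`` or ``feces``).
Files are tab-delimited UTF-8 with samples as rows and genera as columns;
genus names are opaque strings ("Escherichia/Shigella" is a single token).

Three printed summary tables from the multi-cohort milk/feces study are
packaged as transcribed fixtures: cohort-mean relative abundances of the
aggregate genera in infant feces (28 genera) and milk (29 genera), and the
core-genus prevalence table (percent of samples with quantifiable amounts).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("dyadcomm")

#: Cohort labels of the study, in printed column order.
COHORTS = ("ETR", "ETU", "GBR", "GBU", "GN", "KE", "PE", "SP", "SW", "USC", "USW")

NICHES = ("milk", "feces")

META_COLUMNS = ("cohort", "dyad_id", "niche")

_FIXTURE_FILES = {
    "T2_feces_means": "table2_feces_cohort_means.tsv",
    "T5_milk_means": "table5_milk_cohort_means.tsv",
    "T3_prevalence": "table3_core_prevalence.tsv",
}

#: Per-cohort sample counts behind the printed prevalence table, plus totals.
PREVALENCE_SAMPLE_SIZES = {
    "feces": dict(zip(COHORTS, (40, 32, 38, 38, 32, 42, 42, 37, 23, 12, 41)), Overall=377),
    "milk": dict(zip(COHORTS, (40, 34, 39, 38, 37, 42, 43, 40, 23, 19, 39)), Overall=394),
}


class InputError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class CountTable:
    """Samples x genera non-negative integer read counts with sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer matrix indexed by sample id, columns are genus names.
    meta : pandas.DataFrame
        Indexed by sample id with columns ``cohort``, ``dyad_id`` and
        ``niche``.  ``dyad_id`` may be missing (NaN) for unpaired samples;
        dyad operations skip such samples.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.meta = self.meta.loc[self.counts.index, list(META_COLUMNS)].copy()
        _validate_counts(self.counts)
        _validate_meta(self.meta)

    # -- basic accessors -------------------------------------------------
    @property
    def genera(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total_reads(self) -> pd.Series:
        """Per-sample row sums (reads)."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def select_samples(self, ids) -> "CountTable":
        ids = list(ids)
        return CountTable(self.counts.loc[ids], self.meta.loc[ids])

    def select_genera(self, genera) -> "CountTable":
        return CountTable(self.counts[list(genera)], self.meta)

    def subset_cohort(self, cohort: str) -> "CountTable":
        keep = self.meta.index[self.meta["cohort"] == cohort]
        if len(keep) == 0:
            raise InputError(f"no samples in cohort {cohort!r}")
        return self.select_samples(keep)

    def split_by_niche(self) -> dict[str, "CountTable"]:
        out = {}
        for niche in NICHES:
            keep = self.meta.index[self.meta["niche"] == niche]
            if len(keep):
                out[niche] = self.select_samples(keep)
        return out


@dataclass
class AbundanceTable:
    """Row-normalized proportions on the same sample/genus frame.

    ``zero_replaced`` records whether zero proportions have been substituted
    by a small positive constant (after which rows sum to slightly more
    than 1).
    """

    abund: pd.DataFrame
    meta: pd.DataFrame
    zero_replaced: bool = False
    rowsum_atol: float = 1e-9  # loosened after per-entry rounding

    def __post_init__(self) -> None:
        self.abund = self.abund.astype(float).copy()
        self.meta = self.meta.loc[self.abund.index, list(META_COLUMNS)].copy()
        if (self.abund.values < 0).any():
            raise InputError("abundances must be non-negative")
        if not self.zero_replaced:
            sums = self.abund.sum(axis=1).values
            if len(sums) and not np.allclose(sums, 1.0, atol=self.rowsum_atol):
                bad = self.abund.index[np.abs(sums - 1.0) > self.rowsum_atol][0]
                raise InputError(f"row {bad!r} does not sum to 1")

    @property
    def genera(self) -> list[str]:
        return list(self.abund.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abund.index)

    def select_samples(self, ids) -> "AbundanceTable":
        ids = list(ids)
        return AbundanceTable(self.abund.loc[ids], self.meta.loc[ids],
                              self.zero_replaced, self.rowsum_atol)

    def subset_cohort(self, cohort: str) -> "AbundanceTable":
        keep = self.meta.index[self.meta["cohort"] == cohort]
        return AbundanceTable(self.abund.loc[keep], self.meta.loc[keep],
                              self.zero_replaced, self.rowsum_atol)


@dataclass
class PrintedFixture:
    """A transcription of one of the study's printed summary tables."""

    table_id: str
    values: pd.DataFrame
    sha256: str = ""


@dataclass
class DyadPairing:
    """Matched mother-infant dyads plus the leftovers on either side."""

    pairs: list  # (dyad_id, milk sample id, feces sample id), sorted by dyad_id
    unpaired_milk: list
    unpaired_feces: list

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def dyad_ids(self) -> list:
        return [p[0] for p in self.pairs]

    @property
    def milk_ids(self) -> list:
        return [p[1] for p in self.pairs]

    @property
    def feces_ids(self) -> list:
        return [p[2] for p in self.pairs]


# ---------------------------------------------------------------------------
# validation helpers

def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise InputError(f"duplicate sample_id {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise InputError(f"duplicate genus {dup!r}")
    arr = counts.values
    if not np.issubdtype(arr.dtype, np.number):
        raise InputError("counts must be numeric")
    if np.isnan(arr.astype(float)).any():
        i, j = np.argwhere(np.isnan(arr.astype(float)))[0]
        raise InputError(
            f"missing count at sample {counts.index[i]!r}, genus {counts.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise InputError(
            f"negative count {arr[i, j]} at sample {counts.index[i]!r}, "
            f"genus {counts.columns[j]!r}"
        )
    if not np.array_equal(arr, np.floor(arr)):
        frac = arr != np.floor(arr)
        i, j = np.argwhere(frac)[0]
        raise InputError(
            f"non-integer count {arr[i, j]} at sample {counts.index[i]!r}, "
            f"genus {counts.columns[j]!r}"
        )


def _validate_meta(meta: pd.DataFrame) -> None:
    bad = set(meta["niche"].dropna()) - set(NICHES)
    if bad:
        raise InputError(f"malformed niche label(s): {sorted(bad)!r}")
    if meta["cohort"].isna().any() or (meta["cohort"].astype(str) == "").any():
        sid = meta.index[meta["cohort"].isna() | (meta["cohort"].astype(str) == "")][0]
        raise InputError(f"sample {sid!r} has an empty cohort")
    # at most one milk and one feces sample per dyad
    with_dyad = meta.dropna(subset=["dyad_id"])
    dup = with_dyad.duplicated(subset=["dyad_id", "niche"])
    if dup.any():
        row = with_dyad[dup].iloc[0]
        raise InputError(
            f"dyad {row['dyad_id']!r} has more than one {row['niche']} sample"
        )


# ---------------------------------------------------------------------------
# I/O

def read_count_table(counts_path, meta_path) -> CountTable:
    """Read a TSV count matrix plus a TSV metadata table into a ``CountTable``.

    The counts file has a header row of genus names and one row per sample
    keyed by sample id in the first column.  The metadata file supplies
    ``cohort``, ``dyad_id`` and ``niche`` per sample id.  Samples present in
    the counts but absent from the metadata raise :class:`InputError`;
    metadata-only samples are ignored with a logged warning.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    meta.index = meta.index.astype(str)
    missing_meta = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_meta:
        raise InputError(f"metadata file lacks column(s) {missing_meta}")
    absent = counts.index.difference(meta.index)
    if len(absent):
        raise InputError(
            f"sample(s) present in counts but absent from metadata: {list(absent)[:5]}"
        )
    extra = meta.index.difference(counts.index)
    if len(extra):
        logger.warning(
            "ignoring %d metadata-only sample(s): %s", len(extra), list(extra)[:5]
        )
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric count value: {exc}") from exc
    table = CountTable(counts, meta.loc[counts.index])
    table.counts = table.counts.astype(np.int64)
    return table


def write_count_table(table: CountTable, counts_path, meta_path) -> None:
    """Inverse of :func:`read_count_table` (round-trips counts and metadata)."""
    table.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
    table.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# dyad pairing

def pair_dyads(milk: CountTable, feces: CountTable) -> DyadPairing:
    """Match milk and feces samples sharing a dyad id.

    Returns the dyads possessing both niches, sorted by dyad id, plus the
    unpaired sample ids on each side.  Samples without a dyad id are never
    paired.
    """
    def _dyad_map(t: CountTable, niche: str) -> dict:
        sub = t.meta[t.meta["niche"] == niche].dropna(subset=["dyad_id"])
        return dict(zip(sub["dyad_id"], sub.index))

    milk_map = _dyad_map(milk, "milk")
    feces_map = _dyad_map(feces, "feces")
    shared = sorted(set(milk_map) & set(feces_map))
    pairs = [(d, milk_map[d], feces_map[d]) for d in shared]
    paired_milk = {milk_map[d] for d in shared}
    paired_feces = {feces_map[d] for d in shared}
    unpaired_milk = [s for s in milk.sample_ids if s not in paired_milk]
    unpaired_feces = [s for s in feces.sample_ids if s not in paired_feces]
    return DyadPairing(pairs, unpaired_milk, unpaired_feces)


# ---------------------------------------------------------------------------
# packaged fixtures

def fixture_path(table_id: str) -> Path:
    if table_id not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown table_id {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}"
        )
    return Path(resources.files("dyadcomm.fixtures") / _FIXTURE_FILES[table_id])


def load_fixture(table_id: str) -> PrintedFixture:
    """Load one of the packaged printed-table transcriptions.

    ``T2_feces_means`` and ``T5_milk_means`` return genus x cohort matrices
    of cohort-mean relative abundances (%); ``T3_prevalence`` returns a
    (niche, genus) x cohort matrix of prevalence percentages including the
    ``Overall`` column.
    """
    path = fixture_path(table_id)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if table_id == "T3_prevalence":
        df = pd.read_csv(path, sep="\t").set_index(["niche", "genus"])
    else:
        df = pd.read_csv(path, sep="\t", index_col="genus")
    return PrintedFixture(table_id, df, digest)
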