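"""Count-table containers, I/O and sample quality control.

A :class:`SampleTable` pairs a samples x taxa count matrix with per-sample
metadata (plant, sampling date, optional replicate link).  The QC chain
mirrors standard practice for longitudinal amplicon surveys: drop samples
below a minimum read depth (default 10 000 reads), average replicate
samples from the same sampling point on the relative-abundance scale,
aggregate ASVs to species (keeping unclassified ASVs as their own
species-level units), and retain only species exceeding a maximum
relative abundance of 0.05% in at least one sample.

Count-based operations (rarefaction) must run before replicate merging:
the merged table is proportion-valued and flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RANKS = ["Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species"]

__all__ = [
    "SampleTable",
    "TaxonomyTable",
    "filter_min_reads",
    "merge_replicates",
    "aggregate_to_species",
    "retain_abundant_species",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
]


@dataclass
class SampleTable:
    """Samples x taxa abundance matrix with sample annotations.

    ``counts`` has sample ids as the row index and taxon ids as columns.
    ``meta`` is indexed by sample id with columns ``plant``, ``date``
    (datetime), and optional ``replicate_of`` (the sample id of the
    primary sample at the same sampling point, NaN otherwise).
    ``is_proportions`` marks tables whose rows are relative abundances
    (after replicate merging) rather than integer reads.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    is_proportions: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not self.counts.index.equals(self.meta.index):
            missing = self.counts.index.difference(self.meta.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
            self.meta = self.meta.loc[self.counts.index]
        if not self.is_proportions:
            vals = self.counts.to_numpy()
            if np.any(vals < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("count table must hold integers")
        self.meta = self.meta.copy()
        self.meta["date"] = pd.to_datetime(self.meta["date"], format="ISO8601")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        if self.is_proportions:
            return self.counts
        sums = self.counts.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError("zero-read sample present; run filter_min_reads first")
        return self.counts.div(sums, axis=0)

    def subset_plant(self, plant: str) -> "SampleTable":
        keep = self.meta["plant"] == plant
        return replace(
            self, counts=self.counts.loc[keep], meta=self.meta.loc[keep]
        )


@dataclass
class TaxonomyTable:
    """Seven-rank lineage per taxon id (Kingdom .. Species).

    The species label may be missing (NaN/empty) for ASVs classified
    only to a higher rank.
    """

    ranks: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.ranks.columns]
        if missing:
            raise ValueError(f"taxonomy table lacks rank columns: {missing}")

    def species_label(self, taxon_id: str) -> str | None:
        val = self.ranks.at[taxon_id, "Species"]
        if pd.isna(val) or val == "":
            return None
        return str(val)


def filter_min_reads(t: SampleTable, min_reads: int = 10_000) -> SampleTable:
    """Discard samples with fewer than ``min_reads`` total reads.

    The comparison is strict ("less than"): a sample with exactly
    ``min_reads`` reads is retained.  Idempotent.
    """
    if t.is_proportions:
        raise ValueError("read filter applies to count tables, not proportions")
    sums = t.counts.sum(axis=1)
    keep = sums >= min_reads
    dropped = t.sample_ids[~keep]
    if len(dropped):
        log.info("filter_min_reads: dropped %d sample(s): %s",
                 len(dropped), ", ".join(map(str, dropped[:10])))
    if not keep.any():
        raise ValueError("all samples fall below the read threshold")
    return replace(t, counts=t.counts.loc[keep], meta=t.meta.loc[keep])


def merge_replicates(t: SampleTable) -> SampleTable:
    """Average replicate samples from the same sampling point.

    Replicates are linked by the ``replicate_of`` metadata column.  Each
    group collapses to one pseudo-sample whose per-taxon value is the
    arithmetic mean of the replicates' relative abundances, so the
    output is proportion-valued (rows sum to 1).  Groups must share
    plant and date.
    """
    rel = t.relative()
    meta = t.meta
    if "replicate_of" in meta.columns:
        anchor = meta["replicate_of"].where(meta["replicate_of"].notna(),
                                            pd.Series(meta.index, index=meta.index))
        # an anchor dropped earlier (e.g. by the read filter) leaves its
        # replicate standing alone as its own sampling point
        anchor = anchor.where(anchor.isin(meta.index),
                              pd.Series(meta.index, index=meta.index))
    else:
        anchor = pd.Series(meta.index, index=meta.index)
    for a, grp in meta.groupby(anchor):
        if grp["plant"].nunique() > 1 or grp["date"].nunique() > 1:
            raise ValueError(f"replicate group {a!r} spans plants or dates")
    merged = rel.groupby(anchor).mean()
    merged.index.name = t.counts.index.name
    # keep original sample order of the anchors
    order = [s for s in t.sample_ids if s in merged.index]
    merged = merged.loc[order]
    new_meta = meta.loc[order, [c for c in meta.columns if c != "replicate_of"]]
    return SampleTable(counts=merged, meta=new_meta, is_proportions=True)


def aggregate_to_species(t: SampleTable, tax: TaxonomyTable) -> SampleTable:
    """Sum ASV columns sharing a species label; keep unclassified ASVs.

    ASVs without a species-level classification remain separate columns
    keyed by their own taxon id (they are treated as distinct
    species-level units at their lowest classified rank).  Per-sample
    totals are conserved exactly.
    """
    missing = t.taxon_ids.difference(tax.ranks.index)
    if len(missing):
        raise ValueError(f"taxa absent from taxonomy: {list(missing)[:5]}")
    species = tax.ranks.loc[t.taxon_ids, "Species"]
    keys = [
        str(s) if (pd.notna(s) and s != "") else str(tid)
        for tid, s in zip(t.taxon_ids, species)
    ]
    agg = t.counts.T.groupby(pd.Index(keys, name="species")).sum().T
    return replace(t, counts=agg)


def retain_abundant_species(
    t: SampleTable, threshold: float = 0.0005
) -> list[str]:
    """Species whose maximum per-sample relative abundance exceeds ``threshold``.

    The comparison is strict (> 0.05% by default): a species sitting at
    exactly the threshold in every sample is dropped.
    """
    rel = t.relative()
    keep = rel.max(axis=0) > threshold
    return [str(c) for c in rel.columns[keep]]


# --- I/O -----------------------------------------------------------------

def read_counts(path, taxa_as_rows: bool = False, sep: str = "\t") -> pd.DataFrame:
    """Read a count table (samples as rows unless ``taxa_as_rows``)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.T if taxa_as_rows else df


def write_counts(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata CSV (sample_id, plant, date, replicate_of)."""
    meta = pd.read_csv(path, index_col=0)
    meta["date"] = pd.to_datetime(meta["date"], format="ISO8601")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path)


def read_taxonomy(path, sep: str = "\t") -> TaxonomyTable:
    return TaxonomyTable(pd.read_csv(path, sep=sep, index_col=0))


def write_taxonomy(tax: TaxonomyTable, path, sep: str = "\t") -> None:
    tax.ranks.to_csv(path, sep=sep)
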