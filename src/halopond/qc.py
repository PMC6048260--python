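"""Quality filters applied to raw OTU counts before any analysis.

Pipeline order: low-abundance OTU removal (min total reads), contaminant
(e.g. chloroplast) removal, shallow-sample removal.  Filters operate on raw
counts; relative abundances are derived afterwards.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .containers import CountTable, TaxonomyTable


def filter_min_total(table: CountTable, min_total: int = 10) -> CountTable:
    """Drop OTUs whose total read count across all samples is below ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.counts.sum(axis=1) >= min_total
    if not keep.any():
        warnings.warn("min-total filter removed every OTU", stacklevel=2)
    return table.with_counts(table.counts.loc[keep], f"filter_min_total({min_total})")


def remove_flagged_otus(
    table: CountTable, tax: TaxonomyTable, flag: str = "chloroplast"
) -> tuple[CountTable, pd.Series]:
    """Remove contaminant-flagged OTUs; report the read fraction removed per sample.

    Every OTU in the table must be present in the taxonomy; an unknown OTU is
    an error (it cannot be judged clean).
    """
    if not flag:
        raise ValueError("flag label must be non-empty")
    missing = set(table.otu_ids) - set(tax.otu_ids)
    if missing:
        raise KeyError(f"OTUs missing from taxonomy: {sorted(missing)[:5]}")
    flagged = [o for o in table.otu_ids if o in set(tax.flagged(flag))]
    totals = table.counts.sum(axis=0)
    flagged_counts = table.counts.loc[flagged].sum(axis=0)
    removed_fraction = flagged_counts.div(totals).where(totals > 0, 0.0)
    removed_fraction.name = "removed_fraction"
    kept = table.counts.drop(index=flagged)
    return table.with_counts(kept, f"remove_flagged_otus({flag!r})"), removed_fraction


def drop_shallow_samples(table: CountTable, min_depth: int = 500) -> CountTable:
    """Drop samples with fewer than ``min_depth`` total reads."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    keep = table.sample_depths() >= min_depth
    if not keep.any():
        raise ValueError("every sample falls below min_depth")
    new = CountTable(
        counts=table.counts.loc[:, keep],
        metadata=table.metadata.loc[keep],
        provenance=table.provenance + (f"drop_shallow_samples({min_depth})",),
    )
    return new


def relative_abundance(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Column-normalise counts to per-sample fractions (each column sums to 1)."""
    counts = table.counts if isinstance(table, CountTable) else table
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-sum samples: {list(zero.index)}")
    return counts / totals
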