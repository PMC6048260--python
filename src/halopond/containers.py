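"""In-memory containers for the pond-survey pipeline.

The central object is :class:`CountTable`, an integer OTU x sample count
matrix bundled with per-sample metadata (pond, water/sediment fraction,
salinity in % w/v).  Taxonomy lives in :class:`TaxonomyTable`, a per-OTU
table of rank labels plus an optional contaminant flag (e.g. "chloroplast").
Both are thin, validated wrappers around pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
FRACTIONS = ("water", "sediment")

METADATA_COLUMNS = ("pond", "fraction", "salinity_percent")


@dataclass
class CountTable:
    """OTU x sample count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers, index = OTU ids, columns = sample ids.
    metadata
        DataFrame indexed by sample id with columns ``pond``, ``fraction``
        (water or sediment) and ``salinity_percent`` (>= 0).
    provenance
        Ordered record of the filters already applied to this table.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate OTU ids")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(c.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if (self.metadata["salinity_percent"] < 0).any():
            raise ValueError("negative salinity")
        bad = set(self.metadata["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fraction labels: {sorted(bad)}")
        # keep metadata aligned and restricted to present samples
        self.metadata = self.metadata.loc[list(c.columns)]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def with_counts(self, counts: pd.DataFrame, step: str | None = None) -> "CountTable":
        """Return a new table with replaced counts and an appended provenance step."""
        prov = self.provenance + ((step,) if step else ())
        return CountTable(counts=counts, metadata=self.metadata, provenance=prov)

    def site_of(self, sample_id: str) -> str:
        row = self.metadata.loc[sample_id]
        return f"{row['pond']}-{row['fraction']}"

    def sites(self) -> pd.Series:
        """Sample -> site label (pond-fraction), the replicate grouping unit."""
        return self.metadata["pond"].astype(str) + "-" + self.metadata["fraction"].astype(str)


@dataclass
class TaxonomyTable:
    """Per-OTU rank labels (domain..genus, coarse to fine) plus contaminant flag.

    ``table`` is indexed by OTU id; rank columns may carry "unclassified".
    ``flag`` is an empty string for clean OTUs, otherwise the contaminant
    source label (e.g. "chloroplast").
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate OTU ids in taxonomy")
        for r in RANKS:
            if r not in self.table.columns:
                raise ValueError(f"taxonomy missing rank column {r!r}")
        if "flag" not in self.table.columns:
            self.table = self.table.assign(flag="")
        self.table["flag"] = self.table["flag"].fillna("")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.table.index)

    def flagged(self, flag: str) -> list[str]:
        """OTU ids carrying the given contaminant flag."""
        return list(self.table.index[self.table["flag"] == flag])

    def rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.table[rank]

    def lineage(self) -> pd.Series:
        return self.table[list(RANKS)].agg(";".join, axis=1)


def make_metadata(
    sample_ids: list[str],
    ponds: list[str],
    fractions: list[str],
    salinities: list[float],
) -> pd.DataFrame:
    """Assemble a sample metadata frame from parallel lists."""
    return pd.DataFrame(
        {
            "pond": ponds,
            "fraction": fractions,
            "salinity_percent": salinities,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
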