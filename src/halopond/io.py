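"""Readers and writers for the plain-text interchange formats.

OTU table: TSV, first column ``otu_id``, remaining columns sample ids,
integer cells.  Taxonomy: ``otu_id<TAB>domain;...;genus<TAB>flag`` (flag may
be empty).  Metadata: ``sample_id<TAB>pond<TAB>fraction<TAB>salinity_percent``.
Proteins: FASTA plus an annotation TSV ``protein_id<TAB>cazy_family<TAB>sample_id``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import RANKS, CountTable, TaxonomyTable


def read_count_table(otu_path: str | Path, metadata_path: str | Path) -> CountTable:
    counts = pd.read_csv(otu_path, sep="\t", index_col="otu_id")
    counts.index = counts.index.astype(str)
    meta = read_metadata(metadata_path)
    return CountTable(counts=counts.astype(int), metadata=meta)


def write_count_table(table: CountTable, otu_path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "otu_id"
    out.to_csv(otu_path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta.index = meta.index.astype(str)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    raw = pd.read_csv(
        path, sep="\t", header=0, names=["otu_id", "lineage", "flag"], dtype=str
    ).fillna("")
    ranks = raw["lineage"].str.split(";", expand=True).reindex(columns=range(len(RANKS)))
    ranks.columns = list(RANKS)
    ranks = ranks.fillna("unclassified").replace("", "unclassified")
    tab = ranks.assign(flag=raw["flag"].values)
    tab.index = pd.Index(raw["otu_id"].astype(str), name="otu_id")
    return TaxonomyTable(tab)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "otu_id": tax.table.index,
            "lineage": tax.lineage().values,
            "flag": tax.table["flag"].values,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_proteins(fasta_path: str | Path, annotation_path: str | Path):
    """Read a protein FASTA plus CAZy annotation TSV into ProteinRecord objects."""
    from .cazymes import ProteinRecord

    ann = pd.read_csv(
        annotation_path, sep="\t", header=0,
        names=["protein_id", "cazy_family", "sample_id"], dtype=str,
    ).set_index("protein_id")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in ann.index:
            raise ValueError(f"protein {rec.id!r} missing from annotation table")
        row = ann.loc[rec.id]
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                cazy_family=row["cazy_family"],
                sample_id=row["sample_id"],
            )
        )
    return records


def write_proteins(records, fasta_path: str | Path, annotation_path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "protein_id": [r.id for r in records],
            "cazy_family": [r.cazy_family for r in records],
            "sample_id": [r.sample_id for r in records],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str) -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
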