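"""Alpha diversity (richness, Shannon entropy, evenness) and Bray-Curtis
sample clustering.

Shannon entropy is reported in nats.  Evenness is Pielou's H/ln(S); for a
sample with one or zero observed OTUs the ratio is 0/0 and is defined as 0
so the metric stays total.  Sample clustering builds an agglomerative
dendrogram (average linkage by default) on the Bray-Curtis dissimilarity
matrix and cuts it at a fixed height; groups are lettered A, B, ... in
order of first sample appearance.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .containers import CountTable


def diversity_metrics(table: CountTable) -> pd.DataFrame:
    """Per-sample observed richness, Shannon H (nats) and evenness H/ln(S)."""
    counts = table.counts.to_numpy(dtype=float)
    if counts.size == 0:
        raise ValueError("empty count table")
    totals = counts.sum(axis=0)
    richness = (counts > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    evenness = np.where(richness > 1, shannon / np.log(np.maximum(richness, 2)), 0.0)
    return pd.DataFrame(
        {
            "observed_richness": richness.astype(int),
            "shannon_H": shannon,
            "shannon_evenness": evenness,
        },
        index=table.counts.columns,
    )


def bray_curtis(data: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples: 1 - 2*sum(min)/(sum(a)+sum(b))."""
    mat = data.counts if isinstance(data, CountTable) else data
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = mat.to_numpy(dtype=float).T  # samples x OTUs
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


def _letters(i: int) -> str:
    # A..Z, then AA, AB, ...
    s = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        s = string.ascii_uppercase[rem] + s
    return s


@dataclass
class SampleClustering:
    """Result of cutting the Bray-Curtis dendrogram at a fixed height."""

    dissimilarity: pd.DataFrame
    linkage_matrix: np.ndarray
    method: str
    cut: float
    labels: pd.Series  # sample -> letter label

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = TreeNode.from_linkage_matrix(
            self.linkage_matrix, list(self.dissimilarity.index)
        )
        return str(tree).strip()


def cluster_samples(
    dist: pd.DataFrame, cut: float = 0.6, method: str = "average"
) -> SampleClustering:
    """Agglomerate samples on a dissimilarity matrix and cut at ``cut``.

    Two samples share a letter iff they are joined at cophenetic height <= cut.
    """
    if not 0 <= cut <= 1:
        raise ValueError("cut must be in [0, 1]")
    condensed = squareform(dist.to_numpy(), checks=False)
    z = linkage(condensed, method=method)
    raw = fcluster(z, t=cut, criterion="distance")
    # relabel in order of first appearance over the sample order
    mapping: dict[int, str] = {}
    for cl in raw:
        if cl not in mapping:
            mapping[cl] = _letters(len(mapping))
    labels = pd.Series([mapping[c] for c in raw], index=dist.index, name="cluster")
    return SampleClustering(
        dissimilarity=dist, linkage_matrix=z, method=method, cut=cut, labels=labels
    )
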