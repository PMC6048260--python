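"""Co-occurrence "seed bank" sub-network analysis.

The procedure tracks groups of OTUs that keep a common relative-abundance
profile across sample sites — candidate microbial seed banks along the
salinity gradient.  It is deliberately not an interaction-inference method:
in samples drawn from very different environments, co-occurrence reflects
shared habitat preference.

Pipeline: prevalence-filter the QC'd count table (count strictly greater
than ``min_reads`` in at least ``min_samples`` samples), correlate OTU
relative-abundance profiles over all retained samples (zeros included),
Benjamini-Hochberg adjust the two-sided p-values over every unique pair
tested, keep edges with r > r_min and q < q_max (both strict), and read
sub-networks off as connected components.  Components with more than
``min_major_nodes`` nodes are "major" and lettered A, B, ... by descending
node count; everything else is "unaffiliated".

The procedure is wrapped as :class:`CooccurrenceModel`, whose ``fit()``
returns a :class:`CooccurrenceResults` carrying the edge table (r, p, q per
edge), the OTU -> sub-network assignment, per-sample sub-network
abundances, and a ``summary()`` table.

Known limitation: Pearson correlation on relative abundances ignores
compositional coupling between OTUs; a compositionality-aware estimator
(SparCC-style) is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountTable, TaxonomyTable
from .diversity import _letters
from .qc import relative_abundance
from .stats import bh_adjust, pearson_correlation

UNAFFILIATED = "unaffiliated"


def prevalence_filter(
    table: CountTable, min_reads: int = 10, min_samples: int = 5
) -> CountTable:
    """Keep OTUs observed with more than ``min_reads`` reads (strict) in at
    least ``min_samples`` samples."""
    if min_samples > table.n_samples:
        raise ValueError("min_samples exceeds the number of samples")
    hits = (table.counts > min_reads).sum(axis=1)
    keep = hits >= min_samples
    return table.with_counts(
        table.counts.loc[keep], f"prevalence_filter({min_reads},{min_samples})"
    )


def correlate_pairs(fractions: pd.DataFrame) -> pd.DataFrame:
    """Unique unordered OTU pairs with Pearson r, p and BH q.

    BH runs once over every pair with a defined correlation; pairs involving
    a zero-variance OTU are dropped (no edge possible).
    """
    r, p = pearson_correlation(fractions)
    ids = np.asarray(fractions.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    rv = r.to_numpy()[iu, ju]
    pv = p.to_numpy()[iu, ju]
    ok = np.isfinite(pv)
    pairs = pd.DataFrame(
        {
            "otu_a": ids[iu][ok],
            "otu_b": ids[ju][ok],
            "r": rv[ok],
            "p": pv[ok],
        }
    )
    pairs["q"] = bh_adjust(pairs["p"].to_numpy()) if len(pairs) else pairs["p"]
    return pairs


def build_cooccurrence_graph(
    pairs: pd.DataFrame,
    nodes: list[str],
    r_min: float = 0.98,
    q_max: float = 0.05,
) -> nx.Graph:
    """Graph over ``nodes`` with an edge iff r > r_min and q < q_max (strict)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    sel = pairs[(pairs["r"] > r_min) & (pairs["q"] < q_max)]
    for row in sel.sort_values(["otu_a", "otu_b"]).itertuples(index=False):
        g.add_edge(row.otu_a, row.otu_b, r=float(row.r), p=float(row.p), q=float(row.q))
    return g


def extract_subnetworks(graph: nx.Graph, min_major_nodes: int = 10) -> pd.Series:
    """Label connected components: majors (> min_major_nodes nodes) get
    letters by descending size (ties broken by smallest member OTU id);
    all remaining nodes are "unaffiliated"."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    majors = [c for c in comps if len(c) > min_major_nodes]
    majors.sort(key=lambda c: (-len(c), c[0]))
    assign = {n: UNAFFILIATED for n in graph.nodes}
    for i, comp in enumerate(majors):
        lab = _letters(i)
        for n in comp:
            assign[n] = lab
    return pd.Series(assign, name="subnetwork").sort_index()


def subnetwork_abundance(assign: pd.Series, fractions: pd.DataFrame) -> pd.DataFrame:
    """Summed relative abundance of each sub-network label per sample.

    Rows are the major labels plus "unaffiliated"; any relative-abundance
    mass belonging to OTUs absent from ``assign`` (dropped by the prevalence
    filter) is reported in a "filtered" row so each column totals 1.
    """
    missing = set(assign.index) - set(fractions.index)
    if missing:
        raise KeyError(f"assigned OTUs missing from fractions: {sorted(missing)[:5]}")
    rows = {}
    labels = sorted(set(assign) - {UNAFFILIATED}) + [UNAFFILIATED]
    for lab in labels:
        members = assign.index[assign == lab]
        rows[lab] = fractions.loc[members].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.loc["filtered"] = 1.0 - out.sum(axis=0)
    return out


def site_mean_sd(per_sample: pd.DataFrame, sites: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and standard deviation over replicate samples of each site."""
    grouped = per_sample.T.groupby(sites)
    return grouped.mean().T, grouped.std(ddof=0).T


def subnetwork_taxa(
    assign: pd.Series,
    tax: TaxonomyTable,
    rank: str = "phylum",
    fractions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Taxon composition of each sub-network at a rank.

    Returns per (label, taxon): ``fraction_by_count`` (share of member OTUs)
    and, when fractions are given, ``fraction_by_abundance`` (share of the
    label's total relative abundance summed over samples).  Unclassified
    members count as their own category.
    """
    taxa = tax.rank(rank).reindex(assign.index).fillna("unclassified")
    out = []
    for lab in sorted(assign.unique()):
        members = assign.index[assign == lab]
        by_count = taxa.loc[members].value_counts(normalize=True)
        if fractions is not None:
            mass = fractions.loc[members].sum(axis=1)
            by_ab = mass.groupby(taxa.loc[members]).sum()
            by_ab = by_ab / by_ab.sum() if by_ab.sum() > 0 else by_ab
        for taxon in by_count.index:
            rec = {
                "subnetwork": lab,
                rank: taxon,
                "fraction_by_count": by_count[taxon],
            }
            if fractions is not None:
                rec["fraction_by_abundance"] = float(by_ab.get(taxon, 0.0))
            out.append(rec)
    return pd.DataFrame(out)


@dataclass
class CooccurrenceModel:
    """Co-occurrence sub-network model over a QC'd count table.

    Parameters default to the published procedure: >10 reads in at least 5
    samples, Pearson r > 0.98, BH q < 0.05, major sub-networks with more
    than 10 nodes.
    """

    table: CountTable
    taxonomy: TaxonomyTable | None = None
    min_reads: int = 10
    min_samples: int = 5
    r_min: float = 0.98
    q_max: float = 0.05
    min_major_nodes: int = 10

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, metadata: pd.DataFrame, **kwargs
    ) -> "CooccurrenceModel":
        return cls(CountTable(counts=counts, metadata=metadata), **kwargs)

    def fit(self) -> "CooccurrenceResults":
        fractions = relative_abundance(self.table)
        filtered = prevalence_filter(self.table, self.min_reads, self.min_samples)
        node_fracs = fractions.loc[filtered.otu_ids]
        pairs = correlate_pairs(node_fracs)
        graph = build_cooccurrence_graph(pairs, filtered.otu_ids, self.r_min, self.q_max)
        assign = extract_subnetworks(graph, self.min_major_nodes)
        return CooccurrenceResults(
            model=self, fractions=fractions, pairs=pairs, graph=graph, assignment=assign
        )


@dataclass
class CooccurrenceResults:
    """Fitted co-occurrence network: edges, sub-network assignment, abundances."""

    model: CooccurrenceModel
    fractions: pd.DataFrame  # full post-QC fraction matrix (all OTUs)
    pairs: pd.DataFrame  # all tested pairs with r, p, q
    graph: nx.Graph
    assignment: pd.Series  # node OTU -> label

    @property
    def edges(self) -> pd.DataFrame:
        """Edge table (otu_a, otu_b, r, p, q) of the thresholded graph."""
        recs = [
            {"otu_a": a, "otu_b": b, **d} for a, b, d in sorted(self.graph.edges(data=True))
        ]
        cols = ["otu_a", "otu_b", "r", "p", "q"]
        return pd.DataFrame(recs, columns=cols)

    @property
    def major_labels(self) -> list[str]:
        return sorted(set(self.assignment) - {UNAFFILIATED})

    def node_counts(self) -> pd.Series:
        return self.assignment.value_counts()

    def edge_counts(self) -> pd.Series:
        counts = {lab: 0 for lab in self.major_labels + [UNAFFILIATED]}
        for a, b in self.graph.edges:
            counts[self.assignment[a]] += 1
        return pd.Series(counts, name="edges")

    def subnetwork_abundance(self) -> pd.DataFrame:
        return subnetwork_abundance(self.assignment, self.fractions)

    def site_abundance(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-site mean and standard deviation of sub-network abundance
        over replicate samples."""
        return site_mean_sd(self.subnetwork_abundance(), self.model.table.sites())

    def subnetwork_taxa(self, rank: str = "phylum") -> pd.DataFrame:
        if self.model.taxonomy is None:
            raise ValueError("model was built without a taxonomy table")
        return subnetwork_taxa(self.assignment, self.model.taxonomy, rank, self.fractions)

    def relabel_by_dominant_site(self) -> "CooccurrenceResults":
        """Re-letter major sub-networks by the site where each is most
        abundant (site order as in the metadata), instead of by size."""
        mean, _ = self.site_abundance()
        sites = list(dict.fromkeys(self.model.table.sites()))
        majors = self.major_labels
        key = {
            lab: (sites.index(mean.loc[lab].idxmax()), -self.node_counts()[lab])
            for lab in majors
        }
        order = sorted(majors, key=lambda lab: key[lab])
        mapping = {old: _letters(i) for i, old in enumerate(order)}
        mapping[UNAFFILIATED] = UNAFFILIATED
        new_assign = self.assignment.map(mapping)
        return CooccurrenceResults(
            model=self.model,
            fractions=self.fractions,
            pairs=self.pairs,
            graph=self.graph,
            assignment=new_assign,
        )

    def summary(self) -> str:
        m = self.model
        nodes = self.node_counts()
        edges = self.edge_counts()
        ab = self.subnetwork_abundance()
        tab = pd.DataFrame(
            {
                "nodes": nodes,
                "edges": edges,
                "mean_abundance": ab.mean(axis=1).reindex(nodes.index),
            }
        ).loc[self.major_labels + [UNAFFILIATED]]
        lines = [
            "Co-occurrence sub-network results",
            "=" * 48,
            f"samples: {m.table.n_samples}    OTUs (nodes): {self.graph.number_of_nodes()}"
            f"    pairs tested: {len(self.pairs)}",
            f"edge rule: r > {m.r_min} and BH q < {m.q_max}"
            f"    prevalence: >{m.min_reads} reads in >= {m.min_samples} samples",
            f"edges kept: {self.graph.number_of_edges()}"
            f"    major sub-networks (> {m.min_major_nodes} nodes): {len(self.major_labels)}",
            "-" * 48,
            tab.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        nx.set_node_attributes(g, self.assignment.to_dict(), "subnetwork")
        nx.write_graphml(g, str(path))
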