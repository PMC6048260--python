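import numpy as np
import pandas as pd
import pytest

import halopond as hp
from halopond.containers import CountTable, TaxonomyTable, RANKS


def make_table(counts: dict[str, list[int]], sample_ids=None, **meta) -> CountTable:
    """Build a CountTable from {otu_id: row} with placeholder metadata."""
    df = pd.DataFrame.from_dict(counts, orient="index")
    if sample_ids is not None:
        df.columns = sample_ids
    else:
        df.columns = [f"S{i + 1}" for i in range(df.shape[1])]
    n = df.shape[1]
    metadata = pd.DataFrame(
        {
            "pond": meta.get("pond", ["P1"] * n),
            "fraction": meta.get("fraction", ["water"] * n),
            "salinity_percent": meta.get("salinity", [2.5] * n),
        },
        index=df.columns,
    )
    return CountTable(counts=df.astype(int), metadata=metadata)


def make_taxonomy(otu_ids, phylum="Proteobacteria", flags=None) -> TaxonomyTable:
    flags = flags or {}
    rows = []
    for o in otu_ids:
        rows.append(
            ["Bacteria", phylum if not isinstance(phylum, dict) else phylum[o]]
            + ["unclassified"] * 4
            + [flags.get(o, "")]
        )
    tab = pd.DataFrame(rows, columns=list(RANKS) + ["flag"], index=list(otu_ids))
    return TaxonomyTable(tab)


@pytest.fixture
def toy_table():
    # row sums 3, 10, 11, 0, 25
    return make_table(
        {
            "otu1": [1, 1, 1],
            "otu2": [5, 5, 0],
            "otu3": [4, 4, 3],
            "otu4": [0, 0, 0],
            "otu5": [10, 10, 5],
        }
    )


@pytest.fixture(scope="session")
def planted():
    """Reduced-scale planted-block community shared by the network tests."""
    cfg = hp.SimConfig(
        seed=11,
        block_sizes=(15, 15, 15, 15),
        n_background_otus=200,
        n_contaminant_otus=10,
        noise_sigma=0.1,
        depth=50_000,
    )
    table, tax, truth = hp.simulate_community(cfg)
    return table, tax, truth


@pytest.fixture(scope="session")
def planted_results(planted):
    table, tax, truth = planted
    from halopond.pipeline import RunConfig, run_qc

    qc_table, removed = run_qc(table, tax, RunConfig())
    results = hp.CooccurrenceModel(qc_table, taxonomy=tax).fit()
    return qc_table, removed, results, truth
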