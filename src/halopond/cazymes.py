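"""CAZyme class/family/substrate profiling and salinity correlation.

Carbohydrate-active enzymes (CAZymes) are grouped into six classes — AA
(auxiliary activity), CBM (carbohydrate-binding module), CE (carbohydrate
esterase), GH (glycoside hydrolase), GT (glycosyl transferase) and PL
(polysaccharide lyase) — and, within GH, into substrate categories
(cellulose, oligosaccharides, starch, fructans, xylans, ...) via an
editable family -> substrate map.  Profiles are relative abundances with
all annotated CAZymes in a sample as the denominator; the acidic fraction
is the share with computed pI at or below the threshold (default 5.0).

Feature-vs-salinity association is Pearson (Spearman optional) with BH
correction over the features tested in the same run, computed separately
within the water and sediment sample sets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .acidity import PkaSet, classify_acidic, isoelectric_point
from .stats import bh_adjust, pearson_pvalue

CAZY_CLASSES = ("AA", "CBM", "CE", "GH", "GT", "PL")
_FAMILY_RE = re.compile(r"^(AA|CBM|CE|GH|GT|PL)(\d+)")

OTHER = "other"


@dataclass
class ProteinRecord:
    """A predicted protein with its CAZy family call and provenance."""

    id: str
    sequence: str
    cazy_family: str
    sample_id: str
    pI: float | None = None


def family_class(family: str) -> str:
    """CAZy class parsed from a family label ("GH13" -> "GH")."""
    m = _FAMILY_RE.match(family)
    if m is None:
        warnings.warn(f"unparseable CAZy family label {family!r}", stacklevel=2)
        return OTHER
    return m.group(1)


@dataclass
class SubstrateMap:
    """GH family -> substrate category lookup; unmapped families are 'other'."""

    mapping: dict[str, str]

    @classmethod
    def default(cls) -> "SubstrateMap":
        text = resources.files("halopond.data").joinpath("gh_substrates.tsv").read_text()
        mapping = {}
        for line in text.strip().splitlines()[1:]:
            fam, sub = line.split("\t")
            mapping[fam] = sub
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path) -> "SubstrateMap":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["family"], df["substrate"])))

    def category(self, family: str) -> str:
        if family_class(family) != "GH":
            return OTHER
        root = _FAMILY_RE.match(family).group(0)
        return self.mapping.get(root, OTHER)


def substrate_for_family(family: str, smap: SubstrateMap | None = None) -> str:
    return (smap or SubstrateMap.default()).category(family)


@dataclass
class CazyProfile:
    """Per-sample CAZyme relative-abundance profiles and acidic fractions."""

    class_abundance: pd.DataFrame      # classes x samples, columns sum to 1
    family_abundance: pd.DataFrame     # families x samples, columns sum to 1
    substrate_abundance: pd.DataFrame  # substrates x samples, GH records only
    acidic_fraction: pd.Series         # per sample, all CAZymes
    acidic_by_class: pd.DataFrame      # classes x samples
    n_records: pd.Series               # CAZymes per sample
    pi_threshold: float = 5.0


def compute_pi(records: list[ProteinRecord], pka: PkaSet | None = None) -> None:
    """Fill in the pI field of each record (in place) from its sequence."""
    for rec in records:
        if rec.pI is None:
            rec.pI = isoelectric_point(rec.sequence, pka=pka)


def cazy_profile(
    records: list[ProteinRecord],
    pi_threshold: float = 5.0,
    smap: SubstrateMap | None = None,
    pka: PkaSet | None = None,
) -> CazyProfile:
    """Profile a set of annotated proteins per sample (or per genome).

    Denominators are all CAZymes in the sample; substrate fractions are
    over GH records only and sum to 1 per sample where any GH is present.
    """
    if not records:
        raise ValueError("no protein records")
    smap = smap or SubstrateMap.default()
    compute_pi(records, pka)
    df = pd.DataFrame(
        {
            "sample": [r.sample_id for r in records],
            "family": [_FAMILY_RE.match(r.cazy_family).group(0)
                       if _FAMILY_RE.match(r.cazy_family) else r.cazy_family
                       for r in records],
            "clazz": [family_class(r.cazy_family) for r in records],
            "substrate": [smap.category(r.cazy_family) for r in records],
            "acidic": [classify_acidic(r.pI, pi_threshold) for r in records],
        }
    )
    totals = df.groupby("sample").size()
    class_ab = (
        df.groupby(["clazz", "sample"]).size().unstack(fill_value=0)
        .reindex(list(CAZY_CLASSES), fill_value=0) / totals
    )
    fam_ab = df.groupby(["family", "sample"]).size().unstack(fill_value=0) / totals
    gh = df[df["clazz"] == "GH"]
    gh_tot = gh.groupby("sample").size().reindex(totals.index)
    sub_ab = (
        gh.groupby(["substrate", "sample"]).size().unstack(fill_value=0)
        .reindex(columns=totals.index, fill_value=0) / gh_tot
    )
    acidic = df.groupby("sample")["acidic"].mean()
    acidic_cls = (
        df.groupby(["clazz", "sample"])["acidic"].mean()
        .unstack()
        .reindex(list(CAZY_CLASSES))
    )
    return CazyProfile(
        class_abundance=class_ab,
        family_abundance=fam_ab.fillna(0.0),
        substrate_abundance=sub_ab,
        acidic_fraction=acidic,
        acidic_by_class=acidic_cls,
        n_records=totals,
        pi_threshold=pi_threshold,
    )


def site_profile(per_sample: pd.DataFrame, sites: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and standard deviation of a per-sample profile over site replicates."""
    grouped = per_sample.T.groupby(sites.reindex(per_sample.columns))
    return grouped.mean().T, grouped.std(ddof=0).T


def salinity_correlation(
    features: pd.DataFrame,
    salinity: pd.Series,
    alpha: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each feature (row) with salinity across samples.

    Returns one row per feature with r, p, BH q, a ``significant`` flag
    (q <= alpha, inclusive) and the sign of the association.  Constant
    features have undefined correlation: they are excluded from testing and
    reported with ``excluded=True``.
    """
    samples = [s for s in features.columns if s in salinity.index]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with salinity values")
    x = features[samples].to_numpy(dtype=float)
    y = salinity[samples].to_numpy(dtype=float)
    out = pd.DataFrame(index=features.index, columns=["r", "p", "q"], dtype=float)
    out["excluded"] = x.std(axis=1) == 0
    tested = ~out["excluded"].to_numpy()
    if method == "pearson":
        for i in np.flatnonzero(tested):
            r = float(np.corrcoef(x[i], y)[0, 1])
            out.iloc[i, 0] = r
            out.iloc[i, 1] = float(pearson_pvalue(r, len(samples)))
    elif method == "spearman":
        for i in np.flatnonzero(tested):
            r, p = sps.spearmanr(x[i], y)
            out.iloc[i, 0] = float(r)
            out.iloc[i, 1] = float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = (out["q"] <= alpha).fillna(False)
    out["sign"] = np.sign(out["r"]).fillna(0).astype(int)
    out["n"] = len(samples)
    return out


def salinity_correlation_by_fraction(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "pearson",
) -> dict[str, pd.DataFrame]:
    """Run the salinity correlation separately within water and sediment samples."""
    results = {}
    for frac, meta in metadata.groupby("fraction"):
        cols = [s for s in features.columns if s in meta.index]
        if len(cols) < 3:
            continue
        results[str(frac)] = salinity_correlation(
            features[cols], meta["salinity_percent"], alpha=alpha, method=method
        )
    return results
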