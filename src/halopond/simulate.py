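"""Seeded synthetic data emulating the hypersaline-pond survey.

The community generator plants K blocks of OTUs that share a relative-
abundance profile across sites — the ground truth for the co-occurrence
sub-network ("seed bank") procedure — on top of a background of
independently varying OTUs, chloroplast-contaminant OTUs at configurable
per-site fractions, and deliberately shallow replicates.  Counts are drawn
multinomially at a fixed sequencing depth, so every generated table is an
exact composition sample and fully reproducible from its seed.

Within a block, correlation is induced by a shared per-sample lognormal
factor on the block's total mass; individual members keep fixed relative
weights plus a small per-observation lognormal jitter (1/4 of
``noise_sigma``).  With ``noise_sigma = 0`` block members are exactly
proportional across samples (Pearson r = 1 up to counting noise).

Default scale mirrors the study design: 3 ponds (2.5 / 7.5 / 33.2 %
salinity) x water/sediment x 3 replicates = 18 samples of which two
high-salinity sediment replicates are shallow (< 500 reads), ~2,500 OTUs,
7 planted blocks carrying ~60 % of the reads, and 39 chloroplast OTUs.

The protein generator draws amino-acid sequences from a D/E-enriched
(acidic) or K/R-enriched (basic) composition so that the realized fraction
of proteins with pI <= 5 converges to a requested target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, TaxonomyTable, RANKS
from .cazymes import ProteinRecord

BLOCK_PHYLA = (
    "Proteobacteria",
    "Euryarchaeota",
    "Bacteroidetes",
    "Actinobacteria",
    "Cyanobacteria",
    "Balneolaeota",
    "Firmicutes",
    "Verrucomicrobia",
)


@dataclass
class SiteSpec:
    """One pond x fraction site: replicate count and contaminant load."""

    pond: str
    fraction: str  # water | sediment
    salinity_percent: float
    replicates: int = 3
    contaminant_fraction: float = 0.0


def default_sites() -> list[SiteSpec]:
    # contaminant (chloroplast) fractions follow the per-site averages the
    # survey design emulates; the high-salinity pond carries none
    return [
        SiteSpec("2C", "water", 2.5, 3, 0.197),
        SiteSpec("1C", "water", 7.5, 3, 0.017),
        SiteSpec("A23", "water", 33.2, 3, 0.0),
        SiteSpec("2C", "sediment", 2.5, 3, 0.011),
        SiteSpec("1C", "sediment", 7.5, 3, 0.0024),
        SiteSpec("A23", "sediment", 33.2, 3, 0.0),
    ]


def default_block_profiles(
    n_blocks: int,
    n_sites: int,
    dominant_mass: float = 0.5,
    secondary_mass: float = 0.1,
    baseline: float = 0.008,
) -> np.ndarray:
    """Block x site mean-abundance matrix: block k dominates site k mod S,
    with a secondary site two steps over; blocks sharing a dominant site
    split its mass."""
    prof = np.full((n_blocks, n_sites), baseline)
    dom = [k % n_sites for k in range(n_blocks)]
    # the secondary-site offset shifts for blocks that wrap around, so two
    # blocks sharing a dominant site keep distinct profiles
    sec = [(k + 2 + k // n_sites) % n_sites for k in range(n_blocks)]
    for j in range(n_sites):
        owners = [k for k in range(n_blocks) if dom[k] == j]
        for k in owners:
            prof[k, j] += dominant_mass / len(owners)
        second = [k for k in range(n_blocks) if sec[k] == j]
        for k in second:
            prof[k, j] += secondary_mass / max(len(second), 1)
    return prof


@dataclass
class SimConfig:
    """Configuration of the community generator; defaults are the study scale."""

    sites: list[SiteSpec] = field(default_factory=default_sites)
    block_sizes: tuple[int, ...] = (40, 35, 30, 25, 20, 15, 12)
    block_site_profiles: np.ndarray | None = None  # K x n_sites; default built
    n_background_otus: int = 2300
    n_contaminant_otus: int = 39
    noise_sigma: float = 0.1
    depth: int = 50_000
    shallow_samples: dict[str, int] = field(
        default_factory=lambda: {"A23S2": 300, "A23S3": 250}
    )
    seed: int = 0

    def profiles(self) -> np.ndarray:
        if self.block_site_profiles is not None:
            return np.asarray(self.block_site_profiles, dtype=float)
        return default_block_profiles(len(self.block_sizes), len(self.sites))

    def validate(self) -> None:
        prof = self.profiles()
        if prof.shape != (len(self.block_sizes), len(self.sites)):
            raise ValueError("block_site_profiles shape mismatch")
        if (prof < 0).any():
            raise ValueError("negative block profile")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for j, site in enumerate(self.sites):
            total = prof[:, j].sum() + site.contaminant_fraction
            if total > 1:
                raise ValueError(
                    f"site {site.pond}-{site.fraction}: block + contaminant "
                    f"mass {total:.3f} exceeds 1"
                )


@dataclass
class SimTruth:
    """Planted labels and expectations emitted alongside a simulated table."""

    block_labels: pd.Series          # otu -> block_1.. | background | contaminant
    expected_fractions: pd.DataFrame  # OTU x sample, columns sum to 1
    metadata: pd.DataFrame
    config: SimConfig


def _sample_names(sites: list[SiteSpec]) -> tuple[list[str], list[int]]:
    names, site_idx = [], []
    for j, site in enumerate(sites):
        code = "L" if site.fraction == "water" else "S"
        for rep in range(1, site.replicates + 1):
            names.append(f"{site.pond}{code}{rep}")
            site_idx.append(j)
    return names, site_idx


def simulate_community(cfg: SimConfig) -> tuple[CountTable, TaxonomyTable, SimTruth]:
    """Draw a community count table with planted correlated OTU blocks."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    prof = cfg.profiles()
    K = len(cfg.block_sizes)
    names, site_idx = _sample_names(cfg.sites)
    n_samples = len(names)
    sigma = cfg.noise_sigma
    jitter = 0.25 * sigma

    n_block = int(sum(cfg.block_sizes))
    n_total = n_block + cfg.n_background_otus + cfg.n_contaminant_otus
    otu_ids = [f"OTU_{i + 1:05d}" for i in range(n_total)]
    labels = []
    for k, size in enumerate(cfg.block_sizes):
        labels += [f"block_{k + 1}"] * size
    labels += ["background"] * cfg.n_background_otus
    labels += ["contaminant"] * cfg.n_contaminant_otus
    label_s = pd.Series(labels, index=otu_ids, name="block")

    # fixed per-OTU weights
    block_w = [rng.lognormal(0.0, 0.5, size) for size in cfg.block_sizes]
    block_w = [w / w.sum() for w in block_w]
    bg_base = rng.lognormal(0.0, 1.5, cfg.n_background_otus)
    bg_affinity = rng.lognormal(0.0, 0.5, (cfg.n_background_otus, len(cfg.sites)))
    contam_w = rng.lognormal(0.0, 1.0, max(cfg.n_contaminant_otus, 1))
    contam_w = contam_w / contam_w.sum()

    expected = np.zeros((n_total, n_samples))
    for s, j in enumerate(site_idx):
        site = cfg.sites[j]
        # without contaminant OTUs there is no contaminant mass to inject
        contam_frac = site.contaminant_fraction if cfg.n_contaminant_otus else 0.0
        mass = np.empty(n_total)
        pos = 0
        for k, size in enumerate(cfg.block_sizes):
            g = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
            e = rng.lognormal(0.0, jitter, size) if jitter > 0 else np.ones(size)
            within = block_w[k] * e
            mass[pos:pos + size] = prof[k, j] * g * within / within.sum()
            pos += size
        bg_mass = 1.0 - prof[:, j].sum() - contam_frac
        eps = rng.lognormal(0.0, sigma, cfg.n_background_otus) if sigma > 0 else 1.0
        bg = bg_base * bg_affinity[:, j] * eps
        mass[pos:pos + cfg.n_background_otus] = bg_mass * bg / bg.sum()
        pos += cfg.n_background_otus
        if cfg.n_contaminant_otus:
            mass[pos:] = contam_frac * contam_w
        expected[:, s] = mass / mass.sum()

    counts = np.zeros((n_total, n_samples), dtype=int)
    for s, name in enumerate(names):
        depth = cfg.shallow_samples.get(name, cfg.depth)
        counts[:, s] = rng.multinomial(depth, expected[:, s])

    metadata = pd.DataFrame(
        {
            "pond": [cfg.sites[j].pond for j in site_idx],
            "fraction": [cfg.sites[j].fraction for j in site_idx],
            "salinity_percent": [cfg.sites[j].salinity_percent for j in site_idx],
        },
        index=pd.Index(names, name="sample_id"),
    )
    table = CountTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=names),
        metadata=metadata,
        provenance=("simulate_community",),
    )
    tax = _simulated_taxonomy(label_s, rng)
    truth = SimTruth(
        block_labels=label_s,
        expected_fractions=pd.DataFrame(expected, index=otu_ids, columns=names),
        metadata=metadata,
        config=cfg,
    )
    return table, tax, truth


def _simulated_taxonomy(labels: pd.Series, rng: np.random.Generator) -> TaxonomyTable:
    rows = []
    phyla = list(BLOCK_PHYLA)
    for otu, lab in labels.items():
        if lab == "contaminant":
            genus = "Odontella" if rng.random() < 0.84 else "Guillardia"
            rows.append(
                ("Eukaryota", "Chloroplast", "unclassified", "unclassified",
                 "unclassified", genus, "chloroplast")
            )
        elif lab == "background":
            ph = phyla[rng.integers(0, len(phyla))]
            rows.append(("Bacteria", ph, "unclassified", "unclassified",
                         "unclassified", "unclassified", ""))
        else:
            k = int(lab.split("_")[1]) - 1
            ph = phyla[k % len(phyla)]
            dom = "Archaea" if ph == "Euryarchaeota" else "Bacteria"
            rows.append((dom, ph, "unclassified", "unclassified",
                         "unclassified", "unclassified", ""))
    tab = pd.DataFrame(rows, columns=list(RANKS) + ["flag"], index=labels.index)
    tab.index.name = "otu_id"
    return TaxonomyTable(tab)


# ---------------------------------------------------------------------------
# protein generator

_BASE_FREQ = {
    "A": 0.080, "C": 0.010, "D": 0.050, "E": 0.060, "F": 0.040, "G": 0.070,
    "H": 0.022, "I": 0.058, "K": 0.058, "L": 0.096, "M": 0.022, "N": 0.040,
    "P": 0.048, "Q": 0.038, "R": 0.055, "S": 0.068, "T": 0.052, "V": 0.068,
    "W": 0.011, "Y": 0.030,
}

DEFAULT_FAMILY_WEIGHTS = {
    "GH13": 0.09, "GH3": 0.06, "GH2": 0.05, "GH1": 0.04, "GH31": 0.04,
    "GH5": 0.015, "GH15": 0.03, "GH57": 0.02, "GH77": 0.02, "GH27": 0.015,
    "GH32": 0.02, "GH68": 0.01, "GH30": 0.015, "GH16": 0.015, "GH23": 0.05,
    "GH74": 0.01, "GT2": 0.09, "GT4": 0.08, "GT41": 0.03, "GT51": 0.03,
    "GT81": 0.02, "GT66": 0.015, "GT75": 0.01, "CBM40": 0.04, "CBM44": 0.03,
    "CE1": 0.05, "CE4": 0.04, "CE10": 0.03, "AA2": 0.03, "AA3": 0.03,
    "PL1": 0.02, "PL9": 0.01,
}

# per-site acidic-pI targets emulated by the survey-scale protein generator
DEFAULT_ACIDIC_TARGETS = {
    ("2C", "water"): 0.270, ("1C", "water"): 0.420, ("A23", "water"): 0.814,
    ("2C", "sediment"): 0.360, ("1C", "sediment"): 0.382, ("A23", "sediment"): 0.463,
}


def _composition(acidic: bool) -> tuple[np.ndarray, list[str]]:
    freq = dict(_BASE_FREQ)
    if acidic:
        freq.update({"D": 0.120, "E": 0.125, "K": 0.014, "R": 0.010, "H": 0.012})
    else:
        freq.update({"D": 0.028, "E": 0.030, "K": 0.090, "R": 0.082, "H": 0.030})
    letters = sorted(freq)
    p = np.array([freq[a] for a in letters])
    return p / p.sum(), letters


def simulate_proteins(
    n: int,
    acidic_target: float = 0.4,
    family_weights: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
    id_prefix: str = "prot",
    length_range: tuple[int, int] = (120, 450),
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Draw ``n`` annotated proteins with a target acidic (pI <= 5) fraction.

    Each record's intended acidity class is Bernoulli(acidic_target) and is
    recorded in the returned truth table; the realized pI-based fraction
    converges to the target as n grows because the two compositions sit far
    on either side of the pI threshold.
    """
    if not 0 <= acidic_target <= 1:
        raise ValueError("acidic_target must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = family_weights or DEFAULT_FAMILY_WEIGHTS
    fams = sorted(weights)
    fw = np.array([weights[f] for f in fams], dtype=float)
    fw = fw / fw.sum()
    p_acid, letters = _composition(True)
    p_base, _ = _composition(False)
    records, truth = [], []
    arr = np.array(letters)
    for i in range(n):
        acid = bool(rng.random() < acidic_target)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(arr[rng.choice(len(arr), size=length, p=p_acid if acid else p_base)])
        fam = fams[int(rng.choice(len(fams), p=fw))]
        pid = f"{id_prefix}_{i + 1:05d}"
        records.append(ProteinRecord(id=pid, sequence=seq, cazy_family=fam, sample_id=sample_id))
        truth.append({"protein_id": pid, "intended_acidic": acid, "cazy_family": fam})
    return records, pd.DataFrame(truth).set_index("protein_id")


def simulate_protein_survey(
    metadata: pd.DataFrame,
    n_per_sample: int = 400,
    acidic_targets: dict[tuple[str, str], float] | None = None,
    family_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """One protein set per sample, acidic target chosen by (pond, fraction)."""
    targets = acidic_targets or DEFAULT_ACIDIC_TARGETS
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for sample_id, row in metadata.iterrows():
        target = targets.get((row["pond"], row["fraction"]), 0.4)
        recs, truth = simulate_proteins(
            n_per_sample, target, family_weights, rng,
            sample_id=str(sample_id), id_prefix=f"{sample_id}_prot",
        )
        records += recs
        truth["sample_id"] = sample_id
        truths.append(truth)
    return records, pd.concat(truths)
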