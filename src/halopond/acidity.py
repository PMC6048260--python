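"""Protein isoelectric point (pI) from sequence.

An acidic proteome (low pI) is a hallmark of "salt-in" halophiles, whose
enzymes stay soluble and active at high ionic strength; classifying
predicted proteins as acidic (pI <= 5.0) is therefore the screening step
for salt-tolerant enzyme candidates.

The net charge of a protein at a given pH follows the Henderson-Hasselbalch
model, summing over ionizable side chains (D, E, C, Y acidic; H, K, R
basic) and both termini:

    Q(pH) = sum_basic  n_g / (1 + 10^(pH - pKa_g))
          - sum_acidic n_g / (1 + 10^(pKa_g - pH))

Q is strictly decreasing in pH and always has both a positive (N-terminus)
and a negative (C-terminus) contribution, so a unique zero crossing exists
in (0, 14); we locate it by bisection.  The pKa set is the EMBOSS-style
default and is an editable configuration value — published pI estimates
vary by a few tenths of a pH unit depending on the pKa table, so the
classifying threshold matters more than the third decimal.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, asdict
from importlib import resources

ACIDIC_RESIDUES = ("D", "E", "C", "Y")
BASIC_RESIDUES = ("H", "K", "R")
CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS = set("XBZJUO")  # contribute no charge unless strict mode


@dataclass(frozen=True)
class PkaSet:
    """pKa values for the ionizable side chains and the termini."""

    nterm: float
    cterm: float
    D: float
    E: float
    C: float
    Y: float
    H: float
    K: float
    R: float

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if not 0 < val < 14:
                raise ValueError(f"pKa {name}={val} outside (0, 14)")

    @classmethod
    def default(cls) -> "PkaSet":
        return _DEFAULT_PKA

    @classmethod
    def from_json(cls, path) -> "PkaSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def _load_default() -> PkaSet:
    text = resources.files("halopond.data").joinpath("pka_emboss.json").read_text()
    return PkaSet(**json.loads(text))


_DEFAULT_PKA = _load_default()


def _residue_counts(sequence: str, strict: bool) -> Counter:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - CANONICAL - AMBIGUOUS
    if bad:
        raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
    if strict and set(seq) & AMBIGUOUS:
        raise ValueError("ambiguous residues present in strict mode")
    return Counter(seq)


def net_charge(sequence: str, pH: float, pka: PkaSet | None = None, strict: bool = False) -> float:
    """Net charge Q(pH) of a protein, termini included."""
    pka = pka or _DEFAULT_PKA
    counts = _residue_counts(sequence, strict)
    return _charge_from_counts(counts, pH, pka)


def _charge_from_counts(counts: Counter, pH: float, pka: PkaSet) -> float:
    pos = 1.0 / (1.0 + 10.0 ** (pH - pka.nterm))  # N-terminus
    for res in BASIC_RESIDUES:
        pos += counts[res] / (1.0 + 10.0 ** (pH - getattr(pka, res)))
    neg = 1.0 / (1.0 + 10.0 ** (pka.cterm - pH))  # C-terminus
    for res in ACIDIC_RESIDUES:
        neg += counts[res] / (1.0 + 10.0 ** (getattr(pka, res) - pH))
    return pos - neg


def isoelectric_point(
    sequence: str,
    pka: PkaSet | None = None,
    tol: float = 1e-6,
    strict: bool = False,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The default interval tolerance (1e-6 pH units) keeps |Q(pI)| well below
    1e-3 even for large proteins, whose charge curve is steep near the
    crossing.
    """
    pka = pka or _DEFAULT_PKA
    counts = _residue_counts(sequence, strict)
    lo, hi = 0.0, 14.0
    # Q(0) > 0 and Q(14) < 0 always: both termini are ionizable
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _charge_from_counts(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_acidic(pI: float, threshold: float = 5.0) -> bool:
    """True iff pI <= threshold (inclusive: a pI of exactly 5.0 is acidic)."""
    if not 0 <= pI <= 14:
        raise ValueError("pI outside [0, 14]")
    return pI <= threshold
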