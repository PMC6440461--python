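"""Codon usage: start/stop classification, RSCU and amino-acid profiles.

RSCU (relative synonymous codon usage) of codon ``c`` in its synonymous
family ``F`` is ``count(c) * |F| / sum(count(c') for c' in F)`` — observed
usage over the expectation under uniform use within the family.  Amino-acid
composition is reported as CDspT (codons per thousand codons) with leucine
split into Leu1 (CUN) / Leu2 (UUR) and serine into Ser1 (AGN) / Ser2 (UCN),
the convention of comparative insect mitogenomics.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import GeneticCode, INVERTEBRATE_MITO, iter_codons

ALL_CODONS = ["".join(p) for p in itertools.product("TCAG", repeat=3)]

#: split six-fold families by codon class (first two bases), the labelling
#: used for the Leu1/Leu2 and Ser1/Ser2 accounting
_SPLIT_CLASSES = {
    "L": {"CT": "Leu1", "TT": "Leu2"},
    "S": {"AG": "Ser1", "TC": "Ser2"},
}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro", "T": "Thr",
    "W": "Trp", "Y": "Tyr", "V": "Val",
}


def aa_class(codon: str, code: GeneticCode = INVERTEBRATE_MITO) -> Optional[str]:
    """Amino-acid class label of a codon; split Leu/Ser; None for stops."""
    aa = code.codon_to_aa[codon]
    if aa == "*":
        return None
    if aa in _SPLIT_CLASSES:
        return _SPLIT_CLASSES[aa][codon[:2]]
    return _AA3[aa]


def codon_families(
    code: GeneticCode = INVERTEBRATE_MITO, split_leu_ser: bool = True
) -> dict[str, list[str]]:
    """Synonymous families, keyed by class label, stops excluded.

    With ``split_leu_ser`` (default) the six-codon Leu and Ser families are
    treated as two separate RSCU families of 2 and 4 codons; without it each
    is a single six-codon family (labelled ``Leu`` / ``Ser``).
    """
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        if aa == "*":
            continue
        if split_leu_ser:
            label = aa_class(codon, code)
        else:
            label = {"L": "Leu", "S": "Ser"}.get(aa) or _AA3[aa]
        fams.setdefault(label, []).append(codon)
    return fams


# ---------------------------------------------------------------------------
# Start / stop classification
# ---------------------------------------------------------------------------

@dataclass
class CodonReport:
    gene: str
    start_codon: str
    start_class: str          # ATN | GTG | TTG | other
    stop_codon: str           # triplet, or the literal incomplete tail
    stop_class: str           # TAA | TAG | incomplete-TA | incomplete-T | other


def classify_start(codon: str) -> str:
    codon = codon.upper()
    if len(codon) == 3 and codon.startswith("AT") and codon[2] in "ACGT":
        return "ATN"
    if codon in ("GTG", "TTG"):
        return codon
    return "other"


def classify_codons(cds: str, gene: str = "") -> CodonReport:
    """Start and stop codon classes of one CDS.

    The stop class is read off the tail: a full final triplet is classed
    TAA/TAG/other, while CDS lengths of 3n+2 / 3n+1 indicate the incomplete
    stops TA / T completed by polyadenylation.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError(f"CDS for {gene or 'gene'} shorter than two codons")
    start = cds[:3]
    tail = len(cds) % 3
    if tail == 0:
        stop = cds[-3:]
        stop_class = stop if stop in ("TAA", "TAG") else "other"
    elif tail == 2:
        stop, stop_class = cds[-2:], "incomplete-TA"
    else:
        stop, stop_class = cds[-1:], "incomplete-T"
    return CodonReport(gene, start, classify_start(start), stop, stop_class)


# ---------------------------------------------------------------------------
# Codon counting and RSCU
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Per-codon counts and (optionally) RSCU values over all 64 codons."""

    counts: dict[str, int]
    rscu: Optional[dict[str, Optional[float]]] = None
    code: GeneticCode = field(default=INVERTEBRATE_MITO, repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for codon in ALL_CODONS:
            rows.append({
                "codon": codon,
                "aa": self.code.codon_to_aa[codon],
                "class": aa_class(codon, self.code) or "*",
                "count": self.counts.get(codon, 0),
                "RSCU": None if self.rscu is None else self.rscu.get(codon),
            })
        return pd.DataFrame(rows)


def count_codons(
    cds_set: Sequence[str], code: GeneticCode = INVERTEBRATE_MITO
) -> CodonUsageTable:
    """Count codons over complete triplets of in-frame CDSs.

    Stop codons and incomplete trailing codons are excluded; literal start
    triplets are counted as themselves.
    """
    counter: Counter = Counter()
    for cds in cds_set:
        for codon in iter_codons(cds.upper()):
            if codon in code.stop_codons or any(b not in "ACGT" for b in codon):
                continue
            counter[codon] += 1
    return CodonUsageTable(counts={c: counter.get(c, 0) for c in ALL_CODONS}, code=code)


def rscu(
    table: CodonUsageTable,
    code: Optional[GeneticCode] = None,
    split_leu_ser: bool = True,
) -> CodonUsageTable:
    """Attach RSCU values to a codon-usage table.

    Families with zero total usage get RSCU ``None``.  Six-fold Leu/Ser are
    split into 2+4 codon families by default; pass ``split_leu_ser=False``
    for the six-codon-family dialect.
    """
    code = code or table.code
    values: dict[str, Optional[float]] = {}
    for family in codon_families(code, split_leu_ser).values():
        fam_total = sum(table.counts.get(c, 0) for c in family)
        for c in family:
            values[c] = (
                None if fam_total == 0
                else table.counts.get(c, 0) * len(family) / fam_total
            )
    for stop in code.stop_codons:
        values[stop] = None
    return CodonUsageTable(counts=dict(table.counts), rscu=values, code=code)


# ---------------------------------------------------------------------------
# Amino-acid composition (CDspT)
# ---------------------------------------------------------------------------

@dataclass
class AminoAcidProfile:
    """Codons-per-thousand-codons usage by amino-acid class."""

    cdspt: dict[str, float]

    def top(self, k: int = 5) -> list[str]:
        return [
            cls for cls, _ in sorted(
                self.cdspt.items(), key=lambda kv: (-kv[1], kv[0])
            )[:k]
        ]


def aa_profile(
    table: CodonUsageTable, code: Optional[GeneticCode] = None
) -> AminoAcidProfile:
    """CDspT per amino-acid class (Leu and Ser split), stops excluded."""
    code = code or table.code
    if table.total == 0:
        raise ValueError("empty codon table")
    sums: dict[str, int] = {label: 0 for label in codon_families(code)}
    for codon, n in table.counts.items():
        label = aa_class(codon, code)
        if label is not None:
            sums[label] += n
    total = sum(sums.values())
    return AminoAcidProfile({label: 1000 * n / total for label, n in sums.items()})


def family_ordering(
    profile: AminoAcidProfile, classes: Sequence[str], tol: float = 0.0
) -> str:
    """Render classes in descending CDspT order, ties joined with ``/``.

    Example output: ``"Phe > Ile > Met > Leu2 > Ser2"``.
    """
    ranked = sorted(classes, key=lambda cls: (-profile.cdspt[cls], cls))
    groups: list[list[str]] = []
    for cls in ranked:
        if groups and abs(profile.cdspt[groups[-1][-1]] - profile.cdspt[cls]) <= tol:
            groups[-1].append(cls)
        else:
            groups.append([cls])
    return " > ".join("/".join(g) for g in groups)
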