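"""Core domain types for annotated circular mitochondrial genomes.

The toolkit works with the canonical 37-gene metazoan mitochondrial gene set
(13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus the non-coding A+T-rich
control region.  Coordinates are 0-based half-open on the published (heavy,
majority) strand; a feature that spans the origin of the circular molecule
is stored as a single interval with ``end > genome length``, never split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# Canonical gene vocabulary
# ---------------------------------------------------------------------------

PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)

TRNA_NAMES = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
)

RRNA_NAMES = ("rrnL", "rrnS")

CONTROL_REGION = "CR"

ALL_GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES + (CONTROL_REGION,)

_TYPE_BY_NAME = (
    {n: "PCG" for n in PCG_NAMES}
    | {n: "tRNA" for n in TRNA_NAMES}
    | {n: "rRNA" for n in RRNA_NAMES}
    | {CONTROL_REGION: "control_region"}
)

#: anticodons disambiguating the duplicated leucine / serine tRNAs
_LEU_SER_ANTICODONS = {
    ("trnL", "TAG"): "trnL1",   # recognises CUN codons
    ("trnL", "TAA"): "trnL2",   # recognises UUR codons
    ("trnS", "TCT"): "trnS1",   # recognises AGN codons
    ("trnS", "GCT"): "trnS1",
    ("trnS", "TGA"): "trnS2",   # recognises UCN codons
}


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, canonical = line.split("\t")
        table[raw] = canonical
    # canonical tokens always map to themselves
    for name in ALL_GENE_NAMES:
        table.setdefault(name.lower(), name)
    return table


_SYNONYMS: dict[str, str] | None = None


def _synonyms() -> dict[str, str]:
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    return _SYNONYMS


def normalize_gene_name(raw: str, anticodon: str | None = None) -> tuple[str, str]:
    """Map a free-text gene label to a canonical token and feature type.

    Returns ``(canonical_name, type)`` where type is one of ``PCG``, ``tRNA``,
    ``rRNA``, ``control_region`` or ``other``.  Matching is case-insensitive
    and tolerant of common annotation synonyms (``COI`` -> ``cox1``,
    ``ND2`` -> ``nad2``, ``D-loop`` -> ``CR`` ...).  For the duplicated
    leucine/serine tRNAs an ``anticodon`` triplet resolves the isoacceptor
    (e.g. ``tRNA-Ser`` with anticodon TCT -> ``trnS1``).  Unknown labels are
    preserved verbatim with type ``other``; the function never raises.
    """
    key = raw.strip().lower()
    key = key.replace(" ", "").replace("_", "-")
    canonical = _synonyms().get(key)
    if canonical in ("trnL", "trnS"):
        if anticodon:
            canonical = _LEU_SER_ANTICODONS.get(
                (canonical, anticodon.upper().replace("U", "T")), canonical
            )
        if canonical == "trnL":
            canonical = "trnL2"  # UUR isoacceptor is the common default label
        elif canonical == "trnS":
            canonical = "trnS1"  # AGN isoacceptor lacks the DHU arm; default
    if canonical is None:
        return raw, "other"
    return canonical, _TYPE_BY_NAME.get(canonical, "other")


# ---------------------------------------------------------------------------
# Features and genomes
# ---------------------------------------------------------------------------

VALID_TYPES = ("PCG", "tRNA", "rRNA", "control_region", "other")


@dataclass
class GeneFeature:
    """One annotated gene or region on a circular genome.

    ``start``/``end`` are 0-based half-open genome coordinates on the
    published strand; ``end`` may exceed the genome length to encode a
    feature that runs across the origin.  ``strand`` is ``H`` (published
    orientation) or ``L`` (reverse complement).
    """

    name: str
    type: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.type not in VALID_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.name}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps_origin(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class MitoGenome:
    """A circular annotated mitochondrial genome."""

    id: str
    sequence: str
    organism: str = ""
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = self.length
        seen: set[str] = set()
        for f in self.features:
            if not (0 <= f.start < n and f.end <= 2 * n):
                raise ValueError(
                    f"feature {f.name} span [{f.start},{f.end}) outside [0,{2 * n})"
                )
            if f.type != "other":
                if f.name in seen and not self.allow_duplicates:
                    raise ValueError(f"duplicate gene name {f.name!r}")
                seen.add(f.name)

    def get(self, name: str) -> Optional[GeneFeature]:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def features_of_type(self, *types: str) -> list[GeneFeature]:
        return [f for f in self.features if f.type in types]

    def sorted_features(self) -> list[GeneFeature]:
        """Features ordered by start coordinate around the circle."""
        return sorted(self.features, key=lambda f: (f.start, f.end, f.name))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_gene_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Sequence of a feature in its reading orientation.

    H-strand features return the published-strand substring; L-strand
    features its reverse complement.  Features with ``end > length`` wrap
    the circular origin.
    """
    if feature.length > genome.length:
        raise ValueError(
            f"feature {feature.name} longer ({feature.length}) than genome ({genome.length})"
        )
    doubled = genome.sequence + genome.sequence
    sub = doubled[feature.start:feature.end]
    if feature.strand == "L":
        sub = reverse_complement(sub)
    return sub


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

_BASES = "TCAG"


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    The default instance is NCBI table 5 (invertebrate mitochondrial):
    AGA/AGG code for Ser, ATA for Met and TGA for Trp.
    """

    table_id: int
    codon_to_aa: dict[str, str]       # 64 entries, stops mapped to '*'
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(t.forward_table)
        for stop in t.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
        )

    def family(self, codon: str) -> list[str]:
        """All codons synonymous with ``codon`` (its full degenerate family)."""
        aa = self.codon_to_aa[codon]
        return [c for c, a in self.codon_to_aa.items() if a == aa]


INVERTEBRATE_MITO = GeneticCode.from_ncbi(5)


class InternalStopWarning(UserWarning):
    pass


def translate(
    cds: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    complete_stop: bool = True,
) -> str:
    """Translate an in-frame CDS to protein.

    A trailing ``T`` or ``TA`` (an incomplete stop completed to TAA by
    post-transcriptional polyadenylation) is filled in before translation
    when ``complete_stop`` is set.  The terminal stop is dropped from the
    returned protein.  Internal stops trigger an ``InternalStopWarning``
    listing their codon positions.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    tail = len(cds) % 3
    if tail and complete_stop:
        fragment = cds[-tail:]
        if fragment in ("T", "TA"):
            cds = cds + "TAA"[tail:]
        else:
            warnings.warn(
                f"trailing fragment {fragment!r} is not a truncated TAA; dropped",
                UserWarning,
            )
            cds = cds[: len(cds) - tail]
    elif tail:
        cds = cds[: len(cds) - tail]

    aas = []
    internal_stops = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = code.codon_to_aa.get(codon, "X")
        if aa == "*" and i < n_codons - 1:
            internal_stops.append(i)
        aas.append(aa)
    if internal_stops:
        warnings.warn(
            f"internal stop codon(s) at codon position(s) {internal_stops}",
            InternalStopWarning,
        )
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def iter_codons(cds: str) -> Iterable[str]:
    """Complete triplets of an in-frame CDS (trailing fragment dropped)."""
    for i in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[i : i + 3]
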