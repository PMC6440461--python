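"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed over
unambiguous bases only.  Profiles are produced for the whole genome, the
concatenated protein-coding genes (all / H-strand / L-strand), every
individual PCG, the concatenated tRNAs, both rRNAs and the control region.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import MitoGenome, extract_gene_sequence, iter_codons


@dataclass
class CompositionProfile:
    """Base counts and skew statistics for one named region set."""

    region: str
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.total

    @property
    def at_skew(self) -> Optional[float]:
        at = self.a + self.t
        return (self.a - self.t) / at if at else None

    @property
    def gc_skew(self) -> Optional[float]:
        gc = self.g + self.c
        return (self.g - self.c) / gc if gc else None

    def as_row(self) -> dict:
        """Row for the TSV report (percent to 1 d.p., skews to 3 d.p.)."""
        return {
            "region": self.region,
            "A": self.a, "C": self.c, "G": self.g, "T": self.t,
            "length": self.total,
            "AT_pct": round(100 * self.at_content, 1),
            "AT_skew": None if self.at_skew is None else round(self.at_skew, 3),
            "GC_skew": None if self.gc_skew is None else round(self.gc_skew, 3),
        }


def base_composition(seq: str, region: str = "sequence") -> CompositionProfile:
    """Composition of one sequence; IUPAC ambiguity codes are not counted."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    return CompositionProfile(
        region=region,
        a=counts.get("A", 0), c=counts.get("C", 0),
        g=counts.get("G", 0), t=counts.get("T", 0),
    )


def region_profiles(genome: MitoGenome) -> list[CompositionProfile]:
    """Standard per-genome region profile set.

    L-strand genes are reverse-complemented (read in their own orientation)
    before concatenation; the whole-genome profile is taken on the published
    strand as-is.
    """
    profiles = [base_composition(genome.sequence, "whole_genome")]

    pcgs = [f for f in genome.sorted_features() if f.type == "PCG"]
    if pcgs:
        seqs = {f.name: extract_gene_sequence(genome, f) for f in pcgs}
        profiles.append(base_composition("".join(seqs.values()), "PCGs_all"))
        for strand in ("H", "L"):
            sub = [seqs[f.name] for f in pcgs if f.strand == strand]
            if sub:
                profiles.append(base_composition("".join(sub), f"PCGs_{strand}"))
        for f in pcgs:
            profiles.append(base_composition(seqs[f.name], f.name))
    else:
        warnings.warn(f"{genome.id}: no protein-coding genes annotated")

    trnas = [f for f in genome.sorted_features() if f.type == "tRNA"]
    if trnas:
        cat = "".join(extract_gene_sequence(genome, f) for f in trnas)
        profiles.append(base_composition(cat, "tRNAs"))
    for rrna in ("rrnL", "rrnS"):
        f = genome.get(rrna)
        if f is None:
            warnings.warn(f"{genome.id}: {rrna} not annotated; profile omitted")
            continue
        profiles.append(base_composition(extract_gene_sequence(genome, f), rrna))

    cr = genome.get("CR")
    if cr is None:
        # fall back on the inferred control region between rrnS and trnM
        from .architecture import control_region

        try:
            cr = control_region(genome)
        except ValueError:
            warnings.warn(f"{genome.id}: control region unavailable; profile omitted")
            cr = None
    if cr is not None:
        profiles.append(base_composition(extract_gene_sequence(genome, cr), "CR"))
        # whole genome excluding CR, for comparability across annotations
        doubled = genome.sequence * 2
        without = doubled[cr.end:cr.start + genome.length]
        if without:
            profiles.append(base_composition(without, "whole_genome_minus_CR"))
    return profiles


@dataclass
class PositionProfile:
    """Nucleotide frequencies at one codon position for one strand class."""

    strand: str
    position: int  # 1, 2 or 3
    freqs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if total and abs(total - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def codon_position_profile(cds_set: Sequence[tuple[str, str]]) -> list[PositionProfile]:
    """Per-strand, per-codon-position base frequencies of a CDS collection.

    ``cds_set`` is a list of ``(cds, strand)`` pairs with the CDS already in
    reading orientation; incomplete trailing codons are dropped.
    """
    counts: dict[tuple[str, int], Counter] = {}
    for cds, strand in cds_set:
        for codon in iter_codons(cds.upper()):
            for pos, base in enumerate(codon, start=1):
                if base in "ACGT":
                    counts.setdefault((strand, pos), Counter())[base] += 1
    profiles = []
    for (strand, pos), counter in sorted(counts.items()):
        total = sum(counter.values())
        profiles.append(
            PositionProfile(
                strand=strand, position=pos,
                freqs={b: counter.get(b, 0) / total for b in "ACGT"},
            )
        )
    return profiles


def profiles_to_frame(
    profiles_by_genome: dict[str, list[CompositionProfile]]
) -> pd.DataFrame:
    """Long-format table: one row per (genome, region)."""
    rows = []
    for genome_id, profiles in profiles_by_genome.items():
        for p in profiles:
            rows.append({"genome": genome_id} | p.as_row())
    return pd.DataFrame(rows)
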