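"""Alignment, conservation scoring and supermatrix export.

A deterministic Needleman–Wunsch global aligner (linear gap penalty,
fixed tie-break) and a center-star progressive multiple aligner support
two downstream products: %INUC — the percentage of alignment columns in
which every compared genome carries the same unambiguous nucleotide — and
the concatenated 13-PCG supermatrix, aligned at the amino-acid level with
nucleotide triplets threaded back through the protein alignment, with
per-gene and per-codon-position partitions for phylogenetic software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    GeneticCode,
    INVERTEBRATE_MITO,
    MitoGenome,
    PCG_NAMES,
    extract_gene_sequence,
    translate,
)

GAP = "-"

#: default scoring (match, mismatch, gap)
NUC_SCORES = (1, -1, -2)
PROT_SCORES = (1, 0, -1)


@dataclass
class Alignment:
    rows: list[tuple[str, str]]            # (label, gapped sequence)
    score: Optional[int] = None

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def degapped(self) -> dict[str, str]:
        return {label: seq.replace(GAP, "") for label, seq in self.rows}

    def column(self, i: int) -> list[str]:
        return [seq[i] for _, seq in self.rows]


def pairwise_align(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2,
    labels: tuple[str, str] = ("a", "b"),
) -> Alignment:
    """Global alignment with linear gap penalty.

    Tie-break in the traceback is diagonal > up (gap in ``b``) > left
    (gap in ``a``), making the alignment deterministic.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0] = gap * np.arange(m + 1)
    H[1:, 0] = gap * np.arange(1, n + 1)
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(b_arr == a_arr[i - 1], match, mismatch)
        best = np.maximum(H[i - 1, :m] + sub, H[i - 1, 1:] + gap)
        # fold in the left-dependency H[i,j] = max(best[j], H[i,j-1] + gap)
        # via a prefix max of best[j] - j*gap
        shifted = np.empty(m + 1, dtype=np.int64)
        shifted[0] = H[i, 0]
        shifted[1:] = best - gap * js
        H[i, 1:] = np.maximum.accumulate(shifted)[1:] + gap * js
    ga, gb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            ga.append(a[i - 1]); gb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            ga.append(a[i - 1]); gb.append(GAP); i -= 1
        else:
            ga.append(GAP); gb.append(b[j - 1]); j -= 1
    return Alignment(
        rows=[(labels[0], "".join(reversed(ga))), (labels[1], "".join(reversed(gb)))],
        score=int(H[n, m]),
    )


def progressive_msa(
    seqs: Sequence[str],
    labels: Optional[Sequence[str]] = None,
    match: int = 1, mismatch: int = -1, gap: int = -2,
) -> Alignment:
    """Center-star progressive multiple alignment.

    The center is the sequence maximising its summed pairwise alignment
    score against all others (ties to the lowest index); every other
    sequence is aligned to the center and merged under the
    once-a-gap-always-a-gap rule.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = list(labels) if labels is not None else [f"seq{i}" for i in range(len(seqs))]
    k = len(seqs)
    sums = [0] * k
    pair_scores: dict[tuple[int, int], int] = {}
    for i in range(k):
        for j in range(i + 1, k):
            s = pairwise_align(seqs[i], seqs[j], match, mismatch, gap).score
            pair_scores[(i, j)] = s
            sums[i] += s
            sums[j] += s
    center = max(range(k), key=lambda i: (sums[i], -i))

    master = seqs[center]            # center with accumulated gaps
    merged: list[str] = []           # non-center rows, aligned to master
    order = [i for i in range(k) if i != center]
    for idx in order:
        aln = pairwise_align(master.replace(GAP, ""), seqs[idx], match, mismatch, gap)
        gc, gs = aln.rows[0][1], aln.rows[1][1]
        # re-insert master's existing gap columns into (gc, gs)
        new_master, new_row = [], []
        updated = ["" for _ in merged]
        mi = ci = 0
        while mi < len(master) or ci < len(gc):
            m_char = master[mi] if mi < len(master) else None
            c_char = gc[ci] if ci < len(gc) else None
            if m_char == GAP and (c_char != GAP or ci >= len(gc)):
                new_master.append(GAP); new_row.append(GAP)
                for r, row in enumerate(merged):
                    updated[r] += row[mi]
                mi += 1
            elif c_char == GAP and (m_char != GAP or mi >= len(master)):
                new_master.append(GAP); new_row.append(gs[ci])
                for r in range(len(merged)):
                    updated[r] += GAP
                ci += 1
            else:
                new_master.append(m_char); new_row.append(gs[ci])
                for r, row in enumerate(merged):
                    updated[r] += row[mi]
                mi += 1; ci += 1
        master = "".join(new_master)
        merged = updated
        merged.append("".join(new_row))

    rows = [(labels[center], master)]
    rows += [(labels[idx], merged[pos]) for pos, idx in enumerate(order)]
    by_label = dict(rows)
    return Alignment(rows=[(lab, by_label[lab]) for lab in labels])


def percent_inuc(aln: Alignment) -> float:
    """Percentage of columns identical in unambiguous nucleotide across all
    rows (gaps and ambiguity codes count as non-identical); 1 d.p."""
    if len(aln.rows) < 2:
        raise ValueError("need at least two rows")
    if aln.length == 0:
        raise ValueError("zero-length alignment")
    ident = 0
    for i in range(aln.length):
        col = aln.column(i)
        if col[0] in "ACGT" and all(c == col[0] for c in col[1:]):
            ident += 1
    return round(100 * ident / aln.length, 1)


def gene_inuc(
    genomes: Sequence[MitoGenome], genes: Sequence[str]
) -> dict[str, float]:
    """%INUC per orthologous gene, from a fresh nucleotide MSA of each."""
    out: dict[str, float] = {}
    for gene in genes:
        have = [(g.id, extract_gene_sequence(g, g.get(gene)))
                for g in genomes if g.get(gene) is not None]
        if len(have) < 2:
            warnings.warn(f"gene {gene}: fewer than two genomes carry it; skipped")
            continue
        aln = progressive_msa([s for _, s in have], labels=[l for l, _ in have])
        out[gene] = percent_inuc(aln)
    return out


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    name: str
    start: int          # 1-based inclusive
    end: int
    codon_position: Optional[int] = None

    def raxml(self) -> str:
        if self.codon_position is None:
            return f"DNA, {self.name} = {self.start}-{self.end}"
        return (f"DNA, {self.name}_pos{self.codon_position} = "
                f"{self.start + self.codon_position - 1}-{self.end}\\3")

    def nexus(self) -> str:
        if self.codon_position is None:
            return f"charset {self.name} = {self.start}-{self.end};"
        return (f"charset {self.name}_pos{self.codon_position} = "
                f"{self.start + self.codon_position - 1}-{self.end}\\3;")


@dataclass
class Supermatrix:
    alignment: Alignment
    partitions: list[Partition] = field(default_factory=list)

    @property
    def gene_partitions(self) -> list[Partition]:
        return [p for p in self.partitions if p.codon_position is None]

    @property
    def codon_partitions(self) -> list[Partition]:
        return [p for p in self.partitions if p.codon_position is not None]

    def to_fasta(self) -> str:
        return "".join(f">{lab}\n{seq}\n" for lab, seq in self.alignment.rows)

    def to_phylip(self) -> str:
        lines = [f"{len(self.alignment.rows)} {self.alignment.length}"]
        lines += [f"{lab}  {seq}" for lab, seq in self.alignment.rows]
        return "\n".join(lines) + "\n"

    def raxml_partitions(self) -> str:
        return "\n".join(p.raxml() for p in self.partitions) + "\n"

    def nexus_charsets(self) -> str:
        body = "\n".join("  " + p.nexus() for p in self.partitions)
        return f"begin sets;\n{body}\nend;\n"


def _coding_portion(cds: str, code: GeneticCode) -> str:
    """Trim a CDS to its complete non-stop codons (drop incomplete tail and
    the terminal stop)."""
    cds = cds[: len(cds) - len(cds) % 3]
    while len(cds) >= 3 and cds[-3:] in code.stop_codons:
        cds = cds[:-3]
    return cds


def build_supermatrix(
    genomes: Sequence[MitoGenome],
    genes: Sequence[str] = PCG_NAMES,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> Supermatrix:
    """Concatenated amino-acid-guided nucleotide supermatrix of ``genes``.

    Each gene set is translated, aligned as protein, and the original
    codons are threaded back through the protein alignment (a residue gap
    becomes a codon gap).  Genomes missing any requested gene are dropped
    with a warning.  Partitions are emitted per gene and per codon position.
    """
    kept = []
    for g in genomes:
        missing = [gene for gene in genes if g.get(gene) is None]
        if missing:
            warnings.warn(f"{g.id}: missing {missing}; dropped from supermatrix")
        else:
            kept.append(g)
    if len(kept) < 2:
        raise ValueError("fewer than two genomes carry all requested genes")

    labels = [g.id for g in kept]
    concatenated = {lab: "" for lab in labels}
    partitions: list[Partition] = []
    offset = 0
    for gene in genes:
        cdss = {
            g.id: _coding_portion(extract_gene_sequence(g, g.get(gene)), code)
            for g in kept
        }
        prots = {lab: translate(cds, code, complete_stop=False) for lab, cds in cdss.items()}
        paln = progressive_msa(
            [prots[lab] for lab in labels], labels=labels, match=PROT_SCORES[0],
            mismatch=PROT_SCORES[1], gap=PROT_SCORES[2],
        )
        for lab, gapped in paln.rows:
            threaded, pos, cds = [], 0, cdss[lab]
            for ch in gapped:
                if ch == GAP:
                    threaded.append(GAP * 3)
                else:
                    threaded.append(cds[pos : pos + 3])
                    pos += 3
            concatenated[lab] += "".join(threaded)
        gene_len = 3 * paln.length
        partitions.append(Partition(gene, offset + 1, offset + gene_len))
        for pos in (1, 2, 3):
            partitions.append(Partition(gene, offset + 1, offset + gene_len, pos))
        offset += gene_len
    return Supermatrix(
        alignment=Alignment(rows=[(lab, concatenated[lab]) for lab in labels]),
        partitions=partitions,
    )
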