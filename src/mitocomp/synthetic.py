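"""Synthetic annotated mitogenomes with known ground truth.

The generator emits circular ~15–16 kb planthopper-like mitogenomes
carrying the 37 canonical genes plus a control region, in either the
ancestral insect gene order or the Delphacidae-rearranged order.  Planted
properties — gene coordinates, junction overlap motifs (the 7-bp
"ATGATAA" at atp8/atp6 and the 8-bp "AAGCCTTA" at trnW/trnC), control
region tandem repeats (135 bp x 5 copies by default), whole-genome base
composition and the amino-acid usage bias of the protein-coding genes —
are recorded in a GroundTruth manifest so that every analysis module can
be checked against a known answer.

Protein-coding sequences are built codon by codon: an amino-acid class is
drawn from the bias weights (defaulting to the AT-rich planthopper profile
with Phe > Ile > Met > Leu2 > Ser2), then a codon within the class with
A-ending codons favoured and G-ending rare.  Non-coding sequence (tRNAs,
rRNAs, spacers, control region) is drawn from a background base
distribution solved so that the expected whole-genome composition equals
the requested A+T content and skews.  tRNA and rRNA sequences are plain
background at the target composition; no cloverleaf structure is modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .architecture import ANCESTRAL_ORDER, DELPHACID_ORDER
from .codon import aa_class, codon_families
from .model import GeneFeature, GeneticCode, INVERTEBRATE_MITO, MitoGenome, reverse_complement

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default amino-acid class weights; plants Phe > Ile > Met > Leu2 > Ser2
#: with the top five classes making up more than half of all residues
DEFAULT_AA_WEIGHTS: dict[str, float] = {
    "Phe": 0.130, "Ile": 0.118, "Met": 0.104, "Leu2": 0.094, "Ser2": 0.086,
    "Asn": 0.040, "Gly": 0.040, "Tyr": 0.035, "Lys": 0.035, "Thr": 0.035,
    "Val": 0.030, "Ala": 0.030, "Ser1": 0.025, "Pro": 0.025, "Leu1": 0.020,
    "Glu": 0.020, "Asp": 0.020, "His": 0.020, "Trp": 0.015, "Gln": 0.015,
    "Arg": 0.015, "Cys": 0.008,
}

#: third-position base preference within a codon family (NNA common, NNG rare)
DEFAULT_WOBBLE_WEIGHTS: dict[str, float] = {"A": 0.55, "T": 0.30, "C": 0.10, "G": 0.05}

#: protein-coding gene lengths (nt, including start and stop) at realistic
#: insect-mitogenome magnitudes; lengths mod 3 encode the default stop type
DEFAULT_PCG_LENGTHS: dict[str, int] = {
    "nad2": 975, "cox1": 1533, "cox2": 682, "atp8": 156, "atp6": 675,
    "cox3": 786, "nad3": 351, "nad5": 1715, "nad4": 1338, "nad4l": 288,
    "nad6": 498, "cob": 1134, "nad1": 927,
}

DEFAULT_STOP_TYPES: dict[str, str] = {"cox2": "T", "nad5": "TA"}  # others TAA
DEFAULT_START_CODONS: dict[str, str] = {"nad1": "GTG"}           # others ATG

DEFAULT_OVERLAPS: dict[tuple[str, str], str] = {
    ("atp8", "atp6"): "ATGATAA",
    ("trnW", "trnC"): "AAGCCTTA",
}

_TEMPLATES = {"ancestral": ANCESTRAL_ORDER, "delphacid": DELPHACID_ORDER}


@dataclass
class GenomeSpec:
    """Parameters of one synthetic mitogenome."""

    template: str = "ancestral"          # "ancestral" | "delphacid"
    seed: int = 0
    label: str = "SYN"
    organism: str = "synthetic planthopper"
    at_content: float = 0.76             # whole-genome A+T fraction
    at_skew: float = 0.17                # whole-genome, published strand
    gc_skew: float = -0.17
    pcg_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    trna_length_range: tuple[int, int] = (55, 72)
    rrn_lengths: dict[str, int] = field(
        default_factory=lambda: {"rrnL": 1200, "rrnS": 780})
    cr_background: int = 700             # CR length excluding planted repeats
    cr_repeats: tuple[tuple[int, int], ...] = ((135, 5),)   # (unit bp, copies)
    overlaps: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAPS))
    spacer_range: tuple[int, int] = (0, 5)
    start_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_START_CODONS))
    stop_types: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STOP_TYPES))
    aa_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_WEIGHTS))
    wobble_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WOBBLE_WEIGHTS))
    rotate: int = 0                      # rotate origin by this many nt

    def order(self) -> tuple[tuple[str, str], ...]:
        if self.template not in _TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        return _TEMPLATES[self.template]

    def validate(self) -> None:
        for gene, length in self.pcg_lengths.items():
            stop = self.stop_types.get(gene, "TAA")
            need = {"TAA": 0, "TAG": 0, "TA": 2, "T": 1}[stop]
            if length % 3 != need:
                raise ValueError(
                    f"{gene}: length {length} incompatible with stop type {stop!r}")
            if length < 9:
                raise ValueError(f"{gene}: length {length} too short")
        for (up, down), motif in self.overlaps.items():
            limit = min(self._gene_length_bound(up), self._gene_length_bound(down))
            if len(motif) >= limit:
                raise ValueError(
                    f"overlap motif {motif!r} at {up}/{down} longer than the genes")
        for period, copies in self.cr_repeats:
            if period < 1 or copies < 2:
                raise ValueError("repeat unit length must be >=1 and copies >=2")
        if not (0 < self.at_content < 1):
            raise ValueError("at_content must be in (0,1)")

    def _gene_length_bound(self, gene: str) -> int:
        if gene in self.pcg_lengths:
            return self.pcg_lengths[gene]
        if gene in self.rrn_lengths:
            return self.rrn_lengths[gene]
        return self.trna_length_range[0]


@dataclass
class PlantedRepeat:
    cr_start: int
    genome_start: int
    period: int
    copies: int
    unit: str


@dataclass
class GroundTruth:
    """What was actually written into a generated genome."""

    template: str
    genome_length: int
    coordinates: dict[str, tuple[int, int, str]]
    overlaps: dict[tuple[str, str], str]
    repeats: list[PlantedRepeat]
    base_counts: dict[str, int]          # realized whole-genome counts
    target_at: float
    aa_ranking: list[str]                # realized top-5 amino-acid classes

    @property
    def at_content(self) -> float:
        n = sum(self.base_counts.values())
        return (self.base_counts["A"] + self.base_counts["T"]) / n

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["overlaps"] = {f"{u}/{v}": m for (u, v), m in self.overlaps.items()}
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# sequence sampling helpers
# ---------------------------------------------------------------------------

def _codon_distribution(
    spec: GenomeSpec, code: GeneticCode = INVERTEBRATE_MITO
) -> tuple[list[str], np.ndarray]:
    """Non-stop codon sampling distribution from the amino-acid class
    weights and the third-position wobble preference."""
    fams = codon_families(code, split_leu_ser=True)
    codons: list[str] = []
    probs: list[float] = []
    total_w = sum(spec.aa_weights.get(label, 0.0) for label in fams)
    for label, family in fams.items():
        class_w = spec.aa_weights.get(label, 0.0) / total_w
        wobble = np.array([spec.wobble_weights[c[2]] for c in family], dtype=float)
        wobble /= wobble.sum()
        for codon, w in zip(family, wobble):
            codons.append(codon)
            probs.append(class_w * w)
    p = np.asarray(probs, dtype=float)
    return codons, p / p.sum()


def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """[A, C, G, T] probabilities from content/skew targets."""
    gc = 1.0 - at
    return np.array([
        at * (1 + at_skew) / 2,
        gc * (1 - gc_skew) / 2,
        gc * (1 + gc_skew) / 2,
        at * (1 - at_skew) / 2,
    ])


def _counts_of(seq: str) -> np.ndarray:
    return np.array([seq.count(b) for b in "ACGT"], dtype=float)


def _sample_background(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_mitogenome(
    spec: GenomeSpec, code: GeneticCode = INVERTEBRATE_MITO
) -> tuple[MitoGenome, GroundTruth]:
    """Emit one annotated genome and its ground-truth manifest.

    Identical specs (including seed) give byte-identical genomes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = spec.order()
    codons, codon_p = _codon_distribution(spec, code)

    # -- draw the layout first so the background composition can be solved
    gene_lengths: dict[str, int] = {}
    for name, _strand in order:
        if name in spec.pcg_lengths:
            gene_lengths[name] = spec.pcg_lengths[name]
        elif name in spec.rrn_lengths:
            gene_lengths[name] = spec.rrn_lengths[name]
        elif name == "CR":
            gene_lengths[name] = spec.cr_background + sum(
                p * c for p, c in spec.cr_repeats)
        else:
            lo, hi = spec.trna_length_range
            gene_lengths[name] = int(rng.integers(lo, hi + 1))

    adjacent_pairs = {
        (order[i][0], order[(i + 1) % len(order)][0]) for i in range(len(order))
    }
    realized_overlaps = {
        pair: motif for pair, motif in spec.overlaps.items() if pair in adjacent_pairs
    }
    spacers: dict[int, int] = {}
    for i in range(len(order)):
        up, down = order[i][0], order[(i + 1) % len(order)][0]
        if (up, down) in realized_overlaps:
            spacers[i] = -len(realized_overlaps[(up, down)])
        elif "CR" in (up, down):
            # the control region is the entire intergenic span by definition
            spacers[i] = 0
        else:
            spacers[i] = int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1))
    genome_length = sum(gene_lengths.values()) + sum(spacers.values())

    # -- expected published-strand base counts contributed by the PCGs
    base_idx = {b: i for i, b in enumerate("ACGT")}
    codon_base = np.zeros((len(codons), 4))
    for k, codon in enumerate(codons):
        for b in codon:
            codon_base[k, base_idx[b]] += 1
    exp_codon_bases = codon_p @ codon_base          # per body codon
    pcg_counts = np.zeros(4)
    strand_of = dict(order)
    for gene, length in spec.pcg_lengths.items():
        start = spec.start_codons.get(gene, "ATG")
        stop = {"TAA": "TAA", "TAG": "TAG", "TA": "TA", "T": "T"}[
            spec.stop_types.get(gene, "TAA")]
        n_body = (length - 3 - len(stop)) // 3
        reading = n_body * exp_codon_bases + _counts_of(start) + _counts_of(stop)
        if strand_of[gene] == "L":
            reading = reading[::-1]     # A<->T, C<->G under complement
        pcg_counts += reading

    target_counts = genome_length * _base_probs(
        spec.at_content, spec.at_skew, spec.gc_skew)
    bg_len = genome_length - sum(
        spec.pcg_lengths[g] for g in spec.pcg_lengths) - sum(
        min(0, s) for s in spacers.values())
    bg_probs = (target_counts - pcg_counts) / max(bg_len, 1)
    bg_probs = np.clip(bg_probs, 0.005, None)
    bg_probs = bg_probs / bg_probs.sum()

    # -- build gene sequences (published strand)
    def pcg_sequence(gene: str) -> str:
        length = spec.pcg_lengths[gene]
        start = spec.start_codons.get(gene, "ATG")
        stop = spec.stop_types.get(gene, "TAA")
        n_body = (length - 3 - len(stop)) // 3
        body = "".join(rng.choice(codons, size=n_body, p=codon_p))
        return start + body + stop

    cr_seq, planted_repeats = _control_region_sequence(spec, rng, bg_probs)
    gene_seq: dict[str, str] = {}
    for name, strand in order:
        if name in spec.pcg_lengths:
            reading = pcg_sequence(name)
            gene_seq[name] = reading if strand == "H" else reverse_complement(reading)
        elif name == "CR":
            gene_seq[name] = cr_seq
        else:
            gene_seq[name] = _sample_background(rng, gene_lengths[name], bg_probs)

    # -- plant junction overlap motifs (published strand, shared nucleotides)
    for (up, down), motif in realized_overlaps.items():
        k = len(motif)
        gene_seq[up] = gene_seq[up][:-k] + motif
        gene_seq[down] = motif + gene_seq[down][k:]

    # -- assemble the circle
    seq = ["N"] * genome_length
    features: list[GeneFeature] = []
    coordinates: dict[str, tuple[int, int, str]] = {}
    cursor = 0
    from .model import normalize_gene_name

    for i, (name, strand) in enumerate(order):
        start = cursor
        s = gene_seq[name]
        for j, ch in enumerate(s):
            seq[(start + j) % genome_length] = ch
        end = start + len(s)
        ftype = "control_region" if name == "CR" else normalize_gene_name(name)[1]
        features.append(GeneFeature(name=name, type=ftype, strand=strand,
                                    start=start, end=end))
        coordinates[name] = (start, end, strand)
        cursor = end + spacers[i]

    # -- fill spacers with background
    occupied = [False] * genome_length
    for name, (s, e, _st) in coordinates.items():
        for j in range(s, e):
            occupied[j % genome_length] = True
    gaps = [j for j in range(genome_length) if not occupied[j]]
    fill = _sample_background(rng, len(gaps), bg_probs)
    for j, ch in zip(gaps, fill):
        seq[j] = ch

    sequence = "".join(seq)

    # -- optional rotation of the origin (produces origin-spanning features)
    r = spec.rotate % genome_length
    if r:
        sequence = sequence[r:] + sequence[:r]
        rotated = []
        for f in features:
            ns = (f.start - r) % genome_length
            rotated.append(dataclasses.replace(f, start=ns, end=ns + f.length))
        features = rotated
        coordinates = {f.name: (f.start, f.end, f.strand) for f in features}

    cr_start = coordinates["CR"][0]
    for rep in planted_repeats:
        rep.genome_start = (cr_start + rep.cr_start) % genome_length

    genome = MitoGenome(
        id=spec.label,
        sequence=sequence,
        organism=spec.organism,
        circular=True,
        features=sorted(features, key=lambda f: (f.start, f.end, f.name)),
    )
    counts = {b: sequence.count(b) for b in "ACGT"}
    # realized amino-acid class usage of the emitted coding sequences
    # (ground truth records what was written, not the sampling target)
    class_counts: dict[str, int] = {}
    for gene in spec.pcg_lengths:
        reading = gene_seq[gene]
        if strand_of[gene] == "L":
            reading = reverse_complement(reading)
        for i in range(0, len(reading) - len(reading) % 3, 3):
            label = aa_class(reading[i : i + 3], code)
            if label is not None:
                class_counts[label] = class_counts.get(label, 0) + 1
    ranking = sorted(class_counts, key=lambda a: (-class_counts[a], a))[:5]
    truth = GroundTruth(
        template=spec.template,
        genome_length=genome_length,
        coordinates=coordinates,
        overlaps=realized_overlaps,
        repeats=planted_repeats,
        base_counts=counts,
        target_at=spec.at_content,
        aa_ranking=ranking,
    )
    return genome, truth


def _control_region_sequence(
    spec: GenomeSpec, rng: np.random.Generator, bg_probs: np.ndarray
) -> tuple[str, list[PlantedRepeat]]:
    """Background CR with tandem repeat arrays planted at known offsets.

    Repeat units are resampled until primitive (no sub-period), and the
    background characters flanking each array are adjusted so the array
    cannot be extended — the scanner must recover exactly the planted
    period and copy number.
    """
    n_rep = len(spec.cr_repeats)
    chunk = spec.cr_background // (n_rep + 1)
    pieces: list[str] = []
    repeats: list[PlantedRepeat] = []
    pos = 0
    for idx, (period, copies) in enumerate(spec.cr_repeats):
        bg = _sample_background(rng, chunk, bg_probs)
        pieces.append(bg)
        pos += len(bg)
        unit = _sample_background(rng, period, bg_probs)
        while _is_periodic(unit):
            unit = _sample_background(rng, period, bg_probs)
        pieces.append(unit * copies)
        repeats.append(PlantedRepeat(cr_start=pos, genome_start=-1,
                                     period=period, copies=copies, unit=unit))
        pos += period * copies
    tail = spec.cr_background - chunk * n_rep
    pieces.append(_sample_background(rng, tail, bg_probs))
    cr = list("".join(pieces))
    # forbid extension of each array into its flanks
    for rep in repeats:
        s, e, p = rep.cr_start, rep.cr_start + rep.period * rep.copies, rep.period
        if s > 0 and cr[s - 1] == cr[s - 1 + p]:
            cr[s - 1] = _different_base(cr[s - 1 + p], bg_probs)
        if e < len(cr) and cr[e] == cr[e - p]:
            cr[e] = _different_base(cr[e - p], bg_probs)
    return "".join(cr), repeats


def _is_periodic(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return True
    return False


def _different_base(avoid: str, bg_probs: np.ndarray) -> str:
    ranked = sorted(zip("ACGT", bg_probs), key=lambda kv: -kv[1])
    for b, _w in ranked:
        if b != avoid:
            return b
    raise AssertionError


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------

def achilid_like_spec(**overrides) -> GenomeSpec:
    """Ancestral-order spec at Achilidae-like composition."""
    return GenomeSpec(**({"template": "ancestral", "at_content": 0.765,
                          "at_skew": 0.20, "label": "achilid"} | overrides))


def delphacid_like_spec(**overrides) -> GenomeSpec:
    """Rearranged-order spec with the lower AT-skew typical of Delphacidae."""
    return GenomeSpec(**({"template": "delphacid", "at_content": 0.748,
                          "at_skew": 0.06, "label": "delphacid"} | overrides))


def generate_clade(
    n_a: int,
    n_b: int,
    spec_a: Optional[GenomeSpec] = None,
    spec_b: Optional[GenomeSpec] = None,
    seed: int = 0,
    jitter_at: float = 0.004,
    jitter_skew: float = 0.02,
) -> tuple[list[MitoGenome], list[GroundTruth]]:
    """Two groups of genomes drawn around two parameter sets.

    Group A defaults to the ancestral/Achilidae-like spec and group B to
    the Delphacidae-like spec (rearranged order, lower AT-skew); each
    genome gets deterministic per-genome jitter on composition targets.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one genome")
    spec_a = spec_a or achilid_like_spec()
    spec_b = spec_b or delphacid_like_spec()
    master = np.random.default_rng(seed)
    genomes: list[MitoGenome] = []
    truths: list[GroundTruth] = []
    for group, base, n in (("A", spec_a, n_a), ("B", spec_b, n_b)):
        for i in range(n):
            child = dataclasses.replace(
                base,
                seed=int(master.integers(0, 2**31 - 1)),
                label=f"{base.label}_{group}{i + 1}",
                at_content=base.at_content + float(master.uniform(-jitter_at, jitter_at)),
                at_skew=base.at_skew + float(master.uniform(-jitter_skew, jitter_skew)),
            )
            g, t = generate_mitogenome(child)
            genomes.append(g)
            truths.append(t)
    return genomes, truths
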