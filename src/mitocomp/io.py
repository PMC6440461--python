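"""GenBank and FASTA input/output.

GenBank flat files carry 1-based inclusive coordinates; everything inside
the package is 0-based half-open.  Biopython does that conversion for us.
A feature spanning the origin of the circular molecule appears in GenBank
as a two-part ``join()`` location; internally it becomes a single interval
with ``end > genome length``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import GeneFeature, MitoGenome, normalize_gene_name

PathLike = Union[str, Path]

#: GenBank feature keys parsed into gene features
_PARSED_KEYS = {"CDS", "tRNA", "rRNA", "misc_feature", "D-loop"}

_KEY_BY_TYPE = {
    "PCG": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "D-loop",
    "other": "misc_feature",
}


class GenBankParseError(ValueError):
    pass


def _feature_label(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    if feat.type == "D-loop":
        return "D-loop"
    return None


def _span(feat: SeqFeature, genome_length: int) -> tuple[int, int]:
    loc = feat.location
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == genome_length:
        # origin-spanning join(): tail of the molecule + head
        return int(parts[1].start), genome_length + int(parts[0].end)
    return int(loc.start), int(loc.end)


def read_genbank(path: PathLike) -> list[MitoGenome]:
    """Read one or more annotated mitogenomes from a GenBank flat file."""
    genomes = []
    try:
        with open(path) as handle:
            records = list(SeqIO.parse(handle, "genbank"))
    except OSError:
        raise
    except Exception as exc:  # biopython raises assorted ValueError subclasses
        raise GenBankParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenBankParseError(f"no GenBank records found in {path}")
    for rec in records:
        try:
            genomes.append(_record_to_genome(rec))
        except GenBankParseError:
            raise
        except Exception as exc:
            raise GenBankParseError(f"malformed record {rec.id!r}: {exc}") from exc
    return genomes


def _record_to_genome(rec: SeqRecord) -> MitoGenome:
    seq = str(rec.seq).upper()
    features: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type not in _PARSED_KEYS:
            continue
        label = _feature_label(feat)
        if label is None:
            warnings.warn(f"{rec.id}: unnamed {feat.type} feature skipped")
            continue
        anticodon = None
        if "anticodon" in feat.qualifiers:
            ac = str(feat.qualifiers["anticodon"][0])
            # qualifier may be a bare triplet or the full "(pos:..,aa:..,seq:xxx)"
            anticodon = ac.split("seq:")[-1].rstrip(")").upper() if "seq:" in ac else ac.upper()
        name, ftype = normalize_gene_name(label, anticodon=anticodon)
        if ftype == "other":
            warnings.warn(f"{rec.id}: unmappable gene name {label!r}; typed 'other'")
        start, end = _span(feat, len(seq))
        strand = "L" if feat.location.strand == -1 else "H"
        features.append(
            GeneFeature(name=name, type=ftype, strand=strand,
                        start=start, end=end, anticodon=anticodon)
        )
    if not features:
        warnings.warn(f"{rec.id}: record has no gene features")
    topology = rec.annotations.get("topology", "circular")
    organism = rec.annotations.get("organism", "")
    return MitoGenome(
        id=rec.id or rec.name,
        sequence=seq,
        organism=organism,
        circular=(topology == "circular"),
        features=sorted(features, key=lambda f: (f.start, f.end, f.name)),
    )


def _location(f: GeneFeature, genome_length: int):
    strand = -1 if f.strand == "L" else 1
    if f.end <= genome_length:
        return SimpleLocation(f.start, f.end, strand=strand)
    head = SimpleLocation(f.start, genome_length, strand=strand)
    tail = SimpleLocation(0, f.end - genome_length, strand=strand)
    parts = [head, tail] if strand == 1 else [tail, head]
    return CompoundLocation(parts)


def write_genbank(genome: MitoGenome, path: PathLike) -> None:
    """Write a genome as a parseable GenBank record.

    ``read_genbank(write_genbank(g))`` recovers ``g`` up to feature ordering.
    """
    n = genome.length
    for f in genome.features:
        if not (0 <= f.start < n and f.end <= 2 * n):
            raise ValueError(f"feature {f.name} span [{f.start},{f.end}) outside [0,{2 * n})")
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.split(".")[0][:16] or "mitogenome",
        description=f"{genome.organism} mitochondrion, complete genome".strip(),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.organism,
        },
    )
    rec.features.append(SeqFeature(SimpleLocation(0, n, strand=1), type="source"))
    for f in genome.sorted_features():
        qualifiers = {"gene": [f.name]}
        if f.anticodon:
            qualifiers["anticodon"] = [f.anticodon]
        rec.features.append(
            SeqFeature(_location(f, n), type=_KEY_BY_TYPE[f.type], qualifiers=qualifiers)
        )
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: PathLike) -> list[MitoGenome]:
    """Read unannotated sequences as genomes with empty feature lists."""
    genomes = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            genomes.append(MitoGenome(id=rec.id, sequence=str(rec.seq),
                                      organism=rec.description.partition(" ")[2]))
    if not genomes:
        raise GenBankParseError(f"no FASTA records found in {path}")
    return genomes


def write_fasta(genomes: list[MitoGenome] | MitoGenome, path: PathLike) -> None:
    if isinstance(genomes, MitoGenome):
        genomes = [genomes]
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description=g.organism) for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")
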