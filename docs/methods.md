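# Methods

`mitocomp` implements the comparative-mitogenomics workflow used to
characterise newly sequenced insect mitochondrial genomes against their
relatives: genome architecture (gene order, junction overlaps and spacers,
control-region repeats), nucleotide and codon-level composition statistics,
conservation scoring of orthologous genes, compositional clustering, and
export of a concatenated protein-coding supermatrix for phylogenetic
software. This note records the models, conventions, numerical choices and
limitations behind each step.

## Coordinate model

Genomes are circular. Internally all coordinates are 0-based half-open on
the published (majority heavy-strand) orientation; GenBank I/O converts
to/from the format's 1-based inclusive convention. A feature crossing the
origin is stored as a single interval with `end > genome length` — never
split — so junction arithmetic (`gap = next.start − prev.end`) needs no
special cases. On write, such a feature becomes a two-part `join()`
location; on read the two parts are fused back. Sequence extraction works
on the doubled sequence string and reverse-complements L-strand features.

IUPAC ambiguity codes are retained in sequences but excluded from every
composition numerator and denominator. Duplicate canonical gene names are
rejected unless a genome is explicitly flagged as carrying duplicates.

## Composition and skews

Strand asymmetry follows the standard definitions

    AT-skew = (A − T) / (A + T)        GC-skew = (G − C) / (G + C)

computed over unambiguous bases; a skew with a zero denominator is reported
as null. Percentages are rendered to 1 decimal place and skews to 3 in the
tabular reports. The standard per-genome profile set covers the whole
genome, the concatenated protein-coding genes (all, H-strand-only,
L-strand-only, each gene), the concatenated tRNAs, both rRNAs and the
control region; L-strand genes are read in their own orientation (reverse
complement) before concatenation, while the whole-genome profile is taken
on the published strand as-is. Because it is ambiguous whether a
whole-genome A+T figure should include the hypervariable control region,
profiles are emitted both with (`whole_genome`) and without it
(`whole_genome_minus_CR`).

## Codon usage

Start codons are classed ATN / GTG / TTG / other from the literal first
triplet. Stop classes are read off the CDS tail: a length divisible by
three ends in a full TAA/TAG (or "other"); remainders of 2 and 1 are the
incomplete stops TA and T, completed to TAA by post-transcriptional
polyadenylation. Translation uses NCBI table 5 (invertebrate
mitochondrial: AGA/AGG→Ser, ATA→Met, TGA→Trp).

RSCU(c) = count(c)·|F| / Σ_{c′∈F} count(c′) over the synonymous family F.
Stop codons and incomplete trailing codons are excluded from counting;
literal start triplets are counted as themselves (the MEGA convention).
The six-fold leucine and serine families are split by codon class —
Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN — into separate RSCU
families of 4+2 and 4+4 codons, matching the Leu2/Ser2 accounting used in
insect mitogenomics; a six-codon-family dialect (`split_leu_ser=False`) is
provided because published tables differ on this point. Amino-acid usage
is reported as CDspT (codons per thousand codons; sums to 1000 up to
rounding), and family orderings are rendered as descending chains with
exact ties joined by "/" (e.g. "Ile/Leu2").

## Gene order and rearrangements

A genome's gene order is its features sorted by start around the circle,
linearised at trnI (alphabetically first gene when trnI is absent). The
built-in reference is the putative ancestral insect arrangement; a
Delphacidae-style variant (trnW/trnC exchanged; trnT/trnP exchanged with
nad6 repositioned) is also built in. Rearrangement magnitude is the
breakpoint distance: the number of directed, strand-aware circular
adjacencies of the observed order absent from the reference. Two genes
adjacent in both orders but in opposite relative order are reported as a
swapped pair; a gene whose predecessor and successor both changed — and
which is not part of a flank-preserving reciprocal swap — is reported as
repositioned. Full sorting-by-reversals event inference is deliberately
out of scope: the report identifies moved genes, not a unique event
history.

## Junctions and the control region

For each consecutive feature pair on the circle the junction gap is
`next.start − prev.end` (negative = overlap; the overlapping
published-strand nucleotides are attached). Each overlapping junction is
counted once, so per-genome totals satisfy the circular closure identity
Σ feature lengths + Σ signed gaps = genome length for non-nested
annotations; nested features are reported with a warning.

The control region is the annotated A+T-rich feature when present;
otherwise it is inferred as the largest annotation-free sub-interval of
the circular arc from the rrnS end to the trnM start — in the ancestral
arrangement exactly the span between rrnS and trnI.

## Tandem repeats

The scanner is an exact-match detector: for each period p it extends
maximal runs of positions satisfying `seq[i] == seq[i−p]`; a run of span s
starting at `start` is s/p copies (possibly fractional) of
`seq[start:start+p]`. Runs below the copy threshold are dropped and
overlapping candidates of different periods are deduplicated by keeping
the longest span, ties going to the smallest period. Unlike
alignment-based tools in the tandem-repeats-finder tradition it admits no
mismatches or indels within the array; this trades sensitivity to
degenerate repeats for determinism and exact testability against an O(n³)
brute-force oracle. Recommended control-region settings: `min_period=10`,
`min_copies=3` (suppresses homopolymer/dinucleotide noise).

## Alignment and conservation

The pairwise aligner is global (Needleman–Wunsch) with match/mismatch
scores and a linear gap penalty, vectorised row-wise over numpy with the
left-dependency folded in as a prefix maximum; the traceback tie-break is
fixed (diagonal > up > left) so alignments are deterministic. Defaults:
nucleotide +1/−1/−2, protein +1/0/−1 — chosen for determinism and exposed
in the API, not tuned to reproduce any external aligner. The multiple
aligner is center-star: the sequence maximising summed pairwise score is
the center and the others are merged against it under
once-a-gap-always-a-gap.

%INUC for a gene is computed on a fresh multiple alignment of its
orthologous sequences: 100 × (columns in which every row carries the same
unambiguous nucleotide) / alignment length, to 1 decimal place. Gaps and
ambiguity codes never count as identical — a conservative convention, so
absolute %INUC values are method-dependent and only relative (rank)
statements are meaningful.

The supermatrix is amino-acid guided: each protein-coding gene is trimmed
to complete non-stop codons, translated, aligned as protein, and the
original codons are threaded back through the protein alignment (a residue
gap becomes a 3-nt gap), so degapping any row recovers its input coding
sequence exactly. Genes are concatenated in canonical order; genomes
missing a requested gene are dropped with a warning rather than padded.
Partitions are emitted per gene and per codon position (RAxML-style and
NEXUS charset syntax).

## Compositional clustering

Genomes are embedded as feature vectors (whole-genome AT%, AT-skew,
GC-skew by default; CDspT entries selectable). Features are z-scored by
default because AT% and skews live on different scales; constant columns
are zeroed with a warning. Distances are Euclidean. Clustering is
agglomerative with average linkage (UPGMA) by default — single and
complete linkage are available — with node height = merge distance / 2 and
merge ties broken by the lexicographically smallest pair of cluster labels
(a cluster is labelled by its smallest leaf), making the tree invariant to
input row order. On an ultrametric input the generating tree is recovered
exactly.

## The synthetic-data generator

The generator is the test substrate: it emits annotated circular genomes
whose every analysed property is planted and recorded in a GroundTruth
manifest.

Study conditions (the defaults): a ~15.9 kb circle carrying the 37
canonical genes plus control region in the ancestral or Delphacidae
arrangement; whole-genome A+T 0.76 with AT-skew +0.17 and GC-skew −0.17 on
the published strand (Achilidae-like and Delphacidae-like presets use
AT-skew 0.20 vs 0.06, inside the published 0.091–0.284 envelope and below
it respectively); protein-coding gene lengths at realistic magnitudes
(156–1,715 nt) with ATG starts except nad1 (GTG) and TAA stops except
cox2 (incomplete T) and nad5 (incomplete TA); tRNAs drawn uniformly from
55–72 nt; rRNAs 1,200/780 nt; a 7-bp ATGATAA overlap at atp8/atp6 and an
8-bp AAGCCTTA overlap at trnW/trnC (the latter absent under the
Delphacidae arrangement, where the genes are no longer adjacent); a
control region of 700 nt background plus a planted 135 bp × 5 tandem
array; inter-gene spacers of 0–5 nt (0 around the control region, which is
the intergenic span by definition).

Coding sequence is sampled codon-by-codon: an amino-acid class is drawn
from bias weights planting Phe > Ile > Met > Leu2 > Ser2 (top five > 50%
of residues), then a codon within the class with third-position preference
A 0.55 / T 0.30 / C 0.10 / G 0.05 — yielding the NNA-rich/NNG-poor usage
and T-rich second positions characteristic of AT-rich insect mitogenomes,
with no rejection steps (stops cannot be drawn). Non-coding background is
sampled i.i.d. from a base distribution solved in expectation so that the
whole genome hits the target composition given the coding sequence's
contribution; the manifest records realized values, and with ~15.9 kb the
realized whole-genome A+T lies within ±0.01 of target with large margin.
Repeat units are resampled until primitive and their flanking bases
adjusted so the array cannot be extended, making period and copy number
exactly recoverable. A `rotate` parameter shifts the origin to produce
origin-spanning features for round-trip testing.

What the generator does **not** emulate: phylogenetic relatedness (each
genome is an independent draw, so synthetic %INUC is low and carries no
evolutionary signal), tRNA/rRNA secondary structure, substitution-model
realism, within-genome composition gradients, and degenerate/imperfect
repeat arrays. Passing tests therefore demonstrate correctness of the
measurement machinery on known inputs, not biological inference on real
data.

## Problem sizes used in the automated checks

The test suite and the acceptance script run entirely on synthetic data at
the default genome scale: 20 generator seeds for planted-parameter
recovery, 8-genome two-group simulations for clustering, 5-genome sets for
supermatrix and conservation scoring, brute-force oracle comparisons on
sequences ≤ 200 nt (repeats) and ≤ 6 nt (alignment scores, exhaustive at
lengths ≤ 2–3 plus random sampling above). These sizes give tight
statistical margins for every planted assertion while the whole suite
completes in well under a minute.

## Known limitations

- The exact-match repeat scanner misses diverged repeat copies that
  alignment-based detectors would merge into one array.
- Breakpoint distance is a magnitude, not an event reconstruction;
  distinguishing tandem-duplication-random-loss from transposition
  histories is out of scope.
- %INUC depends on alignment parameters; values are comparable within one
  run, not across tools.
- The center-star MSA is O(k²) in sequences and does not refine guide
  alignments; for large ortholog sets a dedicated aligner is preferable.
- Inference of the control region requires annotated rrnS and trnM flanks.
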