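"""Gene order, rearrangements, junction accounting and tandem repeats."""

import dataclasses

import numpy as np
import pytest

from mitocomp.architecture import (
    ANCESTRAL_ORDER,
    DELPHACID_ORDER,
    GeneOrder,
    compare_orders,
    control_region,
    find_tandem_repeats,
    gene_order,
    junction_motif,
    junctions,
)
from mitocomp.model import GeneFeature, MitoGenome, extract_gene_sequence
from mitocomp.synthetic import GenomeSpec, generate_mitogenome


class TestGeneOrder:
    def test_ancestral_template_matches_reference(self, ancestral):
        g, _ = ancestral
        assert gene_order(g).genes == ANCESTRAL_ORDER

    def test_rotation_invariance(self):
        g1, _ = generate_mitogenome(GenomeSpec(seed=31))
        g2, _ = generate_mitogenome(GenomeSpec(seed=31, rotate=1000))
        assert gene_order(g1).genes == gene_order(g2).genes

    def test_order_from_coordinates_not_file_order(self, ancestral):
        g, _ = ancestral
        shuffled = dataclasses.replace(g, features=list(reversed(g.features)))
        assert gene_order(shuffled).genes == gene_order(g).genes

    def test_strand_split_23_14(self, ancestral):
        g, _ = ancestral
        strands = [s for name, s in gene_order(g).genes if name != "CR"]
        assert strands.count("H") == 23
        assert strands.count("L") == 14


def _independent_breakpoints(obs, ref):
    """Positional oracle: observed adjacencies whose successor in the
    reference differs (circular, strand-aware)."""
    pos = {g: i for i, (g, _s) in enumerate(ref)}
    strand = dict(ref)
    n = len(ref)
    count = 0
    for i, (g, s) in enumerate(obs):
        ng, ns = obs[(i + 1) % len(obs)]
        ref_next = ref[(pos[g] + 1) % n]
        if s != strand[g] or (ng, ns) != ref_next:
            count += 1
    return count


class TestCompareOrders:
    def test_identity(self):
        r = compare_orders(GeneOrder(ANCESTRAL_ORDER), GeneOrder(ANCESTRAL_ORDER))
        assert r.identical and r.breakpoints == 0
        assert r.swapped_pairs == [] and r.repositioned == []

    def test_delphacid_rearrangement_report(self):
        r = compare_orders(GeneOrder(DELPHACID_ORDER), GeneOrder(ANCESTRAL_ORDER))
        assert not r.identical
        assert ("trnW", "trnC") in r.swapped_pairs
        assert ("trnT", "trnP") in r.swapped_pairs
        assert "nad6" in r.repositioned
        # the reciprocal trnW/trnC exchange keeps its flanks: not repositioned
        assert "trnW" not in r.repositioned and "trnC" not in r.repositioned

    def test_breakpoints_symmetric(self):
        a = compare_orders(GeneOrder(DELPHACID_ORDER), GeneOrder(ANCESTRAL_ORDER))
        b = compare_orders(GeneOrder(ANCESTRAL_ORDER), GeneOrder(DELPHACID_ORDER))
        assert a.breakpoints == b.breakpoints

    def test_random_permutations_match_adjacency_oracle(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(10)]
        ref = tuple((g, "H") for g in genes)
        for _ in range(50):
            perm = list(genes)
            rng.shuffle(perm)
            strands = rng.choice(["H", "L"], size=10)
            obs = tuple((g, s) for g, s in zip(perm, strands))
            r = compare_orders(GeneOrder(obs), GeneOrder(ref))
            assert r.breakpoints == _independent_breakpoints(obs, ref)

    def test_disjoint_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_orders(GeneOrder((("a", "H"),)), GeneOrder((("b", "H"),)))


class TestJunctions:
    def _toy(self, spans, length=40):
        feats = [GeneFeature(f"g{i}", "PCG", "H", s, e) for i, (s, e) in enumerate(spans)]
        return MitoGenome(id="toy", sequence="ACGT" * (length // 4),
                          features=feats, allow_duplicates=True)

    def test_abutting_zero_gap(self):
        g = self._toy([(0, 10), (10, 20)])
        rep = junctions(g)
        assert rep.junctions[0].gap == 0

    def test_overlap_sequence(self):
        g = self._toy([(0, 10), (7, 20)])
        rep = junctions(g)
        assert rep.junctions[0].gap == -3
        assert rep.junctions[0].sequence == g.sequence[7:10]

    def test_circular_closure(self, ancestral):
        g, _ = ancestral
        rep = junctions(g)
        total = sum(f.length for f in g.features) + sum(j.gap for j in rep.junctions)
        assert total == g.length

    def test_planted_overlap_is_longest(self, ancestral):
        g, _ = ancestral
        rep = junctions(g)
        lo = rep.longest_overlap
        assert {lo.upstream, lo.downstream} == {"trnW", "trnC"}
        assert lo.gap == -8
        assert rep.total_overlap == 15  # 7 + 8 planted


class TestJunctionMotif:
    def test_planted_motifs(self, ancestral):
        g, _ = ancestral
        assert junction_motif(g, "atp8", "atp6") == "ATGATAA"
        assert junction_motif(g, "trnW", "trnC") == "AAGCCTTA"

    def test_abutting_genes_none(self, ancestral):
        g, _ = ancestral
        # trnI/trnQ have a non-negative spacer in the generator
        assert junction_motif(g, "trnI", "trnQ") is None

    def test_missing_gene_raises(self, ancestral):
        g, _ = ancestral
        with pytest.raises(ValueError):
            junction_motif(g, "atp8", "nope")


class TestControlRegion:
    def test_annotated_cr_returned(self, ancestral):
        g, truth = ancestral
        cr = control_region(g)
        assert (cr.start, cr.end) == truth.coordinates["CR"][:2]

    def test_inferred_cr_matches_annotation(self, ancestral):
        g, truth = ancestral
        stripped = dataclasses.replace(
            g, features=[f for f in g.features if f.name != "CR"])
        cr = control_region(stripped)
        assert (cr.start, cr.end) == truth.coordinates["CR"][:2]

    def test_origin_spanning_cr_length(self):
        g, truth = generate_mitogenome(GenomeSpec(seed=41, rotate=15200, label="W"))
        cr_truth = truth.coordinates["CR"]
        stripped = dataclasses.replace(
            g, features=[f for f in g.features if f.name != "CR"])
        cr = control_region(stripped)
        assert cr.length == cr_truth[1] - cr_truth[0]
        doubled = g.sequence * 2
        assert doubled[cr.start:cr.end] == doubled[cr_truth[0]:cr_truth[1]]

    def test_no_flanks_raises(self):
        g = MitoGenome(id="x", sequence="ACGT" * 10)
        with pytest.raises(ValueError):
            control_region(g)


def _brute_force_repeats(seq, min_period, max_period, min_copies):
    """O(n^3) oracle: test every (start, period) for maximal exact runs,
    then apply the same longest-span / smallest-period deduplication."""
    n = len(seq)
    cands = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        for s in range(n - 2 * p + 1):
            if s > 0 and seq[s - 1] == seq[s - 1 + p]:
                continue  # not maximal on the left
            e = s + p
            while e < n and seq[e] == seq[e - p]:
                e += 1
            span = e - s
            if span / p >= min_copies:
                cands.append((s, p, span))
    cands.sort(key=lambda c: (-c[2], c[1], c[0]))
    kept = []
    for s, p, span in cands:
        if all(s + span <= ks or s >= ks + kspan for ks, kp, kspan in kept):
            kept.append((s, p, span))
    return sorted(kept)


class TestTandemRepeats:
    def test_triplet_repeat(self):
        (r,) = find_tandem_repeats("ACGACGACG", 1, 5, 2)
        assert (r.start, r.period, r.copies) == (0, 3, 3.0)

    def test_homopolymer_dedup(self):
        (r,) = find_tandem_repeats("AAAA", 1, 3, 2)
        assert r.period == 1  # smallest period wins the tie
        (r2,) = find_tandem_repeats("AAAA", 2, 3, 2)
        assert r2.period == 2  # reported when period 1 is excluded

    def test_fractional_copies(self):
        (r,) = find_tandem_repeats("ACGTACGTAC", 4, 5, 2)
        assert r.period == 4
        assert r.copies == pytest.approx(2.5)
        assert r.span == 10

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", 0, 5, 2)
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", 1, 5, 1.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        # small alphabets provoke plenty of accidental repeats
        alphabet = ["AT", "ACGT", "AC"][seed % 3]
        n = int(rng.integers(20, 200))
        seq = "".join(rng.choice(list(alphabet), size=n))
        got = sorted((r.start, r.period, round(r.period * r.copies))
                     for r in find_tandem_repeats(seq, 1, 20, 2))
        assert got == _brute_force_repeats(seq, 1, 20, 2)

    def test_planted_cr_repeat_recovered(self, ancestral):
        g, truth = ancestral
        cr = control_region(g)
        reps = find_tandem_repeats(extract_gene_sequence(g, cr), 10, 200, 3)
        planted = truth.repeats[0]
        match = [r for r in reps if r.period == planted.period]
        assert len(match) == 1
        assert match[0].copies == pytest.approx(planted.copies)
        assert match[0].start == planted.cr_start
        assert match[0].unit == planted.unit
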