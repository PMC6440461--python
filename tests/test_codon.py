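"""Start/stop classes, codon counting, RSCU and CDspT profiles."""

import itertools

import numpy as np
import pytest

from mitocomp.codon import (
    ALL_CODONS,
    aa_profile,
    classify_codons,
    classify_start,
    codon_families,
    count_codons,
    family_ordering,
    rscu,
    CodonUsageTable,
    AminoAcidProfile,
)
from mitocomp.model import INVERTEBRATE_MITO, extract_gene_sequence


class TestClassify:
    def test_typical_atn_taa(self):
        r = classify_codons("ATG" + "AAA" * 5 + "TAA", "cox1")
        assert (r.start_class, r.stop_class) == ("ATN", "TAA")

    def test_gtg_with_incomplete_ta(self):
        r = classify_codons("GTG" + "AAA" * 5 + "TA", "nad1")
        assert r.start_class == "GTG"
        assert r.stop_class == "incomplete-TA"

    def test_all_64_start_triplets_match_lookup(self):
        for triplet in ALL_CODONS:
            # independent hand lookup
            if triplet[0] == "A" and triplet[1] == "T":
                expected = "ATN"
            elif triplet in ("GTG", "TTG"):
                expected = triplet
            else:
                expected = "other"
            assert classify_start(triplet) == expected

    def test_incomplete_iff_length_not_multiple_of_three(self):
        for tail, cls in (("", "TAA"), ("TA", "incomplete-TA"), ("T", "incomplete-T")):
            cds = "ATG" + "CCT" * 4 + (tail if tail else "TAA")
            assert classify_codons(cds).stop_class == cls

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError):
            classify_codons("ATG")


class TestCounting:
    def test_simple_count(self):
        t = count_codons(["ATGATG"])
        assert t.counts["ATG"] == 2
        assert t.total == 2

    def test_trailing_fragment_and_stops_excluded(self):
        t = count_codons(["ATGTAATA"])  # ATG + TAA(stop) + TA fragment
        assert t.counts["ATG"] == 1
        assert t.counts["TAA"] == 0
        assert t.total == 1

    def test_totals_arithmetic(self, ancestral):
        g, _ = ancestral
        cds = [extract_gene_sequence(g, f) for f in g.features if f.type == "PCG"]
        t = count_codons(cds)
        expected = sum(len(c) // 3 for c in cds) - sum(
            1 for c in cds
            for i in range(0, len(c) - len(c) % 3, 3)
            if c[i:i + 3] in INVERTEBRATE_MITO.stop_codons
        )
        assert t.total == expected


class TestRSCU:
    def test_two_codon_family_formula(self):
        counts = {c: 0 for c in ALL_CODONS}
        counts["TTT"], counts["TTC"] = 3, 1
        t = rscu(CodonUsageTable(counts=counts))
        assert t.rscu["TTT"] == pytest.approx(1.5)
        assert t.rscu["TTC"] == pytest.approx(0.5)

    def test_uniform_usage_gives_unit_rscu(self):
        counts = {c: 2 for c in ALL_CODONS}
        t = rscu(CodonUsageTable(counts=counts))
        for fam in codon_families().values():
            for c in fam:
                assert t.rscu[c] == pytest.approx(1.0)

    def test_empty_family_is_none(self):
        counts = {c: 0 for c in ALL_CODONS}
        counts["AAA"] = 5
        t = rscu(CodonUsageTable(counts=counts))
        assert t.rscu["TTT"] is None
        assert t.rscu["AAA"] == pytest.approx(2.0)  # Lys family {AAA, AAG}

    def test_random_sample_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        sense = [c for c in ALL_CODONS if c not in INVERTEBRATE_MITO.stop_codons]
        draw = rng.choice(sense, size=500)
        counts = {c: int((draw == c).sum()) for c in ALL_CODONS}
        t = rscu(CodonUsageTable(counts=counts))
        for fam in codon_families().values():
            total = sum(counts[c] for c in fam)
            for c in fam:
                expect = None if total == 0 else counts[c] * len(fam) / total
                if expect is None:
                    assert t.rscu[c] is None
                else:
                    assert t.rscu[c] == pytest.approx(expect)

    def test_family_rscu_sums_to_family_size(self, ancestral):
        g, _ = ancestral
        cds = [extract_gene_sequence(g, f) for f in g.features if f.type == "PCG"]
        t = rscu(count_codons(cds))
        for fam in codon_families().values():
            if all(t.rscu[c] is not None for c in fam):
                assert sum(t.rscu[c] for c in fam) == pytest.approx(len(fam))

    def test_six_codon_family_mode(self):
        counts = {c: 1 for c in ALL_CODONS}
        split = codon_families(split_leu_ser=True)
        assert len(split["Leu2"]) == 2 and len(split["Leu1"]) == 4
        assert len(split["Ser1"]) == 4 and len(split["Ser2"]) == 4  # AGN=4 in table 5
        joined = codon_families(split_leu_ser=False)
        assert len(joined["Leu"]) == 6 and len(joined["Ser"]) == 8
        t = rscu(CodonUsageTable(counts=counts), split_leu_ser=False)
        assert t.rscu["TTA"] == pytest.approx(1.0)


class TestAAProfile:
    def test_single_class(self):
        t = count_codons(["TTTTTC"])
        p = aa_profile(t)
        assert p.cdspt["Phe"] == pytest.approx(1000)

    def test_cdspt_sums_to_thousand(self, ancestral):
        g, _ = ancestral
        cds = [extract_gene_sequence(g, f) for f in g.features if f.type == "PCG"]
        p = aa_profile(count_codons(cds))
        assert sum(p.cdspt.values()) == pytest.approx(1000, abs=0.5)

    def test_planted_ranking_recovered(self, ancestral):
        g, truth = ancestral
        cds = [extract_gene_sequence(g, f) for f in g.features if f.type == "PCG"]
        p = aa_profile(count_codons(cds))
        assert p.top(5) == truth.aa_ranking
        # the five classes favoured by the sampling bias dominate
        assert set(p.top(5)) == {"Phe", "Ile", "Met", "Leu2", "Ser2"}
        assert sum(p.cdspt[a] for a in p.top(5)) > 500

    def test_nna_outnumber_nng(self, ancestral):
        g, _ = ancestral
        cds = [extract_gene_sequence(g, f) for f in g.features if f.type == "PCG"]
        t = count_codons(cds)
        nna = sum(n for c, n in t.counts.items() if c[2] == "A")
        nng = sum(n for c, n in t.counts.items() if c[2] == "G")
        assert nna > nng


class TestFamilyOrdering:
    PROFILE = AminoAcidProfile(
        {"Phe": 120, "Ile": 100, "Met": 90, "Leu2": 80, "Ser2": 70})

    def test_descending_render(self):
        out = family_ordering(self.PROFILE, ["Phe", "Ile", "Met", "Leu2", "Ser2"])
        assert out == "Phe > Ile > Met > Leu2 > Ser2"

    def test_tie_rendering(self):
        p = AminoAcidProfile({"Phe": 120, "Ile": 100, "Leu2": 100, "Met": 90, "Ser2": 80})
        out = family_ordering(p, ["Phe", "Ile", "Leu2", "Met", "Ser2"])
        assert out == "Phe > Ile/Leu2 > Met > Ser2"

    def test_matches_sort_oracle_on_permutations(self):
        classes = ["Phe", "Ile", "Met", "Leu2", "Ser2"]
        for perm in itertools.permutations([120, 100, 90, 80, 70]):
            p = AminoAcidProfile(dict(zip(classes, perm)))
            expected = " > ".join(sorted(classes, key=lambda c: -p.cdspt[c]))
            assert family_ordering(p, classes) == expected
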