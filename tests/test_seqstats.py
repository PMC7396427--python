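import collections
import random

import pytest
from hypothesis import given, strategies as st

from mitocomp import (
    AnnotationError,
    AnnotationRecord,
    CodonCountTable,
    GenomeSequence,
    MitogenomeAnnotation,
    aa_usage,
    base_composition,
    composition_report,
    count_codons,
    custom_genetic_code,
    extract_cds,
    get_genetic_code,
    rscu,
    skew,
)
from mitocomp.seqstats import CODONS, dna_to_rna, round_half_up


class TestBaseComposition:
    def test_forced_half_and_half(self):
        comp = base_composition("AATT")
        assert comp.percent("A") == comp.percent("T") == 50.0
        assert comp.percent("G") == comp.percent("C") == 0.0

    def test_matches_independent_tally_on_random_sequence(self):
        rng = random.Random(42)
        seq = "".join(rng.choices("ACGTN", weights=[4, 2, 1, 3, 0.1], k=10_000))
        comp = base_composition(seq)
        counter = collections.Counter(seq)
        for b in "ACGT":
            assert comp.counts[b] == counter[b]
        assert comp.other == counter["N"]
        total = sum(counter[b] for b in "ACGT")
        assert comp.percent("A") == pytest.approx(100 * counter["A"] / total)

    def test_empty_input_is_an_error(self):
        with pytest.raises(AnnotationError):
            base_composition("")

    def test_percents_sum_to_100(self):
        comp = base_composition("ACGTACGGTTTAN")
        assert sum(comp.percent(b) for b in "ACGT") == pytest.approx(100.0)
        assert comp.at_percent + comp.gc_percent == pytest.approx(100.0)


class TestSkew:
    def test_published_whole_genome_skews(self):
        """Strand skews recomputed from the printed whole-genome base
        percentages of the focal mitogenome."""
        assert round_half_up(skew(35.64, 29.55), 3) == 0.093  # AT
        # GC-skew from the printed G/C percentages lands within one unit
        # in the last printed digit of the published -0.273
        assert skew(12.64, 22.16) == pytest.approx(-0.273, abs=1e-3)

    def test_symmetry_zero(self):
        assert skew(3.3, 3.3) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            skew(0, 0)

    @given(
        st.floats(0.01, 1e3), st.floats(0.01, 1e3), st.floats(0.01, 1e3)
    )
    def test_scale_invariance(self, x, y, k):
        assert skew(k * x, k * y) == pytest.approx(skew(x, y), rel=1e-9)


class TestCodonCounting:
    def test_three_codon_toy(self):
        table = count_codons(["ATGAAATAA"])
        assert table["ATG"] == table["AAA"] == table["TAA"] == 1
        assert table.total == 3

    def test_matches_sliding_triplet_tally(self):
        rng = random.Random(7)
        cds_list = [
            "".join(rng.choices("ACGT", k=3 * rng.randint(5, 50))) for _ in range(30)
        ]
        table = count_codons(cds_list)
        oracle = collections.Counter()
        for cds in cds_list:
            for i in range(0, len(cds), 3):
                oracle[cds[i : i + 3]] += 1
        assert all(table[c] == oracle[c] for c in CODONS)
        assert table.total == sum(oracle.values())

    def test_trailing_bases_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            table = count_codons(["ATGAAATA"])  # 8 bases
        assert table.total == 2
        assert any("not divisible by 3" in m for m in caplog.messages)

    def test_ambiguous_codons_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            table = count_codons(["ATGNNNAAA"])
        assert table.total == 2

    def test_fixture_total(self, focal_counts):
        assert focal_counts.total == 5323


class TestGeneticCodes:
    def test_label_codes_differ_where_expected(self):
        std = get_genetic_code("standard")
        inv = get_genetic_code("invertebrate_mito")
        ech = get_genetic_code("echinoderm_mito")
        assert std.aa_of_codon["AGA"] == "R" and inv.aa_of_codon["AGA"] == "S"
        assert std.aa_of_codon["TGA"] == "*" and inv.aa_of_codon["TGA"] == "W"
        assert inv.aa_of_codon["AAA"] == "K" and ech.aa_of_codon["AAA"] == "N"
        assert inv.aa_of_codon["ATA"] == "M" and ech.aa_of_codon["ATA"] == "I"

    def test_families_partition_the_64_codons(self):
        for name in ("standard", "invertebrate_mito", "echinoderm_mito"):
            fams = get_genetic_code(name).families
            members = [c for fam in fams.values() for c in fam]
            assert sorted(members) == sorted(CODONS)

    def test_standard_code_merges_agr_with_cgn(self):
        fams = get_genetic_code("standard").families
        assert set(fams["R"]) == {"CGT", "CGC", "CGA", "CGG", "AGA", "AGG"}
        assert set(fams["*"]) == {"TAA", "TAG", "TGA"}

    def test_custom_code_from_mapping(self):
        base = get_genetic_code("standard")
        mapping = dict(base.aa_of_codon)
        mapping["UGA"] = "W"  # RNA alphabet accepted
        code = custom_genetic_code("my_code", mapping, starts=("ATG", "GTG"))
        assert code.aa_of_codon["TGA"] == "W"
        assert len(code.families["W"]) == 2


class TestRscu:
    def test_uniform_counts_give_unity(self):
        table = CodonCountTable(counts={c: 1 for c in CODONS})
        values = rscu(table, "standard")
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_fixture_anchor_codons(self, focal_counts):
        """RSCU recomputed under standard-code synonymous families
        reproduces the published six-codon-family values."""
        values = rscu(focal_counts, "standard")
        assert round_half_up(values["TTA"], 2) == 1.76
        assert round_half_up(values["AGA"], 2) == 2.46
        assert round_half_up(values["TAA"], 2) == 1.71
        assert round_half_up(values["GGA"], 2) == 2.20

    def test_empty_family_yields_zeros(self):
        counts = {c: 0 for c in CODONS}
        counts["TTA"] = 5
        values = rscu(CodonCountTable(counts=counts), "standard")
        assert values["GGA"] == 0.0
        assert values["TTA"] == pytest.approx(6.0)

    @given(
        st.lists(st.integers(0, 500), min_size=64, max_size=64),
        st.sampled_from(["standard", "invertebrate_mito", "echinoderm_mito"]),
    )
    def test_family_sums_equal_family_sizes(self, values, code_name):
        """Sum of RSCU over each nonzero family equals the family size."""
        table = CodonCountTable(counts=dict(zip(CODONS, values)))
        out = rscu(table, code_name)
        for fam in get_genetic_code(code_name).families.values():
            total = sum(table[c] for c in fam)
            fam_sum = sum(out[c] for c in fam)
            expected = len(fam) if total else 0.0
            assert fam_sum == pytest.approx(expected, abs=1e-9)


class TestAaUsage:
    def test_fixture_top_five(self, focal_counts):
        """Under invertebrate-mitochondrial labels the five most used
        amino acids match the published percentages."""
        usage = aa_usage(focal_counts, "invertebrate_mito")
        expected = {"S": 12.91, "L": 10.82, "K": 8.34, "P": 7.06, "T": 6.01}
        for aa, pct in expected.items():
            assert usage[aa] == pytest.approx(pct, abs=0.005)
        top5 = sorted((aa for aa in usage if aa != "*"), key=usage.get, reverse=True)[:5]
        assert top5 == ["S", "L", "K", "P", "T"]

    def test_single_codon_concentration(self):
        counts = {c: 0 for c in CODONS}
        counts["TTA"] = 17
        usage = aa_usage(CodonCountTable(counts=counts), "standard")
        assert usage["L"] == 100.0

    @given(st.lists(st.integers(0, 100), min_size=64, max_size=64).filter(lambda v: sum(v) > 0))
    def test_percents_sum_to_100(self, values):
        usage = aa_usage(CodonCountTable(counts=dict(zip(CODONS, values))), "invertebrate_mito")
        assert sum(usage.values()) == pytest.approx(100.0, abs=0.05)


class TestExtractCds:
    def test_minus_strand_gene_read_on_coding_strand(self):
        # plant ATG...TAA as the reverse complement at positions 3..11
        insert = "TTACATCAT"  # revcomp of ATGATGTAA
        seq = GenomeSequence(id="t", residues="GG" + insert + "GGGG")
        ann = MitogenomeAnnotation(
            genome_id="t", genome_length=len(seq.residues),
            records=[AnnotationRecord("g", "PCG", "-", 3, 11)],
        )
        assert extract_cds(seq, ann)["g"] == "ATGATGTAA"

    def test_origin_spanning_length_matches_feature_length(self):
        seq = GenomeSequence(id="t", residues="ACGT" * 25)
        ann = MitogenomeAnnotation(
            genome_id="t", genome_length=100,
            records=[AnnotationRecord("g", "PCG", "+", 95, 6)],
        )
        cds = extract_cds(seq, ann)["g"]
        assert len(cds) == 12
        assert cds == seq.residues[94:] + seq.residues[:6]


class TestCompositionReport:
    def test_all_a_genome(self):
        seq = GenomeSequence(id="t", residues="A" * 60)
        ann = MitogenomeAnnotation(
            genome_id="t", genome_length=60,
            records=[AnnotationRecord("g", "PCG", "+", 1, 30)],
        )
        df = composition_report(seq, ann).set_index("name")
        assert df.loc["g", "A_pct"] == 100.0
        assert df.loc["g", "at_skew"] == 1.0
        assert df.loc["g", "gc_skew"] is None or df.loc["g", "gc_skew"] != df.loc["g", "gc_skew"]

    def test_whole_circle_feature_equals_genome_row(self):
        rng = random.Random(3)
        seq = GenomeSequence(id="t", residues="".join(rng.choices("ACGT", k=300)))
        ann = MitogenomeAnnotation(
            genome_id="t", genome_length=300,
            records=[AnnotationRecord("g", "rRNA", "+", 1, 300)],
        )
        df = composition_report(seq, ann).set_index("name")
        for col in ("T_pct", "C_pct", "A_pct", "G_pct", "gc_skew", "at_skew"):
            assert df.loc["g", col] == df.loc["genome", col]
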