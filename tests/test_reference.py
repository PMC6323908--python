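"""Coordinate model, locus lookup and functional-effect calling."""

import pytest
from Bio.Seq import Seq

from mitotier.errors import (
    CoordinateError,
    ReferenceMismatchError,
    UnsupportedAlleleError,
)
from mitotier.reference import (
    NUCLEOTIDES,
    Locus,
    LocusMap,
    ReferenceModel,
    classify_substitution,
    human_mt_locus_map,
    synthetic_rcrs_like_reference,
    translate_codon,
)
from mitotier.simulate import toy_reference


class TestLocusLookup:
    def test_position_in_trna_interval_returns_that_locus(self, full_reference):
        reference, locus_map = full_reference
        # linear scan oracle over the bundled table
        for pos, expected in [(600, "MT-TF"), (1650, "MT-TV"), (15900, "MT-TT")]:
            rows = [
                l for l in locus_map
                if l.locus_type == "tRNA" and l.start <= pos <= l.end
            ]
            assert rows and rows[0].name == expected
            locus = locus_map.locus_of(pos, len(reference))
            assert locus.name == expected

    def test_position_zero_is_a_coordinate_error(self, full_reference):
        reference, locus_map = full_reference
        with pytest.raises(CoordinateError):
            locus_map.locus_of(0, len(reference))
        with pytest.raises(CoordinateError):
            locus_map.locus_of(len(reference) + 1, len(reference))

    def test_position_L_on_circular_reference_is_valid(self, full_reference):
        reference, locus_map = full_reference
        locus = locus_map.locus_of(len(reference), len(reference))
        # m.16569 falls in the origin-spanning control region
        assert locus.name == "MT-CR" and locus.wraps_origin

    def test_origin_spanning_locus_contains_both_arms(self, full_reference):
        reference, locus_map = full_reference
        cr = next(l for l in locus_map if l.wraps_origin)
        L = len(reference)
        assert cr.contains(16_100, L) and cr.contains(400, L)
        assert not cr.contains(8_000, L)
        assert cr.span(L) == (L - cr.start + 1) + cr.end

    def test_overlap_tie_break_prefers_cds_then_start(self, full_reference):
        reference, locus_map = full_reference
        L = len(reference)
        # MT-ATP8 (8366-8572) and MT-ATP6 (8527-9207) overlap: earlier start wins
        primary = locus_map.locus_of(8550, L)
        assert primary.name == "MT-ATP8"
        both = locus_map.all_loci_at(8550, L)
        assert [l.name for l in both] == ["MT-ATP8", "MT-ATP6"]
        # tRNA/CDS boundary: CDS priority beats tRNA despite later start
        mixed = LocusMap(
            [
                Locus("G1", "tRNA", 10, 40),
                Locus("G2", "CDS", 30, 60, reading_frame_origin=30),
            ]
        )
        assert mixed.locus_of(35, 100).name == "G2"

    def test_unannotated_position_is_intergenic(self):
        locus_map = LocusMap([Locus("G1", "tRNA", 10, 40)])
        assert locus_map.locus_of(5, 100) == "intergenic"


@pytest.fixture(scope="module")
def toy():
    return toy_reference(seed=3)


class TestClassification:
    def test_cds_classes_match_full_translation_oracle(self, toy):
        """Every substitution in the toy CDS agrees with a brute-force oracle
        that re-translates the whole gene with Biopython before and after."""
        reference, locus_map = toy
        cds = locus_map.by_type("CDS")[0]
        gene = reference.sequence[cds.start - 1 : cds.end]
        protein = str(Seq(gene).translate(table=2))
        for pos in range(cds.start, cds.end + 1):
            offset = pos - cds.start
            ref_base = reference.base_at(pos)
            for alt in NUCLEOTIDES:
                if alt == ref_base:
                    continue
                mutated = gene[:offset] + alt + gene[offset + 1 :]
                mutated_protein = str(Seq(mutated).translate(table=2))
                aa_ref = protein[offset // 3]
                aa_alt = mutated_protein[offset // 3]
                if aa_ref == aa_alt:
                    expected = "synonymous"
                elif aa_alt == "*":
                    expected = "stop-gain"
                elif aa_ref == "*":
                    expected = "stop-loss"
                else:
                    expected = "non-synonymous"
                got = classify_substitution(pos, ref_base, alt, reference, cds)
                assert got == expected, f"m.{pos}{ref_base}>{alt}"

    def test_all_nine_substitutions_of_one_codon(self):
        """Codon-table oracle over the 9 substitutions of a chosen codon:
        CTA (Leu) third-position changes are synonymous under table 2."""
        reference = ReferenceModel("CTA", circular=False, name="mini")
        cds = Locus("G", "CDS", 1, 3, reading_frame_origin=1)
        results = {}
        for pos in (1, 2, 3):
            for alt in NUCLEOTIDES:
                if alt == reference.base_at(pos):
                    continue
                results[(pos, alt)] = classify_substitution(
                    pos, reference.base_at(pos), alt, reference, cds
                )
        # third position: CTN all leucine
        assert all(results[(3, b)] == "synonymous" for b in "CGT")
        # CTA -> TTA is still Leu; ATA is Met, GTA is Val under table 2
        assert results[(1, "T")] == "synonymous"
        assert results[(1, "A")] == "non-synonymous"
        assert results[(1, "G")] == "non-synonymous"

    def test_sense_to_stop_is_stop_gain_brute_force(self):
        """Brute-force over the 64-codon table: every single-base change that
        turns a sense codon into a mitochondrial stop codon is stop-gain."""
        n_checked = 0
        for a in NUCLEOTIDES:
            for b in NUCLEOTIDES:
                for c in NUCLEOTIDES:
                    codon = a + b + c
                    if translate_codon(codon) == "*":
                        continue
                    reference = ReferenceModel(codon, circular=False, name="m")
                    cds = Locus("G", "CDS", 1, 3, reading_frame_origin=1)
                    for i in range(3):
                        for alt in NUCLEOTIDES:
                            if alt == codon[i]:
                                continue
                            mutated = codon[:i] + alt + codon[i + 1 :]
                            if translate_codon(mutated) != "*":
                                continue
                            got = classify_substitution(
                                i + 1, codon[i], alt, reference, cds
                            )
                            assert got == "stop-gain"
                            n_checked += 1
        assert n_checked > 0

    def test_trna_locus_returns_trna_regardless_of_codon_logic(self, toy):
        reference, locus_map = toy
        trna = locus_map.by_type("tRNA")[0]
        pos = trna.start + 5
        ref_base = reference.base_at(pos)
        alt = next(b for b in NUCLEOTIDES if b != ref_base)
        assert classify_substitution(pos, ref_base, alt, reference, trna) == "tRNA"

    def test_minus_strand_cds_uses_reverse_complement_frame(self):
        # genome 5'-CATTTT-3'; minus-strand CDS over 1-6 reads AAAATG,
        # i.e. codon1 = AAA (Lys) at genomic 6-4, codon2 = ATG (Met) at 3-1.
        reference = ReferenceModel("CATTTT", circular=False, name="m")
        cds = Locus("G", "CDS", 1, 6, strand="-", reading_frame_origin=6)
        # genomic pos 1: C is the last base of ATG (coding G); C>A makes ATT (Ile)
        assert classify_substitution(1, "C", "A", reference, cds) == "non-synonymous"
        # genomic pos 4: T is third base of codon AAA (Lys); T>C -> AAG still Lys
        assert classify_substitution(4, "T", "C", reference, cds) == "synonymous"
        # genomic pos 5: second base of AAA; T>A complements to coding T,
        # AAA -> ATA = Met under table 2 -> non-synonymous
        assert classify_substitution(5, "T", "A", reference, cds) == "non-synonymous"

    def test_reference_mismatch_and_ambiguous_alleles_error(self, toy):
        reference, locus_map = toy
        cds = locus_map.by_type("CDS")[0]
        pos = cds.start
        ref_base = reference.base_at(pos)
        wrong = next(b for b in NUCLEOTIDES if b != ref_base)
        with pytest.raises(ReferenceMismatchError):
            classify_substitution(pos, wrong, ref_base, reference, cds)
        with pytest.raises(UnsupportedAlleleError):
            classify_substitution(pos, ref_base, "N", reference, cds)

    def test_classification_is_pure(self, toy):
        reference, locus_map = toy
        cds = locus_map.by_type("CDS")[0]
        pos = cds.start + 10
        ref_base = reference.base_at(pos)
        alt = next(b for b in NUCLEOTIDES if b != ref_base)
        first = classify_substitution(pos, ref_base, alt, reference, cds)
        assert all(
            classify_substitution(pos, ref_base, alt, reference, cds) == first
            for _ in range(5)
        )


class TestBundledData:
    def test_bundled_map_covers_the_standard_37_genes_plus_control_region(self):
        locus_map = human_mt_locus_map()
        assert len(locus_map) == 38
        by_type = {t: len(locus_map.by_type(t)) for t in ("CDS", "tRNA", "rRNA", "regulatory")}
        assert by_type == {"CDS": 13, "tRNA": 22, "rRNA": 2, "regulatory": 1}

    def test_synthetic_reference_has_rcrs_length_and_is_deterministic(self):
        a = synthetic_rcrs_like_reference()
        b = synthetic_rcrs_like_reference()
        assert len(a) == 16_569
        assert a.sequence == b.sequence
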