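"""Allele frequencies, manifest bookkeeping and site-variability scores."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotier.errors import (
    InsufficientDataError,
    LocusTypeError,
    UndefinedFrequencyError,
)
from mitotier.frequency import (
    GenomeCohort,
    manifest_counts,
    normalized_entropy,
    validate_manifest,
)
from mitotier.reference import Locus, LocusMap, ReferenceModel
from mitotier.simulate import SimulationSpec, PlantedVariant, generate_cohort


def _cohort_from_columns(columns: list[str], statuses=None):
    """Build a cohort whose i-th genome is the i-th row of the column strings."""
    n = len(columns[0])
    rows = np.array([[col[g] for col in columns] for g in range(n)], dtype="<U1")
    statuses = statuses or ["healthy"] * n
    return GenomeCohort(rows, [f"g{i}" for i in range(n)], statuses)


class TestAlleleFrequency:
    def test_hand_counted_three_of_ten(self):
        cohort = _cohort_from_columns(["GGGTTTAAAA"])  # 3 T among 10 called
        assert cohort.allele_frequency(1, "T") == pytest.approx(0.3)

    def test_saturation_and_absence(self):
        cohort = _cohort_from_columns(["TTTT"])
        assert cohort.allele_frequency(1, "T") == 1.0
        assert cohort.allele_frequency(1, "C") == 0.0

    def test_uncalled_genomes_leave_the_denominator(self):
        # 2 T carriers among 4 called (2 N excluded entirely)
        cohort = _cohort_from_columns(["TTAANN"])
        assert cohort.allele_frequency(1, "T") == pytest.approx(0.5)

    def test_empty_stratum_is_an_error_not_zero(self):
        cohort = _cohort_from_columns(["AAAA"])  # all healthy
        with pytest.raises(UndefinedFrequencyError):
            cohort.allele_frequency(1, "T", "pathologic")
        cohort_all_n = _cohort_from_columns(["NNNN"])
        with pytest.raises(UndefinedFrequencyError):
            cohort_all_n.allele_frequency(1, "T")

    def test_stratum_frequencies_recombine_to_the_total(self):
        """N_total*af_total = N_h*af_h + N_p*af_p under full call coverage."""
        statuses = ["healthy"] * 6 + ["pathologic"] * 4
        cohort = _cohort_from_columns(["TTAAAATTTA"], statuses)
        af_t = cohort.allele_frequency(1, "T", "all")
        af_h = cohort.allele_frequency(1, "T", "healthy")
        af_p = cohort.allele_frequency(1, "T", "pathologic")
        assert 10 * af_t == pytest.approx(6 * af_h + 4 * af_p)

    def test_planted_af_recovered_within_one_over_n(self):
        spec = SimulationSpec(
            planted=(
                PlantedVariant("tRNA", af_healthy=0.13, af_pathologic=0.27,
                               trna_criteria=None, evidence_available=False),
            ),
            n_healthy=60, n_pathologic=40, seed=11,
        )
        cohort, truth, _, _ = generate_cohort(spec)
        row = truth.iloc[0]
        af_h = cohort.allele_frequency(int(row.position), row.alt, "healthy")
        af_p = cohort.allele_frequency(int(row.position), row.alt, "pathologic")
        assert abs(af_h - 0.13) <= 1 / 60
        assert abs(af_p - 0.27) <= 1 / 40


class TestManifest:
    def test_counts_sum_to_total(self):
        manifest = pd.DataFrame(
            {
                "genome_id": [f"g{i}" for i in range(10)],
                "status": ["healthy"] * 7 + ["pathologic"] * 3,
            }
        )
        assert manifest_counts(manifest) == (7, 3, 10)

    def test_unknown_status_rejected(self):
        manifest = pd.DataFrame(
            {"genome_id": ["a", "b"], "status": ["healthy", "sick"]}
        )
        with pytest.raises(ValueError):
            validate_manifest(manifest)

    def test_duplicate_genome_ids_rejected(self):
        manifest = pd.DataFrame(
            {"genome_id": ["a", "a"], "status": ["healthy", "healthy"]}
        )
        with pytest.raises(ValueError):
            validate_manifest(manifest)


class TestNucleotideVariability:
    def test_monomorphic_column_scores_zero(self):
        cohort = _cohort_from_columns(["AAAAAAAAAA"])
        assert cohort.nt_site_variability(1) == 0.0

    def test_equiprobable_four_bases_score_one(self):
        cohort = _cohort_from_columns(["ACGTACGT"])
        assert cohort.nt_site_variability(1) == pytest.approx(1.0)

    def test_biallelic_90_10_matches_direct_entropy(self):
        cohort = _cohort_from_columns(["A" * 9 + "G"])
        expected = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1)) / math.log(4)
        value = cohort.nt_site_variability(1)
        assert value == pytest.approx(expected)
        assert 0.0 < value < 1.0

    def test_fewer_than_two_called_genomes_is_insufficient(self):
        cohort = _cohort_from_columns(["ANNN"])
        with pytest.raises(InsufficientDataError):
            cohort.nt_site_variability(1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 30), min_size=4, max_size=4).filter(
            lambda c: sum(c) >= 2
        ),
        perm=st.permutations([0, 1, 2, 3]),
    )
    def test_allele_relabelling_invariance(self, counts, perm):
        """nt_var depends only on the multiset of allele counts."""
        column = "".join(b * c for b, c in zip("ACGT", counts))
        permuted = "".join(
            "ACGT"[perm[i]] * counts[i] for i in range(4)
        )
        a = _cohort_from_columns([column]).nt_site_variability(1)
        b = _cohort_from_columns([permuted]).nt_site_variability(1)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_entropy_statistic_is_pluggable(self):
        cohort = _cohort_from_columns(["AACC"])
        # number-of-distinct-alleles stand-in statistic
        statistic = lambda counts, k: (sum(1 for c in counts if c) - 1) / (k - 1)
        assert cohort.nt_site_variability(1, statistic) == pytest.approx(1 / 3)


class TestAminoAcidVariability:
    def _cds_cohort(self, codons_per_genome):
        rows = np.array([list(seq) for seq in codons_per_genome], dtype="<U1")
        cohort = GenomeCohort(
            rows, [f"g{i}" for i in range(len(codons_per_genome))],
            ["healthy"] * len(codons_per_genome),
        )
        locus = Locus("G", "CDS", 1, len(codons_per_genome[0]),
                      reading_frame_origin=1)
        return cohort, locus

    def test_identical_residues_score_zero(self):
        cohort, locus = self._cds_cohort(["ATG", "ATG", "ATG"])
        assert cohort.aa_site_variability(locus, 0) == 0.0

    def test_synonymous_only_variation_gives_aa_zero_nt_positive(self):
        # CTA and CTG both encode Leu: nucleotide column 3 varies, residue not
        cohort, locus = self._cds_cohort(["CTA", "CTG", "CTA", "CTG"])
        assert cohort.aa_site_variability(locus, 0) == 0.0
        assert cohort.nt_site_variability(3) > 0.0

    def test_even_two_residue_split_matches_closed_form(self):
        # ATG (Met) vs GTG (Val), 50/50
        cohort, locus = self._cds_cohort(["ATG", "GTG", "ATG", "GTG"])
        expected = math.log(2) / math.log(21)
        assert cohort.aa_site_variability(locus, 0) == pytest.approx(expected)

    def test_non_cds_locus_is_a_locus_type_error(self):
        cohort, _ = self._cds_cohort(["ATG", "ATG"])
        with pytest.raises(LocusTypeError):
            cohort.aa_site_variability(Locus("T", "tRNA", 1, 3), 0)

    def test_partially_called_codons_are_excluded(self):
        cohort, locus = self._cds_cohort(["ATG", "ATN", "GTG"])
        # middle genome's codon is uncalled -> 50/50 Met/Val over the rest
        expected = math.log(2) / math.log(21)
        assert cohort.aa_site_variability(locus, 0) == pytest.approx(expected)


def test_normalized_entropy_bounds():
    assert normalized_entropy([5, 0, 0, 0], 4) == 0.0
    assert normalized_entropy([3, 3, 3, 3], 4) == pytest.approx(1.0)
    assert normalized_entropy([], 4) == 0.0
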