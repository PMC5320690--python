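import io

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from snpsieve.core import (
    BaseClass,
    classify_base,
    column_alleles,
    extract_snp_matrix,
    find_variant_sites,
    is_variant_site,
    reference_allele_for_site,
)
from snpsieve.fasta_io import (
    AlignmentSource,
    MalformedFastaError,
    UnequalLengthError,
    write_fasta,
    AlignmentRecord,
)

from conftest import WORKED_EXAMPLE_FASTA, brute_force_sites


def write_alignment(tmp_path, sequences, name="aln.fa"):
    path = tmp_path / name
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">s{i}\n{seq}\n")
    return path


class TestBaseClassification:
    @pytest.mark.parametrize("c", ["N", "n", "?", "-"])
    def test_missing_set(self, c):
        assert classify_base(c) is BaseClass.MISSING

    @pytest.mark.parametrize("c", ["A", "c", "G", "t", "R", "y", ".", "X"])
    def test_everything_else_informative(self, c):
        # ambiguity codes other than N count as alleles
        assert classify_base(c) is BaseClass.INFORMATIVE


class TestColumnPredicate:
    @pytest.mark.parametrize(
        "column,alleles",
        [
            (["A", "A", "A"], {"A"}),
            (["-", "A", "A"], {"A"}),
            (["a", "G", "N"], {"A", "G"}),
            (["-", "N", "?"], set()),
        ],
    )
    def test_column_alleles_folds_case_and_drops_missing(self, column, alleles):
        assert column_alleles(column) == alleles

    @pytest.mark.parametrize(
        "column,variant",
        [
            (["A", "A", "A"], False),  # monomorphic
            (["G", "G", "A"], True),  # two alleles
            (["-", "A", "A"], False),  # gap is non-variant
            (["a", "A", "A"], False),  # case fold
            (["N", "?", "-"], False),  # all missing
            (["A", "R"], True),  # ambiguity code is an allele
        ],
    )
    def test_is_variant_site(self, column, variant):
        assert is_variant_site(column) is variant


class TestReferenceAllele:
    @pytest.mark.parametrize(
        "column,ref",
        [
            (["G", "G", "A"], "G"),
            (["-", "T", "C"], "T"),
            (["a", "G", "G"], "A"),
        ],
    )
    def test_first_informative_rule(self, column, ref):
        assert reference_allele_for_site(column) == ref

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError):
            reference_allele_for_site(["-", "N", "?"])


class TestFindVariantSites:
    def test_worked_example_sites(self, worked_example_path):
        consensus, sites, dims = find_variant_sites(worked_example_path)
        assert tuple(sites) == (1, 4, 7)
        assert sites.p == 3
        assert (dims.s, dims.g) == (3, 12)
        assert len(consensus) == 12

    def test_identical_sequences_have_no_sites(self, tmp_path):
        path = write_alignment(tmp_path, ["ACGT", "ACGT", "ACGT"])
        _, sites, _ = find_variant_sites(path)
        assert sites.p == 0

    def test_single_sequence_has_no_sites(self, tmp_path):
        path = write_alignment(tmp_path, ["ACGTACGT"])
        _, sites, _ = find_variant_sites(path)
        assert sites.p == 0

    def test_unequal_lengths_rejected(self, tmp_path):
        path = write_alignment(tmp_path, ["ACGT", "ACG"])
        with pytest.raises(UnequalLengthError):
            find_variant_sites(path)

    def test_consensus_placeholder_only_where_never_informative(self, tmp_path):
        path = write_alignment(tmp_path, ["-CGT", "NCGA"])
        consensus, _, _ = find_variant_sites(path)
        assert consensus.bases == "-CGT"

    @settings(
        max_examples=200,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        data=st.data(),
        s=st.integers(min_value=1, max_value=20),
        g=st.integers(min_value=1, max_value=200),
    )
    def test_streaming_detector_matches_per_column_oracle(self, data, s, g, tmp_path):
        alphabet = "ACGTacgtNn?-RY"
        sequences = [
            data.draw(st.text(alphabet=alphabet, min_size=g, max_size=g))
            for _ in range(s)
        ]
        text = "".join(f">s{i}\n{seq}\n" for i, seq in enumerate(sequences))
        path = tmp_path / "h.fa"
        path.write_text(text)
        _, sites, _ = find_variant_sites(path)
        assert list(sites) == brute_force_sites(sequences)


class TestExtractSnpMatrix:
    def run_pipeline(self, path):
        source = AlignmentSource(path)
        _, sites, dims = find_variant_sites(source)
        return source, sites, dims, extract_snp_matrix(source, sites, dims)

    def test_worked_example_matrix(self, worked_example_path):
        _, _, _, matrix = self.run_pipeline(worked_example_path)
        assert matrix.sample_ids == ("sample1", "sample2", "sample3")
        assert matrix.rows == ("GAG", "GA-", "AGT")

    def test_exactly_two_passes_over_input(self, worked_example_path):
        source, _, _, _ = self.run_pipeline(worked_example_path)
        assert source.passes == 2
        assert source.bytes_read == 2 * worked_example_path.stat().st_size

    def test_no_sites_gives_empty_rows(self, tmp_path):
        path = write_alignment(tmp_path, ["ACGT", "ACGT"])
        _, _, _, matrix = self.run_pipeline(path)
        assert matrix.rows == ("", "")
        assert matrix.p == 0

    def test_extraction_is_idempotent(self, worked_example_path, tmp_path):
        _, _, _, matrix = self.run_pipeline(worked_example_path)
        again = tmp_path / "snp.fa"
        with open(again, "w") as fh:
            write_fasta(
                (AlignmentRecord(n, r) for n, r in zip(matrix.sample_ids, matrix.rows)),
                fh,
            )
        _, _, _, matrix2 = self.run_pipeline(again)
        assert matrix2.rows == matrix.rows
        assert matrix2.sample_ids == matrix.sample_ids

    def test_every_output_column_is_variant(self, tmp_path):
        path = write_alignment(
            tmp_path, ["AcG-TNA", "aCGATNC", "ACG?TnA"]
        )
        _, _, _, matrix = self.run_pipeline(path)
        assert matrix.p > 0
        for column in matrix.iter_columns():
            assert is_variant_site(column)

    def test_permuting_records_permutes_rows_only(self, tmp_path):
        sequences = ["AG-CACAGTCAC", "AGACAC----AC", "AAACGCATTCAN"]
        p1 = write_alignment(tmp_path, sequences, "a.fa")
        p2 = write_alignment(tmp_path, sequences[::-1], "b.fa")
        _, sites1, _, m1 = (*self.run_pipeline(p1),)
        _, sites2, _, m2 = (*self.run_pipeline(p2),)
        assert tuple(sites1) == tuple(sites2)
        assert m2.rows == m1.rows[::-1]

    def test_source_changed_between_passes_detected(self, tmp_path):
        path = write_alignment(tmp_path, ["ACGT", "AGGT", "ACGA"])
        source = AlignmentSource(path)
        _, sites, dims = find_variant_sites(source)
        write_alignment(tmp_path, ["ACGT", "AGGT"], "aln.fa")  # overwrite
        with pytest.raises(MalformedFastaError, match="changed between passes"):
            extract_snp_matrix(source, sites, dims)

    def test_case_and_gaps_preserved_verbatim(self, tmp_path):
        path = write_alignment(tmp_path, ["aG", "gG", "-G", "NG"])
        _, _, _, matrix = self.run_pipeline(path)
        assert matrix.rows == ("a", "g", "-", "N")


def test_working_set_bounds(tmp_path):
    """First-pass state is 2g characters; second-pass storage is p*s."""
    path = write_alignment(
        tmp_path, ["ACGTACGTAC", "ACATACGAAC", "ACGTACGTTT"]
    )
    source = AlignmentSource(path)
    _, sites, dims = find_variant_sites(source)
    matrix = extract_snp_matrix(source, sites, dims)
    assert sites.aux_chars <= 2 * dims.g
    assert matrix.aux_chars == sites.p * dims.s
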