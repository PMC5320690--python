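import pytest

# Three aligned samples, 12 columns; the polymorphic columns (0-based
# 1, 4 and 7) carry G/G/A, A/A/G and G/-/T respectively.
WORKED_EXAMPLE_FASTA = (
    ">sample1\nAG-CACAGTCAC\n"
    ">sample2\nAGACAC----AC\n"
    ">sample3\nAAACGCATTCAN\n"
)

WORKED_EXAMPLE_SNP_FASTA = ">sample1\nGAG\n>sample2\nGA-\n>sample3\nAGT\n"


def brute_force_sites(sequences):
    """Independent oracle: naive per-column scan for polymorphic columns.

    A column is variant when it holds >= 2 distinct characters after
    uppercasing and discarding the missing set {N, ?, -}.
    """
    missing = {"N", "?", "-"}
    g = len(sequences[0])
    sites = []
    for j in range(g):
        alleles = {
            seq[j].upper() for seq in sequences if seq[j].upper() not in missing
        }
        if len(alleles) >= 2:
            sites.append(j)
    return sites


@pytest.fixture
def worked_example_path(tmp_path):
    path = tmp_path / "worked.aln"
    path.write_text(WORKED_EXAMPLE_FASTA)
    return path
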