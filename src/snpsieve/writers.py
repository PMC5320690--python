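"""Serialization of SNP matrices: multi-FASTA, relaxed PHYLIP, VCF 4.1.

The FASTA writer is the default output and is byte-exact (unwrapped, one
sequence line per sample). PHYLIP output is the relaxed sequential
dialect (names are not truncated to 10 characters), suitable for RAxML.
VCF output follows version 4.1 with haploid single-index GT calls: the
alignment is a single coordinate system labelled contig "1", POS is the
1-based alignment column, gaps are encoded as the ALT allele ``*`` and
unknown bases (N/?) as no-call genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Optional, Sequence, Tuple

from snpsieve.core import (
    SnpMatrix,
    SnpSiteIndex,
    reference_allele_for_site,
)

#: Constant contig label for the alignment's single coordinate system.
VCF_CHROM = "1"
#: ALT symbol used for a gap ('-') allele; VCF cannot carry '-' itself.
GAP_ALLELE = "*"
#: Characters that become no-call ('.') genotypes rather than alleles.
NO_CALL_CHARACTERS = frozenset("N?")


@dataclass(frozen=True)
class VcfSiteRecord:
    """One variant site as CHROM/POS/REF/ALT plus haploid genotype indices.

    ``genotypes`` holds one entry per sample: an index into
    ``[ref] + alts`` (0 = REF), or ``None`` for a no-call.
    """

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    genotypes: Tuple[Optional[int], ...]


def write_snp_fasta(matrix: SnpMatrix, sink: IO[str]) -> None:
    """Write the matrix as unwrapped multi-FASTA.

    Layout is byte-exact: ``'>' + id + newline + row + newline`` per
    sample, in input order.
    """
    for name, row in zip(matrix.sample_ids, matrix.rows):
        sink.write(f">{name}\n{row}\n")


def write_phylip(matrix: SnpMatrix, sink: IO[str]) -> None:
    """Write the matrix as relaxed sequential PHYLIP.

    First line is ``s p``; then one ``id row`` line per sample.
    Sample names are not truncated, so a name containing whitespace would
    corrupt the two-token layout and is rejected.
    """
    for name in matrix.sample_ids:
        if any(c.isspace() for c in name):
            raise ValueError(
                f"sample id {name!r} contains whitespace and cannot be "
                "written in PHYLIP format"
            )
    sink.write(f"{matrix.s} {matrix.p}\n")
    for name, row in zip(matrix.sample_ids, matrix.rows):
        sink.write(f"{name} {row}\n")


def build_vcf_records(matrix: SnpMatrix, sites: SnpSiteIndex) -> list:
    """Turn matrix columns into :class:`VcfSiteRecord` objects.

    For each site (ascending POS = 0-based column + 1): REF is the first
    record's base if informative, otherwise the first informative base
    down the column; ALTs are the remaining distinct folded informative
    alleles in order of first appearance, with ``*`` appended when any
    sample has a gap; each genotype is the sample's allele index, or a
    no-call for N/?.
    """
    records = []
    for j, site in enumerate(sites):
        column = matrix.column(j)
        folded = [c.upper() for c in column]
        ref = reference_allele_for_site(column)
        alts = []
        for c in folded:
            if c in NO_CALL_CHARACTERS or c == "-":
                continue
            if c != ref and c not in alts:
                alts.append(c)
        if "-" in folded:
            alts.append(GAP_ALLELE)
        allele_index = {a: i for i, a in enumerate([ref] + alts)}
        genotypes = tuple(
            None
            if c in NO_CALL_CHARACTERS
            else allele_index[GAP_ALLELE]
            if c == "-"
            else allele_index[c]
            for c in folded
        )
        records.append(
            VcfSiteRecord(
                chrom=VCF_CHROM,
                pos=site + 1,
                ref=ref,
                alts=tuple(alts),
                genotypes=genotypes,
            )
        )
    return records


def write_vcf(
    records: Sequence[VcfSiteRecord],
    sample_ids: Sequence[str],
    sink: IO[str],
    contig_length: Optional[int] = None,
) -> None:
    """Write a VCF 4.1 document with haploid GT calls.

    Emits the ``##fileformat=VCFv4.1`` line, a contig declaration when the
    alignment length is known, the GT FORMAT declaration, the column
    header naming every sample, then one data line per record with
    placeholder ``.`` for ID/QUAL/FILTER/INFO. Records must already be
    sorted by position.
    """
    sink.write("##fileformat=VCFv4.1\n")
    if contig_length is not None:
        sink.write(f"##contig=<ID={VCF_CHROM},length={contig_length}>\n")
    sink.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(sample_ids)
    sink.write("\t".join(header) + "\n")
    for rec in records:
        fields = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            ",".join(rec.alts) if rec.alts else ".",
            ".",
            ".",
            ".",
            "GT",
        ]
        fields.extend("." if gt is None else str(gt) for gt in rec.genotypes)
        sink.write("\t".join(fields) + "\n")
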