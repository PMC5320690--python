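"""Two-pass streaming detection and extraction of SNP sites.

A column of the alignment is a SNP site when it carries at least two
distinct *informative* characters, where gaps and unknown bases
(``n``/``N``/``?``/``-``) are non-variant and every other character —
including IUPAC ambiguity codes other than N — counts as an allele.
Comparison is case-insensitive.

The detector streams the alignment twice. Pass one keeps one consensus
character and one variant flag per column (2g bytes of working state): a
column's consensus is the first informative base seen there, and the
column is flagged the moment a different informative base appears. Pass
two re-reads the file and copies out only the flagged columns (p×s
bytes). Peak working set is therefore max(p×s, 2×g) characters and the
input is read exactly twice, so total file I/O lies in [2f, 2f+o] for an
input of f bytes and output of o bytes. Run time is linear in the input.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from snpsieve.fasta_io import (
    AlignmentDimensions,
    AlignmentSource,
    MalformedFastaError,
    UnequalLengthError,
)

#: Characters treated as missing/non-variant (compared after case folding).
MISSING_CHARACTERS = frozenset("N?-")

# 256-entry lookup tables keep the per-record work vectorised.
_UPPER = np.arange(256, dtype=np.uint8)
for _c in range(ord("a"), ord("z") + 1):
    _UPPER[_c] = _c - 32
_IS_MISSING = np.zeros(256, dtype=bool)
for _c in MISSING_CHARACTERS:
    _IS_MISSING[ord(_c)] = True
_NO_CONSENSUS = 0  # sentinel: no informative base observed yet


class BaseClass(enum.Enum):
    """Classification of a single alignment character."""

    INFORMATIVE = "informative"
    MISSING = "missing"


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-column working reference built during the first pass.

    A column holds ``-`` only if no informative base was ever observed
    there; otherwise it holds the first informative base (uppercase).
    """

    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SnpSiteIndex:
    """Strictly increasing 0-based column indices of the variant sites.

    ``aux_chars`` records the auxiliary working-set the detection pass
    actually allocated (consensus + flag arrays), for resource-envelope
    checks.
    """

    sites: Tuple[int, ...]
    aux_chars: int = 0

    @property
    def p(self) -> int:
        return len(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


@dataclass(frozen=True)
class SnpMatrix:
    """s×p matrix of the variant columns, original characters preserved.

    Row order equals input record order; gaps and unknown bases appear
    verbatim, exactly as read.
    """

    sample_ids: Tuple[str, ...]
    rows: Tuple[str, ...]

    @property
    def s(self) -> int:
        return len(self.rows)

    @property
    def p(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def aux_chars(self) -> int:
        """Characters held by the extraction pass (= p×s)."""
        return sum(len(row) for row in self.rows)

    def column(self, j: int) -> Tuple[str, ...]:
        return tuple(row[j] for row in self.rows)

    def iter_columns(self) -> Iterable[Tuple[str, ...]]:
        for j in range(self.p):
            yield self.column(j)


@dataclass(frozen=True)
class ResourceEnvelope:
    """The algorithm's stated resource bounds for one run.

    Peak working set is at most ``max(p*s, 2*g)`` characters plus constant
    overhead; total file I/O for an f-byte input producing o bytes of
    output lies in ``[2f, 2f + o]``.
    """

    p: int
    s: int
    g: int
    f: int
    o: int

    @property
    def max_working_set(self) -> int:
        return max(self.p * self.s, 2 * self.g)

    @property
    def io_lower(self) -> int:
        return 2 * self.f

    @property
    def io_upper(self) -> int:
        return 2 * self.f + self.o

    def io_within_bounds(self, total_io: int) -> bool:
        return self.io_lower <= total_io <= self.io_upper


def classify_base(c: str) -> BaseClass:
    """Classify one character as informative or missing.

    Missing iff the uppercase fold of ``c`` is one of ``N``, ``?``, ``-``;
    everything else (including ambiguity codes such as ``R``) is an
    informative allele. Total over single characters.
    """
    return BaseClass.MISSING if c.upper() in MISSING_CHARACTERS else BaseClass.INFORMATIVE


def column_alleles(column: Sequence[str]) -> set:
    """Uppercase-folded informative characters present in a column."""
    return {
        c.upper() for c in column if classify_base(c) is BaseClass.INFORMATIVE
    }


def is_variant_site(column: Sequence[str]) -> bool:
    """True iff the column carries at least two distinct informative alleles."""
    return len(column_alleles(column)) >= 2


def reference_allele_for_site(column: Sequence[str]) -> str:
    """Reference allele for a variant column.

    The uppercase fold of the first record's character if informative,
    otherwise the first informative character in record order. A variant
    column has at least one informative character, so this always exists.
    """
    for c in column:
        if classify_base(c) is BaseClass.INFORMATIVE:
            return c.upper()
    raise ValueError("column has no informative characters")


def _as_source(source: Union[AlignmentSource, str, Path]) -> AlignmentSource:
    if isinstance(source, AlignmentSource):
        return source
    return AlignmentSource(source)


def find_variant_sites(
    source: Union[AlignmentSource, str, Path],
) -> Tuple[ConsensusSequence, SnpSiteIndex, AlignmentDimensions]:
    """First pass: stream the alignment once and locate all variant columns.

    Equivalent to applying :func:`is_variant_site` to every column, but
    holding only two g-length arrays (consensus + flags) instead of the
    alignment. The consensus of a column is set to the first informative
    base observed; the column is flagged variant the first time a
    different informative base is seen there.

    Returns the consensus, the ordered site index, and the alignment
    dimensions ``(s, g)`` validated incrementally along the way.
    """
    src = _as_source(source)
    consensus = None
    flags = None
    s = 0
    g = 0
    for record in src.records():
        row = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
        if consensus is None:
            g = row.size
            consensus = np.full(g, _NO_CONSENSUS, dtype=np.uint8)
            flags = np.zeros(g, dtype=bool)
        elif row.size != g:
            raise UnequalLengthError(
                f"sequence '{record.id}' has length {row.size}, "
                f"expected alignment length {g}"
            )
        folded = _UPPER[row]
        informative = ~_IS_MISSING[folded]
        consensus[informative & (consensus == _NO_CONSENSUS)] = folded[
            informative & (consensus == _NO_CONSENSUS)
        ]
        # newly-set columns now agree with their own base, so this flags
        # exactly the columns where a second distinct informative allele
        # has appeared
        flags |= informative & (consensus != folded)
        s += 1
    if consensus is None:
        raise MalformedFastaError("alignment contains no records")
    sites = tuple(int(i) for i in np.flatnonzero(flags))
    consensus_str = consensus.copy()
    consensus_str[consensus_str == _NO_CONSENSUS] = ord("-")
    return (
        ConsensusSequence(bases=consensus_str.tobytes().decode("ascii")),
        SnpSiteIndex(sites=sites, aux_chars=consensus.nbytes + flags.nbytes),
        AlignmentDimensions(s=s, g=g),
    )


def extract_snp_matrix(
    source: Union[AlignmentSource, str, Path],
    sites: SnpSiteIndex,
    dims: Optional[AlignmentDimensions] = None,
) -> SnpMatrix:
    """Second pass: re-read the alignment and extract the variant columns.

    Characters are copied verbatim (case, gaps and unknowns preserved), so
    the matrix holds exactly p×s characters. When ``dims`` from the first
    pass is given, the record count and sequence lengths are re-checked so
    a file changed between passes fails loudly rather than silently.
    """
    src = _as_source(source)
    idx = np.fromiter(sites, dtype=np.int64, count=len(sites))
    ids = []
    rows = []
    g = dims.g if dims is not None else None
    for record in src.records():
        row = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
        if g is None:
            g = row.size
        elif row.size != g:
            raise UnequalLengthError(
                f"sequence '{record.id}' has length {row.size}, "
                f"expected alignment length {g} (input changed between passes?)"
            )
        ids.append(record.id)
        rows.append(row[idx].tobytes().decode("ascii"))
    if dims is not None and len(rows) != dims.s:
        raise MalformedFastaError(
            f"alignment held {dims.s} records on the first pass but "
            f"{len(rows)} on the second; input changed between passes"
        )
    if not rows:
        raise MalformedFastaError("alignment contains no records")
    return SnpMatrix(sample_ids=tuple(ids), rows=tuple(rows))
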