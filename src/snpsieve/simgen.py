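"""Planted-SNP synthetic alignments and a scaling-experiment harness.

The generator emulates benchmark alignments parameterised by taxa count
``s``, genome length ``g`` and planted SNP-site count ``p``: a uniform
random background sequence shared by all samples, with exactly ``p``
columns carrying a random bi-allelic bipartition of the samples. Missing
characters (``-``/``N``/``n``/``?``) can be injected at a configurable
rate; two guard samples per planted column are never masked there, so the
planted columns keep at least two distinct informative alleles and the
variant-site count stays exactly ``p`` under the detection predicate.
Monomorphic columns can only lose informative bases, never gain a second
allele, so no spurious sites can appear either.

Generation streams one sample row at a time: working memory is O(g + p),
independent of ``s``.
"""

from __future__ import annotations

import gzip
import io
import time
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from snpsieve.core import extract_snp_matrix, find_variant_sites
from snpsieve.fasta_io import AlignmentSource, CountingTextSink, IOCounter
from snpsieve.writers import write_snp_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MISSING = np.frombuffer(b"-Nn?", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one planted-SNP synthetic alignment.

    ``gap_fraction`` is the probability that any non-guarded cell is
    replaced by a missing character (default 0).
    """

    s: int
    g: int
    p: int
    seed: int
    gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.s < 1 or self.g < 1:
            raise ValueError("alignment needs s >= 1 and g >= 1")
        if not 0 <= self.p <= self.g:
            raise ValueError(f"planted site count p={self.p} must lie in [0, g={self.g}]")
        if self.p >= 1 and self.s < 2:
            raise ValueError("planting variant sites requires at least 2 samples")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")


def generate_alignment(
    spec: SimulationSpec, sink: Union[IO[str], str, Path]
) -> Tuple[int, ...]:
    """Write a planted-SNP alignment and return the sorted planted positions.

    ``sink`` may be a text file object or a path; a path ending in ``.gz``
    is written gzip-compressed. Output is fully reproducible from
    ``spec.seed``: the same spec always yields byte-identical FASTA.
    """
    rng = np.random.default_rng(spec.seed)
    background = _BASES[rng.integers(0, 4, size=spec.g)]
    positions = np.sort(rng.choice(spec.g, size=spec.p, replace=False))

    # Per planted column: two distinct alleles and two guard samples, one
    # carrying each allele, exempt from missing-character injection there.
    allele_pairs = np.empty((spec.p, 2), dtype=np.uint8)
    for j in range(spec.p):
        allele_pairs[j] = _BASES[rng.choice(4, size=2, replace=False)]
    if spec.p:
        guard_a = rng.integers(0, spec.s, size=spec.p)
        guard_b = (guard_a + 1 + rng.integers(0, spec.s - 1, size=spec.p)) % spec.s
    else:
        guard_a = guard_b = np.empty(0, dtype=np.int64)

    own_handle = False
    if isinstance(sink, (str, Path)):
        path = Path(sink)
        if path.suffix == ".gz":
            out: IO[str] = io.TextIOWrapper(gzip.open(path, "wb"), encoding="ascii")
        else:
            out = open(path, "w", encoding="ascii")
        own_handle = True
    else:
        out = sink

    try:
        for i in range(spec.s):
            row = background.copy()
            if spec.p:
                takes_b = rng.random(spec.p) < 0.5
                takes_b[guard_a == i] = False
                takes_b[guard_b == i] = True
                row[positions] = np.where(takes_b, allele_pairs[:, 1], allele_pairs[:, 0])
            if spec.gap_fraction > 0.0:
                mask = rng.random(spec.g) < spec.gap_fraction
                if spec.p:
                    mask[positions[guard_a == i]] = False
                    mask[positions[guard_b == i]] = False
                n_missing = int(mask.sum())
                row[mask] = _MISSING[rng.integers(0, len(_MISSING), size=n_missing)]
            out.write(f">sample{i + 1}\n")
            out.write(row.tobytes().decode("ascii"))
            out.write("\n")
    finally:
        if own_handle:
            out.close()
    return tuple(int(x) for x in positions)


@dataclass(frozen=True)
class ScalingResult:
    """One row of a scaling experiment: correctness plus resource readings."""

    spec: SimulationSpec
    p_found: int
    positions_match: bool
    elapsed: float
    file_size: int
    bytes_read: int
    bytes_written: int

    @property
    def correct(self) -> bool:
        return self.p_found == self.spec.p and self.positions_match


def _default_runner(path: Path) -> Tuple[Sequence[int], int, int]:
    """Run detection + extraction + FASTA output with instrumented I/O.

    Returns (found sites, raw bytes read from the input, characters
    written to the output sink).
    """
    source = AlignmentSource(path)
    consensus, sites, dims = find_variant_sites(source)
    matrix = extract_snp_matrix(source, sites, dims)
    counter = IOCounter()
    write_snp_fasta(matrix, CountingTextSink(io.StringIO(), counter))
    return tuple(sites), source.bytes_read, counter.bytes_written


def run_scaling_experiment(
    grid: Sequence[SimulationSpec],
    runner: Optional[Callable[[Path], Tuple[Sequence[int], int, int]]] = None,
    workdir: Union[str, Path, None] = None,
) -> List[ScalingResult]:
    """Generate each alignment in ``grid``, run the pipeline, and record
    correctness (found sites vs planted manifest) and resource figures.

    Alignments are written under ``workdir`` (a temporary directory by
    default) and removed after each run.
    """
    import tempfile

    if not grid:
        raise ValueError("grid must contain at least one SimulationSpec")
    if runner is None:
        runner = _default_runner
    results: List[ScalingResult] = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for k, spec in enumerate(grid):
            path = Path(tmp) / f"sim_{k}.aln"
            planted = generate_alignment(spec, path)
            file_size = path.stat().st_size
            start = time.perf_counter()
            found, bytes_read, bytes_written = runner(path)
            elapsed = time.perf_counter() - start
            results.append(
                ScalingResult(
                    spec=spec,
                    p_found=len(found),
                    positions_match=tuple(found) == planted,
                    elapsed=elapsed,
                    file_size=file_size,
                    bytes_read=bytes_read,
                    bytes_written=bytes_written,
                )
            )
            path.unlink()
    return results


def write_report(results: Sequence[ScalingResult], sink: IO[str]) -> None:
    """Emit the experiment as a tab-delimited table."""
    sink.write(
        "s\tg\tp\tgap_fraction\tseed\tp_found\tcorrect\telapsed_s\t"
        "file_bytes\tbytes_read\tbytes_written\n"
    )
    for r in results:
        sink.write(
            f"{r.spec.s}\t{r.spec.g}\t{r.spec.p}\t{r.spec.gap_fraction}\t"
            f"{r.spec.seed}\t{r.p_found}\t{r.correct}\t{r.elapsed:.4f}\t"
            f"{r.file_size}\t{r.bytes_read}\t{r.bytes_written}\n"
        )
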