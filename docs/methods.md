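# Methods

## The detection predicate

An alignment column is a SNP site iff it contains at least two distinct
informative characters after uppercase folding, where the missing set is
exactly {`N`, `?`, `-`} (so `n` is missing via folding). Everything else
is an allele, including IUPAC ambiguity codes other than N (`R`, `Y`,
`S`, `W`, `K`, `M`, `B`, `D`, `H`, `V`) and non-IUPAC characters such as
`.`: the missing set is a closed enumeration, not "anything
non-ACGT". Consequences that follow directly:

- a column of one informative allele plus any mixture of gaps/unknowns
  is monomorphic and excluded;
- a column that is entirely missing is not a variant site;
- `a` vs `A` is not variation, but extracted matrix characters preserve
  the original case and missing characters verbatim.

This declarative predicate is the ground truth. The streaming consensus
is an implementation strategy and is held to it by a property test that
compares the detector against a brute-force per-column scan (written
independently in the test suite) on randomized alignments over the full
alphabet.

## Two-pass streaming algorithm

Pass one keeps two g-length arrays: the consensus (one byte per column,
initialised to a sentinel meaning "no informative base seen yet") and a
variant flag per column. For each record, vectorised over the row: fold
case, mark informative positions, set unset consensus entries to the
row's base, then OR into the flags every position where an informative
base differs from the consensus. Because a column's consensus is fixed
at the first informative base, a flag is raised iff a second distinct
informative allele exists — exactly the predicate. Auxiliary storage is
2g bytes; the measured allocation is attached to the site index
(`aux_chars`) so tests and the acceptance script can check the bound
rather than trust it.

Pass two re-reads the file (the source abstraction counts opens and raw
bytes) and gathers the flagged columns per record with a fancy-indexed
copy, p characters per row, p×s total. Record count and sequence
lengths are re-checked on the second pass so an input replaced between
passes fails loudly. Total reads of the input are exactly two, giving
the I/O envelope 2f ≤ I/O ≤ 2f + o; byte counting happens below the
gzip layer, so f is on-disk (compressed) size for compressed input.

Degenerate inputs: a single-sequence alignment and an all-identical
alignment both yield p = 0 (variation needs two informative alleles);
an empty file or a file whose first non-blank character is not `>` is a
malformed-FASTA error; unequal sequence lengths abort naming the
offending record. Duplicate sample ids warn but parse, since output is
positional.

## Output formats

- **FASTA** (default): unwrapped, byte-exact `>id\nrow\n` per sample.
- **PHYLIP**: relaxed sequential — `s p` header then `id row` lines,
  names not truncated to 10 characters (the dialect RAxML accepts);
  whitespace in a name would corrupt the two-token layout and is
  rejected.
- **VCF 4.1**: the alignment is one coordinate system, labelled contig
  `1`; POS is the 1-based alignment column. REF is the first record's
  base if informative, else the first informative base down the column.
  ALTs are the remaining distinct folded informative alleles in order
  of first appearance, with `*` appended when any sample has a gap (VCF
  cannot carry `-` as an allele string; `*` is the standard
  missing-allele symbol). Genotypes are haploid single indices —
  appropriate for prokaryotic genomes — with `N`/`?` as no-calls. All
  other fixed columns are `.` placeholders. Conformance is checked in
  the tests by parsing every emitted document with pysam (htslib), an
  implementation the writer shares no code with.

## Synthetic alignments

`simgen` plants an exactly known number of SNP sites: a uniform-random
ACGT background shared by all samples; p distinct columns drawn without
replacement; at each planted column two distinct bases and a random
Bernoulli(½) bipartition of the samples, with two guard samples (one
per allele) forced, so every planted column is bi-allelic by
construction. Optional missing-character injection (`gap_fraction`,
default 0, drawing from `-`/`N`/`n`/`?`) never touches the guards at
their planted columns, so planted columns keep ≥ 2 informative alleles
and monomorphic columns can only lose bases — the variant-site count
stays exactly p under the predicate. Generation streams one row at a
time (O(g + p) memory) and is byte-reproducible from the seed.

What this emulates and what it does not: the generator reproduces
benchmark-style alignments parameterised by (s, g, p) — the quantities
the algorithm's resource envelope is stated in — not phylogenetically
realistic data. There is no coalescent structure, no substitution
model, no linkage, and background columns are i.i.d. Passing tests
therefore demonstrate exact site recovery, format correctness and the
resource envelope, not robustness to properties the predicate ignores
anyway (the detector is a per-column set computation, so realism of the
column arrangement does not affect correctness).

`run_scaling_experiment` generates each grid point, runs the pipeline
with instrumented I/O, and reports p_found vs p, elapsed time, file
size and bytes read/written as a tab-delimited table.

## Problem sizes and checks

The test and acceptance grids use s ∈ {2, 10, 100, 1000}, g ∈ {10³,
10⁵}, p ∈ {0, 1, g/10}, with and without 10 % gap injection (48 runs,
the largest 10⁸ characters), plus 1000 randomized small alignments
(s ≤ 20, g ≤ 200) for the oracle comparison and a 10× input-size sweep
for the linear-time check; these sizes exercise every parameter while
keeping a full run to seconds on one CPU. The linearity check allows a
3× noise factor over the ideal 10× ratio, since small runs are
dominated by constant overhead. A published 1842-taxon *S.* Typhi
alignment (8.3 GB) provides an optional real-data check — 22 618
expected sites — that runs only when the file has been downloaded
locally.

## Known limitations

- The whole input must be a valid single alignment; there is no
  recovery or column-wise error tolerance.
- Monomorphic-site output and ACGT-only column filtering are out of
  scope.
- VCF output is sites-only (no INFO annotations, no diploid genotypes,
  no BCF/bgzip/tabix).
- The second pass holds the full p×s matrix; for alignments where
  nearly every column is variant this approaches the input size, as the
  envelope max(p×s, 2g) implies.
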