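# snpsieve

Streaming extraction of SNP sites from whole-genome multi-FASTA
alignments, for prokaryotic population genomics and phylogenetics
preprocessing.

A routine step in bacterial population studies is reducing a large
whole-genome alignment (thousands of taxa, megabases of columns) to just
its polymorphic columns before tree building with FastTree or RAxML, or
variant-level analysis with BCFtools. Naive approaches load the whole
alignment into memory; `snpsieve` instead streams the file twice and
keeps only a consensus and the variant columns, so memory scales with
the variation, not the input.

## Algorithm

Let *s* be the number of samples, *g* the alignment length and *p* the
number of SNP sites. A column is a **SNP site** when it carries at least
two distinct *informative* characters; gaps and unknown bases
(`n`/`N`/`?`/`-`) are non-variant, and comparison is case-insensitive.
Any other character — including IUPAC ambiguity codes other than N — is
an allele.

- **Pass 1** reads each sequence in turn against a consensus: a column's
  consensus is the first informative base seen there, and the column is
  flagged variant the moment a different informative base appears.
  Working state: 2×*g* characters.
- **Pass 2** re-reads the file and copies out the flagged columns
  verbatim (case and gaps preserved): *p*×*s* characters.

Peak working set is therefore max(*p*×*s*, 2×*g*) plus constant
overhead, total file I/O lies in [2*f*, 2*f*+*o*] for an *f*-byte input
and *o*-byte output, and run time is linear in the input size. Input may
be gzip-compressed (detected from the magic bytes, not the extension).

Output formats: multi-FASTA (default), relaxed sequential PHYLIP, or
VCF 4.1 with haploid single-index `GT` calls (POS is the 1-based
alignment column; gaps become the `*` ALT allele; `N`/`?` become
no-calls).

## Worked example

Given `example.aln`:

```
>sample1
AG-CACAGTCAC
>sample2
AGACAC----AC
>sample3
AAACGCATTCAN
```

```sh
$ snpsieve example.aln
>sample1
GAG
>sample2
GA-
>sample3
AGT
snpsieve: 3 samples, 12 columns, 3 SNP sites
```

Column 1 (`A/A/A`) is monomorphic and column 2 (`A/A/-`) has only one
informative allele, so neither is output; columns 2, 5 and 8 (1-based)
each carry two informative alleles and survive. The summary line goes to
stderr so the FASTA can be piped. The same sites as VCF:

```sh
$ snpsieve -v example.aln
##fileformat=VCFv4.1
##contig=<ID=1,length=12>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM  POS  ID  REF  ALT  QUAL  FILTER  INFO  FORMAT  sample1  sample2  sample3
1       2    .   G    A    .     .       .     GT      0        0        1
1       5    .   A    G    .     .       .     GT      0        0        1
1       8    .   G    T,*  .     .       .     GT      0        2        1
```

At POS 8 sample2 has a gap: it is encoded as the `*` allele (index 2).
`-p` writes relaxed PHYLIP (`3 3` header, then `sample1 GAG` …), and
`-o FILE` redirects output.

The library surface mirrors the pipeline
(`find_variant_sites` → `extract_snp_matrix` → a writer), and
`snpsieve.simgen` generates planted-SNP benchmark alignments with a
known site manifest plus a scaling-experiment harness.

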