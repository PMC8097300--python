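# The `.tpbwt` compressed panel format

A `.tpbwt` file stores a phased haplotype panel as run-length-encoded allele
columns in templated-PBWT order, so that sweeps over the panel can query
alleles once per run instead of once per haplotype.  All integers are
little-endian.  Decompression is bit-exact: missing alleles are stored as an
explicit third symbol, and the per-template haplotype orderings are not
stored — a reader rebuilds them incrementally with the same deterministic
sort used at compression time (no phase corrections are ever applied during
encoding, so the orderings are a pure function of the stored alleles).

## Header

| field         | type                   | meaning                                  |
|---------------|------------------------|------------------------------------------|
| magic         | 5 bytes `TPBW1`        | file identification                      |
| version       | u8                     | format version, currently 1              |
| M             | u32                    | number of haplotype rows                 |
| N             | u32                    | number of sites                          |
| t             | u16                    | number of templates                      |
| period        | u16                    | template mask period                     |
| masks         | t × period bytes       | 0/1 mask values, one row per template    |
| chrom_len     | u16                    | byte length of the chromosome label      |
| chromosome    | chrom_len bytes, UTF-8 | chromosome label                         |
| n_samples     | u32                    | number of diploid samples (M = 2·n)      |
| sample ids    | n × (u16 len + UTF-8)  | sample identifiers, in haplotype order   |
| bp            | N × i64                | physical positions (VCF POS, ascending)  |
| cm            | N × f64                | genetic positions (cM, non-decreasing)   |

## Body

For each site `k = 0 … N−1`, and for each template `j` (ascending) whose
mask processes `k` (`masks[j][k mod period] == 1`):

* `n_runs` — varint (LEB128, 7 data bits per byte, high bit = continuation)
* `n_runs` × run — varint encoding `(length << 2) | symbol`, where symbol is
  0, 1, or 2 (missing)

Runs are laid out in that template's haplotype ordering at site `k` (the
positional prefix array *before* incorporating site `k`); run lengths at
each cell sum to M.  Readers must reject files whose magic or version do
not match, whose runs do not sum to M, or that end prematurely; the package
reports the byte offset of a truncation.

Panels embed their template set; two panels can only be swept together
(out-of-sample comparison) when their template sets, chromosome and site
positions agree.  `tpbwt subset-sites` cuts two panels down to their shared
sites.
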