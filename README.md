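# genochain

Storage and analysis of personal genomic data on a blockchain-style data
store. `genochain` keeps reference-aligned sequencing reads (SAM/BAM) and
genetic variants (VCF) **on-chain** — inside append-only, hash-chained
key:value data streams — and answers genomic queries (read retrieval,
depth, pileup, variant lookup) directly from the chain, without ever
reconstructing the flat file first.

It is aimed at anyone prototyping owner-controlled genomic storage: the
data owner initializes a chain, grants a sequencer write permission, and
clinicians/researchers query the data with read-only access; every
publication and permission change is an on-chain, timestamped, tamper-
evident transaction.

## How it works

**Stream store.** A chain is a set of named streams of items
`(publisher, keys, data)`. Publishing an item is a transaction; pending
transactions are sealed into blocks linked by SHA-256 hashes, so any
single-byte change to persisted data flips `Chain.verify()` to invalid.
The store is a single-node, file-backed emulation of permissioned-
blockchain stream semantics (one directory: item log, block log, derived
key index).

**SAMchain layout.** Reads are range objects, so a plain key:value index
cannot answer region queries. Each chromosome is therefore split into
fixed-length bins of `bin_length` bp, one stream per bin
(`{chrom}stream{j}`, bin *j* covering `[(j−1)·L+1, j·L]`): a chromosome of
248,956,422 bp at 1 Mbp bins gets 249 streams. A mapped read is filed in
the bin of its start position with a key `FLANK=0`, or `FLANK=1` when its
alignment spills into the next bin — a query for a region then reads only
the intersecting bins plus the one upstream bin (for FLANK=1 reads), so
query cost scales with bin occupancy, not chain size. Headers live in
`metaData`; unmapped reads and non-configured contigs in
`unmappedANDcontigs`.

**Modcigar compression.** On-chain records drop SEQ and QUAL and store
only the *difference* from the reference (CRAM-inspired): a `;`-joined
list of `<query-offset><op><bases>` tokens with ops `X` (mismatch), `I`
(insertion), `S` (soft-clip), e.g. `12XA;45IACG`. Reference + CIGAR +
modcigar regenerate the original sequence exactly; qualities are discarded
irrecoverably and reconstructed files carry the `*` sentinel. On a
10,000-read fixture this cuts plaintext record bytes ~7-fold.

**VCFchain.** Variants are point positions, so no binning: one
`allVariantData` stream whose items carry `POS:<chrom>:<pos>`,
`GT:<genotype>` and `ID:<rsid>` keys and the verbatim VCF data line as
payload. `query_and` retrieves by position and AND-filters by genotype
and/or rsID.

A deterministic synthetic module (`genochain.synthetic`) generates the
reference FASTA, simulated SAM and VCF fixtures, so everything is testable
offline.

## Worked example

```sh
cat > params.yaml <<EOF
seed: 42
chromosomes: [[chr1, 500000]]
n_reads: 2000
read_length: 150
n_variants: 200
EOF
cat > chain.yaml <<EOF
chromosomes: [[chr1, 500000]]
bin_length: 100000
read_length: 300
reference_id: demo
EOF

genochain sim ref   --params params.yaml --out ref.fa
genochain sim reads --params params.yaml --ref ref.fa --out reads.sam
genochain samchain build  --path chain --config chain.yaml
genochain samchain insert --path chain --sam reads.sam --ref ref.fa
```

which prints

```
built SAMchain with 5 binned streams
{"mapped": 1980, "unmapped": 20, "flank1": 4, "header_lines": 2}
```

— 5 bins (500 kbp at 100-kbp bins), 1,980 mapped reads binned, 20
unmapped reads routed to `unmappedANDcontigs`, and 4 reads whose
alignments straddle a bin boundary (stored with key `FLANK=1`). Querying:

```sh
$ genochain sctools queryReads --path chain --region chr1:100000-100010 --ref ref.fa | cut -f1-6
read001193	0	chr1	99900	39	150M
read001325	0	chr1	99941	34	9M2I139M
```

Both hits *start in bin 1* but overlap the queried positions in bin 2 —
they are found through the upstream-bin FLANK rule, with their sequences
regenerated from reference + modcigar. Depth and pileup come straight off
the chain:

```sh
$ genochain sctools pileup --path chain --region chr1:100001-100002 --ref ref.fa
chr1	100001	G	2	GG
chr1	100002	T	2	TT
```

(position, reference base, depth, per-read observed bases). Finally

```sh
genochain sctools buildBAM --path chain --ref ref.fa --out rebuilt.bam
genochain chain verify --path chain
```

rebuilds a coordinate-sorted BAM identical to the input up to qualities
and reports `{"valid": true, "first_bad_height": null}`.

The same flow works for variants: `genochain vcfchain build / insert /
query --pos chr1:1946 [--gt 0/1] [--rsid rs17]`.

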