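# Methods

## The stream-store model

`genochain.chainstore` emulates the data-stream semantics of permissioned
blockchains on a single node. A chain is an on-disk directory with an
append-only item log (`items.jsonl`), a block log (`blocks.jsonl`) and a
self-describing header that records the digest algorithm (SHA-256). The
per-key retrieval index is derived data: it is rebuilt on open and is
deliberately outside the integrity perimeter.

Every published item carries a publisher identity, 1–256-character
printable-ASCII keys (no whitespace, no quotes), an opaque byte payload,
a Unix blocktime and a transaction id. The txid is the SHA-256 digest of
`(stream, publisher, sorted keys, payload, counter, blocktime)` — the
chain-wide monotonic counter makes txids unique even for byte-identical
payloads, and including every persisted field makes any single-byte edit
of the stored item detectable. Blocks cover `(height, timestamp, ordered
txids, previous hash)`; the genesis block anchors the chain with an
all-zero previous hash.

**Block sealing** is logical, not wall-clock: a block is sealed
automatically every `block_size` pending transactions (default 1,000) or
on an explicit `mine_pending()` flush. This keeps runs deterministic; a
wall-clock target-block-time would only change *where* block boundaries
fall, never stream contents. Confirmations are computed at read time as
(number of blocks − item's block height), 0 for pending items, so mining
never rewrites stored items.

**Permissions** model the network roles (owner, sequencer, clinician,
researcher) as publisher identities. Grants and revocations are
themselves timestamped stream items in a reserved `_permissions` stream;
the effective permission is the latest entry per (grantee, role). The
owner implicitly holds every role; read is open by default, write/admin
require a grant. Stream creation is likewise recorded as a transaction in
a reserved `_streams` stream.

**Verification** (`Chain.verify`) re-derives everything from the
persisted bytes: block digests and prev-hash links, consecutive heights,
and every item txid. Files are split on raw `\n` bytes so a corrupted
newline merges lines (and fails) instead of silently re-splitting on
another control character. A malformed or mismatching item is attributed
to its containing block by txid when parseable, otherwise by ordinal
(publication order equals mining order on a single node).

## Reference-based read compression (modcigar)

The on-chain record of a mapped read keeps the SAM mandatory fields minus
SEQ and QUAL, plus a *modcigar*: the minimal set of read bases that
differ from the reference, as `;`-joined tokens
`<0-based query offset><op><bases>` with strictly increasing offsets.
Ops: `X` — one contiguous run of mismatching bases inside an alignment-
match segment; `I` — the bases of an insertion; `S` — the bases of a
soft-clip (they are absent from the reference, so every `S` CIGAR segment
must carry a token; hard clips carry nothing). The empty string means the
read equals the reference across its alignment.

Decoding walks the CIGAR over the reference window starting at the mapped
position: M segments copy reference bases then overlay `X` tokens, `I`/`S`
segments take their bases from exactly one token each, `D`/`N` skip
reference bases. `decode(encode(seq)) == seq` is enforced as a property
test across mutation rates (including rate 0 and length-1 reads) and for
every read the simulator emits.

Numerical/representation choices: sequences are uppercased before
comparison (SAM case carries no meaning), `N` versus a non-`N` base *is* a
mismatch, `=`/`X` CIGAR ops are accepted on input and normalized to `M`
for storage, and the empty modcigar is rendered as `*` inside the
tab-separated payload so field counts stay fixed. Quality strings are
discarded at encode time and are unrecoverable by design; reconstruction
emits the `*` sentinel, and all round-trip equivalences exclude QUAL.

## SAMchain layout and insertion

`ChainConfig` fixes the chromosome set and lengths, the bin length and a
declared maximum read (reference-span) length; the constructor enforces
`bin_length >= declared_read_length`, which makes "spans more than two
bins" impossible for conforming input and a hard error otherwise. Bins
are 1-based closed intervals; `n_bins` is ceiling division;
`bin_index(pos) = floor((pos−1)/bin_length) + 1`, so a read ending exactly
on a bin boundary has `FLANK=0`.

Insertion routes a record to `unmappedANDcontigs` when the unmapped FLAG
bit is set, RNAME is `*`, or RNAME is not a configured chromosome (the
workable reading of "contigs"); such records keep their sequence verbatim
(QUAL replaced by `*`) so they can be realigned later. All other records
are modcigar-encoded and published to the bin of their start position.
Header lines are published line-by-line (newlines included) to
`metaData`, so their concatenation is byte-identical to the input header.
Secondary/supplementary alignments and duplicates are stored like any
other record; optional tags are stored verbatim after the modcigar field.

**Resumable insertion.** Free disk space is checked every 1,000 records
(configurable, and injectable for testing) against a configurable
minimum. On breach the pending block is sealed, a checkpoint with the
next record ordinal is written inside the chain directory, and a storage
error carrying the resume point is raised. Re-running with `resume=True`
skips the already-inserted ordinals; the resulting per-stream item
sequence is identical to an uninterrupted run (asserted in the tests).
The insertion report of a resumed run counts only the records it inserted
itself.

## Query semantics

All coordinates are SAM convention: 1-based, closed intervals; overlap is
closed-interval intersection, so a read whose reference end equals the
query start is returned. Region resolution (`streams_for`) selects the
bins intersecting the query plus the single upstream bin of the first
(when one exists); from the upstream bin only `FLANK=1` items are fetched
via the key index, since nothing else there can reach the region. A read
log on the store asserts that queries touch exactly these streams.

`query_depth` counts, per position, reads whose CIGAR places a query base
there (M/=/X); deletions and reference skips contribute zero, and
I/S/H/P never cover a reference position. `pileup` emits one column per
position with at least one covering *or deleted* read: chromosome,
position, reference base, depth, and the per-read observed bases in
publication order, with `*` marking reads deleted at that position —
deletion markers are excluded from depth so pileup and depth agree. The
MAPQ filter available on every query is inclusive (`mapq >= threshold`).

`build_bam` rebuilds a complete alignment file: header from `metaData`,
every binned record with its sequence regenerated, every unmapped record
verbatim, coordinate-sorted with unmapped records last (what downstream
tools expect from an indexed store). Output format follows the extension
(`.bam` binary, else SAM text).

## VCFchain

Two streams only — `metaData` (header lines) and `allVariantData` (one
item per data line, payload verbatim) — relying purely on the key index:
variants are points, so binning buys nothing. Keys are
`POS:<chrom>:<pos>`, `GT:<gt>` and `ID:<rsid>` (omitted for `.`);
genotypes are verbatim, so `0/1` and `0|1` are distinct keys and phasing
is preserved. Duplicate positions are permitted and all matches returned
(strictly more general than assuming uniqueness; identical behaviour on
unique-position files). Only single-sample VCFs are accepted — the use
case is a personal genome — and malformed data lines are skipped and
reported by line number rather than aborting the insertion.

## Synthetic fixtures

The generator emulates a small personal-genome slice: a uniform-random
reference (defaults: one 2-Mbp chromosome, the scale of a single disease
locus), 10,000 150-bp reads with per-base independent mismatches (1%),
geometric indels (0.1% each, mean length 2, total capped at a quarter of
the read length), optional soft-clips and a fixed unmapped fraction
emitted as FLAG-0x4 records, plus a 1,000-variant single-sample VCF
mixing SNPs (70%), short indels (20%) and symbolic `<DEL>` structural
variants (10%), het with probability 0.5 and rsIDs on half the records.
QUAL is a constant character so its deliberate loss is visible in diffs.

Determinism: every read/variant draws from its own counter-derived
substream (`default_rng([seed, domain, counter])`), so outputs are
byte-identical for equal parameters regardless of generation order or
platform. What the generator does **not** model: realistic error
profiles, quality models, coverage or GC bias, paired ends, multiple
samples. Passing tests therefore demonstrate correctness of storage,
indexing, encoding and query logic — not robustness to the full
messiness of production sequencing data (e.g. exotic read names, CIGARs
with N/H/P ops are handled by the codec but not emitted by the
generator).

## Problem sizes and test design

The test fixtures are one 300-kbp chromosome with 1,000 reads at 50-kbp
bins (so bin-straddling FLANK=1 reads occur regularly) and, for the
storage and round-trip checks, the 2-Mbp / 10,000-read benchmark
configuration. Query modules are validated against independent
brute-force oracles built from the *original* SAM via pysam's aligned-
pairs interface (a different code path from the package's CIGAR walker)
over randomized point, range and boundary-straddling regions. Integrity
is validated by a 100-position single-byte corruption fuzz over both the
item and block logs.

The measured ~7-fold plaintext record-byte reduction on the benchmark
fixture exceeds the ~2-fold one would see on typical real files, because
synthetic records have short read names and no optional-tag bloat, so
SEQ+QUAL dominate record bytes; the quantity is reported as computed, not
tuned.

## Known limitations

Single process, single node: no networking, consensus, proof-of-work or
mining diversity — immutability here means tamper *evidence*, not
distributed irreversibility. The whole chain index lives in memory on
open, which is fine at personal-genome scale but untested beyond it.
Qualities are unrecoverable by design. The wire formats (payload layout,
modcigar grammar, digest inputs) are versioned in `metaData` but are this
package's own and not bit-compatible with any external blockchain
platform.
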