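"""Analytics over a SAMchain: region queries, depth, pileup, BAM rebuild.

All operations resolve a genomic region to the minimal set of binned
streams (:func:`streams_for`): the bins intersecting the region plus the
single bin immediately upstream of the first, which may hold FLANK=1 reads
whose alignments spill into the region.  Only those streams are read, so
query cost depends on the number of items in the touched bins, not on the
chain size.

Coordinate conventions are SAM's: 1-based, closed intervals; a read whose
reference end equals the query start overlaps.  Depth at a position counts
reads with a query base aligned there (CIGAR M/=/X); deletions and
reference skips (D/N) in a read contribute zero, and I/S/H/P never cover a
reference position.  The optional MAPQ filter is inclusive (``mapq >=
min_mapq`` retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pysam

from . import refcodec
from .samchain import (
    KEY_FLANK1,
    SamChain,
    StoredRead,
    UNMAPPED_STREAM,
    bin_index,
    bin_interval,
    n_bins,
    stream_name,
)

__all__ = [
    "RegionQuery",
    "PileupColumn",
    "streams_for",
    "query_reads",
    "query_depth",
    "pileup",
    "build_bam",
]

#: Marker for a read deleted at a pileup position (excluded from depth).
DELETION_MARKER = "*"


@dataclass(frozen=True)
class RegionQuery:
    """A 1-based closed genomic interval with an optional MAPQ filter."""

    chrom: str
    start: int
    end: int
    min_mapq: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.start}-{self.end}")


@dataclass(frozen=True)
class PileupColumn:
    """Per-position pileup: reference base, coverage, observed bases.

    ``bases`` holds one character per read in publication order — the
    read's base for covering reads, :data:`DELETION_MARKER` for reads
    deleted at this position.  ``depth`` counts covering reads only, so it
    matches :func:`query_depth`.
    """

    chrom: str
    pos: int
    ref_base: str
    depth: int
    bases: str

    def to_tsv(self) -> str:
        return "\t".join([self.chrom, str(self.pos), self.ref_base,
                          str(self.depth), self.bases])


def _validate(query: RegionQuery, sc: SamChain) -> int:
    lengths = sc.config.chrom_lengths
    if query.chrom not in lengths:
        raise ValueError(f"chromosome {query.chrom!r} not configured")
    if query.end > lengths[query.chrom]:
        raise ValueError(
            f"region end {query.end} beyond chromosome length "
            f"{lengths[query.chrom]}")
    return lengths[query.chrom]


def streams_for(query: RegionQuery, config) -> list[tuple[str, int]]:
    """Bins intersecting the region, preceded by the upstream flank bin.

    Returns ``(chrom, j)`` pairs in genomic order.  When the first
    intersecting bin is not the chromosome's first bin, the bin just
    upstream is prepended: a FLANK=1 read starting there may extend into
    the region.
    """
    lengths = dict(config.chromosomes)
    if query.chrom not in lengths:
        raise ValueError(f"chromosome {query.chrom!r} not configured")
    last_bin = n_bins(lengths[query.chrom], config.bin_length)
    first = bin_index(query.start, config.bin_length)
    last = min(bin_index(query.end, config.bin_length), last_bin)
    bins = list(range(first, last + 1))
    if first > 1:
        bins.insert(0, first - 1)
    return [(query.chrom, j) for j in bins]


def _candidate_reads(sc: SamChain, query: RegionQuery) -> list[StoredRead]:
    """Stored reads overlapping the region, in stream/publication order.

    For the upstream flank bin (which does not itself intersect the
    region) only FLANK=1 items are retrieved via the key index.
    """
    chain = sc.chain
    out: list[StoredRead] = []
    for chrom, j in streams_for(query, sc.config):
        lo, hi = bin_interval(j, sc.config.bin_length)
        name = stream_name(chrom, j)
        if hi < query.start or lo > query.end:
            items = chain.list_stream_key_items(name, KEY_FLANK1)
        else:
            items = chain.list_stream_items(name)
        for item in items:
            read = StoredRead.from_payload(item.data)
            if read.pos > query.end or read.reference_end < query.start:
                continue
            if query.min_mapq is not None and read.mapq < query.min_mapq:
                continue
            out.append(read)
    return out


def _fetch_window(reference: pysam.FastaFile, read: StoredRead) -> str:
    span = refcodec.cigar_reference_span(read.cigar)
    return reference.fetch(read.rname, read.pos - 1, read.pos - 1 + span)


def query_reads(sc: SamChain, query: RegionQuery,
                reference: pysam.FastaFile) -> list[str]:
    """SAM lines of the stored reads overlapping a region.

    Sequences are regenerated from the reference via the stored modcigar;
    QUAL is the missing sentinel.
    """
    _validate(query, sc)
    lines = []
    for read in _candidate_reads(sc, query):
        seq = refcodec.decode_sequence(_fetch_window(reference, read),
                                       read.cigar, read.modcigar)
        lines.append(read.to_sam_line(seq))
    return lines


def query_depth(sc: SamChain, query: RegionQuery) -> np.ndarray:
    """Per-position read depth over the region (index 0 = query start)."""
    _validate(query, sc)
    depth = np.zeros(query.end - query.start + 1, dtype=np.int64)
    for read in _candidate_reads(sc, query):
        r = read.pos
        for n, op in refcodec.parse_cigar(read.cigar):
            if op in refcodec.ALIGN_OPS:
                lo = max(r, query.start)
                hi = min(r + n - 1, query.end)
                if lo <= hi:
                    depth[lo - query.start:hi - query.start + 1] += 1
                r += n
            elif op in "DN":
                r += n
    return depth


def pileup(sc: SamChain, query: RegionQuery,
           reference: pysam.FastaFile) -> list[PileupColumn]:
    """Pileup columns for every region position with coverage.

    Positions covered by no read (and deleted in none) emit no column.
    Within a column, bases appear in stream publication order.
    """
    _validate(query, sc)
    width = query.end - query.start + 1
    columns: list[list[str]] = [[] for _ in range(width)]
    for read in _candidate_reads(sc, query):
        seq = refcodec.decode_sequence(_fetch_window(reference, read),
                                       read.cigar, read.modcigar)
        q, r = 0, read.pos
        for n, op in refcodec.parse_cigar(read.cigar):
            if op in refcodec.ALIGN_OPS:
                for i in range(n):
                    p = r + i
                    if query.start <= p <= query.end:
                        columns[p - query.start].append(seq[q + i])
                q += n
                r += n
            elif op == "D":
                for i in range(n):
                    p = r + i
                    if query.start <= p <= query.end:
                        columns[p - query.start].append(DELETION_MARKER)
                r += n
            elif op == "N":
                r += n
            elif op in "IS":
                q += n
    ref_seq = reference.fetch(query.chrom, query.start - 1,
                              query.end).upper()
    out = []
    for i, col in enumerate(columns):
        if not col:
            continue
        bases = "".join(col)
        depth = len(bases) - bases.count(DELETION_MARKER)
        out.append(PileupColumn(query.chrom, query.start + i,
                                ref_seq[i], depth, bases))
    return out


def build_bam(sc: SamChain, reference: pysam.FastaFile, out_path,
              min_mapq: Optional[int] = None) -> int:
    """Rebuild an alignment file from everything stored on-chain.

    Output carries the original header; every stored record appears exactly
    once with its sequence regenerated (unmapped records keep their
    verbatim stored sequence) and QUAL as the missing sentinel.  Records
    are coordinate-sorted with unmapped records last.  The format follows
    the output extension (``.bam`` binary, otherwise SAM text).  Returns
    the number of records written.
    """
    header_text = sc.header_text()
    header = pysam.AlignmentHeader.from_text(header_text)
    order = {name: i for i, name in enumerate(header.references)}

    mapped_recs: list[tuple[int, int, str]] = []
    for name in sc.binned_streams():
        for item in sc.chain.list_stream_items(name):
            read = StoredRead.from_payload(item.data)
            if min_mapq is not None and read.mapq < min_mapq:
                continue
            seq = refcodec.decode_sequence(_fetch_window(reference, read),
                                           read.cigar, read.modcigar)
            mapped_recs.append((order.get(read.rname, len(order)),
                                read.pos, read.to_sam_line(seq)))
    mapped_recs.sort(key=lambda t: (t[0], t[1]))

    unmapped_lines = [item.data.decode("utf-8")
                      for item in sc.chain.list_stream_items(UNMAPPED_STREAM)]

    mode = "wb" if str(out_path).endswith(".bam") else "w"
    count = 0
    with pysam.AlignmentFile(str(out_path), mode, header=header) as out:
        for _, _, line in mapped_recs:
            out.write(pysam.AlignedSegment.fromstring(line, header))
            count += 1
        for line in unmapped_lines:
            out.write(pysam.AlignedSegment.fromstring(line, header))
            count += 1
    return count
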