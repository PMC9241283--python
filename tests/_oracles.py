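"""Independent brute-force oracles for the on-chain analytics.

These deliberately avoid the package's own CIGAR walker: alignment
coordinates come from pysam's ``get_aligned_pairs`` on the *original* SAM
(sequences still present), and region queries are linear scans over every
record.  Results are compared against the chain-backed implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam


@dataclass(frozen=True)
class OracleRead:
    qname: str
    chrom: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    mapq: int
    seq: str
    pairs: tuple        # (qpos or None, rpos 1-based) aligned pairs


def load_oracle_reads(sam_path) -> list[OracleRead]:
    """All mapped records of a SAM with precomputed aligned pairs."""
    out = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            pairs = tuple((q, r + 1) for q, r in rec.get_aligned_pairs()
                          if r is not None)
            out.append(OracleRead(rec.query_name, rec.reference_name,
                                  rec.reference_start + 1, rec.reference_end,
                                  rec.mapping_quality,
                                  rec.query_sequence.upper(), pairs))
    return out


def _overlapping(reads, chrom, start, end, min_mapq):
    for r in reads:
        if r.chrom != chrom or r.start > end or r.end < start:
            continue
        if min_mapq is not None and r.mapq < min_mapq:
            continue
        yield r


def reads_in_region(reads, chrom, start, end, min_mapq=None):
    """Identity set of records overlapping a closed region."""
    return {(r.qname, r.start) for r in
            _overlapping(reads, chrom, start, end, min_mapq)}


def depth_in_region(reads, chrom, start, end, min_mapq=None) -> np.ndarray:
    """Per-base depth by counting aligned query bases from aligned pairs."""
    depth = np.zeros(end - start + 1, dtype=np.int64)
    for r in _overlapping(reads, chrom, start, end, min_mapq):
        for q, rpos in r.pairs:
            if q is not None and start <= rpos <= end:
                depth[rpos - start] += 1
    return depth


def pileup_in_region(reads, ref_fasta: pysam.FastaFile, chrom, start, end,
                     min_mapq=None):
    """``{pos: (ref_base, depth, sorted covering bases, n_deleted)}``.

    Aligned pairs with a query position contribute the read base; pairs
    without one are per-read deletions at that reference position.
    """
    cols: dict[int, list] = {}
    dels: dict[int, int] = {}
    for r in _overlapping(reads, chrom, start, end, min_mapq):
        for q, rpos in r.pairs:
            if not start <= rpos <= end:
                continue
            if q is None:
                dels[rpos] = dels.get(rpos, 0) + 1
                cols.setdefault(rpos, [])
            else:
                cols.setdefault(rpos, []).append(r.seq[q])
    ref = ref_fasta.fetch(chrom, start - 1, end).upper()
    return {pos: (ref[pos - start], len(bases), "".join(sorted(bases)),
                  dels.get(pos, 0))
            for pos, bases in cols.items()}
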