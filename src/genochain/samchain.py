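"""SAMchain: binned on-chain storage of reference-aligned reads.

A SAMchain is a chain-store laid out for genomic locality:

* ``metaData`` — chain settings and the SAM header, line by line;
* ``unmappedANDcontigs`` — unmapped reads and reads on contigs not covered
  by the chain configuration, stored with their sequence so they can be
  realigned later;
* one binned stream per fixed-length interval of every configured
  chromosome, named ``{chrom}stream{j}`` with ``j`` from 1.  A mapped read
  is filed in the bin containing its start coordinate; a ``FLANK`` key
  records whether its alignment spills into the next bin (``FLANK=1``) or
  not (``FLANK=0``), so region queries know to also scan the upstream bin.

Bin ``j`` covers the 1-based closed interval
``[(j-1)*bin_length + 1, j*bin_length]``.  The configured bin length must be
at least the declared maximum read length, which guarantees no read can span
more than two bins (FLANK is binary).

On-chain item payloads are tab-separated: the SAM mandatory fields QNAME
through TLEN (SEQ and QUAL removed), the serialized modcigar (``*`` when the
read equals the reference), then any optional tags verbatim.  Unmapped
records are stored as their original SAM line with QUAL replaced by ``*``
(quality strings are discarded chain-wide).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pysam

from . import refcodec
from .chainstore import Chain

__all__ = [
    "ChainConfig",
    "SamChain",
    "InsertionReport",
    "ChainStorageError",
    "n_bins",
    "bin_index",
    "bin_interval",
    "flank_of",
    "stream_name",
    "build_chain",
    "insert_data",
]

PAYLOAD_VERSION = 1
METADATA_STREAM = "metaData"
UNMAPPED_STREAM = "unmappedANDcontigs"
KEY_SETTINGS = "settings"
KEY_HEADER = "header"
KEY_FLANK0 = "FLANK=0"
KEY_FLANK1 = "FLANK=1"


class ChainStorageError(RuntimeError):
    """Raised when free storage drops below the configured minimum.

    The chain is sealed and a checkpoint persisted before raising, so the
    insertion can be resumed from ``resume_ordinal`` once space is freed.
    """

    def __init__(self, resume_ordinal: int, free: int, required: int):
        super().__init__(
            f"storage below minimum ({free} < {required} free bytes); "
            f"chain sealed, resume from record {resume_ordinal}")
        self.resume_ordinal = resume_ordinal


@dataclass(frozen=True)
class ChainConfig:
    """Chain layout settings, stored in the metaData stream.

    ``bin_length`` must be >= ``declared_read_length`` (the maximum
    reference span of any read), otherwise a read could span more than two
    bins and FLANK could not describe it.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_length: int
    declared_read_length: int
    reference_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.bin_length < 1 or self.declared_read_length < 1:
            raise ValueError("bin_length and declared_read_length must be >= 1")
        if self.bin_length < self.declared_read_length:
            raise ValueError(
                "bin_length must be >= declared_read_length so no read can "
                "span more than two bins")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has length {length}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def to_json(self) -> str:
        """Canonical serialization (stable across runs)."""
        return json.dumps({
            "chromosomes": [list(c) for c in self.chromosomes],
            "bin_length": self.bin_length,
            "declared_read_length": self.declared_read_length,
            "reference_id": self.reference_id,
            "payload_version": PAYLOAD_VERSION,
        }, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "ChainConfig":
        obj = json.loads(text)
        return cls(
            chromosomes=tuple((n, l) for n, l in obj["chromosomes"]),
            bin_length=obj["bin_length"],
            declared_read_length=obj["declared_read_length"],
            reference_id=obj["reference_id"])


def n_bins(chrom_length: int, bin_length: int) -> int:
    """Number of bins covering a chromosome (ceiling division).

    A chromosome of 248,956,422 bp at 1 Mbp bins needs 249 bins.
    """
    if chrom_length < 1 or bin_length < 1:
        raise ValueError("lengths must be >= 1")
    return -(-chrom_length // bin_length)


def bin_index(pos: int, bin_length: int) -> int:
    """1-based bin index of a 1-based reference position."""
    if pos < 1:
        raise ValueError("positions are 1-based")
    return (pos - 1) // bin_length + 1


def bin_interval(j: int, bin_length: int) -> tuple[int, int]:
    """1-based closed interval covered by bin ``j``."""
    return (j - 1) * bin_length + 1, j * bin_length


def flank_of(pos: int, cigar: str, bin_length: int) -> int:
    """1 if the alignment spills into the next bin, 0 if it fits in one.

    The reference end is ``pos + reference_span(cigar) - 1``.  A read whose
    end lands two or more bins downstream is unrepresentable (FLANK is
    binary) and raises ``ValueError``.
    """
    span = refcodec.cigar_reference_span(cigar)
    if span < 1:
        raise ValueError(f"CIGAR {cigar!r} consumes no reference")
    end = pos + span - 1
    delta = bin_index(end, bin_length) - bin_index(pos, bin_length)
    if delta > 1:
        raise ValueError(
            f"read at pos {pos} with CIGAR {cigar!r} spans {delta + 1} bins; "
            "increase bin_length")
    return delta


def stream_name(chrom: str, j: int) -> str:
    return f"{chrom}stream{j}"


@dataclass(frozen=True)
class InsertionReport:
    mapped: int = 0
    unmapped: int = 0
    flank1: int = 0
    header_lines: int = 0


@dataclass(frozen=True)
class StoredRead:
    """A parsed on-chain binned payload."""

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    modcigar: refcodec.ModCigar
    tags: tuple[str, ...]

    @property
    def reference_end(self) -> int:
        return self.pos + refcodec.cigar_reference_span(self.cigar) - 1

    def to_sam_line(self, seq: str) -> str:
        fields = [self.qname, str(self.flag), self.rname, str(self.pos),
                  str(self.mapq), self.cigar, self.rnext, str(self.pnext),
                  str(self.tlen), seq, "*", *self.tags]
        return "\t".join(fields)

    @classmethod
    def from_payload(cls, payload: bytes) -> "StoredRead":
        f = payload.decode("utf-8").split("\t")
        mod = refcodec.parse("" if f[9] == "*" else f[9])
        return cls(f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[5], f[6],
                   int(f[7]), int(f[8]), mod, tuple(f[10:]))


class SamChain:
    """Handle pairing a chain store with its SAMchain configuration."""

    def __init__(self, chain: Chain, config: ChainConfig):
        self.chain = chain
        self.config = config

    @classmethod
    def open(cls, chain: Chain) -> "SamChain":
        items = chain.list_stream_key_items(METADATA_STREAM, KEY_SETTINGS)
        if not items:
            raise ValueError("chain has no SAMchain settings in metaData")
        return cls(chain, ChainConfig.from_json(items[0].data.decode("utf-8")))

    def binned_streams(self, chrom: Optional[str] = None) -> list[str]:
        names = []
        for name, length in self.config.chromosomes:
            if chrom is not None and name != chrom:
                continue
            names.extend(stream_name(name, j)
                         for j in range(1, n_bins(length,
                                                  self.config.bin_length) + 1))
        return names

    def header_text(self) -> str:
        items = self.chain.list_stream_key_items(METADATA_STREAM, KEY_HEADER)
        return "".join(item.data.decode("utf-8") for item in items)


def build_chain(chain: Chain, config: ChainConfig,
                caller: Optional[str] = None) -> SamChain:
    """Create the SAMchain stream layout on a fresh chain.

    Creates ``metaData``, ``unmappedANDcontigs`` and one stream per bin of
    every configured chromosome, then publishes the canonical settings to
    ``metaData`` and seals the setup block.
    """
    chain.create_stream(METADATA_STREAM, caller)
    chain.create_stream(UNMAPPED_STREAM, caller)
    for name, length in config.chromosomes:
        for j in range(1, n_bins(length, config.bin_length) + 1):
            chain.create_stream(stream_name(name, j), caller)
    publisher = chain.owner if caller is None else caller
    chain.publish(METADATA_STREAM, publisher, (KEY_SETTINGS,),
                  config.to_json().encode("utf-8"))
    chain.mine_pending()
    return SamChain(chain, config)


def _checkpoint_path(chain: Chain) -> Path:
    return chain.path / "insert_checkpoint.json"


def _record_payload_and_stream(sc: SamChain, rec: pysam.AlignedSegment,
                               reference: pysam.FastaFile):
    """Route one SAM record; returns (stream, keys, payload, is_mapped, flank)."""
    fields = rec.to_string().split("\t")
    chroms = sc.config.chrom_lengths
    unmapped = rec.is_unmapped or rec.reference_name is None \
        or rec.reference_name not in chroms
    if unmapped:
        fields[10] = "*"  # qualities are discarded chain-wide
        payload = "\t".join(fields).encode("utf-8")
        return UNMAPPED_STREAM, (fields[0],), payload, False, 0

    pos = int(fields[3])
    cigar = refcodec.normalize_cigar(fields[5])
    span = refcodec.cigar_reference_span(cigar)
    ref_window = reference.fetch(rec.reference_name, pos - 1, pos - 1 + span)
    mod = refcodec.encode_modcigar(fields[9], cigar, ref_window)
    modtext = refcodec.serialize(mod) or "*"
    payload = "\t".join(fields[0:5] + [cigar] + fields[6:9]
                        + [modtext] + fields[11:]).encode("utf-8")
    flank = flank_of(pos, cigar, sc.config.bin_length)
    stream = stream_name(rec.reference_name,
                         bin_index(pos, sc.config.bin_length))
    key = KEY_FLANK1 if flank else KEY_FLANK0
    return stream, (key,), payload, True, flank


def insert_data(sc: SamChain, sam_path, reference_path,
                publisher: Optional[str] = None,
                resume: bool = False,
                min_free_bytes: int = 0,
                check_every: int = 1000,
                free_bytes_fn: Optional[Callable[[], int]] = None,
                ) -> InsertionReport:
    """Insert a SAM/BAM file into a built SAMchain.

    Header lines go line-by-line to ``metaData``; unmapped/contig records go
    to ``unmappedANDcontigs``; every other record is diff-encoded against
    the reference and published to the bin of its start position under its
    FLANK key.

    Free storage is checked every ``check_every`` records against
    ``min_free_bytes``; on breach the pending block is sealed, a checkpoint
    with the next record ordinal is persisted, and :class:`ChainStorageError`
    is raised.  Re-running with ``resume=True`` skips the records already
    on-chain, yielding a chain identical to an uninterrupted run.
    """
    chain = sc.chain
    publisher = chain.owner if publisher is None else publisher
    free_fn = chain.free_bytes if free_bytes_fn is None else free_bytes_fn

    start_ordinal = 0
    header_done = False
    ckpt = _checkpoint_path(chain)
    if resume and ckpt.exists():
        state = json.loads(ckpt.read_text())
        start_ordinal = state["next_ordinal"]
        header_done = state["header_done"]

    mapped = unmapped = flank1 = header_lines = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam, \
            pysam.FastaFile(str(reference_path)) as reference:
        if not header_done:
            for line in sam.text.splitlines(keepends=True):
                chain.publish(METADATA_STREAM, publisher, (KEY_HEADER,),
                              line.encode("utf-8"))
                header_lines += 1
            ckpt.write_text(json.dumps(
                {"next_ordinal": 0, "header_done": True}))

        for ordinal, rec in enumerate(sam.fetch(until_eof=True)):
            if ordinal < start_ordinal:
                continue
            if check_every and ordinal % check_every == 0:
                free = free_fn()
                if free < min_free_bytes:
                    chain.mine_pending()
                    ckpt.write_text(json.dumps(
                        {"next_ordinal": ordinal, "header_done": True}))
                    raise ChainStorageError(ordinal, free, min_free_bytes)
            stream, keys, payload, is_mapped, flank = \
                _record_payload_and_stream(sc, rec, reference)
            chain.publish(stream, publisher, keys, payload)
            if is_mapped:
                mapped += 1
                flank1 += flank
            else:
                unmapped += 1

    chain.mine_pending()
    if ckpt.exists():
        ckpt.unlink()
    return InsertionReport(mapped, unmapped, flank1, header_lines)
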