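"""VCFchain: on-chain storage and conjunctive querying of genetic variants.

A VCFchain has exactly two data streams: ``metaData`` (the VCF header,
line by line) and ``allVariantData`` (one item per variant data line).
Unlike SAMchain there is no positional binning — variants are point
positions, so the per-key index alone answers position queries.  Each item
carries three kinds of keys:

* ``POS:<chrom>:<pos>`` — always present;
* ``GT:<genotype>`` — the single sample's GT string, verbatim ("0/1" and
  "0|1" are distinct keys: phasing is preserved);
* ``ID:<rsid>`` — omitted when the ID column is ".".

The item payload is the original VCF data line, byte for byte, so the
input file is recoverable from the chain (up to data-line order).
Duplicate positions are permitted and all matches are returned.

Only single-sample VCFs are accepted (the use case is a personal genome);
multi-sample input is an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .chainstore import Chain

__all__ = [
    "VariantRecord",
    "VcfChain",
    "VcfInsertionReport",
    "build_vcf_chain",
    "insert_vcf",
    "query_and",
]

METADATA_STREAM = "metaData"
VARIANT_STREAM = "allVariantData"
KEY_HEADER = "header"


@dataclass(frozen=True)
class VariantRecord:
    """One VCF data line; ``line`` preserves the original bytes."""

    chrom: str
    pos: int
    rsid: str
    ref_allele: str
    alt_allele: str
    qual: str
    filter: str
    info: str
    genotype: str
    line: str

    @classmethod
    def from_line(cls, line: str) -> "VariantRecord":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 10:
            raise ValueError("VCF data line has fewer than 10 columns "
                             "(single-sample VCF required)")
        if len(fields) > 10:
            raise ValueError("multi-sample VCF not supported")
        fmt = fields[8].split(":")
        if "GT" not in fmt:
            raise ValueError("FORMAT lacks GT")
        gt = fields[9].split(":")[fmt.index("GT")]
        pos = int(fields[1])
        if pos < 1 or not fields[3]:
            raise ValueError("invalid POS or empty REF")
        return cls(fields[0], pos, fields[2], fields[3], fields[4],
                   fields[5], fields[6], fields[7], gt,
                   line.rstrip("\n"))

    def keys(self) -> tuple[str, ...]:
        keys = [f"POS:{self.chrom}:{self.pos}", f"GT:{self.genotype}"]
        if self.rsid != ".":
            keys.append(f"ID:{self.rsid}")
        return tuple(keys)


@dataclass(frozen=True)
class VcfInsertionReport:
    variants: int = 0
    header_lines: int = 0
    malformed: int = 0
    malformed_lines: tuple[int, ...] = ()


class VcfChain:
    def __init__(self, chain: Chain):
        self.chain = chain

    def header_text(self) -> str:
        items = self.chain.list_stream_key_items(METADATA_STREAM, KEY_HEADER)
        return "".join(item.data.decode("utf-8") for item in items)

    def variant_lines(self) -> list[str]:
        return [item.data.decode("utf-8")
                for item in self.chain.list_stream_items(VARIANT_STREAM)]


def build_vcf_chain(chain: Chain, caller: Optional[str] = None) -> VcfChain:
    """Create the two VCFchain streams on a fresh chain."""
    chain.create_stream(METADATA_STREAM, caller)
    chain.create_stream(VARIANT_STREAM, caller)
    chain.mine_pending()
    return VcfChain(chain)


def insert_vcf(vc: VcfChain, vcf_path,
               publisher: Optional[str] = None) -> VcfInsertionReport:
    """Insert a VCF file: header to metaData, each data line as one item.

    Malformed data lines are skipped (reported with their 1-based line
    numbers) and insertion continues.
    """
    chain = vc.chain
    publisher = chain.owner if publisher is None else publisher
    variants = header_lines = 0
    bad: list[int] = []
    with open(vcf_path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                chain.publish(METADATA_STREAM, publisher, (KEY_HEADER,),
                              line.encode("utf-8"))
                header_lines += 1
                continue
            if not line.strip():
                continue
            try:
                rec = VariantRecord.from_line(line)
            except ValueError:
                bad.append(lineno)
                continue
            chain.publish(VARIANT_STREAM, publisher, rec.keys(),
                          rec.line.encode("utf-8"))
            variants += 1
    chain.mine_pending()
    return VcfInsertionReport(variants, header_lines, len(bad), tuple(bad))


def query_and(vc: VcfChain, chrom: str, pos: int,
              genotype: Optional[str] = None,
              rsid: Optional[str] = None) -> list[VariantRecord]:
    """Variants at a position, AND-filtered by genotype and/or rsID.

    Retrieval uses the POS key index; the optional filters are applied
    conjunctively.  No match is an empty list, never an error.  Records
    come back in publication order and render as standard VCF data lines.
    """
    items = vc.chain.list_stream_key_items(VARIANT_STREAM,
                                           f"POS:{chrom}:{pos}")
    out = []
    for item in items:
        rec = VariantRecord.from_line(item.data.decode("utf-8"))
        if genotype is not None and rec.genotype != genotype:
            continue
        if rsid is not None and rec.rsid != rsid:
            continue
        out.append(rec)
    return out
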