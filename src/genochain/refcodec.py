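"""Reference-based read compression: the "modcigar" diff encoding.

Instead of storing a read's sequence (and quality string) on-chain, only the
bases that *differ* from the reference are kept, CRAM-style: mismatches,
insertions and soft-clipped bases.  Together with the read's CIGAR and the
reference genome this is enough to regenerate the original sequence exactly.
Quality strings are discarded irrecoverably at encode time; reconstruction
emits the SAM missing-quality sentinel (``*``).

Wire format
-----------
A modcigar is a ``;``-joined list of tokens ``<offset><op><bases>`` where
``offset`` is the 0-based query offset of the first base of the token,
``op`` is one of ``X`` (mismatch run), ``I`` (insertion) or ``S``
(soft-clip), and ``bases`` are the read bases over ``{A,C,G,T,N}``.  Offsets
are strictly increasing.  The empty string means the read equals the
reference over its whole alignment, e.g.::

    ""              read identical to reference
    "12XA"          single mismatch: query base 12 is A
    "12XA;45IACG"   plus a 3-bp insertion at query offset 45

Sequences are uppercased before comparison: case carries no information in
SAM, so a read base differing from the reference only by case is not a
mismatch; ``N`` versus a non-``N`` base is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "ModCigar",
    "encode_modcigar",
    "decode_sequence",
    "serialize",
    "parse",
    "parse_cigar",
    "cigar_reference_span",
    "cigar_query_length",
    "normalize_cigar",
    "ModCigarError",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_TOKEN_RE = re.compile(r"^(\d+)([XIS])([ACGTN]+)$")

#: CIGAR ops that consume the query sequence.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR ops that consume the reference.
REF_OPS = frozenset("MDN=X")
#: CIGAR ops that consume both (alignment matches).
ALIGN_OPS = frozenset("M=X")


class ModCigarError(ValueError):
    """Malformed modcigar or modcigar/CIGAR inconsistency."""


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Tokenize a CIGAR string into ``(length, op)`` pairs."""
    if cigar in ("", "*"):
        return []
    pos = 0
    out = []
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ModCigarError(f"malformed CIGAR {cigar!r}")
        out.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise ModCigarError(f"malformed CIGAR {cigar!r}")
    return out


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in QUERY_OPS)


def cigar_reference_span(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in REF_OPS)


def normalize_cigar(cigar: str) -> str:
    """Fold ``=``/``X`` alignment ops into ``M``, merging adjacent runs."""
    ops = parse_cigar(cigar)
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if op in "=X":
            op = "M"
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return "".join(f"{n}{op}" for n, op in merged) or "*"


@dataclass(frozen=True)
class ModCigar:
    """Ordered difference tokens between a read and the reference.

    Each token is ``(query_offset, op, bases)`` with strictly increasing
    0-based query offsets and ``op`` in ``{X, I, S}``.
    """

    tokens: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        last_end = 0
        for i, (off, op, bases) in enumerate(self.tokens):
            if op not in "XIS":
                raise ModCigarError(f"illegal op {op!r}")
            if not bases or set(bases) - set("ACGTN"):
                raise ModCigarError(f"illegal bases {bases!r}")
            if off < 0 or (i > 0 and off < last_end):
                raise ModCigarError("token offsets must be increasing")
            last_end = off + len(bases)

    def __bool__(self) -> bool:
        return bool(self.tokens)

    def __iter__(self) -> Iterator[tuple[int, str, str]]:
        return iter(self.tokens)


def serialize(modcigar: ModCigar) -> str:
    """Canonical string form; the empty modcigar renders as ``""``."""
    return ";".join(f"{off}{op}{bases}" for off, op, bases in modcigar.tokens)


def parse(text: str) -> ModCigar:
    """Inverse of :func:`serialize`; rejects any non-canonical rendering."""
    if text == "":
        return ModCigar()
    tokens = []
    for part in text.split(";"):
        m = _TOKEN_RE.match(part)
        if not m:
            raise ModCigarError(f"malformed modcigar token {part!r}")
        tokens.append((int(m.group(1)), m.group(2), m.group(3)))
    return ModCigar(tuple(tokens))


def encode_modcigar(seq: str, cigar: str, ref_window: str) -> ModCigar:
    """Encode ``seq`` as its difference from the reference.

    ``ref_window`` is the reference sequence starting at the read's mapped
    position and covering the CIGAR's full reference span.  The encoding is
    minimal: bases equal to the reference produce no token.

    Raises
    ------
    ModCigarError
        If ``seq`` does not match the CIGAR's query length or
        ``ref_window`` is shorter than the CIGAR's reference span.
    """
    ops = parse_cigar(cigar)
    seq_u = seq.upper()
    ref_u = ref_window.upper()
    if len(seq_u) != sum(n for n, op in ops if op in QUERY_OPS):
        raise ModCigarError(
            f"sequence length {len(seq)} does not match CIGAR {cigar!r}")
    if len(ref_u) < sum(n for n, op in ops if op in REF_OPS):
        raise ModCigarError("reference window shorter than CIGAR span")

    tokens: list[tuple[int, str, str]] = []
    q = r = 0
    for n, op in ops:
        if op in ALIGN_OPS:
            run_start = None
            for i in range(n):
                if seq_u[q + i] != ref_u[r + i]:
                    if run_start is None:
                        run_start = i
                elif run_start is not None:
                    tokens.append((q + run_start, "X",
                                   seq_u[q + run_start:q + i]))
                    run_start = None
            if run_start is not None:
                tokens.append((q + run_start, "X", seq_u[q + run_start:q + n]))
            q += n
            r += n
        elif op == "I":
            tokens.append((q, "I", seq_u[q:q + n]))
            q += n
        elif op == "S":
            tokens.append((q, "S", seq_u[q:q + n]))
            q += n
        elif op in "DN":
            r += n
        # H and P consume nothing
    return ModCigar(tuple(tokens))


def decode_sequence(ref_window: str, cigar: str, modcigar: ModCigar) -> str:
    """Regenerate a read's sequence from reference + CIGAR + modcigar.

    Inverse of :func:`encode_modcigar`: positions not covered by any token
    take the reference base walked by the CIGAR; every ``I``/``S`` CIGAR
    segment must be covered by exactly one matching token.
    """
    ops = parse_cigar(cigar)
    ref_u = ref_window.upper()
    if len(ref_u) < sum(n for n, op in ops if op in REF_OPS):
        raise ModCigarError("reference window shorter than CIGAR span")

    tokens = list(modcigar.tokens)
    ti = 0
    out: list[str] = []
    q = r = 0
    for n, op in ops:
        if op in ALIGN_OPS:
            seg = list(ref_u[r:r + n])
            while ti < len(tokens) and tokens[ti][0] < q + n:
                off, top, bases = tokens[ti]
                if top != "X" or off < q or off + len(bases) > q + n:
                    raise ModCigarError(
                        f"token {off}{top}{bases} inconsistent with CIGAR "
                        f"{cigar!r}")
                seg[off - q:off - q + len(bases)] = list(bases)
                ti += 1
            out.append("".join(seg))
            q += n
            r += n
        elif op in "IS":
            if ti >= len(tokens):
                raise ModCigarError(
                    f"missing modcigar bases for {n}{op} segment")
            off, top, bases = tokens[ti]
            if top != op or off != q or len(bases) != n:
                raise ModCigarError(
                    f"token {off}{top}{bases} inconsistent with {n}{op} "
                    f"segment at query offset {q}")
            out.append(bases)
            ti += 1
            q += n
        elif op in "DN":
            r += n
    if ti != len(tokens):
        raise ModCigarError("unconsumed modcigar tokens")
    return "".join(out)
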