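"""Deterministic synthetic fixtures: reference FASTA, aligned reads, VCF.

Everything downstream (chain building, diff encoding, queries, round
trips) is exercised on data produced here, with no external downloads.
The generator is a pure function of its parameters: the same
:class:`SimulationParams` yield byte-identical files on any platform.
Determinism comes from an integer-seeded counter-derived substream per
read/variant (``default_rng([seed, domain, counter])``), so outputs do not
depend on generation order.

This is a test-fixture generator, not a sequencing simulator: mutations
are applied per base independently, indel lengths are geometric (mean 2,
capped at a quarter of the read length), qualities are a constant
character, and there are no error-rate or coverage biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SimulationParams", "make_reference", "simulate_reads",
           "simulate_vcf"]

_BASES = np.array(list("ACGT"))
_QUAL_CHAR = "I"

# substream domains
_DOM_REF, _DOM_READ, _DOM_VCF = 0, 1, 2


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the fixture generator.

    Defaults emulate a small personal-genome slice: one 2-Mbp chromosome
    (the scale of a single disease locus), 10,000 150-bp reads at a 1%
    mismatch and 0.1% indel rate, and 1,000 variants with a 50:50
    het/hom-alt split.
    """

    seed: int = 1
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 2_000_000),)
    n_reads: int = 10_000
    read_length: int = 150
    mismatch_rate: float = 0.01
    insertion_rate: float = 0.001
    deletion_rate: float = 0.001
    softclip_rate: float = 0.01
    unmapped_fraction: float = 0.01
    n_variants: int = 1_000
    het_fraction: float = 0.5
    rsid_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mismatch_rate", "insertion_rate", "deletion_rate",
                     "softclip_rate", "unmapped_fraction", "het_fraction",
                     "rsid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_length < 1 or self.n_reads < 0 or self.n_variants < 0:
            raise ValueError("lengths and counts must be non-negative")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has length {length}")


def _rng(params: SimulationParams, domain: int, counter: int):
    return np.random.default_rng([params.seed, domain, counter])


def make_reference(params: SimulationParams, out_path) -> Path:
    """Write a FASTA with one uniform-random record per chromosome."""
    out_path = Path(out_path)
    with out_path.open("w") as fh:
        for i, (name, length) in enumerate(params.chromosomes):
            rng = _rng(params, _DOM_REF, i)
            seq = "".join(_BASES[rng.integers(0, 4, size=length)])
            fh.write(f">{name}\n")
            for off in range(0, length, 60):
                fh.write(seq[off:off + 60] + "\n")
    return out_path


def _load_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _geometric(rng, cap: int) -> int:
    """Geometric length with mean 2, capped (always >= 1)."""
    return int(min(rng.geometric(0.5), max(cap, 1)))


def _mutate_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _sim_one_read(params: SimulationParams, k: int, chroms, lengths,
                  cum_weights) -> str:
    rng = _rng(params, _DOM_READ, k)
    L = params.read_length
    indel_cap = max(L // 4, 1)

    # chromosome weighted by length, start leaving room for deletions
    u = rng.random()
    ci = int(np.searchsorted(cum_weights, u, side="right"))
    ci = min(ci, len(chroms) - 1)
    name, seq_len = chroms[ci]
    ref = lengths[name]
    max_start = seq_len - 2 * L + 1
    if max_start < 1:
        raise ValueError("read_length too large for shortest chromosome")
    start = int(rng.integers(1, max_start + 1))

    sc_lead = sc_tail = 0
    if rng.random() < params.softclip_rate / 2:
        sc_lead = _geometric(rng, indel_cap)
    if rng.random() < params.softclip_rate / 2:
        sc_tail = _geometric(rng, indel_cap)
    core = L - sc_lead - sc_tail
    if core < 1:
        sc_lead = sc_tail = 0
        core = L

    ops: list[tuple[int, str]] = []
    read: list[str] = []
    q = 0          # core query bases consumed
    r = start - 1  # 0-based reference cursor
    deleted = 0

    def push(n, op):
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + n, op)
        else:
            ops.append((n, op))

    while q < core:
        u = rng.random()
        if u < params.insertion_rate and 0 < q < core - 1:
            n = min(_geometric(rng, indel_cap), core - q - 1)
            read.extend(_BASES[rng.integers(0, 4, size=n)])
            push(n, "I")
            q += n
        elif (u < params.insertion_rate + params.deletion_rate
              and 0 < q and deleted < indel_cap):
            n = min(_geometric(rng, indel_cap), indel_cap - deleted)
            push(n, "D")
            r += n
            deleted += n
        else:
            base = ref[r]
            if rng.random() < params.mismatch_rate:
                base = _mutate_base(rng, base)
            read.append(base)
            push(1, "M")
            q += 1
            r += 1

    cigar_parts = []
    if sc_lead:
        cigar_parts.append(f"{sc_lead}S")
    cigar_parts.extend(f"{n}{op}" for n, op in ops)
    if sc_tail:
        cigar_parts.append(f"{sc_tail}S")
    lead = "".join(_BASES[rng.integers(0, 4, size=sc_lead)])
    tail = "".join(_BASES[rng.integers(0, 4, size=sc_tail)])
    seq = lead + "".join(read) + tail
    mapq = int(rng.integers(0, 61))
    return "\t".join([
        f"read{k:06d}", "0", name, str(start), str(mapq),
        "".join(cigar_parts), "*", "0", "0", seq, _QUAL_CHAR * len(seq),
        f"XC:i:{k}",
    ])


def simulate_reads(reference_path, params: SimulationParams, out_path) -> Path:
    """Write a SAM of simulated reads aligned to the reference.

    Exactly ``round(n_reads * unmapped_fraction)`` reads (the trailing
    ones) are emitted unmapped (FLAG 0x4, RNAME ``*``); every other read
    gets a uniform start, per-base mutations at the configured rates, a
    consistent CIGAR, and a constant quality string.
    """
    lengths = _load_fasta(reference_path)
    chroms = [(n, l) for n, l in params.chromosomes]
    for name, declared in chroms:
        if name not in lengths or len(lengths[name]) != declared:
            raise ValueError(f"reference does not match params for {name!r}")
    if params.read_length * 2 >= min(l for _, l in chroms):
        raise ValueError("read_length too large for shortest chromosome")

    total = sum(l for _, l in chroms)
    cum_weights = np.cumsum([l / total for _, l in chroms])
    n_unmapped = round(params.n_reads * params.unmapped_fraction)
    n_mapped = params.n_reads - n_unmapped

    out_path = Path(out_path)
    with out_path.open("w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, l in chroms:
            fh.write(f"@SQ\tSN:{name}\tLN:{l}\n")
        for k in range(n_mapped):
            fh.write(_sim_one_read(params, k, chroms, lengths, cum_weights)
                     + "\n")
        for k in range(n_mapped, params.n_reads):
            rng = _rng(params, _DOM_READ, k)
            seq = "".join(_BASES[rng.integers(0, 4, size=params.read_length)])
            fh.write("\t".join([
                f"read{k:06d}", "4", "*", "0", "0", "*", "*", "0", "0",
                seq, _QUAL_CHAR * len(seq), f"XC:i:{k}"]) + "\n")
    return out_path


def simulate_vcf(reference_path, params: SimulationParams, out_path) -> Path:
    """Write a single-sample VCF of SNPs, short indels and symbolic SVs.

    Positions are distinct; the type mix is 70% SNP, 20% indel, 10%
    symbolic deletion.  Genotypes are "0/1" with probability
    ``het_fraction``, else "1/1"; rsIDs ``rs<k>`` are assigned to
    ``rsid_fraction`` of the variants.
    """
    lengths = _load_fasta(reference_path)
    chroms = list(params.chromosomes)
    margin = 50
    slots = [(name, p) for name, l in chroms
             for p in range(margin, l - margin)]
    if params.n_variants > len(slots):
        raise ValueError("n_variants exceeds available positions")
    rng = _rng(params, _DOM_VCF, 0)
    picked = sorted(rng.choice(len(slots), size=params.n_variants,
                               replace=False))
    chrom_order = {name: i for i, (name, _) in enumerate(chroms)}
    sites = sorted((slots[i] for i in picked),
                   key=lambda t: (chrom_order[t[0]], t[1]))

    out_path = Path(out_path)
    with out_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description='
                 '"SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description='
                 '"SV end">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        for name, l in chroms:
            fh.write(f"##contig=<ID={name},length={l}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 "\tSAMPLE\n")
        for k, (name, pos) in enumerate(sites):
            vrng = _rng(params, _DOM_VCF, k + 1)
            ref = lengths[name]
            u = vrng.random()
            info = "."
            if u < 0.7:  # SNP
                ref_a = ref[pos - 1]
                alt_a = _mutate_base(vrng, ref_a)
            elif u < 0.8:  # short insertion
                n = int(vrng.integers(1, 6))
                ref_a = ref[pos - 1]
                alt_a = ref_a + "".join(_BASES[vrng.integers(0, 4, size=n)])
            elif u < 0.9:  # short deletion
                n = int(vrng.integers(1, 6))
                ref_a = ref[pos - 1:pos + n]
                alt_a = ref_a[0]
            else:  # symbolic structural deletion
                n = int(vrng.integers(50, 501))
                ref_a = ref[pos - 1]
                alt_a = "<DEL>"
                info = f"SVTYPE=DEL;END={pos + n}"
            gt = "0/1" if vrng.random() < params.het_fraction else "1/1"
            rsid = f"rs{k + 1}" if vrng.random() < params.rsid_fraction \
                else "."
            fh.write("\t".join([name, str(pos), rsid, ref_a, alt_a, "100",
                                "PASS", info, "GT", gt]) + "\n")
    return out_path
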