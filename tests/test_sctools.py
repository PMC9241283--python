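"""Region queries, depth, pileup and BAM rebuild against brute-force
oracles on the original SAM."""

import random

import numpy as np
import pysam
import pytest

import genochain as g
from genochain import sctools
from genochain.sctools import RegionQuery, streams_for

import _oracles
from conftest import SMALL, SMALL_CONFIG

CHROM = "chrA"
CHROM_LEN = dict(SMALL.chromosomes)[CHROM]
BIN = SMALL_CONFIG.bin_length


@pytest.fixture(scope="module")
def oracle_reads(fixture_dir):
    return _oracles.load_oracle_reads(fixture_dir / "reads.sam")


def _random_regions(n, seed):
    """Point and range queries, biased toward bin boundaries."""
    rng = random.Random(seed)
    regions = []
    for i in range(n):
        if i % 3 == 0:  # straddle a bin boundary
            j = rng.randint(1, CHROM_LEN // BIN - 1)
            start = max(1, j * BIN - rng.randint(0, 300))
            end = min(CHROM_LEN, j * BIN + rng.randint(0, 300))
        elif i % 3 == 1:  # point query
            start = end = rng.randint(1, CHROM_LEN)
        else:
            start = rng.randint(1, CHROM_LEN)
            end = min(CHROM_LEN, start + rng.randint(0, 5000))
        min_mapq = rng.choice([None, None, 20, 40])
        regions.append(RegionQuery(CHROM, start, end, min_mapq=min_mapq))
    return regions


class TestStreamsFor:
    def test_first_bin_has_no_upstream(self):
        assert streams_for(RegionQuery(CHROM, 1, 50), SMALL_CONFIG) == \
            [(CHROM, 1)]

    def test_upstream_bin_prepended(self):
        q = RegionQuery(CHROM, BIN + 100, BIN + 200)
        assert streams_for(q, SMALL_CONFIG) == [(CHROM, 1), (CHROM, 2)]

    def test_multi_bin_range(self):
        q = RegionQuery(CHROM, 2 * BIN + BIN // 2, 3 * BIN + BIN // 5)
        assert streams_for(q, SMALL_CONFIG) == \
            [(CHROM, 2), (CHROM, 3), (CHROM, 4)]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            streams_for(RegionQuery("chrZ", 1, 10), SMALL_CONFIG)


class TestQueryReads:
    def test_empty_region(self, populated_samchain, reference):
        sc, _ = populated_samchain
        # region past every simulated read start (reads leave a 2-read-length
        # margin at the chromosome end)
        q = RegionQuery(CHROM, CHROM_LEN - 10, CHROM_LEN)
        assert sctools.query_reads(sc, q, reference) == []

    def test_matches_linear_scan_oracle(self, populated_samchain, reference,
                                        oracle_reads):
        sc, _ = populated_samchain
        for q in _random_regions(100, seed=21):
            expected = _oracles.reads_in_region(oracle_reads, q.chrom,
                                                q.start, q.end, q.min_mapq)
            got = {(line.split("\t")[0], int(line.split("\t")[3]))
                   for line in sctools.query_reads(sc, q, reference)}
            assert got == expected

    def test_sequences_regenerated_exactly(self, populated_samchain,
                                           reference, oracle_reads):
        sc, _ = populated_samchain
        originals = {(r.qname, r.start): r.seq for r in oracle_reads}
        q = RegionQuery(CHROM, 1, 20_000)
        lines = sctools.query_reads(sc, q, reference)
        assert lines
        for line in lines:
            f = line.split("\t")
            assert f[9] == originals[(f[0], int(f[3]))]
            assert f[10] == "*"

    def test_flank_read_found_from_next_bin(self, tmp_path, reference,
                                            fixture_dir):
        """A read starting in bin j with FLANK=1 is returned for a query
        confined to bin j+1."""
        sam_text = ("@HD\tVN:1.6\n@SQ\tSN:chrA\tLN:300000\n"
                    "flank\t0\tchrA\t49951\t60\t100M\t*\t0\t0\t"
                    + "A" * 100 + "\t" + "I" * 100 + "\n")
        sam_path = tmp_path / "flank.sam"
        sam_path.write_text(sam_text)
        chain = g.Chain.create(tmp_path / "c")
        sc = g.build_chain(chain, SMALL_CONFIG)
        g.insert_data(sc, sam_path, fixture_dir / "ref.fa")
        items = chain.list_stream_key_items("chrAstream1", "FLANK=1")
        assert len(items) == 1
        lines = sctools.query_reads(
            sc, RegionQuery(CHROM, 50_010, 50_020), reference)
        assert [l.split("\t")[0] for l in lines] == ["flank"]


class TestQueryDepth:
    def test_single_read_block_depth(self, tmp_path, fixture_dir):
        sam_text = ("@HD\tVN:1.6\n@SQ\tSN:chrA\tLN:300000\n"
                    "r\t0\tchrA\t11\t60\t100M\t*\t0\t0\t"
                    + "A" * 100 + "\t" + "I" * 100 + "\n")
        (tmp_path / "one.sam").write_text(sam_text)
        chain = g.Chain.create(tmp_path / "c")
        sc = g.build_chain(chain, SMALL_CONFIG)
        g.insert_data(sc, tmp_path / "one.sam", fixture_dir / "ref.fa")
        depth = sctools.query_depth(sc, RegionQuery(CHROM, 1, 200))
        expected = np.zeros(200, dtype=int)
        expected[10:110] = 1
        assert (depth == expected).all()

    def test_deletion_contributes_zero(self, tmp_path, fixture_dir):
        """A 4M2D4M read covers 1-4 and 7-10 but not the deleted 5-6."""
        sam_text = ("@HD\tVN:1.6\n@SQ\tSN:chrA\tLN:300000\n"
                    "r\t0\tchrA\t1\t60\t4M2D4M\t*\t0\t0\t"
                    "ACGTACGT\tIIIIIIII\n")
        (tmp_path / "del.sam").write_text(sam_text)
        chain = g.Chain.create(tmp_path / "c")
        sc = g.build_chain(chain, SMALL_CONFIG)
        g.insert_data(sc, tmp_path / "del.sam", fixture_dir / "ref.fa")
        depth = sctools.query_depth(sc, RegionQuery(CHROM, 1, 10))
        assert depth.tolist() == [1, 1, 1, 1, 0, 0, 1, 1, 1, 1]

    def test_matches_counting_oracle(self, populated_samchain, oracle_reads):
        sc, _ = populated_samchain
        for q in _random_regions(100, seed=22):
            expected = _oracles.depth_in_region(oracle_reads, q.chrom,
                                                q.start, q.end, q.min_mapq)
            got = sctools.query_depth(sc, q)
            assert (got == expected).all()

    def test_mapq_filter_is_inclusive(self, populated_samchain,
                                      oracle_reads):
        sc, _ = populated_samchain
        q = RegionQuery(CHROM, 1, 50_000, min_mapq=30)
        expected = _oracles.depth_in_region(oracle_reads, CHROM, 1, 50_000,
                                            min_mapq=30)
        assert (sctools.query_depth(sc, q) == expected).all()

    def test_total_depth_equals_aligned_bases(self, populated_samchain):
        """Sum of depth over the chromosome equals the sum of M lengths of
        every stored read (consistency invariant)."""
        sc, _ = populated_samchain
        total = sctools.query_depth(
            sc, RegionQuery(CHROM, 1, CHROM_LEN)).sum()
        from genochain import refcodec, samchain
        aligned = 0
        for name in sc.binned_streams():
            for item in sc.chain.list_stream_items(name):
                read = samchain.StoredRead.from_payload(item.data)
                aligned += sum(n for n, op in refcodec.parse_cigar(read.cigar)
                               if op in refcodec.ALIGN_OPS)
        assert total == aligned


class TestPileup:
    def test_snp_column_shows_both_alleles(self, tmp_path, fixture_dir,
                                           reference):
        ref_base = reference.fetch(CHROM, 99, 100).upper()
        alt = "A" if ref_base != "A" else "C"
        window = reference.fetch(CHROM, 90, 110).upper()
        snp_seq = window[:9] + alt + window[10:]
        sam_text = ("@HD\tVN:1.6\n@SQ\tSN:chrA\tLN:300000\n"
                    f"ref\t0\tchrA\t91\t60\t20M\t*\t0\t0\t{window}\t"
                    + "I" * 20 + "\n"
                    f"snp\t0\tchrA\t91\t60\t20M\t*\t0\t0\t{snp_seq}\t"
                    + "I" * 20 + "\n")
        (tmp_path / "snp.sam").write_text(sam_text)
        chain = g.Chain.create(tmp_path / "c")
        sc = g.build_chain(chain, SMALL_CONFIG)
        g.insert_data(sc, tmp_path / "snp.sam", fixture_dir / "ref.fa")
        cols = sctools.pileup(sc, RegionQuery(CHROM, 100, 100), reference)
        assert len(cols) == 1
        col = cols[0]
        assert col.depth == 2
        assert col.ref_base == ref_base
        assert sorted(col.bases) == sorted(ref_base + alt)

    def test_zero_coverage_emits_no_column(self, populated_samchain,
                                           reference):
        sc, _ = populated_samchain
        cols = sctools.pileup(
            sc, RegionQuery(CHROM, CHROM_LEN - 5, CHROM_LEN), reference)
        assert cols == []

    def test_matches_pileup_oracle(self, populated_samchain, reference,
                                   oracle_reads):
        sc, _ = populated_samchain
        for q in _random_regions(60, seed=23):
            expected = _oracles.pileup_in_region(
                oracle_reads, reference, q.chrom, q.start, q.end, q.min_mapq)
            got = {c.pos: (c.ref_base,
                           c.depth,
                           "".join(sorted(c.bases.replace(
                               sctools.DELETION_MARKER, ""))),
                           c.bases.count(sctools.DELETION_MARKER))
                   for c in sctools.pileup(sc, q, reference)}
            assert got == expected


class TestLocality:
    def test_query_touches_only_resolved_streams(self, populated_samchain,
                                                 reference):
        """A region query reads exactly the streams streams_for names."""
        sc, _ = populated_samchain
        q = RegionQuery(CHROM, 2 * BIN + 10, 2 * BIN + 500)
        expected = {f"{c}stream{j}" for c, j in streams_for(q, sc.config)}
        sc.chain.read_log.clear()
        sctools.query_reads(sc, q, reference)
        assert set(sc.chain.read_log) == expected


class TestBuildBam:
    def test_round_trip_lossless_except_qual(self, populated_samchain,
                                             reference, fixture_dir,
                                             tmp_path):
        """Rebuilt BAM matches the input SAM on every field but QUAL."""
        sc, _ = populated_samchain
        out = tmp_path / "rebuilt.bam"
        n = sctools.build_bam(sc, reference, out)
        assert n == SMALL.n_reads

        def snapshot(path):
            recs = {}
            with pysam.AlignmentFile(str(path), check_sq=False) as fh:
                for rec in fh.fetch(until_eof=True):
                    f = rec.to_string().split("\t")
                    f[5] = f[5].replace("=", "M").replace("X", "M")
                    f[10] = "*"  # QUAL excluded from the comparison
                    recs[f[0]] = f
            return recs

        assert snapshot(out) == snapshot(fixture_dir / "reads.sam")

    def test_header_byte_identical(self, populated_samchain, reference,
                                   fixture_dir, tmp_path):
        sc, _ = populated_samchain
        out = tmp_path / "rebuilt.sam"
        sctools.build_bam(sc, reference, out)
        with pysam.AlignmentFile(str(fixture_dir / "reads.sam"),
                                 check_sq=False) as orig, \
                pysam.AlignmentFile(str(out), check_sq=False) as rebuilt:
            assert rebuilt.text == orig.text

    def test_coordinate_sorted_mapped_then_unmapped(self, populated_samchain,
                                                    reference, tmp_path):
        sc, _ = populated_samchain
        out = tmp_path / "rebuilt.bam"
        sctools.build_bam(sc, reference, out)
        positions = []
        seen_unmapped = False
        with pysam.AlignmentFile(str(out)) as fh:
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped:
                    seen_unmapped = True
                else:
                    assert not seen_unmapped  # unmapped strictly last
                    positions.append(rec.reference_start)
        assert positions == sorted(positions)
        assert seen_unmapped
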