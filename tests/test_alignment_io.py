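"""Alignment access, junction extraction, coverage and BAM splitting."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from scapa.alignment_io import (
    AlignmentRecord,
    build_gene_coverage,
    export_coverage,
    extract_junctions,
    read_alignments,
    split_bam_by_population,
)

CHROM_LEN = 100_000


def _write_bam(path, reads):
    """reads: list of (qname, pos0, cigar, cb, ub, flag)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": CHROM_LEN}]}
    reads = sorted(reads, key=lambda r: r[1])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for qname, pos0, cigar, cb, ub, flag in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.reference_name = "chr1"
            a.reference_start = pos0
            a.flag = flag
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = "A" * a.infer_query_length()
            if cb is not None:
                a.set_tag("CB", cb)
            if ub is not None:
                a.set_tag("UB", ub)
            bam.write(a)
    pysam.index(str(path))
    return path


def test_empty_bam_yields_no_records(tmp_path):
    bam = _write_bam(tmp_path / "empty.bam", [])
    assert list(read_alignments(bam)) == []


def test_whitelist_filters_and_optional_umi(tmp_path):
    reads = [
        ("r1", 100, "91M", "BC1", "U1", 0),
        ("r2", 200, "91M", "BC1", "U2", 0),
        ("r3", 300, "91M", "BC2", "U3", 0),
        ("r4", 400, "91M", "BC3", "U4", 0),  # not whitelisted
        ("r5", 500, "91M", None, None, 0),  # no barcode
    ]
    bam = _write_bam(tmp_path / "wl.bam", reads)
    got = list(read_alignments(bam, whitelist={"BC1", "BC2"}))
    assert len(got) == 3
    # whitelist off: all 5, UMI absent is preserved as None
    all_recs = list(read_alignments(bam))
    assert len(all_recs) == 5
    assert all_recs[-1].umi is None and all_recs[-1].cell_barcode is None


def test_missing_index_is_an_error(tmp_path):
    bam = _write_bam(tmp_path / "x.bam", [("r", 10, "10M", None, None, 0)])
    (tmp_path / "x.bam.bai").unlink()
    with pytest.raises(FileNotFoundError):
        list(read_alignments(bam, region=("chr1", 1, 1000)))


def test_spliced_cigar_blocks_and_junction_span():
    # read starting at 1-based 1001 with 50M100N50M: matches cover
    # 1001-1050 and 1151-1250, intron span 1051-1150
    rec = AlignmentRecord(
        chrom="chr1", blocks=[(1001, 1050), (1151, 1250)], strand="+",
        skips=[(1051, 1150)],
    )
    juncs = extract_junctions([rec])
    assert len(juncs) == 1
    assert (juncs[0].intron_start, juncs[0].intron_end) == (1051, 1150)
    assert juncs[0].support == 1


def test_spliced_bam_parsing_matches_block_arithmetic(tmp_path):
    bam = _write_bam(tmp_path / "sp.bam", [("r", 1000, "50M100N50M", "B", "U", 0)])
    (rec,) = read_alignments(bam)
    assert rec.blocks == [(1001, 1050), (1151, 1200)]
    assert rec.skips == [(1051, 1150)]


def test_junction_support_counts_reads_and_is_order_invariant():
    recs = [
        AlignmentRecord("chr1", [(1001, 1050), (1151, 1250)], "+", skips=[(1051, 1150)])
        for _ in range(60)
    ]
    assert extract_junctions(recs)[0].support == 60
    rev = extract_junctions(list(reversed(recs)))
    assert rev[0].support == 60


def test_no_skip_means_no_junction_and_short_overhang_is_dropped():
    plain = AlignmentRecord("chr1", [(1001, 1100)], "+")
    assert extract_junctions([plain]) == []
    short = AlignmentRecord(
        "chr1", [(1048, 1050), (1151, 1250)], "+", skips=[(1051, 1150)]
    )
    assert extract_junctions([short], min_overhang=5) == []


def test_coverage_direct_construction_and_skips():
    span = ("chr1", 1001, 1400)
    assert build_gene_coverage([], span).values.sum() == 0
    one = AlignmentRecord("chr1", [(1101, 1200)], "+")
    track = build_gene_coverage([one], span)
    assert track.values.sum() == 100
    assert (track.values[100:200] == 1).all()
    spliced = AlignmentRecord(
        "chr1", [(1001, 1050), (1151, 1200)], "+", skips=[(1051, 1150)]
    )
    track = build_gene_coverage([spliced], span)
    assert (track.values[0:50] == 1).all()
    assert (track.values[50:150] == 0).all()
    assert (track.values[150:200] == 1).all()


def test_coverage_additivity_over_reads():
    rng = np.random.default_rng(0)
    span = ("chr1", 1, 2000)
    reads = [
        AlignmentRecord("chr1", [(int(s), int(s) + 90)], "+")
        for s in rng.integers(1, 1900, size=40)
    ]
    total = build_gene_coverage(reads, span).values
    summed = sum(build_gene_coverage([r], span).values for r in reads)
    assert (total == summed).all()


def test_split_bam_partitions_reads(tmp_path):
    reads = [(f"r{i}", 100 * i + 10, "91M", f"BC{i % 5}", f"U{i}", 0) for i in range(10)]
    bam = _write_bam(tmp_path / "pop.bam", reads)
    pmap = {"BC0": "A", "BC1": "A", "BC2": "A", "BC3": "A", "BC4": "B"}
    outs = split_bam_by_population(bam, pmap, tmp_path / "split")
    counts = {}
    for label, path in outs.items():
        with pysam.AlignmentFile(str(path)) as fh:
            counts[label] = sum(1 for _ in fh.fetch(until_eof=True))
    assert counts == {"A": 8, "B": 2}
    assert sum(counts.values()) == 10  # conservation


def test_split_bam_empty_population_is_indexed_and_empty(tmp_path):
    bam = _write_bam(tmp_path / "p2.bam", [("r0", 10, "91M", "BC0", "U", 0)])
    outs = split_bam_by_population(bam, {"BC0": "A", "BCX": "B"}, tmp_path / "s2")
    with pysam.AlignmentFile(str(outs["B"])) as fh:
        assert sum(1 for _ in fh.fetch(until_eof=True)) == 0
    assert outs["B"].with_suffix(".bam.bai").exists()


def test_export_coverage_bins_and_identity(tmp_path):
    # uniform coverage 3 over 1001-1090
    reads = [(f"r{i}", 1000, "90M", "B", f"U{i}", 0) for i in range(3)]
    bam = _write_bam(tmp_path / "cov.bam", reads)
    out = export_coverage(bam, ("chr1", 1001, 1090), 10, tmp_path / "c.bedGraph")
    lines = [ln.split("\t") for ln in out.read_text().splitlines()]
    assert len(lines) == 9
    assert all(float(v) == 3.0 for *_, v in lines)
    assert lines[0][1] == "1000" and lines[0][2] == "1010"  # 0-based half-open
    # binsize 1 reproduces the raw track
    out1 = export_coverage(bam, ("chr1", 1001, 1090), 1, tmp_path / "c1.bedGraph")
    vals = [float(ln.split("\t")[3]) for ln in out1.read_text().splitlines()]
    assert vals == [3.0] * 90
    with pytest.raises(ValueError):
        export_coverage(bam, ("chr1", 1001, 1090), 0, tmp_path / "bad.bedGraph")


def test_export_coverage_sparse_omits_zero_bins(tmp_path):
    bam = _write_bam(tmp_path / "z.bam", [("r", 1000, "10M", "B", "U", 0)])
    sparse = export_coverage(bam, ("chr1", 1, 2000), 100, tmp_path / "s.bedGraph")
    dense = export_coverage(bam, ("chr1", 1, 2000), 100, tmp_path / "d.bedGraph", dense=True)
    assert len(sparse.read_text().splitlines()) == 1
    assert len(dense.read_text().splitlines()) == 20


def test_junction_bed_bed12_and_bed6(tmp_path):
    # regtools-style BED12: anchors 50+50 around a 100-bp intron at
    # 0-based [1000, 1250); intron 1-based [1051, 1150]
    bed = tmp_path / "j.bed"
    bed.write_text(
        "chr1\t1000\t1200\tJUNC1\t60\t+\t1000\t1200\t0,0,0\t2\t50,50\t0,150\n"
        "chr2\t5000\t5400\tJUNC2\t10\t-\n"
    )
    from scapa.alignment_io import read_junction_bed

    j12, j6 = read_junction_bed(bed)
    assert (j12.chrom, j12.intron_start, j12.intron_end, j12.support) == (
        "chr1", 1051, 1150, 60,
    )
    assert (j6.chrom, j6.intron_start, j6.intron_end, j6.support) == (
        "chr2", 5001, 5400, 10,
    )
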