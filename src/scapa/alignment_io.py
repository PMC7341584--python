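"""Tagged-alignment access, junction extraction, coverage tracks and BAM splitting.

Internal coordinates are 1-based inclusive; bedGraph output is emitted
0-based half-open. Cell barcode / UMI tags default to the CellRanger
error-corrected tags (CB/UB) with the raw tags (CR/UR) as a configurable
fallback.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(slots=True)
class AlignmentRecord:
    """One aligned read reduced to its genomic footprint and cell identity.

    blocks are the aligned reference segments (CIGAR M/=/X with D merged),
    skips the intronic N gaps between consecutive blocks; both 1-based
    inclusive and sorted.
    """

    chrom: str
    blocks: list[Interval]
    strand: str
    cell_barcode: str | None = None
    umi: str | None = None
    skips: list[Interval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass(slots=True)
class Junction:
    chrom: str
    intron_start: int  # first intronic base, 1-based
    intron_end: int  # last intronic base, 1-based
    strand: str
    support: int = 1


@dataclass(slots=True)
class CoverageTrack:
    chrom: str
    origin: int  # genomic position (1-based) of values[0]
    values: np.ndarray
    strand: str


# CIGAR op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ===7 X=8
_REF_CONSUME_BLOCK = {0, 2, 7, 8}


def _parse_blocks(read: pysam.AlignedSegment) -> tuple[list[Interval], list[Interval]]:
    blocks: list[Interval] = []
    skips: list[Interval] = []
    pos = read.reference_start + 1  # to 1-based
    cur_start = None
    for op, length in read.cigartuples:
        if op in _REF_CONSUME_BLOCK:
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == 3:  # N: close block, record skip
            if cur_start is not None:
                blocks.append((cur_start, pos - 1))
                cur_start = None
            skips.append((pos, pos + length - 1))
            pos += length
        # I/S/H/P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, pos - 1))
    return blocks, skips


def read_alignments(
    bam_path: str | os.PathLike,
    region: tuple[str, int, int] | None = None,
    whitelist: set[str] | None = None,
    cb_tag: str = "CB",
    umi_tag: str = "UB",
    include_flagged: bool = False,
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from an indexed BAM.

    region is (chrom, start, end) 1-based inclusive, or None for the whole
    file. With a whitelist, reads lacking a barcode or carrying a
    non-whitelisted one are dropped (counts logged). Secondary,
    supplementary and duplicate-flagged reads are skipped unless
    include_flagged is set.
    """
    bam_path = str(bam_path)
    if region is not None and not (
        os.path.exists(bam_path + ".bai") or os.path.exists(bam_path[:-4] + ".bai")
        or os.path.exists(bam_path + ".csi")
    ):
        raise FileNotFoundError(f"BAM index not found for {bam_path}")
    dropped = 0
    malformed = 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if region is None:
            it: Iterable[pysam.AlignedSegment] = bam.fetch(until_eof=True)
        else:
            chrom, start, end = region
            it = bam.fetch(chrom, start - 1, end)
        for read in it:
            if read.is_unmapped or read.cigartuples is None:
                continue
            if not include_flagged and (
                read.is_secondary or read.is_supplementary or read.is_duplicate
            ):
                continue
            cb = read.get_tag(cb_tag) if read.has_tag(cb_tag) else None
            if whitelist is not None and (cb is None or cb not in whitelist):
                dropped += 1
                continue
            try:
                blocks, skips = _parse_blocks(read)
            except (ValueError, TypeError):
                malformed += 1
                continue
            if not blocks:
                malformed += 1
                continue
            umi = read.get_tag(umi_tag) if read.has_tag(umi_tag) else None
            yield AlignmentRecord(
                chrom=read.reference_name,
                blocks=blocks,
                strand="-" if read.is_reverse else "+",
                cell_barcode=cb,
                umi=umi,
                skips=skips,
            )
    if dropped:
        log.info("read_alignments: dropped %d non-whitelisted reads", dropped)
    if malformed:
        log.warning("read_alignments: skipped %d malformed records", malformed)


def extract_junctions(
    records: Iterable[AlignmentRecord], min_overhang: int = 5
) -> list[Junction]:
    """Collapse CIGAR N gaps into supported junctions.

    A read supports a junction only when its aligned blocks flanking the
    gap both span at least min_overhang bases.
    """
    support: dict[tuple[str, int, int], list] = {}
    for rec in records:
        if not rec.skips:
            continue
        for i, (ss, se) in enumerate(rec.skips):
            left = rec.blocks[i]
            right = rec.blocks[i + 1]
            if (left[1] - left[0] + 1) < min_overhang:
                continue
            if (right[1] - right[0] + 1) < min_overhang:
                continue
            key = (rec.chrom, ss, se)
            entry = support.setdefault(key, [rec.strand, 0])
            entry[1] += 1
    out = [
        Junction(chrom=k[0], intron_start=k[1], intron_end=k[2], strand=v[0], support=v[1])
        for k, v in support.items()
    ]
    out.sort(key=lambda j: (j.chrom, j.intron_start, j.intron_end))
    return out


def read_junction_bed(path: str | os.PathLike) -> list[Junction]:
    """Parse junctions from a BED file (regtools-style BED12 or plain BED6).

    In BED12, the two blocks are the exonic anchors and the junction is
    the gap between them; the score column carries the supporting read
    count. Plain BED6 lines are taken as the intronic span directly.
    Output coordinates are 1-based inclusive intronic spans.
    """
    out: list[Junction] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            score = int(float(fields[4])) if len(fields) > 4 and fields[4] != "." else 1
            strand = fields[5] if len(fields) > 5 else "+"
            if len(fields) >= 12:
                sizes = [int(s) for s in fields[10].rstrip(",").split(",")]
                if len(sizes) != 2:
                    log.warning("skipping BED12 line with %d blocks", len(sizes))
                    continue
                intron_start = start0 + sizes[0] + 1  # to 1-based intronic
                intron_end = end0 - sizes[1]
            else:
                intron_start = start0 + 1
                intron_end = end0
            out.append(
                Junction(
                    chrom=chrom,
                    intron_start=intron_start,
                    intron_end=intron_end,
                    strand=strand,
                    support=max(score, 1),
                )
            )
    out.sort(key=lambda j: (j.chrom, j.intron_start, j.intron_end))
    return out


def build_gene_coverage(
    records: Iterable[AlignmentRecord],
    gene_span: tuple[str, int, int],
    strand: str = "+",
) -> CoverageTrack:
    """Per-base read coverage over a gene span; N gaps contribute nothing."""
    chrom, start, end = gene_span
    values = np.zeros(end - start + 1, dtype=np.int64)
    n = len(values)
    for rec in records:
        if rec.chrom != chrom:
            continue
        for bs, be in rec.blocks:
            lo = max(bs - start, 0)
            hi = min(be - start + 1, n)
            if lo < hi:
                values[lo:hi] += 1
    return CoverageTrack(chrom=chrom, origin=start, values=values, strand=strand)


def split_bam_by_population(
    bam_path: str | os.PathLike,
    population_map: dict[str, str],
    out_dir: str | os.PathLike,
    cb_tag: str = "CB",
) -> dict[str, Path]:
    """Write one indexed BAM per population label (SplitBam-style).

    population_map maps cell barcode -> label. Reads whose barcode is
    absent from the map are dropped. Returns label -> output path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = sorted(set(population_map.values()))
    outs: dict[str, Path] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        writers = {}
        counts = dict.fromkeys(labels, 0)
        for label in labels:
            path = out_dir / f"{label}.bam"
            writers[label] = pysam.AlignmentFile(str(path), "wb", template=bam)
            outs[label] = path
        for read in bam.fetch(until_eof=True):
            if not read.has_tag(cb_tag):
                continue
            label = population_map.get(read.get_tag(cb_tag))
            if label is None:
                continue
            writers[label].write(read)
            counts[label] += 1
        for label, w in writers.items():
            w.close()
            pysam.index(str(outs[label]))
            if counts[label] == 0:
                log.warning("population %r received no reads", label)
    return outs


def export_coverage(
    bam_path: str | os.PathLike,
    region: tuple[str, int, int],
    binsize: int,
    out_path: str | os.PathLike,
    dense: bool = False,
    **read_kwargs,
) -> Path:
    """Export per-bin mean coverage of a region as bedGraph.

    Zero bins are omitted in the default sparse dialect; dense=True writes
    every bin. bedGraph intervals are 0-based half-open.
    """
    if binsize < 1:
        raise ValueError(f"binsize must be >= 1, got {binsize}")
    chrom, start, end = region
    track = build_gene_coverage(
        read_alignments(bam_path, region=region, **read_kwargs), region
    )
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        n = len(track.values)
        for lo in range(0, n, binsize):
            hi = min(lo + binsize, n)
            mean = float(track.values[lo:hi].mean())
            if mean == 0.0 and not dense:
                continue
            g0 = start - 1 + lo  # 0-based
            g1 = start - 1 + hi
            fh.write(f"{chrom}\t{g0}\t{g1}\t{mean:g}\n")
    return out_path
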