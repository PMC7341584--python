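"""UMI counting of alignments against merged peak coordinates.

Produces the sparse peak x cell matrix. The UMI collapse key is
(cell barcode, UMI, gene): each distinct molecule is counted once per
peak it overlaps, where overlap requires an aligned block (not a spliced
gap) to intersect the peak interval by at least one base.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .alignment_io import AlignmentRecord, read_alignments
from .gene_models import GeneModel
from .peak_merging import MergedPeak


@dataclass
class PeakCountMatrix:
    counts: sp.csr_matrix  # peaks x cells
    peak_ids: list[str]
    barcodes: list[str]

    def __post_init__(self):
        if self.counts.shape != (len(self.peak_ids), len(self.barcodes)):
            raise ValueError("matrix dimensions do not match id lists")

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


def _count_gene(
    records: Iterable[AlignmentRecord],
    peaks: Sequence[MergedPeak],
    gene_id: str,
    strict_strand: bool,
    molecules: set,
) -> None:
    for rec in records:
        if rec.cell_barcode is None or rec.umi is None:
            continue
        for idx, peak in enumerate(peaks):
            if strict_strand and rec.strand != peak.strand:
                continue
            hit = any(bs <= peak.end and be >= peak.start for bs, be in rec.blocks)
            if hit:
                molecules.add((rec.cell_barcode, rec.umi, gene_id, peak.peak_id))


def count_umis_from_records(
    records_by_gene: dict[str, Sequence[AlignmentRecord]],
    merged_peaks: Sequence[MergedPeak],
    whitelist: set[str],
    strict_strand: bool = False,
) -> PeakCountMatrix:
    """Count distinct molecules per peak per cell from in-memory records.

    records_by_gene maps gene_id to the alignments overlapping that gene
    (already whitelist-filtered or not; non-whitelisted barcodes are
    dropped here regardless).
    """
    if not merged_peaks:
        raise ValueError("no peaks to count against")
    if not whitelist:
        raise ValueError("empty barcode whitelist")
    peaks_by_gene: dict[str, list[MergedPeak]] = {}
    for p in merged_peaks:
        peaks_by_gene.setdefault(p.gene_id, []).append(p)

    molecules: set = set()
    for gene_id, peaks in peaks_by_gene.items():
        recs = [
            r
            for r in records_by_gene.get(gene_id, ())
            if r.cell_barcode in whitelist
        ]
        _count_gene(recs, peaks, gene_id, strict_strand, molecules)
    return _molecules_to_matrix(molecules, merged_peaks, whitelist)


def _molecules_to_matrix(
    molecules: set, merged_peaks: Sequence[MergedPeak], whitelist: set[str]
) -> PeakCountMatrix:
    peak_ids = [p.peak_id for p in merged_peaks]
    barcodes = sorted(whitelist)
    p_index = {pid: i for i, pid in enumerate(peak_ids)}
    b_index = {bc: i for i, bc in enumerate(barcodes)}
    rows, cols = [], []
    for cb, _umi, _gene, pid in molecules:
        rows.append(p_index[pid])
        cols.append(b_index[cb])
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(peak_ids), len(barcodes)),
    ).tocsr()
    return PeakCountMatrix(counts=counts, peak_ids=peak_ids, barcodes=barcodes)


def count_umis(
    bam_path: str | os.PathLike,
    merged_peaks: Sequence[MergedPeak],
    gene_models: dict[str, GeneModel],
    whitelist: set[str],
    strict_strand: bool = False,
    cb_tag: str = "CB",
    umi_tag: str = "UB",
) -> PeakCountMatrix:
    """Count UMIs per peak per cell by fetching alignments gene by gene."""
    if not merged_peaks:
        raise ValueError("no peaks to count against")
    if not whitelist:
        raise ValueError("empty barcode whitelist")
    peaks_by_gene: dict[str, list[MergedPeak]] = {}
    for p in merged_peaks:
        peaks_by_gene.setdefault(p.gene_id, []).append(p)
    molecules: set = set()
    for gene_id, peaks in peaks_by_gene.items():
        gene = gene_models.get(gene_id)
        if gene is None:
            continue
        recs = read_alignments(
            bam_path,
            region=(gene.chrom, gene.start, gene.end),
            whitelist=whitelist,
            cb_tag=cb_tag,
            umi_tag=umi_tag,
        )
        _count_gene(recs, peaks, gene_id, strict_strand, molecules)
    return _molecules_to_matrix(molecules, merged_peaks, whitelist)


def write_count_matrix(matrix: PeakCountMatrix, out_dir: str | os.PathLike) -> Path:
    """Write MatrixMarket triplet layout: matrix.mtx + peaks.tsv + barcodes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), matrix.counts.tocoo(), field="integer")
    pd.Series(matrix.peak_ids).to_csv(out_dir / "peaks.tsv", index=False, header=False)
    pd.Series(matrix.barcodes).to_csv(out_dir / "barcodes.tsv", index=False, header=False)
    return out_dir


def read_count_matrix(in_dir: str | os.PathLike) -> PeakCountMatrix:
    in_dir = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(str(in_dir / "matrix.mtx")), dtype=np.int64)
    peak_ids = pd.read_csv(in_dir / "peaks.tsv", header=None)[0].tolist()
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", header=None)[0].tolist()
    return PeakCountMatrix(counts=counts, peak_ids=peak_ids, barcodes=barcodes)
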