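"""Peak annotation: genomic feature types and internal-priming sequence signals.

Feature annotation follows the hierarchy UTR3 > UTR5 > exon > intron
across a gene's transcripts; all overlapped features are retained.
Sequence annotation scans, on the gene's sense strand, the window
downstream of the peak for the canonical polyA motif (AATAAA in genomic
DNA sense) and for A-rich stretches (any 13-mer with at most one
mismatch from poly-A, the internal-priming signature), and the window
upstream for the matching T-rich stretch.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from pyfaidx import Fasta

from .gene_models import GeneModel
from .peak_merging import MergedPeak

log = logging.getLogger(__name__)

HIERARCHY = ["UTR3", "UTR5", "exon", "intron"]
POLYA_MOTIF = "AATAAA"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(slots=True)
class PeakAnnotation:
    peak_id: str
    feature_types: set[str] = field(default_factory=set)
    primary_feature: str = "intergenic"
    polyA_motif: bool = False
    a_rich_downstream: bool = False
    t_rich_upstream: bool = False


def _overlaps(iv: tuple[int, int], start: int, end: int) -> bool:
    return iv[0] <= end and iv[1] >= start


def annotate_feature_type(peak: MergedPeak, gene: GeneModel) -> tuple[set[str], str]:
    """All features the peak overlaps across the gene's transcripts, plus
    the primary label under the UTR3 > UTR5 > exon > intron hierarchy."""
    found: set[str] = set()
    for tx in gene.transcripts:
        for iv in tx.utr3:
            if _overlaps(iv, peak.start, peak.end):
                found.add("UTR3")
        for iv in tx.utr5:
            if _overlaps(iv, peak.start, peak.end):
                found.add("UTR5")
        for iv in tx.coding_exons():
            if _overlaps(iv, peak.start, peak.end):
                found.add("exon")
        for iv in tx.introns():
            if _overlaps(iv, peak.start, peak.end):
                found.add("intron")
    primary = next((h for h in HIERARCHY if h in found), "intergenic")
    return found, primary


def has_base_run(seq: str, base: str, k: int = 13, max_mismatch: int = 1) -> bool:
    """True when any length-k window of seq has at most max_mismatch
    positions differing from the given base."""
    seq = seq.upper()
    if len(seq) < k:
        return False
    mism = [0 if c == base else 1 for c in seq]
    window = sum(mism[:k])
    if window <= max_mismatch:
        return True
    for i in range(k, len(seq)):
        window += mism[i] - mism[i - k]
        if window <= max_mismatch:
            return True
    return False


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(genome: Fasta, chrom: str, start: int, end: int) -> str:
    """1-based inclusive fetch, truncated at contig bounds."""
    n = len(genome[chrom])
    start = max(1, start)
    end = min(n, end)
    if start > end:
        return ""
    return str(genome[chrom][start - 1 : end])


def scan_sequence_motifs(
    peak: MergedPeak, genome: Fasta, window: int = 200
) -> tuple[bool, bool, bool]:
    """(polyA_motif, a_rich_downstream, t_rich_upstream) for one peak.

    Downstream/upstream are in transcription direction: minus-strand
    peaks use mirrored windows and the reverse complement, so both
    strands are scanned in sense-strand space.
    """
    if peak.strand == "+":
        down = _fetch(genome, peak.chrom, peak.end + 1, peak.end + window)
        up = _fetch(genome, peak.chrom, peak.start - window, peak.start - 1)
    else:
        down = _revcomp(_fetch(genome, peak.chrom, peak.start - window, peak.start - 1))
        up = _revcomp(_fetch(genome, peak.chrom, peak.end + 1, peak.end + window))
    polya = POLYA_MOTIF in down.upper()
    a_rich = has_base_run(down, "A")
    t_rich = has_base_run(up, "T")
    return polya, a_rich, t_rich


def annotate_peaks(
    peaks: Sequence[MergedPeak],
    gene_models: dict[str, GeneModel],
    genome_path: str | os.PathLike | None = None,
    window: int = 200,
) -> pd.DataFrame:
    """Annotate every peak; returns one row per input peak.

    Columns: peak_id, gene_id, chrom, start, end, strand, feature_types
    (comma-joined), primary_feature, polyA_motif, a_rich_downstream,
    t_rich_upstream. Without a genome, sequence flags are all False.
    """
    genome = Fasta(str(genome_path)) if genome_path is not None else None
    if genome is not None:
        missing = sorted({p.chrom for p in peaks} - set(genome.keys()))
        if missing:
            raise ValueError(f"chromosomes absent from FASTA: {', '.join(missing)}")
    rows = []
    for peak in peaks:
        gene = gene_models.get(peak.gene_id)
        if gene is not None:
            features, primary = annotate_feature_type(peak, gene)
        else:
            features, primary = set(), "intergenic"
        polya = a_rich = t_rich = False
        if genome is not None:
            polya, a_rich, t_rich = scan_sequence_motifs(peak, genome, window)
        rows.append(
            {
                "peak_id": peak.peak_id,
                "gene_id": peak.gene_id,
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "strand": peak.strand,
                "feature_types": ",".join(sorted(features)) if features else ".",
                "primary_feature": primary,
                "polyA_motif": polya,
                "a_rich_downstream": a_rich,
                "t_rich_upstream": t_rich,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "gene_id",
            "chrom",
            "start",
            "end",
            "strand",
            "feature_types",
            "primary_feature",
            "polyA_motif",
            "a_rich_downstream",
            "t_rich_upstream",
        ],
    )
    if len(df):
        frac = df["primary_feature"].value_counts(normalize=True).to_dict()
        log.info(
            "annotated %d peaks; feature fractions %s; A-rich fraction %.3f",
            len(df),
            {k: round(v, 3) for k, v in frac.items()},
            df["a_rich_downstream"].mean(),
        )
    return df
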