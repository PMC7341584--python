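"""Merging peak sets called from multiple datasets into unified coordinates.

Two peaks from the same gene are compared with a width-relative similarity
score: distance = (|delta start| + |delta end|) / width(scoring peak),
similarity = max(0, 1 - distance). A pair is matched when the score is
>= 0.75 in one orientation and >= 0.75 * (1 - 0.25) = 0.5625 in the
other (the relaxed second criterion). Matched peaks collapse to the union
of their coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(slots=True)
class PeakRecord:
    """Coordinate view of a called peak, the unit peak merging operates on."""

    peak_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    dataset_id: str | None = None


@dataclass(slots=True)
class SimilarityScore:
    value: float
    peak_a_id: str
    peak_b_id: str


@dataclass(slots=True)
class MergedPeak:
    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    source_peak_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def peak_id(self) -> str:
        return f"{self.gene_id}:{self.chrom}:{self.start}-{self.end}:{self.strand}"


def similarity_score(
    peak_a: PeakRecord, peak_b: PeakRecord, distance_mode: str = "sum"
) -> SimilarityScore:
    """Similarity of peak_b to peak_a, scored relative to peak_a's width.

    The coordinate distance is the sum of |start| and |end| differences
    by default; distance_mode="max" uses the larger of the two instead.
    Asymmetric when widths differ; 1.0 means identical coordinates, 0.0
    means the coordinate differences exceed the scoring peak's width.
    """
    width = peak_a.end - peak_a.start
    if width <= 0:
        raise ValueError(f"zero-width peak {peak_a.peak_id}")
    d_start = abs(peak_a.start - peak_b.start)
    d_end = abs(peak_a.end - peak_b.end)
    if distance_mode == "sum":
        distance = (d_start + d_end) / width
    elif distance_mode == "max":
        distance = max(d_start, d_end) / width
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    return SimilarityScore(
        value=max(0.0, 1.0 - distance), peak_a_id=peak_a.peak_id, peak_b_id=peak_b.peak_id
    )


def scores_matched(
    s_ab: float, s_ba: float, threshold: float = 0.75, relax: float = 0.25
) -> bool:
    """The two-threshold matching rule on a pair of similarity scores:
    one orientation must reach the threshold, the other may deviate from
    it by up to the relax fraction (0.75 and 0.5625 by default)."""
    relaxed = threshold * (1.0 - relax)
    return (s_ab >= threshold and s_ba >= relaxed) or (
        s_ba >= threshold and s_ab >= relaxed
    )


def match_peaks_pairwise(
    set_a: Sequence[PeakRecord],
    set_b: Sequence[PeakRecord],
    threshold: float = 0.75,
    relax: float = 0.25,
    distance_mode: str = "sum",
) -> list[tuple[PeakRecord, PeakRecord]]:
    """Greedy one-to-one matching of peaks between two datasets.

    Within each (gene, strand) group, a pair is matched when at least one
    orientation scores >= threshold and the other >= threshold*(1-relax).
    Candidate pairs are taken best-score-first; each peak matches at most
    once. Ties are broken by genomic coordinate for determinism.
    """
    by_gene_a: dict[tuple[str, str], list[PeakRecord]] = {}
    for p in set_a:
        by_gene_a.setdefault((p.gene_id, p.strand), []).append(p)

    candidates: list[tuple[float, tuple, PeakRecord, PeakRecord]] = []
    for p_b in set_b:
        group = by_gene_a.get((p_b.gene_id, p_b.strand), ())
        for p_a in group:
            s_ab = similarity_score(p_a, p_b, distance_mode).value
            s_ba = similarity_score(p_b, p_a, distance_mode).value
            if scores_matched(s_ab, s_ba, threshold, relax):
                tiebreak = (p_a.chrom, p_a.start, p_a.end, p_b.start, p_b.end)
                candidates.append((max(s_ab, s_ba), tiebreak, p_a, p_b))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[PeakRecord, PeakRecord]] = []
    for _, _, p_a, p_b in candidates:
        if p_a.peak_id in used_a or p_b.peak_id in used_b:
            continue
        used_a.add(p_a.peak_id)
        used_b.add(p_b.peak_id)
        pairs.append((p_a, p_b))
    return pairs


def _as_merged(p: PeakRecord) -> MergedPeak:
    ds = p.dataset_id or "dataset0"
    return MergedPeak(
        chrom=p.chrom,
        strand=p.strand,
        start=p.start,
        end=p.end,
        gene_id=p.gene_id,
        source_peak_ids={ds: [p.peak_id]},
    )


def merge_peak_sets(
    peak_sets: Sequence[Sequence[PeakRecord]],
    threshold: float = 0.75,
    relax: float = 0.25,
    distance_mode: str = "sum",
) -> list[MergedPeak]:
    """Iteratively merge peak sets (in input order) into unified coordinates.

    Matched peaks take the union of start/end across datasets; unmatched
    peaks are carried through unchanged. The final list is sorted by
    genomic coordinate and peak ids re-derived from merged coordinates.
    """
    if not peak_sets:
        raise ValueError("at least one peak set required")
    merged = [_as_merged(p) for p in peak_sets[0]]
    for peak_set in peak_sets[1:]:
        current_view = [
            PeakRecord(
                peak_id=m.peak_id,
                gene_id=m.gene_id,
                chrom=m.chrom,
                strand=m.strand,
                start=m.start,
                end=m.end,
            )
            for m in merged
        ]
        by_id = {v.peak_id: m for v, m in zip(current_view, merged)}
        pairs = match_peaks_pairwise(current_view, peak_set, threshold, relax, distance_mode)
        matched_b = set()
        for view_a, p_b in pairs:
            m = by_id[view_a.peak_id]
            m.start = min(m.start, p_b.start)
            m.end = max(m.end, p_b.end)
            ds = p_b.dataset_id or "dataset1"
            m.source_peak_ids.setdefault(ds, []).append(p_b.peak_id)
            matched_b.add(p_b.peak_id)
        for p_b in peak_set:
            if p_b.peak_id not in matched_b:
                merged.append(_as_merged(p_b))
    merged.sort(key=lambda m: (m.chrom, m.start, m.end, m.strand, m.gene_id))
    return merged
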