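"""3'UTR-shortening inference and the relative-peak-expression transform.

Shortening: differentially used 3'UTR peaks are placed on their
transcript 3'UTR, every expressed non-A-rich peak on the same UTR is
ranked by proximity to the terminating exon (score 0 = most proximal,
1 = most distal), and the score distributions of up- vs downregulated
peaks are compared with a Wilcoxon rank-sum test — upregulated peaks
concentrated at proximal positions indicate 3'UTR shortening.

Relative expression: R = log2(x / (G + v) * P + 1) per cell and peak,
where G is the cluster's mean gene-level expression over the gene's
peaks, P the peak's relative usage within the cluster, and v a
pseudo-count; highlights usage shifts masked by gene-level expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .gene_models import GeneModel

log = logging.getLogger(__name__)


@dataclass(slots=True)
class UTRPeakRank:
    peak_id: str
    gene_id: str
    utr_id: str
    location_score: float
    du_direction: str  # "up" | "down" | "untested"


@dataclass(slots=True)
class ShorteningResult:
    comparison: str
    statistic: float | None
    p_value: float | None
    direction: str  # "shortening" | "lengthening" | "none"
    n_up: int
    n_down: int


def _utr_span(intervals: Sequence[tuple[int, int]]) -> tuple[int, int]:
    return min(s for s, _ in intervals), max(e for _, e in intervals)


def _longest_containing_utr(
    gene: GeneModel, start: int, end: int
) -> tuple[str, tuple[int, int]] | None:
    """Longest transcript 3'UTR overlapping [start, end], or None."""
    best = None
    for tx_id, intervals in gene.utr3_intervals():
        lo, hi = _utr_span(intervals)
        if lo <= end and hi >= start:
            length = hi - lo
            if best is None or length > best[0]:
                best = (length, tx_id, (lo, hi))
    if best is None:
        return None
    return best[1], best[2]


def utr_location_scores(
    du_results: pd.DataFrame,
    gene_models: dict[str, GeneModel],
    annotations: pd.DataFrame,
) -> list[UTRPeakRank]:
    """Score DU 3'UTR peaks by their position along their 3'UTR.

    du_results must come from a DU run restricted to 3'UTR peaks with
    A-rich peaks excluded. For each significant (DU) peak, all tested
    peaks on the same (longest containing) 3'UTR are ordered by
    strand-aware distance from the terminating exon and scored
    i/(k-1) for rank i of k (a single peak scores 0). Peaks that cannot
    be placed on an annotated 3'UTR are dropped with a log entry.
    """
    ann = annotations.set_index("peak_id")
    coords = {
        pid: (int(row["start"]), int(row["end"]), row["strand"])
        for pid, row in ann.iterrows()
    }
    tested = du_results[du_results["test_status"] == "tested"]
    out: list[UTRPeakRank] = []
    for row in tested[tested["significant"]].itertuples():
        gene = gene_models.get(row.gene_id)
        if gene is None or row.peak_id not in coords:
            log.warning("DU peak %s not assignable to a 3'UTR; skipped", row.peak_id)
            continue
        start, end, strand = coords[row.peak_id]
        found = _longest_containing_utr(gene, start, end)
        if found is None:
            log.warning("DU peak %s not assignable to a 3'UTR; skipped", row.peak_id)
            continue
        utr_tx, (utr_lo, utr_hi) = found
        # every expressed (tested) peak of the gene lying on the same UTR
        members = []
        for peer in tested[tested["gene_id"] == row.gene_id].itertuples():
            if peer.peak_id not in coords:
                continue
            ps, pe, _ = coords[peer.peak_id]
            if ps <= utr_hi and pe >= utr_lo:
                members.append((peer.peak_id, (ps + pe) / 2.0))
        members.sort(key=lambda m: m[1], reverse=(strand == "-"))
        k = len(members)
        ranks = {pid: (i / (k - 1) if k > 1 else 0.0) for i, (pid, _) in enumerate(members)}
        direction = "up" if row.usage_LFC > 0 else "down"
        out.append(
            UTRPeakRank(
                peak_id=row.peak_id,
                gene_id=row.gene_id,
                utr_id=utr_tx,
                location_score=ranks[row.peak_id],
                du_direction=direction,
            )
        )
    return out


def test_utr_shortening(
    ranks: Sequence[UTRPeakRank],
    comparison: str = "",
    p_threshold: float = 0.05,
) -> ShorteningResult:
    """Wilcoxon rank-sum comparison of up- vs downregulated peak positions.

    direction = "shortening" when upregulated peaks sit more proximal
    (lower median score) than downregulated ones and p < p_threshold.
    With either group empty, no test is performed.
    """
    up = [r.location_score for r in ranks if r.du_direction == "up"]
    down = [r.location_score for r in ranks if r.du_direction == "down"]
    if not up or not down:
        return ShorteningResult(comparison, None, None, "none", len(up), len(down))
    stat, p = mannwhitneyu(up, down, alternative="two-sided", method="asymptotic")
    direction = "none"
    if p < p_threshold:
        if np.median(up) < np.median(down):
            direction = "shortening"
        elif np.median(up) > np.median(down):
            direction = "lengthening"
    return ShorteningResult(comparison, float(stat), float(p), direction, len(up), len(down))


def relative_peak_expression(
    x: np.ndarray,
    cluster_assignment: Sequence,
    v: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Relative expression R = log2(x/(G+v) * P + 1) for one gene's peaks.

    x is peaks x cells on a normalised expression scale (conventionally
    log-normalised counts-per-ten-thousand); cluster_assignment gives a
    cluster id per cell. Per cluster, G is the grand mean over all peaks
    and cells and P_i = mean_j(x_ij)/G the relative usage of peak i.
    A cluster with G = 0 gets R = 0 for all its cells. Returns the R
    matrix and a per-(cluster, peak) table of G and P.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("x must be peaks x cells with at least 2 peaks")
    clusters = np.asarray(cluster_assignment)
    if clusters.shape[0] != x.shape[1]:
        raise ValueError("one cluster id per cell required")
    r = np.zeros_like(x)
    rows = []
    for c in pd.unique(clusters):
        cols = clusters == c
        sub = x[:, cols]
        g = sub.mean()  # 1/(n*m) * sum over peaks and cells
        if g == 0:
            for i in range(x.shape[0]):
                rows.append({"cluster": c, "peak": i, "G": 0.0, "P": 0.0})
            continue
        p_usage = sub.mean(axis=1) / g
        r[:, cols] = np.log2(sub / (g + v) * p_usage[:, None] + 1.0)
        for i in range(x.shape[0]):
            rows.append({"cluster": c, "peak": i, "G": g, "P": float(p_usage[i])})
    return r, pd.DataFrame(rows)


def normalize_counts_per_10k(counts: np.ndarray) -> np.ndarray:
    """log1p counts-per-ten-thousand per cell (columns), the conventional
    single-cell normalisation scale used for relative expression."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * 1e4)
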