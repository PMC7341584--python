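"""Splice-aware discovery of Gaussian-shaped coverage peaks, one gene at a time.

The procedure: junctions observed in the reads are filtered for support,
read coverage is partitioned into an across-junction track (retained
intronic spans excised, flanks concatenated) and one within-junction track
per retained intronic span, and each track is scanned by iterative
fit-and-subtract: find the apex, fit y = k*exp(-(x-mu)^2 / (2*sigma^2))
over a 600-bp window by non-linear least squares, call the interval
centre +/- 3*sigma, zero it, repeat until the residual-coverage or
peak-height stopping rule fires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .alignment_io import (
    AlignmentRecord,
    Junction,
    build_gene_coverage,
    extract_junctions,
)
from .gene_models import GeneModel

log = logging.getLogger(__name__)


@dataclass(slots=True)
class FitConfig:
    """Thresholds and fit-window geometry for peak discovery.

    Junction filter: keep junctions supported by at least
    max(min_jcutoff, min_jcutoff_prop * max gene coverage) reads.
    Stopping rule 1 (residual coverage): stop when unassigned coverage is
    both <= min_cov_prop of the gene total and <= min_cov_cutoff.
    Stopping rule 2 (peak height): stop when the current apex is both
    < min_peak_cutoff and < min_peak_prop of the gene's maximum coverage.
    """

    min_jcutoff: int = 50
    min_jcutoff_prop: float = 0.05
    min_cov_prop: float = 0.05
    min_cov_cutoff: int = 500
    min_peak_cutoff: int = 200
    min_peak_prop: float = 0.05
    fit_window: int = 600
    mu_init: float = 300.0
    sigma_init: float = 100.0
    sigma_bounds: tuple[float, float] = (5.0, 350.0)
    max_iterations: int = 200
    min_overhang: int = 5

    def __post_init__(self):
        if self.fit_window % 2:
            raise ValueError("fit_window must be even")
        for frac in (self.min_jcutoff_prop, self.min_cov_prop, self.min_peak_prop):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")


@dataclass(slots=True)
class GaussianFit:
    k: float
    mu: float  # offset within the fitted window (bp)
    sigma: float
    converged: bool
    window_start: int = 0  # track index of window[0]


@dataclass(slots=True)
class PeakCall:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive genomic
    end: int
    fit: GaussianFit
    junction_class: str  # "across_junction" | "within_junction"
    rank: int
    dataset_id: str | None = None
    centre: int = 0  # genomic position of the fitted peak centre

    @property
    def peak_id(self) -> str:
        return f"{self.gene_id}:{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass(slots=True)
class _Track:
    values: np.ndarray  # working copy, mutated during calling
    positions: np.ndarray  # genomic position (1-based) per index
    kind: str  # "across" | "within"


def filter_junctions(
    junctions: Iterable[Junction], coverage: np.ndarray, config: FitConfig
) -> list[Junction]:
    """Keep junctions supported by enough reads relative to gene coverage."""
    max_cov = int(coverage.max()) if len(coverage) else 0
    threshold = max(config.min_jcutoff, config.min_jcutoff_prop * max_cov)
    return [j for j in junctions if j.support >= threshold]


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]  # type: ignore[misc]


def split_coverage_by_junctions(
    records: Sequence[AlignmentRecord],
    filtered_junctions: Sequence[Junction],
    gene_span: tuple[str, int, int],
) -> tuple[_Track, list[_Track]]:
    """Partition gene coverage into across- and within-junction tracks.

    Overlapping retained intronic spans are merged before use. A read is
    within-junction when all of its aligned blocks lie inside one merged
    intronic span; all remaining reads form the across-junction coverage,
    from which the merged spans are excised and the flanks concatenated.
    The positions array maps track indices back to genomic coordinates.
    """
    chrom, gstart, gend = gene_span
    spans = _merge_intervals(
        [
            (max(j.intron_start, gstart), min(j.intron_end, gend))
            for j in filtered_junctions
            if j.intron_start <= gend and j.intron_end >= gstart
        ]
    )

    def _span_of(rec: AlignmentRecord) -> tuple[int, int] | None:
        for s, e in spans:
            if rec.start >= s and rec.end <= e:
                return (s, e)
        return None

    within_reads: dict[tuple[int, int], list[AlignmentRecord]] = {s: [] for s in spans}
    across_reads: list[AlignmentRecord] = []
    for rec in records:
        sp = _span_of(rec)
        if sp is None:
            across_reads.append(rec)
        else:
            within_reads[sp].append(rec)

    total = build_gene_coverage(across_reads, gene_span).values
    positions = np.arange(gstart, gend + 1, dtype=np.int64)
    keep = np.ones(len(positions), dtype=bool)
    for s, e in spans:
        keep[s - gstart : e - gstart + 1] = False
    across = _Track(values=total[keep].copy(), positions=positions[keep], kind="across")

    withins: list[_Track] = []
    for s, e in spans:
        track = build_gene_coverage(within_reads[(s, e)], (chrom, s, e))
        withins.append(
            _Track(
                values=track.values.copy(),
                positions=np.arange(s, e + 1, dtype=np.int64),
                kind="within",
            )
        )
    return across, withins


def _gauss(x: np.ndarray, k: float, mu: float, sigma: float) -> np.ndarray:
    return k * np.exp(-0.5 * (x - mu) ** 2 / sigma**2)


def fit_gaussian_peak(
    values: np.ndarray, apex_position: int, config: FitConfig | None = None
) -> GaussianFit:
    """Least-squares Gaussian fit over a fit_window region centred on the apex.

    The window is clipped at track bounds, in which case the location
    initialiser is re-centred on the window midpoint. Fits that fail to
    converge, or converge onto a sigma bound (degenerate flat fits), are
    reported with converged=False.
    """
    config = config or FitConfig()
    half = config.fit_window // 2
    lo = max(0, apex_position - half)
    hi = min(len(values), apex_position + half)
    window = np.asarray(values[lo:hi], dtype=float)
    fail = GaussianFit(0.0, 0.0, 0.0, False, window_start=lo)
    if len(window) < 4 or window.max() <= 0:
        return fail
    x = np.arange(len(window), dtype=float)
    mu0 = config.mu_init if (lo == apex_position - half and len(window) == config.fit_window) else len(window) / 2.0
    k0 = float(window.max())
    s_lo, s_hi = config.sigma_bounds
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            window,
            p0=[k0, mu0, config.sigma_init],
            bounds=([1e-9, -half, s_lo], [np.inf, len(window) + half, s_hi]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return fail
    k, mu, sigma = (float(v) for v in popt)
    if not np.isfinite([k, mu, sigma]).all():
        return fail
    # reject degenerate fits pinned at the sigma bounds
    if sigma <= s_lo * 1.001 or sigma >= s_hi * 0.999:
        return fail
    return GaussianFit(k=k, mu=mu, sigma=sigma, converged=True, window_start=lo)


def _call_track(
    track: _Track,
    gene: GeneModel,
    config: FitConfig,
    gene_max: float,
    total_cov: float,
    assigned: list[float],
    rank_counter: list[int],
    dataset_id: str | None,
) -> list[PeakCall]:
    peaks: list[PeakCall] = []
    values = track.values
    jclass = "across_junction" if track.kind == "across" else "within_junction"
    for _ in range(config.max_iterations):
        unassigned = total_cov - assigned[0]
        if unassigned <= config.min_cov_prop * total_cov and unassigned <= config.min_cov_cutoff:
            break
        if not len(values):
            break
        apex = int(np.argmax(values))
        height = float(values[apex])
        if height <= 0:
            break
        if height < config.min_peak_cutoff and height < config.min_peak_prop * gene_max:
            break
        fit = fit_gaussian_peak(values, apex, config)
        if not fit.converged:
            # zero the window so the same apex is not revisited
            half = config.fit_window // 2
            lo = max(0, apex - half)
            hi = min(len(values), apex + half)
            assigned[0] += float(values[lo:hi].sum())
            values[lo:hi] = 0
            continue
        centre = fit.window_start + fit.mu
        lo = int(round(centre - 3.0 * fit.sigma))
        hi = int(round(centre + 3.0 * fit.sigma))
        lo = max(0, lo)
        hi = min(len(values) - 1, hi)
        if hi < lo:
            break
        assigned[0] += float(values[lo : hi + 1].sum())
        values[lo : hi + 1] = 0
        g_start = int(track.positions[lo])
        g_end = int(track.positions[hi])
        centre_idx = min(max(int(round(centre)), 0), len(values) - 1)
        g_centre = int(track.positions[centre_idx])
        rank_counter[0] += 1
        peaks.append(
            PeakCall(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                start=min(g_start, g_end),
                end=max(g_start, g_end),
                fit=fit,
                junction_class=jclass,
                rank=rank_counter[0],
                dataset_id=dataset_id,
                centre=g_centre,
            )
        )
    return peaks


def call_peaks_for_gene(
    records: Sequence[AlignmentRecord],
    gene: GeneModel,
    config: FitConfig | None = None,
    junctions: Sequence[Junction] | None = None,
    dataset_id: str | None = None,
) -> list[PeakCall]:
    """Run the full splice-aware fit-and-subtract procedure on one gene.

    Junctions default to those observed in the records; a pre-computed
    list (e.g. from a junction BED) may be supplied instead. Peaks are
    returned in discovery order: across-junction track first, then each
    within-junction track in genomic order. Residual-coverage and
    peak-height stopping thresholds are evaluated against gene-level
    totals on every track.
    """
    config = config or FitConfig()
    records = list(records)
    gene_span = (gene.chrom, gene.start, gene.end)
    total_track = build_gene_coverage(records, gene_span).values
    if total_track.max(initial=0) == 0:
        return []
    if junctions is None:
        junctions = extract_junctions(records, min_overhang=config.min_overhang)
    retained = filter_junctions(junctions, total_track, config)
    across, withins = split_coverage_by_junctions(records, retained, gene_span)

    gene_max = float(total_track.max())
    total_cov = float(total_track.sum())
    assigned = [0.0]
    rank_counter = [0]
    peaks = _call_track(
        across, gene, config, gene_max, total_cov, assigned, rank_counter, dataset_id
    )
    for track in withins:
        peaks.extend(
            _call_track(
                track, gene, config, gene_max, total_cov, assigned, rank_counter, dataset_id
            )
        )
    return peaks
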