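"""Benchmark evaluation of pipeline stages against synthetic truth tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential_usage import du_test_pseudobulk, estimate_size_factors
from .gene_models import GeneModel
from .peak_calling import FitConfig, call_peaks_for_gene
from .simulate import (
    SyntheticScenario,
    iter_gene_records,
    simulate_two_bin_pseudobulk,
)


@dataclass
class RecoveryResult:
    n_true: int
    n_called: int
    n_matched: int
    partial_intron_intrusions: int
    peaks: list

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_called if self.n_called else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 0.0


def _gene_models_from_scenario(scenario: SyntheticScenario) -> dict[str, GeneModel]:
    """Gene models equivalent to the scenario's GTF, built directly."""
    from .gene_models import TranscriptModel

    out = {}
    for layout in scenario.genes:
        tx = TranscriptModel(
            transcript_id=f"{layout.gene_id}.t1",
            strand=layout.strand,
            exons=sorted([layout.exon1, layout.exon2]),
            cds=sorted([layout.exon1, layout.cds2]),
            utr3=[layout.utr3],
        )
        out[layout.gene_id] = GeneModel(
            gene_id=layout.gene_id,
            chrom=layout.chrom,
            strand=layout.strand,
            start=layout.start,
            end=layout.end,
            transcripts=[tx],
        )
    return out


def evaluate_peak_recovery(
    scenario: SyntheticScenario,
    config: FitConfig | None = None,
    centre_tolerance: int = 50,
) -> RecoveryResult:
    """Call peaks on a scenario's reads and score them against the truth.

    A called peak matches a truth peak when its fitted genomic centre lies
    within centre_tolerance of the expected coverage apex; matching is
    greedy one-to-one per gene. Splice-awareness is scored as the number
    of across-junction peaks that partially intrude into an intron
    interior (peaks cleanly spanning an excised intron, with both ends in
    exons, are legitimate spliced peaks and not counted).
    """
    genes = _gene_models_from_scenario(scenario)
    truth = scenario.truth
    n_true = n_called = n_matched = intrusions = 0
    all_peaks = []
    for gene_id, records in iter_gene_records(scenario):
        peaks = call_peaks_for_gene(records, genes[gene_id], config)
        all_peaks.extend(peaks)
        apexes = truth.loc[truth.gene_id == gene_id, "apex_pos"].tolist()
        n_true += len(apexes)
        n_called += len(peaks)
        used: set[int] = set()
        for p in peaks:
            best = None
            for i, apex in enumerate(apexes):
                if i in used or abs(p.centre - apex) > centre_tolerance:
                    continue
                if best is None or abs(p.centre - apex) < abs(p.centre - apexes[best]):
                    best = i
            if best is not None:
                used.add(best)
                n_matched += 1
        introns = genes[gene_id].transcripts[0].introns()
        for p in peaks:
            if p.junction_class != "across_junction":
                continue
            for s, e in introns:
                lo, hi = max(p.start, s + 1), min(p.end, e - 1)
                if lo <= hi and not (p.start < s and p.end > e):
                    intrusions += 1
    return RecoveryResult(n_true, n_called, n_matched, intrusions, all_peaks)


def null_rejection_rate(
    n_genes: int = 500,
    mean_total: float = 400.0,
    seed: int = 1,
    alpha_level: float = 0.05,
) -> tuple[float, float]:
    """Type-I error of the usage test on null two-peak genes.

    Returns (rejection rate at alpha_level on raw p, KS uniformity p),
    computed on one test per gene (a two-peak gene's tests mirror each
    other exactly).
    """
    rng = np.random.default_rng([seed, 31])
    props = [[p, 1 - p] for p in rng.uniform(0.3, 0.7, size=n_genes)]
    counts, pids, gids, pops = simulate_two_bin_pseudobulk(
        props, props, mean_total=mean_total, seed=int(rng.integers(2**31))
    )
    sf = estimate_size_factors(counts)
    res = du_test_pseudobulk(counts, pids, gids, sf, pops)
    first = res[(res.test_status == "tested") & res.peak_id.str.endswith("_p0")]
    rate = float((first.p_value < alpha_level).mean())
    ks_p = float(stats.kstest(first.p_value.to_numpy(), "uniform").pvalue)
    return rate, ks_p


def switch_detection_power(
    n_runs: int = 100,
    mean_total: float = 400.0,
    seed: int = 1,
) -> tuple[float, float]:
    """Power to flag the canonical usage switch (0.8/0.2 -> 0.2/0.8).

    Returns (fraction of runs where the proximal peak is flagged DU with
    the correct sign at p_adj < 0.01 and |LFC| > 0.5, mean fitted LFC).
    The expected usage log2 fold-change is log2((0.2/0.8)/(0.8/0.2)) = -4.
    """
    hits = 0
    lfcs = []
    for r in range(n_runs):
        counts, pids, gids, pops = simulate_two_bin_pseudobulk(
            [[0.8, 0.2]], [[0.2, 0.8]], mean_total=mean_total, seed=seed * 100_003 + r
        )
        res = du_test_pseudobulk(counts, pids, gids, np.ones(counts.shape[1]), pops)
        row = res[res.peak_id == "g0_p0"].iloc[0]
        if row.significant and row.usage_LFC < 0:
            hits += 1
        if row.usage_LFC is not None and np.isfinite(row.usage_LFC):
            lfcs.append(row.usage_LFC)
    return hits / n_runs, float(np.mean(lfcs))


def shortening_null_pvalues(
    n_replicates: int = 200, n_peaks_per_group: int = 30, seed: int = 1
) -> np.ndarray:
    """Shortening-test p-values when up/down scores share one distribution."""
    from .downstream import UTRPeakRank, test_utr_shortening

    rng = np.random.default_rng([seed, 37])
    out = []
    for _ in range(n_replicates):
        scores = rng.uniform(0, 1, size=2 * n_peaks_per_group)
        ranks = [
            UTRPeakRank(f"p{i}", "g", "t", float(s), "up" if i < n_peaks_per_group else "down")
            for i, s in enumerate(scores)
        ]
        out.append(test_utr_shortening(ranks).p_value)
    return np.asarray(out)
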