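"""Pseudo-bulk construction, size factors and the NB usage interaction test."""

from __future__ import annotations

import logging

import numpy as np
import pytest
import scipy.sparse as sp

from scapa.differential_usage import (
    du_test_pseudobulk,
    estimate_size_factors,
    make_pseudobulk,
    shorth,
)
from scapa.peak_counting import PeakCountMatrix
from scapa.simulate import simulate_two_bin_pseudobulk


def _matrix(counts, barcodes=None):
    counts = np.asarray(counts, dtype=np.int64)
    barcodes = barcodes or [f"BC{i}" for i in range(counts.shape[1])]
    return PeakCountMatrix(
        sp.csr_matrix(counts), [f"G:p{i}" for i in range(counts.shape[0])], barcodes
    )


class TestPseudobulk:
    def test_n1_equals_population_column_sums(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(4, 8))
        m = _matrix(counts)
        pb = make_pseudobulk(m, {"A": m.barcodes[:4], "B": m.barcodes[4:]}, n=1)
        assert (pb.counts[:, 0] == counts[:, :4].sum(axis=1)).all()
        assert (pb.counts[:, 1] == counts[:, 4:].sum(axis=1)).all()

    def test_conservation_12_cells_6_groups(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, size=(5, 12))
        m = _matrix(counts)
        pb = make_pseudobulk(m, {"A": m.barcodes}, n=6, seed=3)
        assert pb.counts.shape == (5, 6)
        assert (pb.counts.sum(axis=1) == counts.sum(axis=1)).all()
        sizes = {}
        for col in pb.cell_assignment.values():
            sizes[col] = sizes.get(col, 0) + 1
        assert sorted(sizes.values()) == [2] * 6

    def test_fewer_cells_than_groups_reduces_n(self, caplog):
        counts = np.ones((2, 4), dtype=np.int64)
        m = _matrix(counts)
        with caplog.at_level(logging.WARNING):
            pb = make_pseudobulk(m, {"A": m.barcodes}, n=6)
        assert pb.counts.shape[1] == 4
        assert any("4 cells" in r.message for r in caplog.records)

    def test_empty_population_is_an_error(self):
        m = _matrix(np.ones((2, 4)))
        with pytest.raises(ValueError):
            make_pseudobulk(m, {"A": []})

    def test_seed_reproducibility_and_label_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 8, size=(6, 20))
        m = _matrix(counts)
        pops = {"A": m.barcodes[:10], "B": m.barcodes[10:]}
        pb1 = make_pseudobulk(m, pops, seed=7)
        pb2 = make_pseudobulk(m, pops, seed=7)
        assert pb1.cell_assignment == pb2.cell_assignment
        swapped = make_pseudobulk(m, {"B": pops["B"], "A": pops["A"]}, seed=7)
        assert swapped.cell_assignment == pb1.cell_assignment


class TestShorth:
    def test_constant_vector(self):
        assert shorth([4.0, 4.0, 4.0]) == 4.0

    def test_worked_example(self):
        # shortest interval holding ceil(5/2)=3 values is [1, 1.2] -> mean 1.1
        assert shorth([1, 1.1, 1.2, 5, 9]) == pytest.approx(1.1)

    def test_tracks_centre_of_unimodal_sample(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, size=2001)
        assert abs(shorth(x) - np.median(x)) < 0.15

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            shorth([])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [5]]), (1, 4))
        assert estimate_size_factors(counts) == pytest.approx(np.ones(4))

    def test_doubled_column_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.integers(5, 100, size=(200, 1))
        counts = np.tile(base, (1, 6)).astype(float)
        counts[:, 2] *= 2
        factors = estimate_size_factors(counts)
        others = np.delete(factors, 2).mean()
        assert factors[2] / others == pytest.approx(2.0, rel=0.01)

    def test_peak_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 50, size=(100, 5))
        f1 = estimate_size_factors(counts)
        f2 = estimate_size_factors(counts[::-1])
        assert f1 == pytest.approx(f2)

    def test_no_all_positive_peak_is_an_error(self):
        counts = np.array([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="positive"):
            estimate_size_factors(counts)


class TestUsageTest:
    def test_null_gene_not_flagged(self):
        counts, pids, gids, pops = simulate_two_bin_pseudobulk(
            [[0.5, 0.5]], [[0.5, 0.5]], mean_total=2000, nb_alpha=0.01, seed=5
        )
        res = du_test_pseudobulk(counts, pids, gids, np.ones(12), pops)
        assert not res["significant"].any()
        assert res["usage_LFC"].abs().max() < 0.5

    def test_simulated_switch_detected_with_correct_sign(self):
        counts, pids, gids, pops = simulate_two_bin_pseudobulk(
            [[0.8, 0.2]], [[0.2, 0.8]], mean_total=400, seed=6
        )
        res = du_test_pseudobulk(counts, pids, gids, np.ones(12), pops)
        r0 = res[res.peak_id == "g0_p0"].iloc[0]
        r1 = res[res.peak_id == "g0_p1"].iloc[0]
        assert r0.significant and r1.significant
        # usage of peak 0 drops in B: LFC ~ log2((0.2/0.8)/(0.8/0.2)) = -4
        assert r0.usage_LFC < -2.0
        assert r1.usage_LFC > 2.0
        assert abs(r0.usage_LFC + 4) < 1.5

    def test_label_swap_flips_lfc_and_keeps_p(self):
        counts, pids, gids, pops = simulate_two_bin_pseudobulk(
            [[0.7, 0.3]], [[0.4, 0.6]], mean_total=300, seed=7
        )
        res_ab = du_test_pseudobulk(counts, pids, gids, np.ones(12), pops)
        swapped_pops = ["B" if p == "A" else "A" for p in pops]
        res_ba = du_test_pseudobulk(counts, pids, gids, np.ones(12), swapped_pops)
        for pid in pids:
            a = res_ab[res_ab.peak_id == pid].iloc[0]
            b = res_ba[res_ba.peak_id == pid].iloc[0]
            assert a.p_value == pytest.approx(b.p_value, rel=1e-6, abs=1e-12)
            assert a.usage_LFC == pytest.approx(-b.usage_LFC, rel=1e-4, abs=1e-8)

    def test_single_peak_gene_skipped(self):
        counts = np.full((1, 12), 50)
        res = du_test_pseudobulk(
            counts, ["g0_p0"], ["g0"], np.ones(12), ["A"] * 6 + ["B"] * 6
        )
        assert res.iloc[0].test_status == "gene_lt2_peaks"
        assert np.isnan(res.iloc[0].p_value) or res.iloc[0].p_value is None


def test_du_test_end_to_end_finds_switching_gene(scenario, fixture_dir, gene_models):
    """Full pipeline on the BAM fixture: only the usage-switching gene is DTU."""
    from scapa.alignment_io import read_alignments
    from scapa.annotation import annotate_peaks
    from scapa.differential_usage import du_test
    from scapa.peak_calling import call_peaks_for_gene
    from scapa.peak_counting import count_umis
    from scapa.peak_merging import PeakRecord, merge_peak_sets

    peaks = []
    for gid, gene in gene_models.items():
        recs = list(
            read_alignments(
                fixture_dir["bam"], region=(gene.chrom, gene.start, gene.end),
                whitelist=scenario.whitelist,
            )
        )
        peaks.extend(call_peaks_for_gene(recs, gene, dataset_id="ds"))
    merged = merge_peak_sets(
        [[PeakRecord(p.peak_id, p.gene_id, p.chrom, p.strand, p.start, p.end, "ds")
          for p in peaks]]
    )
    matrix = count_umis(fixture_dir["bam"], merged, gene_models, scenario.whitelist)
    ann = annotate_peaks(merged, gene_models, fixture_dir["fasta"])
    results, gene_summary, pb = du_test(
        matrix, dict(scenario.barcodes), annotations=ann, seed=1
    )
    dtu = set(gene_summary.loc[gene_summary["dtu"], "gene_id"])
    assert dtu == {"G01"}
    sig = results[results["significant"]].set_index("peak_id")
    # the proximal (lower-usage-in-B) peak drops, the distal one rises
    lfcs = sig["usage_LFC"].sort_index()
    assert len(lfcs) == 2
    assert lfcs.iloc[0] * lfcs.iloc[1] < 0
    # pseudo-bulk conservation: replicate sums equal population sums
    b_index = {bc: i for i, bc in enumerate(matrix.barcodes)}
    for label, cells in scenario.barcodes.items():
        cols = [i for i, p in enumerate(pb.population_labels) if p == label]
        pop_total = matrix.counts[:, [b_index[c] for c in cells]].sum()
        assert pb.counts[:, cols].sum() == pop_total
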