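"""Fully synthetic fixtures: genomes, gene models, tagged reads and truth tables.

The generator emulates the geometry of 3'-biased droplet scRNA-seq:
each gene is a two-exon transcript (5' exon, intron, terminal exon with
a long 3'UTR); molecules pick a polyA site from the gene's true peaks
according to per-population usage proportions, the cleavage position is
drawn Normal(site, sigma), and a 91-nt read is placed immediately
upstream of it in transcription direction (spliced CIGARs when the read
crosses the intron). Optional intronic decoy sites model internal
priming: the genome carries an A-homopolymer downstream of them, while
true sites get a canonical AATAAA motif. A small class of junction-
spanning reads supplies splice-junction evidence, as gene-body
background does in real data. Every read class is recorded in a
machine-readable truth table.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Faidx

from .alignment_io import AlignmentRecord

READ_LENGTH = 91
_BASES = np.array(list("ACGT"))


@dataclass
class GeneConfig:
    gene_id: str
    strand: str = "+"
    sigmas: Sequence[float] = (100.0, 100.0)
    usage: dict[str, Sequence[float]] = field(default_factory=dict)
    has_decoy: bool = False
    decoy_sigma: float = 80.0
    decoy_frac: float = 0.08
    junction_frac: float = 0.0072
    weight: float = 1.0
    total_reads: int | None = None  # exact read count override (else Poisson)


@dataclass
class ScenarioConfig:
    genes: list[GeneConfig]
    populations: list[tuple[str, int]]  # (label, n_cells)
    umi_per_cell: float = 60.0
    seed: int = 1
    read_length: int = READ_LENGTH
    peak_spacing: int = 600
    exon1_length: int = 600
    intron_length: int = 2000
    coding2_length: int = 600
    gene_gap: int = 1000
    chrom: str = "chr1"


@dataclass(slots=True)
class TruthPeak:
    gene_id: str
    kind: str  # "utr3" | "intron_decoy" | "junction_support"
    peak_index: int
    chrom: str
    strand: str
    polya_pos: int  # genomic cleavage position (0 for junction class)
    apex_pos: int  # expected coverage apex in genomic coordinates
    sigma: float
    usage: dict[str, float]
    class_prob: float  # share of the gene's reads


class TxMap:
    """Bidirectional map between transcript and genomic coordinates.

    segments are genomic (start, end) intervals in transcription order;
    for minus-strand genes each segment is walked from its high end.
    """

    def __init__(self, segments: Sequence[tuple[int, int]], strand: str):
        self.segments = list(segments)
        self.strand = strand
        self.lengths = [e - s + 1 for s, e in segments]
        self.length = sum(self.lengths)
        self._cum = np.concatenate([[0], np.cumsum(self.lengths)])

    def t2g(self, t: int) -> int:
        """Transcript position (1-based) to genomic position."""
        if not 1 <= t <= self.length:
            raise ValueError(f"transcript position {t} outside 1..{self.length}")
        i = int(np.searchsorted(self._cum, t, side="left")) - 1
        off = t - 1 - self._cum[i]
        s, e = self.segments[i]
        return s + off if self.strand == "+" else e - off

    def g2t(self, g: int) -> int:
        for i, (s, e) in enumerate(self.segments):
            if s <= g <= e:
                off = g - s if self.strand == "+" else e - g
                return int(self._cum[i] + off + 1)
        raise ValueError(f"genomic position {g} not exonic")

    def interval_blocks(self, t0: int, t1: int) -> list[tuple[int, int]]:
        """Genomic blocks (sorted ascending) covering transcript [t0, t1]."""
        blocks = []
        for i, (s, e) in enumerate(self.segments):
            seg_t0 = self._cum[i] + 1
            seg_t1 = self._cum[i + 1]
            lo = max(t0, seg_t0)
            hi = min(t1, seg_t1)
            if lo > hi:
                continue
            if self.strand == "+":
                blocks.append((s + (lo - seg_t0), s + (hi - seg_t0)))
            else:
                blocks.append((e - (hi - seg_t0), e - (lo - seg_t0)))
        blocks.sort()
        return blocks


@dataclass
class GeneLayout:
    config: GeneConfig
    chrom: str
    start: int
    end: int
    exon1: tuple[int, int]  # 5' exon (transcription order)
    intron: tuple[int, int]
    exon2: tuple[int, int]  # terminal exon incl. 3'UTR
    cds2: tuple[int, int]  # coding part of the terminal exon
    utr3: tuple[int, int]
    txmap: TxMap = field(init=False)
    peaks: list[TruthPeak] = field(default_factory=list)

    def __post_init__(self):
        self.txmap = TxMap([self.exon1, self.exon2], self.config.strand)

    @property
    def gene_id(self) -> str:
        return self.config.gene_id

    @property
    def strand(self) -> str:
        return self.config.strand


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    chrom: str
    chrom_len: int
    genes: list[GeneLayout]
    truth: pd.DataFrame
    barcodes: dict[str, list[str]]  # population label -> barcodes
    genome: str

    @property
    def whitelist(self) -> set[str]:
        return {b for bs in self.barcodes.values() for b in bs}

    @property
    def population_map(self) -> dict[str, str]:
        return {b: label for label, bs in self.barcodes.items() for b in bs}


def _layout_gene(cfg: GeneConfig, scfg: ScenarioConfig, gstart: int) -> GeneLayout:
    n = len(cfg.sigmas)
    utr_len = scfg.peak_spacing * (n - 1) + 1000
    lens = [scfg.exon1_length, scfg.intron_length, scfg.coding2_length + utr_len]
    gend = gstart + sum(lens) - 1
    if cfg.strand == "+":
        exon1 = (gstart, gstart + lens[0] - 1)
        intron = (exon1[1] + 1, exon1[1] + lens[1])
        exon2 = (intron[1] + 1, gend)
        cds2 = (exon2[0], exon2[0] + scfg.coding2_length - 1)
        utr3 = (cds2[1] + 1, gend)
    else:
        exon1 = (gend - lens[0] + 1, gend)
        intron = (exon1[0] - lens[1], exon1[0] - 1)
        exon2 = (gstart, intron[0] - 1)
        cds2 = (exon2[1] - scfg.coding2_length + 1, exon2[1])
        utr3 = (gstart, cds2[0] - 1)
    layout = GeneLayout(cfg, scfg.chrom, gstart, gend, exon1, intron, exon2, cds2, utr3)

    shift = (scfg.read_length - 1) / 2.0
    peak_share = 1.0 - cfg.junction_frac - (cfg.decoy_frac if cfg.has_decoy else 0.0)
    usage = cfg.usage or {label: [1.0 / n] * n for label, _ in scfg.populations}
    for label, props in usage.items():
        if len(props) != n or abs(sum(props) - 1.0) > 1e-8:
            raise ValueError(f"usage for {cfg.gene_id}/{label} is not a length-{n} simplex")
    mean_usage = {
        label: props for label, props in usage.items()
    }
    pops = [label for label, _ in scfg.populations]
    for i, sigma in enumerate(cfg.sigmas):
        # polyA sites spaced along the UTR, transcription order
        t_utr_start = layout.txmap.g2t(utr3[0] if cfg.strand == "+" else utr3[1])
        t_site = t_utr_start + 300 + scfg.peak_spacing * i
        g_site = layout.txmap.t2g(t_site)
        apex = layout.txmap.t2g(int(round(t_site - shift)))
        layout.peaks.append(
            TruthPeak(
                gene_id=cfg.gene_id,
                kind="utr3",
                peak_index=i,
                chrom=scfg.chrom,
                strand=cfg.strand,
                polya_pos=g_site,
                apex_pos=apex,
                sigma=float(sigma),
                usage={p: float(mean_usage[p][i]) for p in pops},
                class_prob=peak_share,  # multiplied by usage at sampling time
            )
        )
    if cfg.has_decoy:
        mid = (intron[0] + intron[1]) // 2
        apex = mid - int(shift) if cfg.strand == "+" else mid + int(shift)
        layout.peaks.append(
            TruthPeak(
                gene_id=cfg.gene_id,
                kind="intron_decoy",
                peak_index=n,
                chrom=scfg.chrom,
                strand=cfg.strand,
                polya_pos=mid,
                apex_pos=apex,
                sigma=cfg.decoy_sigma,
                usage={p: 1.0 for p in pops},
                class_prob=cfg.decoy_frac,
            )
        )
    if cfg.junction_frac > 0:
        # a polyA-like site in the 5' exon just upstream of the junction:
        # its spliced reads supply the splice-junction evidence
        t_site = layout.txmap.lengths[0] - 50
        layout.peaks.append(
            TruthPeak(
                gene_id=cfg.gene_id,
                kind="junction_bridge",
                peak_index=-1,
                chrom=scfg.chrom,
                strand=cfg.strand,
                polya_pos=layout.txmap.t2g(t_site),
                apex_pos=layout.txmap.t2g(int(round(t_site - shift))),
                sigma=60.0,
                usage={p: 1.0 for p in pops},
                class_prob=cfg.junction_frac,
            )
        )
    return layout


def _scrub_runs(arr: np.ndarray, base: str, k: int = 13, max_mismatch: int = 1) -> None:
    """Break accidental near-homopolymer runs of `base` in place."""
    hits = (arr == base).astype(np.int64)
    for _ in range(3):
        window = np.convolve(hits, np.ones(k, dtype=np.int64), mode="valid")
        bad = np.flatnonzero(window >= k - max_mismatch)
        if not len(bad):
            break
        for i in bad[:: max(1, k // 2)]:
            arr[i + k // 2] = "G" if base == "A" else "C"
        hits = (arr == base).astype(np.int64)


def _build_genome(layouts: list[GeneLayout], chrom_len: int, rng: np.random.Generator) -> str:
    arr = _BASES[rng.integers(0, 4, size=chrom_len)].copy()
    _scrub_runs(arr, "A")
    _scrub_runs(arr, "T")
    for layout in layouts:
        for peak in layout.peaks:
            # called intervals end ~3 sigma_eff past the coverage apex
            # (sigma_eff folds in the read-length boxcar); place sequence
            # signals where the downstream scan of the called peak will look
            L = READ_LENGTH
            sigma_eff = math.sqrt(peak.sigma**2 + (L * L - 1) / 12.0)
            off = int(round(3 * sigma_eff - (L - 1) / 2.0))
            if peak.kind == "utr3":
                _embed(arr, peak.polya_pos, layout.strand, "AATAAA", offset=off + 20)
            elif peak.kind == "intron_decoy":
                _embed(arr, peak.polya_pos, layout.strand, "A" * 13, offset=off + 10)
    return "".join(arr.tolist())


_COMP = str.maketrans("ACGT", "TGCA")


def _embed(arr: np.ndarray, pos: int, strand: str, motif: str, offset: int) -> None:
    """Place motif `offset` nt downstream of pos in transcription direction."""
    if strand == "+":
        start = pos + offset  # 1-based genomic start of motif
        seq = motif
    else:
        seq = motif.translate(_COMP)[::-1]
        start = pos - offset - len(motif) + 1
    arr[start - 1 : start - 1 + len(seq)] = list(seq)


def _make_barcodes(populations, barcode_len: int, rng: np.random.Generator):
    out: dict[str, list[str]] = {}
    seen: set[str] = set()
    for label, n_cells in populations:
        bcs = []
        while len(bcs) < n_cells:
            bc = "".join(_BASES[rng.integers(0, 4, size=barcode_len)])
            if bc not in seen:
                seen.add(bc)
                bcs.append(bc)
        out[label] = bcs
    return out


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Lay out genes on one chromosome, build the genome and truth tables.

    Deterministic for a given seed: the same config yields byte-identical
    truth tables and genome.
    """
    if not config.genes:
        raise ValueError("at least one gene required")
    for label, n_cells in config.populations:
        if n_cells < 1:
            raise ValueError(f"population {label!r} must have >= 1 cells")
    layouts = []
    cursor = config.gene_gap + 1
    for cfg in config.genes:
        layout = _layout_gene(cfg, config, cursor)
        layouts.append(layout)
        cursor = layout.end + config.gene_gap + 1
    chrom_len = cursor + 500
    rng = np.random.default_rng([config.seed, 11])
    genome = _build_genome(layouts, chrom_len, rng)
    barcodes = _make_barcodes(config.populations, 16, np.random.default_rng([config.seed, 13]))
    truth_rows = []
    for layout in layouts:
        for peak in layout.peaks:
            row = {
                "gene_id": peak.gene_id,
                "kind": peak.kind,
                "peak_index": peak.peak_index,
                "chrom": peak.chrom,
                "strand": peak.strand,
                "polya_pos": peak.polya_pos,
                "apex_pos": peak.apex_pos,
                "sigma": peak.sigma,
                "class_prob": peak.class_prob,
            }
            for label, _ in config.populations:
                row[f"usage_{label}"] = peak.usage.get(label, np.nan)
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return SyntheticScenario(
        config=config,
        chrom=config.chrom,
        chrom_len=chrom_len,
        genes=layouts,
        truth=truth,
        barcodes=barcodes,
        genome=genome,
    )


def _sample_gene_reads(
    layout: GeneLayout,
    scenario: SyntheticScenario,
    gene_index: int,
) -> list[AlignmentRecord]:
    """Draw all reads of one gene across populations (seeded per gene)."""
    scfg = scenario.config
    cfg = layout.config
    rng = np.random.default_rng([scfg.seed, 17, gene_index])
    total_weight = sum(g.weight for g in scfg.genes)
    reads: list[AlignmentRecord] = []
    L = layout.txmap.length
    read_len = scfg.read_length
    total_cells = sum(n for _, n in scfg.populations)

    for label, n_cells in scfg.populations:
        bcs = scenario.barcodes[label]
        if cfg.total_reads is not None:
            n_reads = int(round(cfg.total_reads * n_cells / total_cells))
        else:
            rate = scfg.umi_per_cell * cfg.weight / total_weight
            n_reads = int(rng.poisson(rate * n_cells))
        if n_reads == 0:
            continue
        # split reads across classes: true peaks (by usage), decoy, junction
        classes = [p for p in layout.peaks]
        probs = []
        for p in classes:
            if p.kind == "utr3":
                probs.append(p.class_prob * p.usage[label])
            else:
                probs.append(p.class_prob)
        probs = np.asarray(probs)
        probs = probs / probs.sum()
        counts = rng.multinomial(n_reads, probs)
        for peak, count in zip(classes, counts):
            if count == 0:
                continue
            cell_idx = rng.integers(0, n_cells, size=count)
            umis = _BASES[rng.integers(0, 4, size=(count, 10))]
            if peak.kind in ("utr3", "junction_bridge"):
                t_site = layout.txmap.g2t(peak.polya_pos)
                t_end = np.clip(
                    np.rint(rng.normal(t_site, peak.sigma, size=count)).astype(int),
                    read_len,
                    L,
                )
                for j in range(count):
                    blocks = layout.txmap.interval_blocks(
                        int(t_end[j]) - read_len + 1, int(t_end[j])
                    )
                    reads.append(
                        AlignmentRecord(
                            chrom=layout.chrom,
                            blocks=blocks,
                            strand=layout.strand,
                            cell_barcode=bcs[cell_idx[j]],
                            umi="".join(umis[j]),
                            skips=_skips(blocks),
                        )
                    )
            else:  # intron_decoy: unspliced pre-mRNA reads inside the intron
                pos = np.rint(rng.normal(peak.polya_pos, peak.sigma, size=count)).astype(int)
                s, e = layout.intron
                if layout.strand == "+":
                    pos = np.clip(pos, s + read_len - 1, e)
                    blks = [(int(p) - read_len + 1, int(p)) for p in pos]
                else:
                    pos = np.clip(pos, s, e - read_len + 1)
                    blks = [(int(p), int(p) + read_len - 1) for p in pos]
                for j in range(count):
                    reads.append(
                        AlignmentRecord(
                            chrom=layout.chrom,
                            blocks=[blks[j]],
                            strand=layout.strand,
                            cell_barcode=bcs[cell_idx[j]],
                            umi="".join(umis[j]),
                        )
                    )
    return reads


def _skips(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(blocks, blocks[1:]) if s2 > e1 + 1
    ]


def iter_gene_records(scenario: SyntheticScenario) -> Iterator[tuple[str, list[AlignmentRecord]]]:
    """Yield (gene_id, reads) per gene; memory-friendly for deep fixtures."""
    for i, layout in enumerate(scenario.genes):
        yield layout.gene_id, _sample_gene_reads(layout, scenario, i)


def write_gtf(scenario: SyntheticScenario, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for layout in scenario.genes:
            gid = layout.gene_id
            tid = f"{gid}.t1"
            attrs_g = f'gene_id "{gid}";'
            attrs_t = f'gene_id "{gid}"; transcript_id "{tid}";'
            rows = [("gene", layout.start, layout.end, attrs_g),
                    ("transcript", layout.start, layout.end, attrs_t)]
            for s, e in (layout.exon1, layout.exon2):
                rows.append(("exon", s, e, attrs_t))
            rows.append(("CDS", layout.exon1[0], layout.exon1[1], attrs_t))
            rows.append(("CDS", layout.cds2[0], layout.cds2[1], attrs_t))
            rows.append(("three_prime_utr", layout.utr3[0], layout.utr3[1], attrs_t))
            for ftype, s, e, attrs in rows:
                fh.write(
                    f"{layout.chrom}\tscapa_sim\t{ftype}\t{s}\t{e}\t.\t{layout.strand}\t.\t{attrs}\n"
                )


def write_fixture_files(scenario: SyntheticScenario, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write genome.fa(+.fai), genes.gtf, reads.bam(+.bai), whitelist.tsv,
    populations.tsv and truth_peaks.tsv; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "genome.fa",
        "gtf": out_dir / "genes.gtf",
        "bam": out_dir / "reads.bam",
        "whitelist": out_dir / "whitelist.tsv",
        "populations": out_dir / "populations.tsv",
        "truth": out_dir / "truth_peaks.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{scenario.chrom}\n")
        for i in range(0, len(scenario.genome), 70):
            fh.write(scenario.genome[i : i + 70] + "\n")
    Faidx(str(paths["fasta"]))
    write_gtf(scenario, paths["gtf"])
    with open(paths["whitelist"], "w") as fh:
        for label in scenario.barcodes:
            for bc in scenario.barcodes[label]:
                fh.write(bc + "\n")
    with open(paths["populations"], "w") as fh:
        fh.write("barcode\tpopulation\n")
        for bc, label in scenario.population_map.items():
            fh.write(f"{bc}\t{label}\n")
    scenario.truth.to_csv(paths["truth"], sep="\t", index=False)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": scenario.chrom, "LN": scenario.chrom_len}],
    }
    all_reads: list[tuple[int, AlignmentRecord, str]] = []
    for gene_id, recs in iter_gene_records(scenario):
        for i, rec in enumerate(recs):
            all_reads.append((rec.blocks[0][0], rec, f"{gene_id}.r{i}"))
    all_reads.sort(key=lambda t: (t[0], t[2]))
    with pysam.AlignmentFile(str(paths["bam"]), "wb", header=header) as bam:
        for _, rec, qname in all_reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.reference_name = scenario.chrom
            a.reference_start = rec.blocks[0][0] - 1
            a.flag = 16 if rec.strand == "-" else 0
            a.mapping_quality = 255
            cigar = []
            for k, (s, e) in enumerate(rec.blocks):
                if k:
                    gap = s - rec.blocks[k - 1][1] - 1
                    cigar.append((3, gap))
                cigar.append((0, e - s + 1))
            a.cigartuples = cigar
            aligned_len = sum(e - s + 1 for s, e in rec.blocks)
            a.query_sequence = "A" * aligned_len
            a.set_tag("CB", rec.cell_barcode)
            a.set_tag("UB", rec.umi)
            bam.write(a)
    pysam.index(str(paths["bam"]))
    return paths


# ---------------------------------------------------------------------------
# ready-made scenario configurations


def default_scenario(seed: int = 1) -> ScenarioConfig:
    """Six genes, two populations of 300 cells, one usage-switching gene
    and one intronic internal-priming decoy; the end-to-end smoke fixture."""
    genes = [
        GeneConfig("G01", "+", sigmas=(100, 100),
                   usage={"A": [0.8, 0.2], "B": [0.2, 0.8]}, junction_frac=0.06),
        GeneConfig("G02", "-", sigmas=(100, 110),
                   usage={"A": [0.5, 0.5], "B": [0.5, 0.5]}, junction_frac=0.06),
        GeneConfig("G03", "+", sigmas=(120, 130),
                   usage={"A": [0.5, 0.5], "B": [0.5, 0.5]},
                   has_decoy=True, decoy_frac=0.10, junction_frac=0.06),
        GeneConfig("G04", "-", sigmas=(90, 100),
                   usage={"A": [0.4, 0.6], "B": [0.4, 0.6]}, junction_frac=0.06),
        GeneConfig("G05", "+", sigmas=(100, 100, 120),
                   usage={"A": [0.4, 0.3, 0.3], "B": [0.4, 0.3, 0.3]}, junction_frac=0.06),
        GeneConfig("G06", "+", sigmas=(100, 140),
                   usage={"A": [0.6, 0.4], "B": [0.6, 0.4]}, junction_frac=0.06),
    ]
    return ScenarioConfig(
        genes=genes, populations=[("A", 300), ("B", 300)], umi_per_cell=60.0, seed=seed
    )


def peak_recovery_scenario(seed: int = 1, n_genes: int = 20, reads_per_gene: int = 50_000) -> ScenarioConfig:
    """Deep single-population fixture for peak-recovery benchmarking:
    n_genes genes with 2-4 polyA sites each (sigma 60-150), 50k reads per
    gene, a quarter of genes carrying an intronic decoy."""
    rng = np.random.default_rng([seed, 23])
    genes = []
    for i in range(n_genes):
        has_decoy = i % 4 == 0
        n_peaks = int(rng.integers(2, 5))
        if n_peaks == 2:
            # a dominant narrow peak would push the coverage-proportional
            # junction filter above the bridge support; keep 2-peak genes wide
            sigmas = [float(rng.uniform(100, 150)) for _ in range(2)]
            usage = [0.5, 0.5]
        else:
            sigmas = [float(rng.uniform(60, 150)) for _ in range(n_peaks)]
            base = [0.4, 0.3, 0.3] if n_peaks == 3 else [0.3, 0.25, 0.25, 0.2]
            usage = list(rng.permutation(base))
        genes.append(
            GeneConfig(
                gene_id=f"G{i + 1:02d}",
                strand="+" if i % 2 == 0 else "-",
                sigmas=sigmas,
                usage={"A": usage},
                has_decoy=has_decoy,
                decoy_frac=0.08,
                junction_frac=0.07,
                total_reads=reads_per_gene,
            )
        )
    return ScenarioConfig(genes=genes, populations=[("A", 400)], seed=seed)


def simulate_two_bin_pseudobulk(
    props_a: Sequence[Sequence[float]],
    props_b: Sequence[Sequence[float]],
    mean_total: float = 400.0,
    n_reps: int = 6,
    nb_alpha: float = 0.05,
    seed: int = 1,
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Simulate pseudo-bulk peak counts for genes with known usage.

    props_a[g] / props_b[g] give the per-peak usage proportions of gene g
    in populations A and B. Each count is NB with mean
    mean_total * proportion and dispersion nb_alpha. Returns
    (counts, peak_ids, gene_ids, population label per column).
    """
    rng = np.random.default_rng(seed)
    pop_labels = ["A"] * n_reps + ["B"] * n_reps
    peak_ids, gene_ids, rows = [], [], []
    for g, (pa, pb) in enumerate(zip(props_a, props_b)):
        if abs(sum(pa) - 1) > 1e-8 or abs(sum(pb) - 1) > 1e-8:
            raise ValueError("usage proportions must sum to 1")
        for i, _ in enumerate(pa):
            mus = [mean_total * pa[i]] * n_reps + [mean_total * pb[i]] * n_reps
            n_param = 1.0 / nb_alpha
            counts = [
                rng.negative_binomial(n_param, n_param / (n_param + mu)) for mu in mus
            ]
            rows.append(counts)
            peak_ids.append(f"g{g}_p{i}")
            gene_ids.append(f"g{g}")
    return np.asarray(rows, dtype=np.int64), peak_ids, gene_ids, pop_labels
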