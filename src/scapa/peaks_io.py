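"""TSV serialisation of called and merged peaks."""

from __future__ import annotations

import os

import pandas as pd

from .peak_calling import PeakCall
from .peak_merging import MergedPeak, PeakRecord

PEAK_COLUMNS = [
    "peak_id",
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "k",
    "mu",
    "sigma",
    "junction_class",
    "rank",
]


def peaks_to_frame(peaks: list[PeakCall], dataset_id: str | None = None) -> pd.DataFrame:
    rows = [
        {
            "peak_id": p.peak_id,
            "gene_id": p.gene_id,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "strand": p.strand,
            "k": p.fit.k,
            "mu": p.fit.mu,
            "sigma": p.fit.sigma,
            "junction_class": p.junction_class,
            "rank": p.rank,
        }
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    if dataset_id is not None:
        df["dataset_id"] = dataset_id
    return df


def write_peaks_tsv(peaks: list[PeakCall], path: str | os.PathLike, dataset_id=None) -> None:
    peaks_to_frame(peaks, dataset_id).to_csv(path, sep="\t", index=False)


def read_peak_records(path: str | os.PathLike, dataset_id: str | None = None) -> list[PeakRecord]:
    df = pd.read_csv(path, sep="\t")
    ds_col = df["dataset_id"] if "dataset_id" in df else [dataset_id] * len(df)
    return [
        PeakRecord(
            peak_id=row.peak_id,
            gene_id=row.gene_id,
            chrom=str(row.chrom),
            strand=row.strand,
            start=int(row.start),
            end=int(row.end),
            dataset_id=ds,
        )
        for row, ds in zip(df.itertuples(), ds_col)
    ]


def merged_peaks_to_frame(merged: list[MergedPeak]) -> pd.DataFrame:
    datasets = sorted({ds for m in merged for ds in m.source_peak_ids})
    rows = []
    for m in merged:
        row = {
            "peak_id": m.peak_id,
            "gene_id": m.gene_id,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
        }
        for ds in datasets:
            row[f"source_{ds}"] = ";".join(m.source_peak_ids.get(ds, [])) or "."
        rows.append(row)
    return pd.DataFrame(rows)


def write_merged_peaks_tsv(merged: list[MergedPeak], path: str | os.PathLike) -> None:
    merged_peaks_to_frame(merged).to_csv(path, sep="\t", index=False)


def read_merged_peaks_tsv(path: str | os.PathLike) -> list[MergedPeak]:
    df = pd.read_csv(path, sep="\t")
    source_cols = [c for c in df.columns if c.startswith("source_")]
    out = []
    for row in df.itertuples():
        sources = {}
        for col in source_cols:
            val = getattr(row, col)
            if isinstance(val, str) and val != ".":
                sources[col[len("source_"):]] = val.split(";")
        out.append(
            MergedPeak(
                chrom=str(row.chrom),
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                gene_id=row.gene_id,
                source_peak_ids=sources,
            )
        )
    return out
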