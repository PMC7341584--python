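"""Gene models parsed from GTF annotation.

A :class:`GeneModel` is the unit of work for peak calling and annotation:
one gene's transcript structures (exons, CDS, UTRs) on one strand.
Coordinates are 1-based inclusive throughout (GTF convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils

Interval = tuple[int, int]


@dataclass(slots=True)
class TranscriptModel:
    transcript_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        exons = sorted(self.exons)
        out = []
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def coding_exons(self) -> list[Interval]:
        """Exon segments restricted to the CDS extent (empty if non-coding)."""
        if not self.cds:
            return list(sorted(self.exons))
        lo = min(s for s, _ in self.cds)
        hi = max(e for _, e in self.cds)
        out = []
        for s, e in sorted(self.exons):
            s2, e2 = max(s, lo), min(e, hi)
            if s2 <= e2:
                out.append((s2, e2))
        return out


@dataclass(slots=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def utr3_intervals(self) -> list[tuple[str, list[Interval]]]:
        """Per-transcript 3'UTR interval lists, skipping transcripts without one."""
        return [(t.transcript_id, t.utr3) for t in self.transcripts if t.utr3]


def _derive_utrs(tx: TranscriptModel) -> None:
    """Fill utr5/utr3 from exon-vs-CDS extents when the GTF lacks UTR features."""
    if tx.utr3 or tx.utr5 or not tx.cds:
        return
    cds_lo = min(s for s, _ in tx.cds)
    cds_hi = max(e for _, e in tx.cds)
    left, right = [], []
    for s, e in sorted(tx.exons):
        if s < cds_lo:
            left.append((s, min(e, cds_lo - 1)))
        if e > cds_hi:
            right.append((max(s, cds_hi + 1), e))
    if tx.strand == "+":
        tx.utr5, tx.utr3 = left, right
    else:
        tx.utr5, tx.utr3 = right, left


def _classify_utr_feature(ftype: str, tx: TranscriptModel, iv: Interval) -> None:
    ftype = ftype.lower()
    if ftype in ("three_prime_utr", "3utr", "three_prime_UTR".lower()):
        tx.utr3.append(iv)
    elif ftype in ("five_prime_utr", "5utr"):
        tx.utr5.append(iv)
    else:  # bare "UTR": classify by position relative to CDS later
        tx.utr3.append(("UTR", iv))  # type: ignore[arg-type]


def load_gene_models(gtf_path: str | os.PathLike) -> dict[str, GeneModel]:
    """Parse a GTF into GeneModel objects keyed by gene_id.

    Accepts GTFs with or without explicit UTR features; when absent, UTRs
    are derived from CDS vs exon extents. Transcripts without CDS are
    treated as fully exonic (no UTR annotation possible).
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    tx_by_gene: dict[str, dict[str, TranscriptModel]] = {}

    for f in db.all_features():
        ftype = f.featuretype.lower()
        gene_id = (f.attributes.get("gene_id") or [None])[0]
        if gene_id is None:
            continue
        if ftype == "gene":
            genes[gene_id] = GeneModel(gene_id, f.seqid, f.strand, f.start, f.end)
            continue
        tx_id = (f.attributes.get("transcript_id") or [None])[0]
        if tx_id is None:
            continue
        txs = tx_by_gene.setdefault(gene_id, {})
        tx = txs.get(tx_id)
        if tx is None:
            tx = txs[tx_id] = TranscriptModel(tx_id, f.strand)
        iv = (f.start, f.end)
        if ftype == "exon":
            tx.exons.append(iv)
        elif ftype == "cds":
            tx.cds.append(iv)
        elif ftype in ("three_prime_utr", "3utr"):
            tx.utr3.append(iv)
        elif ftype in ("five_prime_utr", "5utr"):
            tx.utr5.append(iv)
        elif ftype == "utr":
            tx.exons = tx.exons  # bare UTR handled below via CDS position
            tx.utr3.append(iv)  # provisional; reclassified next

    for gene_id, txs in tx_by_gene.items():
        for tx in txs.values():
            # reclassify provisional bare-UTR intervals by CDS position
            if tx.cds and tx.utr3:
                cds_lo = min(s for s, _ in tx.cds)
                cds_hi = max(e for _, e in tx.cds)
                utr3, utr5 = [], []
                for s, e in tx.utr3:
                    if (tx.strand == "+" and s > cds_hi) or (
                        tx.strand == "-" and e < cds_lo
                    ):
                        utr3.append((s, e))
                    elif (tx.strand == "+" and e < cds_lo) or (
                        tx.strand == "-" and s > cds_hi
                    ):
                        utr5.append((s, e))
                    else:
                        utr3.append((s, e))
                tx.utr3, tx.utr5 = utr3, tx.utr5 + utr5
            if not tx.exons and tx.cds:
                tx.exons = sorted(tx.cds)
            tx.exons.sort()
            _derive_utrs(tx)
        if gene_id not in genes:
            all_tx = list(txs.values())
            lo = min(t.span[0] for t in all_tx)
            hi = max(t.span[1] for t in all_tx)
            # chrom/strand unknown without a gene line; take from a transcript
            genes[gene_id] = GeneModel(gene_id, "", all_tx[0].strand, lo, hi)
        genes[gene_id].transcripts = sorted(
            txs.values(), key=lambda t: t.transcript_id
        )

    # fill chrom for gene-line-less GTFs via db query
    for f in db.all_features():
        gid = (f.attributes.get("gene_id") or [None])[0]
        if gid in genes and not genes[gid].chrom:
            genes[gid].chrom = f.seqid
    return genes
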