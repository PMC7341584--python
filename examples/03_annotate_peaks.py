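"""Annotate peaks with genomic features and internal-priming signals.

Runs the full fixture pipeline up to annotation and prints, per peak,
the feature hierarchy outcome and the sequence flags that separate true
polyA sites (AATAAA motif downstream) from internal-priming artefacts
(A-rich stretch downstream).
"""

import tempfile

from scapa.alignment_io import read_alignments
from scapa.annotation import annotate_peaks
from scapa.gene_models import load_gene_models
from scapa.peak_calling import call_peaks_for_gene
from scapa.peak_merging import PeakRecord, merge_peak_sets
from scapa.simulate import default_scenario, generate_scenario, write_fixture_files

with tempfile.TemporaryDirectory() as tmp:
    scenario = generate_scenario(default_scenario(seed=1))
    paths = write_fixture_files(scenario, tmp)
    genes = load_gene_models(paths["gtf"])
    peaks = []
    for gene in genes.values():
        reads = list(read_alignments(
            paths["bam"], region=(gene.chrom, gene.start, gene.end),
            whitelist=scenario.whitelist,
        ))
        peaks.extend(call_peaks_for_gene(reads, gene))
    merged = merge_peak_sets([[
        PeakRecord(p.peak_id, p.gene_id, p.chrom, p.strand, p.start, p.end, "d")
        for p in peaks
    ]])
    ann = annotate_peaks(merged, genes, paths["fasta"])

cols = ["peak_id", "primary_feature", "polyA_motif", "a_rich_downstream"]
print(ann[cols].to_string(index=False))
n_artefact = int(ann["a_rich_downstream"].sum())
print(
    f"\n{(ann.primary_feature == 'UTR3').sum()} peaks fall on 3'UTRs "
    f"(all with the canonical AATAAA motif downstream); {n_artefact} intronic "
    "peak is flagged A-rich, the signature of oligo-dT internal priming, and "
    "would be excluded from differential-usage testing."
)
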