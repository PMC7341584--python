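"""Call polyA-site peaks on one synthetic gene and compare with the truth.

Builds a small in-memory fixture (one gene, two polyA sites), runs the
splice-aware Gaussian fit-and-subtract caller and prints each called
peak next to the simulated site it recovers.
"""

from scapa.evaluation import _gene_models_from_scenario
from scapa.simulate import (
    GeneConfig,
    ScenarioConfig,
    generate_scenario,
    iter_gene_records,
)
from scapa.peak_calling import call_peaks_for_gene

config = ScenarioConfig(
    genes=[
        GeneConfig("DEMO", "+", sigmas=(100, 120), usage={"A": [0.6, 0.4]},
                   total_reads=20_000)
    ],
    populations=[("A", 100)],
    seed=11,
)
scenario = generate_scenario(config)
genes = _gene_models_from_scenario(scenario)

(gene_id, reads), = iter_gene_records(scenario)
peaks = call_peaks_for_gene(reads, genes[gene_id])

truth = scenario.truth
print(f"gene {gene_id}: {len(reads)} reads, {len(peaks)} peaks called")
for p in peaks:
    nearest = (truth.apex_pos - p.centre).abs().idxmin()
    row = truth.loc[nearest]
    print(
        f"  peak {p.start}-{p.end} ({p.junction_class}), centre {p.centre}, "
        f"k={p.fit.k:.0f} sigma={p.fit.sigma:.0f} | true {row.kind} apex "
        f"{row.apex_pos} (off by {abs(p.centre - row.apex_pos)} bp)"
    )
print(
    "Each called interval spans centre +/- 3 sigma; centres within a few bp\n"
    "of the true coverage apexes mean the Gaussian model located the sites."
)
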