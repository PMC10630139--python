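"""Benchmark sweep: DA ratios x methods, scored with ASW / PCR / ARI.

Runs the simulation benchmark at a reduced size over two differential-
abundance levels and three methods (confounder-filtered OT, the weighted
variant, and the unfiltered full-OT ablation), and prints the long-format
metric table the `cfot benchmark` CLI command writes as TSV.
"""

from cfot import SimulationConfig
from cfot.evaluate import run_benchmark

cfgs = [SimulationConfig(n_cells=1200, n_confounder_genes=300,
                         n_response_genes=150, n_states=4, seed=s, da_ratio=r)
        for r in (1.0, 0.25) for s in (0,)]
rep = run_benchmark(cfgs)

table = rep.pivot_table(index=["da_ratio", "method"], columns="metric",
                        values="value").round(3)
print(table)
# asw_batch / pcr_score: mixing of the matching embedding across conditions
#   (1 = conditions indistinguishable in confounder space; the filtered
#    methods should beat full_ot here)
# ari_ite: recovery of true response clusters from the ITE matrix
# pcr_ite: independence of the ITE from the cell state (attribution quality)
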