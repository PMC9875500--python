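"""Extract the DNB gene module and check its three-property signature.

The dynamic-network-biomarker module is the set of top-scoring genes at the
critical stage.  Its signature: within-module standard deviation (SD_in)
and correlation (PCC_in) peak at the critical stage while the correlation
with outside genes (PCC_out) dips.
"""

import scle
from scle.dnb import dnb_report
from scle.simulate import SimulationConfig, simulate

STAGES = [f"S{i}" for i in range(1, 7)]

config = SimulationConfig(seed=7)
matrix, labels, network, truth = simulate(config)
series = scle.assemble_stage_series(scle.normalize_log1p(matrix), labels, STAGES)

# size the DNB list to the planted module (top 10% of 200 genes = 20)
profile = scle.stage_scle(series, network, top_fraction=0.10)
scle.detect_critical_stage(profile)
report = dnb_report(series, network, profile, seed=7)

recall = len(report.dnb_genes & truth.planted_module) / len(truth.planted_module)
print(f"DNB module: {len(report.dnb_genes)} genes at stage {profile.critical_stage}")
print(f"recall of the planted 20-gene module: {recall:.2f}")
print(f"first-order DNB neighbors: {len(report.neighbors)} genes")
print()
print(report.statistics.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print(
    "SD_in and PCC_in jump at the critical stage while PCC_out is lowest"
    " there: the module fluctuates strongly and coherently on its own just"
    " before the transition, decoupling from the rest of the network."
)
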