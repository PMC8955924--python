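"""Quantify relative gene expression from RT-qPCR Cq plates by ddCq.

Targets are normalised against the mean Cq of three stable reference genes
(ACT, TIF, TIF-GTP), then compared between a treatment and a control
sample: relative expression = 2^(-ddCq). |log2| > 2 flags a strong change;
a Student t-test on the per-replicate dCq values adds a significance call.
"""

import numpy as np

from berrydeg import relative_expression
from berrydeg.simulate import SimulationConfig, simulate_qpcr

cfg = SimulationConfig(
    seed=42,
    cq_noise_sd=0.1,
    qpcr_fold_changes={"HSP22": 8.0, "APX1": 4.0, "ERF105": 0.25, "AUX22": 1.0},
)
plate = simulate_qpcr(cfg)  # maturation: RM (stress) vs SM (control)
result = relative_expression(plate, "RM", "SM")

print("gene     log2    fold     |log2|>2  p-value   planted log2")
for _, row in result.iterrows():
    true_log2 = np.log2(cfg.qpcr_fold_changes[row["gene_id"]])
    mark = "yes" if row["significant_magnitude"] else "no "
    print(f"{row['gene_id']:<8} {row['log2_expression']:+.2f}  "
          f"{row['relative_expression']:7.2f}   {mark}      "
          f"{row['p_value']:.4f}    {true_log2:+.2f}")
# Recovered log2 values sit within the 0.1-cycle noise of the planted truth;
# only genes beyond the 4-fold (|log2| > 2) threshold are flagged by magnitude.
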