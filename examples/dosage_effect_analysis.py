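"""Copy-number dosage effect on expression across a small population.

Builds a gene x accession copy-number matrix, simulates TPM with per-gene
linear dosage models (positive, negative, and null), runs the selection
filters (fold >= 1.1, outlier removal, >= 3 replicates per CN group, V_ST
cap), and classifies each gene's correlation at BH-adjusted p < 0.05.
"""

import numpy as np
import pandas as pd

import copyvar as cv
from copyvar.dosage import GeneCopyNumberMatrix

rng = np.random.default_rng(1)
n_acc = 60
accs = [f"acc{i}" for i in range(n_acc)]
genes = ["dosage_up", "dosage_down", "no_effect"]
cn = pd.DataFrame(
    rng.choice([1, 2, 3], size=(3, n_acc), p=[0.5, 0.3, 0.2]),
    index=genes, columns=accs,
)
model = {
    "dosage_up": (12.0, 3.0, 20.0),    # slope, noise sd, baseline
    "dosage_down": (-12.0, 3.0, 60.0),
    "no_effect": (0.0, 3.0, 30.0),
}
tpm = cv.simulate_dosage_expression(cn, model, seed=1)

grouped = cv.select_genes_for_correlation(GeneCopyNumberMatrix(cn), tpm)
result = cv.correlate_dosage(grouped)
print(result.table[["r", "p_adj", "class"]].to_string())

rates = cv.expression_increase_rates(grouped["dosage_up"])
print("\nexpression increase of the positively correlated gene:")
print(rates.to_string(index=False))
# dup_cn1_pct compares each duplicated state with the single-copy mean;
# add_cn1_pct is the per-added-copy increment on the same denominator.
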