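"""Rank overexpressed genes with the Metric and filter on FPKM.

Metric = log2fc - FDR/0.05 (clamped at zero), defined only for genes with
FDR < 0.05 and log2fc > 0.  A gene is actionable when its average absolute
expression passes 10 FPKM; values within 10% below the cutoff are flagged
borderline.
"""

import pandas as pd

from dimertarget import compute_metric, rank_targets

print("Metric(log2fc=3, fdr=0.01) =", compute_metric(3.0, 0.01))   # 3 - 0.2 = 2.8
print("Metric(log2fc=2, fdr=0.05) =", compute_metric(2.0, 0.05))   # None: not significant

de = pd.DataFrame(
    {
        "log2fc": [3.0, 2.5, 1.2, 4.0, -2.0],
        "fdr": [0.001, 0.02, 0.04, 0.20, 0.001],
    },
    index=pd.Index(["ITGA6", "ITGB4", "ITGAV", "ITGA2", "ITGB2"], name="gene"),
)
fpkm = pd.Series({"ITGA6": 55.0, "ITGB4": 9.5, "ITGAV": 80.0, "ITGA2": 30.0, "ITGB2": 12.0})

ranked = rank_targets(de, fpkm, cutoff=10)
print(ranked.round(3).to_string(index=False))
# ITGA2 (FDR 0.2) and ITGB2 (underexpressed) never enter the ranking;
# ITGB4 at 9.5 FPKM is borderline - near the cutoff but not eligible.
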