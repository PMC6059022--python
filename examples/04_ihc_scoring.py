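"""Quantify ordinal IHC staining tallies and call protein overexpression.

Staining descriptors map to not detected=0, low=0.33, medium=0.66, high=1;
the tumor cohort's weighted average is compared (strict '>') with the
single level assigned to normal tissue.
"""

import pandas as pd

from dimertarget import score_table

tallies = pd.DataFrame(
    [
        # gene, cancer, nd, low, med, high, normal level
        ("ITGA6", "liver", 0, 1, 3, 8, "low"),
        ("ITGB1", "liver", 2, 5, 4, 1, "medium"),
        ("ITGB4", "liver", 0, 0, 6, 0, "medium"),   # equality -> not overexpressed
    ],
    columns=["gene", "cancer", "n_not_detected", "n_low", "n_medium",
             "n_high", "normal_level"],
)
scores = score_table(tallies, genes=["ITGA6", "ITGB1", "ITGB4", "ITGA4"], cancers=["liver"])
print(scores.round(4).to_string(index=False))
# ITGA6: weighted average (0.33+3*0.66+8)/12 = 0.86 > 0.33 -> overexpressed.
# ITGB4 ties its normal level exactly (0.66), which is NOT overexpression.
# ITGA4 has no tally at all and is emitted as reason=no_data.
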