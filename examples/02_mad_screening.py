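"""MAD-based outlier scoring of a small hazard-quotient matrix.

The On statistic counts how many median-absolute-deviations a value lies
from its chemical's median across positions; positions exceeding the cutoff
on some chemical are possible point sources.
"""

import numpy as np
import pandas as pd

import sedsource as ss

values = [1.0, 2.0, 3.0, 4.0, 100.0]
print(f"values = {values}")
print(f"MAD = {ss.mad(values)}  (median 3, |deviations| [2,1,0,1,97], median 1)")
print(f"On(100) = {ss.on_score(100.0, values)}  (|100-3|/1)")

# a 6-position, 3-chemical quotient matrix with one contaminated cell
data = pd.DataFrame(
    {
        "cadmium": [0.40, 0.42, 0.38, 0.41, 0.39, 6.0],  # spike at P6
        "lead": [0.50, 0.55, 0.45, 0.52, 0.48, 0.50],
        "pyrene": [0.30, 0.31, 0.29, 0.30, 0.31, 0.30],
    },
    index=[f"P{i}" for i in range(1, 7)],
)
matrix = ss.ContaminationMatrix(data, value_kind="hq")
report = ss.identify_point_sources(matrix, cutoff=4.0)
print("\nflagged positions and offending chemicals:")
for p in report.ordered_sources:
    chems = report.per_source_chemicals[p]
    scores = [f"{c} (On={report.scores.loc[p, c]:.0f})" for c in chems]
    print(f"  {p}: {', '.join(scores)}")
# P6 is flagged for cadmium only: one anomalous cell identifies both the
# suspect position and the chemical pointing at the discharge type.
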