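"""Ratio-matching: dilution-invariant fingerprints and band clustering.

Two samples fed by the same source keep the same inter-chemical
concentration ratios even when one is diluted; comparing the upper-triangular
ratio matrices elementwise and accepting quotients within 0.90-1.10 links
same-source positions into clusters.
"""

import numpy as np
import pandas as pd

import sedsource as ss
from sedsource.ratios import compare, ratio_matrix

chems = ["chrysene", "pyrene", "hc_gt12"]
source_sample = {"chrysene": 0.4, "pyrene": 0.5, "hc_gt12": 3.5}
diluted = {c: v / 3 for c, v in source_sample.items()}  # same source, 3x diluted
other = {"chrysene": 0.4, "pyrene": 2.0, "hc_gt12": 0.2}  # a different fingerprint

fp_a = ratio_matrix(source_sample, chems)
fp_b = ratio_matrix(diluted, chems)
fp_c = ratio_matrix(other, chems)

print("same source, 3x dilution:  in-band fraction =", compare(fp_a, fp_b).in_band_fraction)
print("different fingerprint:     in-band fraction =", round(compare(fp_a, fp_c).in_band_fraction, 2))

# four positions: two dilutions of each of two signatures
rows = {
    "A1": source_sample,
    "A2": diluted,
    "B1": other,
    "B2": {c: 5 * v for c, v in other.items()},
}
data = pd.DataFrame(rows).T[chems]
matrix = ss.ContaminationMatrix(data, value_kind="raw")
cs = ss.cluster(matrix, band=(0.90, 1.10), link_threshold=0.9)
print("clusters:", [sorted(c) for c in cs.clusters], "singletons:", cs.singletons)
# The A positions cluster together and the B positions cluster together:
# absolute levels differ by 3x and 5x, but the ratio fingerprints match.
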