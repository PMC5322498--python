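"""Detection thresholds and GFP-normalised clone sizes on a toy table.

The noise cutoff is 1 / (number of GFP+ cells transplanted); a clone's
size in a lineage is its read fraction divided by the GFP+ donor fraction
of that lineage.
"""

import pandas as pd

import clonetrace as ct

# the two transplant designs of the reference study
print("young: 1,000 cells x 31% ->",
      f"threshold 1/{round(1000 * 0.31)} = {ct.detection_threshold(1000, 0.31):.4g}")
print("aged:  6,900 cells x 29% ->",
      f"threshold 1/{round(6900 * 0.29)} = {ct.detection_threshold(6900, 0.29):.4g}")

counts = pd.DataFrame(
    [
        ("m1", "B", "CLONE_A", 620),
        ("m1", "B", "CLONE_B", 310),
        ("m1", "B", "CLONE_C", 69),
        ("m1", "B", "NOISE__", 1),
    ],
    columns=["mouse", "lineage", "barcode", "reads"],
)
sheet = pd.DataFrame(
    [{"mouse": "m1", "group": "young", "lineage": "B", "gfp_fraction": 0.31,
      "n_cells_transplanted": 1000, "transduction_fraction": 0.31}]
)
ab = ct.quantify(counts, sheet)
print()
print(ab[["barcode", "reads", "fraction", "clone_size"]].to_string(index=False))
# NOISE__ (fraction 0.001 < 1/310) is classified as noise and dropped;
# clone_size is the clone's share of the mouse's total donor B-cell output,
# so the per-sample clone sizes sum to fraction_sum / 0.31.
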