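"""Match barcodes recovered from iPS lines back to the transplant data.

iPS clones derived from a barcoded mouse carry the parental clone's
barcode; Sanger-sequenced barcodes are matched against the deep-sequencing
abundances to recover the parental clone type.  Truncated reads (<27 bp)
can only be reported with substring candidates.
"""

import pandas as pd

import clonetrace as ct

# detected abundances for one aged mouse (as produced by quantify())
ab = pd.DataFrame(
    [
        ("aged_1", "M", "ATGCATGCATGCATGCATGCATGCATG", 0.32, 0.42),
        ("aged_1", "E", "ATGCATGCATGCATGCATGCATGCATG", 0.18, 0.21),
        ("aged_1", "M", "GGTTCCAAGGTTCCAAGGTTCCAAGGT", 0.41, 0.54),
        ("aged_1", "B", "GGTTCCAAGGTTCCAAGGTTCCAAGGT", 0.05, 0.06),
        ("aged_1", "E", "GGTTCCAAGGTTCCAAGGTTCCAAGGT", 0.22, 0.26),
    ],
    columns=["mouse", "lineage", "barcode", "fraction", "clone_size"],
)
ab["detected"] = True

queries = [
    "ATGCATGCATGCATGCATGCATGCATG",  # full length, M/E parental clone
    "GGTTCCAAGGTTCCAAGG",           # 18 bp truncated read
    "TTTTTTTTTTTTTTTTTTTTTTTTTTT",  # full length, never seen in blood
]
matches = ct.match_ips_barcode(queries, ab)
cols = ["query", "status", "barcode", "clone_type", "fraction_M", "fraction_E"]
print(matches[cols].to_string(index=False))
# The first line is an exact match inheriting the M/E clone type and its
# per-lineage read fractions; the truncated query reports its substring
# candidate without a type; the last is unaffiliated (no haematopoietic
# lineage could be assigned).
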