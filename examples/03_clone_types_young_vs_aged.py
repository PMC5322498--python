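"""Young vs aged clonal behaviour at the reference study design.

Simulates five young (1,000 cells, 31% transduction) and five aged mice
(6,900 cells, 29% transduction), runs the pipeline from the truth-derived
count table, and prints the paper-style summaries: lineage contributions,
clone-type frequencies (mean +/- s.d. across mice), clone-size
fold-ratios and t-tests.  Takes ~30 s (40 samples at 100k reads each).
"""

import tempfile

import clonetrace as ct

with tempfile.TemporaryDirectory() as tmp:
    sim = ct.simulate_study(tmp, seed=1, error_rate=0.0)
    cfg = ct.PipelineConfig(
        sample_sheet=sim["sample_sheet"], groups=sim["groups"],
        count_table=sim["expected_counts"],
    )
    result = ct.run_pipeline(cfg)

for group in ("young", "aged"):
    frac = result.lineage_fraction[group]
    print(f"{group}: clones contributing per lineage "
          + ", ".join(f"{lin} {100 * frac[lin]:.0f}%" for lin in ct.LINEAGES))

print("\nclone-type frequencies, mean +/- s.d. across mice (%):")
for t in ("M", "M/E", "M/B/T/E"):
    y = result.type_summary["young"].loc[t]
    a = result.type_summary["aged"].loc[t]
    print(f"  {t:8s} young {y['mean']:5.1f} +/- {y['sd']:4.1f}   "
          f"aged {a['mean']:5.1f} +/- {a['sd']:4.1f}")

print("\nyoung:aged fold-difference in mean clone size:")
folds = result.fold_ratios
for lin in ("B", "E", "M"):
    row = folds[(folds["lineage"] == lin) & (folds["group_a"] == "aged")]
    # group_a=aged / group_b=young, so invert for the young-over-aged fold
    print(f"  {lin}: {1 / row['fold'].iloc[0]:.1f}-fold smaller aged clones")

tt = result.tests["lineage_contribution"]
print(f"\nT-lineage contribution t-test: p = {tt.loc['T', 'p']:.2e} "
      f"({'significant' if tt.loc['T', 'significant'] else 'n.s.'})")
# Aged clones skew myeloid (M, M/E types up), largely lose T-cell output,
# and produce 20-40x smaller B/E/M clones under this design.
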