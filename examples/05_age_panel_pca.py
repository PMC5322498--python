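"""Age-signature panel selection and single-cell PCA separation.

Part 1 selects an ageing gene panel from synthetic bulk young/aged
expression (intensity floor 50, fold >= 1.5, enrichment-score leading
edges).  Part 2 simulates single-cell qPCR Ct matrices for young,
mid-aged, aged and iPS-HSC groups, preprocesses them (limit-of-detection
imputation, reference-gene centring) and asks whether iPS-HSC cells
co-locate with young rather than aged cells in PCA space.
"""

import clonetrace as ct

# --- panel selection from bulk arrays (6 per age group) ---
sim = ct.simulate_bulk_expression(seed=2, fold=3.0)
selection = ct.select_age_panel(sim["expr"], sim["labels"])
print(f"candidate genes: {len(selection['up'])} up, {len(selection['down'])} down")
print(f"enrichment scores: up {selection['es_up'].es:+.3f}, "
      f"down {selection['es_down'].es:+.3f}")
print(f"selected panel: {len(selection['panel'])} genes "
      f"(leading edges + reference genes)")

# --- single-cell qPCR arm ---
mat = ct.simulate_ct_matrix(
    {"young": 90, "mid-aged": 90, "aged": 90, "iPS-HSC": 90},
    effect_sizes=ct.default_age_effects(3.0),  # 8-fold age effects
    dropout_rate=0.1,
    seed=3,
)
expr = ct.preprocess_ct(mat)
pca, report = ct.pca_separation(expr, mat.groups.loc[expr.index], k=2)
print(f"\ncells retained after dropout filter: {len(expr)} / {len(mat.values)}")
print("explained variance (PC1, PC2): "
      + ", ".join(f"{v:.1%}" for v in pca.explained_variance_ratio))
d = report["centroid_distances"]
print(f"young|aged centroid distance:    {d['young|aged']:.2f}")
print(f"young|iPS-HSC centroid distance: {d['young|iPS-HSC']:.2f}")
print(f"iPS-HSC cells nearest the young centroid: "
      f"{report['ips_nearest_young_fraction']:.1%} of {report['n_ips_cells']}")
# iPS-HSC cells are drawn from the young distribution, so they cluster
# with young HSCs and away from the age-shifted groups: the age signature
# is erased by reprogramming in this model.
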