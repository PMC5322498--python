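"""Clone abundances: per-sample fractions, noise cutoff, GFP-normalised
clone sizes.

The read count of each barcode is expressed as a fraction of the total
barcode reads in its (mouse, lineage) sample.  A barcode whose fraction
falls strictly below 1 / (number of GFP+ cells transplanted into that
mouse) is classified as noise and removed; survivors are "detected".  A
detected clone's size in a lineage is its fraction divided by the GFP+
fraction among donor cells of that lineage, i.e. the share of the mouse's
total donor output in that lineage attributable to the clone.
"""

from __future__ import annotations

import pandas as pd

ABUNDANCE_COLUMNS = ["mouse", "lineage", "barcode", "fraction", "clone_size", "detected"]


def normalize(count_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample barcode read fractions.

    Input columns: mouse, lineage, barcode, reads.  Output adds ``fraction``
    (reads / total reads of the sample); fractions in each non-empty sample
    sum to 1.  Samples without rows simply produce no entries.
    """
    required = {"mouse", "lineage", "barcode", "reads"}
    if not required.issubset(count_table.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    out = count_table.copy()
    if out.empty:
        out["fraction"] = pd.Series(dtype=float)
        return out
    totals = out.groupby(["mouse", "lineage"])["reads"].transform("sum")
    out["fraction"] = out["reads"] / totals
    return out


def detection_threshold(n_cells_transplanted: int, transduction_fraction: float) -> float:
    """Noise cutoff: 1 / round(cells transplanted x transduction fraction).

    The product is the estimated number of GFP+ (barcoded) cells
    transplanted, rounded to the nearest integer because cell counts are
    integral.  Raises if no GFP+ cell is expected.
    """
    gfp_cells = int(round(n_cells_transplanted * transduction_fraction))
    if gfp_cells < 1:
        raise ValueError(
            "expected number of GFP+ cells transplanted is zero; "
            "detection threshold undefined"
        )
    return 1.0 / gfp_cells


def thresholds_from_sample_sheet(sample_sheet: pd.DataFrame) -> pd.Series:
    """Per-mouse detection thresholds from a sample sheet with columns
    mouse, n_cells_transplanted, transduction_fraction."""
    per_mouse = sample_sheet.drop_duplicates("mouse").set_index("mouse")
    return per_mouse.apply(
        lambda r: detection_threshold(
            int(r["n_cells_transplanted"]), float(r["transduction_fraction"])
        ),
        axis=1,
    )


def apply_noise_filter(abundance: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Remove entries whose fraction is strictly below the mouse's detection
    threshold; survivors get ``detected=True``.

    Fractions are deliberately NOT renormalised afterwards, so clone sizes
    remain comparable across mice (noise is "omitted", not redistributed).
    A fraction exactly at the threshold is kept (strictly-below rule).
    """
    if abundance.empty:
        out = abundance.copy()
        out["detected"] = pd.Series(dtype=bool)
        return out
    thresholds = thresholds_from_sample_sheet(sample_sheet)
    missing = set(abundance["mouse"].unique()) - set(thresholds.index)
    if missing:
        raise KeyError(f"sample sheet missing mice: {sorted(missing)}")
    th = abundance["mouse"].map(thresholds)
    out = abundance.loc[abundance["fraction"] >= th].copy()
    out["detected"] = True
    return out.reset_index(drop=True)


def clone_sizes(abundance: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Clone size = fraction / GFP+ donor fraction of that (mouse, lineage).

    The per-sample sum of clone sizes over all barcodes (before noise
    filtering) is 1 / gfp_fraction.  Raises ``KeyError`` when the sample
    sheet lacks a needed (mouse, lineage) GFP fraction.
    """
    out = abundance.copy()
    if out.empty:
        out["clone_size"] = pd.Series(dtype=float)
        return out
    gfp = sample_sheet.set_index(["mouse", "lineage"])["gfp_fraction"]
    if gfp.index.has_duplicates:
        gfp = gfp[~gfp.index.duplicated()]
    idx = pd.MultiIndex.from_frame(out[["mouse", "lineage"]])
    missing = set(idx) - set(gfp.index)
    if missing:
        raise KeyError(
            f"sample sheet missing gfp_fraction for samples: {sorted(missing)}"
        )
    out["clone_size"] = out["fraction"].to_numpy() / gfp.loc[idx].to_numpy()
    return out


def quantify(count_table: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Full quantification: normalise, noise-filter, clone sizes."""
    ab = normalize(count_table)
    ab = apply_noise_filter(ab, sample_sheet)
    ab = clone_sizes(ab, sample_sheet)
    cols = [c for c in ["mouse", "lineage", "barcode", "reads", "fraction",
                        "clone_size", "detected"] if c in ab.columns]
    return ab[cols]
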