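"""Pipeline orchestration and study-style summary tables.

One call runs counts -> abundances -> clone types and emits the summary
tables the clonal analysis is read from: per-group lineage-contribution
fractions, clone-type frequencies (mean +/- s.d. across mice), per-lineage
average clone sizes with young/aged fold-ratios, and unpaired t-tests per
clone type and lineage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import LINEAGES
from .clonetype import compare_groups, lineage_contribution, summarize_clone_types
from .extract import build_count_table
from .quantify import quantify
from .simulate import BarcodeLibrary


@dataclass
class PipelineConfig:
    """Inputs for a full run.

    Exactly one of ``count_table`` (pre-extracted counts) or ``manifest`` +
    ``library`` (FASTQ extraction path) must be provided.  ``groups`` maps
    every mouse to its donor group label (e.g. young/aged).
    """

    sample_sheet: pd.DataFrame
    groups: Mapping[str, str]
    count_table: pd.DataFrame | None = None
    manifest: pd.DataFrame | None = None
    library: BarcodeLibrary | None = None
    max_flank_mismatch: int = 2
    max_id_mismatch: int = 1
    max_distance: int = 2
    ratio_threshold: float = 1 / 8
    fold_per_mouse: bool = False

    def __post_init__(self) -> None:
        has_counts = self.count_table is not None
        has_fastq = self.manifest is not None and self.library is not None
        if has_counts == has_fastq:
            raise ValueError(
                "provide either count_table or (manifest and library), not both"
            )
        mice = set(self.sample_sheet["mouse"].unique())
        ungrouped = mice - set(self.groups)
        if ungrouped:
            raise ValueError(f"mice without a group: {sorted(ungrouped)}")


@dataclass
class PipelineResult:
    count_table: pd.DataFrame
    abundance: pd.DataFrame
    per_mouse_types: dict[str, pd.DataFrame]
    type_summary: dict[str, pd.DataFrame]
    lineage_fraction: dict[str, pd.Series]
    output_share: dict[str, pd.DataFrame]
    mean_clone_size: pd.DataFrame
    fold_ratios: pd.DataFrame
    tests: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def mean_clone_size_table(
    abundance: pd.DataFrame, groups: Mapping[str, str], per_mouse: bool = False
) -> pd.DataFrame:
    """Mean clone size per (group, lineage) over detected clones.

    ``per_mouse=False`` (default) pools all detected clones of a group;
    ``per_mouse=True`` averages per-mouse means, weighting mice equally.
    """
    ab = abundance.copy()
    ab["group"] = ab["mouse"].map(dict(groups))
    if per_mouse:
        per = ab.groupby(["group", "mouse", "lineage"])["clone_size"].mean()
        out = per.groupby(["group", "lineage"]).mean()
    else:
        out = ab.groupby(["group", "lineage"])["clone_size"].mean()
    return out.unstack("lineage").reindex(columns=list(LINEAGES))


def fold_difference(
    abundance: pd.DataFrame,
    groups: Mapping[str, str],
    lineage: str,
    group_a: str,
    group_b: str,
    per_mouse: bool = False,
) -> float:
    """Ratio of mean clone sizes, group_a over group_b, in one lineage.

    Returns NaN (undefined) when either group has no detected clone in the
    lineage — as happens for T cells in aged recipients, where so few
    T-competent clones persist.
    """
    table = mean_clone_size_table(abundance, groups, per_mouse=per_mouse)
    try:
        a = table.loc[group_a, lineage]
        b = table.loc[group_b, lineage]
    except KeyError:
        return float("nan")
    if pd.isna(a) or pd.isna(b) or b == 0:
        return float("nan")
    return float(a / b)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run counts (or FASTQ extraction) through quantification, clone
    typing and group summaries.  Deterministic given inputs."""
    provenance: dict = {"parameters": {
        "max_flank_mismatch": config.max_flank_mismatch,
        "max_id_mismatch": config.max_id_mismatch,
        "max_distance": config.max_distance,
        "ratio_threshold": config.ratio_threshold,
        "fold_per_mouse": config.fold_per_mouse,
    }}
    stage = "extract"
    try:
        if config.count_table is not None:
            counts = config.count_table
        else:
            counts, extract_prov = build_count_table(
                config.manifest,
                config.library,
                max_flank_mismatch=config.max_flank_mismatch,
                max_id_mismatch=config.max_id_mismatch,
                max_distance=config.max_distance,
                ratio_threshold=config.ratio_threshold,
            )
            provenance["extract"] = extract_prov
        stage = "quantify"
        abundance = quantify(counts, config.sample_sheet)
        stage = "clonetype"
        group_names = sorted(set(config.groups.values()))
        per_mouse_types: dict[str, pd.DataFrame] = {}
        type_summary: dict[str, pd.DataFrame] = {}
        lineage_fraction: dict[str, pd.Series] = {}
        per_mouse_lineage: dict[str, pd.DataFrame] = {}
        output_share: dict[str, pd.DataFrame] = {}
        for g in group_names:
            mice = sorted(m for m, gg in config.groups.items() if gg == g)
            sub = abundance[abundance["mouse"].isin(mice)]
            pm, summ = summarize_clone_types(sub, mice=mice)
            per_mouse_types[g] = pm
            type_summary[g] = summ
            lineage_fraction[g], output_share[g] = lineage_contribution(sub, pooled=True)
            per_mouse_lineage[g], _ = lineage_contribution(sub, pooled=False)
        stage = "report"
        mean_sizes = mean_clone_size_table(
            abundance, config.groups, per_mouse=config.fold_per_mouse
        )
        fold_rows = []
        for i, ga in enumerate(group_names):
            for gb in group_names[i + 1 :]:
                for lin in LINEAGES:
                    fold_rows.append({
                        "group_a": ga, "group_b": gb, "lineage": lin,
                        "fold": fold_difference(
                            abundance, config.groups, lin, ga, gb,
                            per_mouse=config.fold_per_mouse,
                        ),
                    })
        fold_ratios = pd.DataFrame(fold_rows)
        tests: dict[str, pd.DataFrame] = {}
        if len(group_names) == 2:
            ga, gb = group_names
            if len(per_mouse_types[ga]) >= 2 and len(per_mouse_types[gb]) >= 2:
                tests["clone_types"] = compare_groups(
                    per_mouse_types[ga], per_mouse_types[gb]
                )
                tests["lineage_contribution"] = compare_groups(
                    per_mouse_lineage[ga] * 100.0, per_mouse_lineage[gb] * 100.0
                )
        provenance["records"] = {
            "count_rows": int(len(counts)),
            "detected_clone_entries": int(len(abundance)),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return PipelineResult(
        count_table=counts,
        abundance=abundance,
        per_mouse_types=per_mouse_types,
        type_summary=type_summary,
        lineage_fraction=lineage_fraction,
        output_share=output_share,
        mean_clone_size=mean_sizes,
        fold_ratios=fold_ratios,
        tests=tests,
        provenance=provenance,
    )


def write_result(result: PipelineResult, outdir) -> None:
    """Persist a result bundle as TSV tables plus a JSON provenance file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.count_table.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    result.abundance.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    for g, df in result.type_summary.items():
        df.to_csv(outdir / f"clone_types_{g}.tsv", sep="\t")
    for g, s in result.lineage_fraction.items():
        s.to_csv(outdir / f"lineage_contribution_{g}.tsv", sep="\t", header=["fraction"])
    result.mean_clone_size.to_csv(outdir / "mean_clone_size.tsv", sep="\t")
    result.fold_ratios.to_csv(outdir / "fold_ratios.tsv", sep="\t", index=False)
    for name, df in result.tests.items():
        df.to_csv(outdir / f"ttest_{name}.tsv", sep="\t")
    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2, default=str)
    )


def file_checksum(path) -> str:
    """SHA-256 of a file, for provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
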