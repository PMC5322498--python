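"""Lineage-intersection clone typing and group comparison.

Detected barcodes are intersected across the four lineages of each mouse to
assign every clone one of the 15 lineage-combination clone types.  Type
frequencies are tabulated per mouse and summarised as mean +/- s.d. across
the mice of a group; lineage contributions and per-type output shares are
computed from clone sizes; young and aged groups are compared by unpaired
two-tailed t-tests (no multiple-testing correction, matching the original
analysis).  Barcodes recovered from iPS lines are matched back to the
transplant data to recover the parental clone type.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CLONE_TYPES, LINEAGES, clone_type_label

_DNA_RE = re.compile(r"^[ACGT]+$")


def classify_clone(presence: Mapping[str, bool]) -> str:
    """Clone-type label from per-lineage detection flags (canonical M/B/T/E
    order); raises on an all-false clone."""
    return clone_type_label({lin: bool(presence.get(lin, False)) for lin in LINEAGES})


def presence_table(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-(mouse, barcode) lineage detection flags and clone type.

    Expects post-cutoff abundance rows (every row counts as a detection).
    """
    if abundance.empty:
        return pd.DataFrame(columns=["mouse", "barcode", *LINEAGES, "clone_type"])
    flags = (
        abundance.assign(flag=1)
        .pivot_table(index=["mouse", "barcode"], columns="lineage", values="flag",
                     aggfunc="max", fill_value=0)
        .reindex(columns=list(LINEAGES), fill_value=0)
        .astype(int)
        .reset_index()
    )
    flags.columns.name = None
    flags["clone_type"] = [
        classify_clone({lin: bool(r[lin]) for lin in LINEAGES})
        for r in flags.to_dict("records")
    ]
    return flags


def summarize_clone_types(
    abundance: pd.DataFrame, mice: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse clone-type frequencies (%) and their mean +/- s.d.

    Frequencies are percentages of each mouse's detected clones; mice with
    zero detected clones are excluded with a warning.  The s.d. uses the
    n-1 denominator (sample s.d. across mice).  Returns
    ``(per_mouse, summary)`` where ``per_mouse`` is mice x 15 types and
    ``summary`` has columns ``mean`` and ``sd`` indexed by type.
    """
    flags = presence_table(abundance)
    if mice is None:
        mice = sorted(flags["mouse"].unique()) if not flags.empty else []
    kept = []
    for mouse in mice:
        sub = flags[flags["mouse"] == mouse]
        if sub.empty:
            warnings.warn(f"mouse {mouse} has zero detected clones; excluded")
            continue
        freq = (
            sub["clone_type"].value_counts(normalize=True)
            .reindex(CLONE_TYPES, fill_value=0.0) * 100.0
        )
        freq.name = mouse
        kept.append(freq)
    if not kept:
        per_mouse = pd.DataFrame(columns=CLONE_TYPES)
    else:
        per_mouse = pd.DataFrame(kept)
        per_mouse.index.name = "mouse"
    summary = pd.DataFrame(
        {"mean": per_mouse.mean(axis=0), "sd": per_mouse.std(axis=0, ddof=1)}
    ).reindex(CLONE_TYPES)
    return per_mouse, summary


def lineage_contribution(
    abundance: pd.DataFrame, pooled: bool = True
) -> tuple[pd.Series | pd.DataFrame, pd.DataFrame]:
    """Lineage-level views of the detected clone pool.

    Returns ``(clone_fraction, output_share)``:

    * ``clone_fraction`` — for each lineage, the fraction of detected
      clones with detection in that lineage.  ``pooled=True`` pools clones
      across all mice present in ``abundance`` (a clone is one (mouse,
      barcode) pair); ``pooled=False`` returns a mice x lineages frame of
      per-mouse fractions.
    * ``output_share`` — clone types x lineages: each type's share of the
      summed clone sizes in that lineage (columns sum to 1 where any clone
      is detected).
    """
    flags = presence_table(abundance)
    if flags.empty:
        empty = pd.Series(0.0, index=list(LINEAGES))
        return empty, pd.DataFrame(0.0, index=CLONE_TYPES, columns=list(LINEAGES))
    if pooled:
        clone_fraction = flags[list(LINEAGES)].mean(axis=0)
    else:
        clone_fraction = flags.groupby("mouse")[list(LINEAGES)].mean()
    if "clone_size" in abundance.columns:
        typed = abundance.merge(
            flags[["mouse", "barcode", "clone_type"]], on=["mouse", "barcode"]
        )
        sums = typed.pivot_table(
            index="clone_type", columns="lineage", values="clone_size",
            aggfunc="sum", fill_value=0.0,
        ).reindex(index=CLONE_TYPES, columns=list(LINEAGES), fill_value=0.0)
        totals = sums.sum(axis=0)
        output_share = sums.div(totals.where(totals > 0, np.nan), axis=1)
    else:
        output_share = pd.DataFrame(np.nan, index=CLONE_TYPES, columns=list(LINEAGES))
    return clone_fraction, output_share


def compare_groups(
    per_mouse_a: pd.DataFrame, per_mouse_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Unpaired two-tailed t-tests per shared column (clone type or lineage).

    Each input is a mice x metrics frame; requires >= 2 mice per group.  No
    multiple-testing correction is applied (faithful to the original
    statistics); rows are flagged significant at p < ``alpha``.
    """
    if len(per_mouse_a) < 2 or len(per_mouse_b) < 2:
        raise ValueError("each group needs at least 2 mice for a t-test")
    cols = [c for c in per_mouse_a.columns if c in per_mouse_b.columns]
    rows = []
    for col in cols:
        a = per_mouse_a[col].to_numpy(dtype=float)
        b = per_mouse_b[col].to_numpy(dtype=float)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t, p = 0.0, 1.0  # identical constant groups: no evidence
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "metric": col,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


MATCH_EXACT = "exact"
MATCH_TRUNCATED = "truncated"
MATCH_UNAFFILIATED = "unaffiliated"

BARCODE_FULL_LENGTH = 27


def match_ips_barcode(
    queries: Iterable[str], abundance: pd.DataFrame
) -> pd.DataFrame:
    """Match barcodes recovered from iPS lines back to the transplant data.

    Full-length (27 bp) queries are matched exactly against detected
    barcodes and inherit the parental clone type and per-lineage fractions;
    shorter queries are flagged "truncated" and reported with every
    detected barcode containing them as a substring (candidates only, no
    type assignment); full-length queries absent from all lineages are
    "unaffiliated".  Raises on non-ACGT characters or over-length queries.
    """
    flags = presence_table(abundance)
    frac = {}
    if not abundance.empty:
        frac = {
            (m, b): g.set_index("lineage")["fraction"].to_dict()
            for (m, b), g in abundance.groupby(["mouse", "barcode"])
        }
    rows = []
    for q in queries:
        q = str(q).upper()
        if not _DNA_RE.match(q):
            raise ValueError(f"query contains non-ACGT characters: {q!r}")
        if len(q) > BARCODE_FULL_LENGTH:
            raise ValueError(f"query longer than {BARCODE_FULL_LENGTH} bp: {q!r}")
        if len(q) == BARCODE_FULL_LENGTH:
            hits = flags[flags["barcode"] == q] if not flags.empty else flags
            if hits is None or hits.empty:
                rows.append(_match_row(q, MATCH_UNAFFILIATED))
            else:
                for r in hits.to_dict("records"):
                    fr = frac.get((r["mouse"], r["barcode"]), {})
                    rows.append(
                        _match_row(
                            q, MATCH_EXACT, mouse=r["mouse"], barcode=r["barcode"],
                            clone_type=r["clone_type"],
                            **{f"fraction_{lin}": fr.get(lin, np.nan) for lin in LINEAGES},
                        )
                    )
        else:
            cands = (
                flags[flags["barcode"].str.contains(q, regex=False)]
                if not flags.empty
                else flags
            )
            if cands is None or cands.empty:
                rows.append(_match_row(q, MATCH_TRUNCATED))
            else:
                for r in cands.to_dict("records"):
                    rows.append(
                        _match_row(
                            q, MATCH_TRUNCATED, mouse=r["mouse"], barcode=r["barcode"]
                        )
                    )
    cols = ["query", "status", "mouse", "barcode", "clone_type"] + [
        f"fraction_{lin}" for lin in LINEAGES
    ]
    return pd.DataFrame(rows, columns=cols)


def _match_row(query, status, **kw):
    row = {"query": query, "status": status, "mouse": None, "barcode": None,
           "clone_type": None}
    for lin in LINEAGES:
        row[f"fraction_{lin}"] = np.nan
    row.update(kw)
    return row
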