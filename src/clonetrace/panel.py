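"""Ageing gene-panel selection and single-cell age-signature scoring.

Panel selection mirrors a standard microarray screen: drop probes below an
absolute intensity floor in every sample, keep genes with at least a
minimum aged/young fold-change, rank by log2 fold-change and take the
leading edge of a weighted running-sum enrichment statistic for the up- and
down-regulated sets.  The single-cell arm converts qPCR Ct values to a
log2-like expression scale anchored at the limit of detection, centres each
cell on its reference genes, and asks — via PCA and nearest group
centroids — whether iPS-derived HSCs co-locate with young rather than aged
cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .simulate import REFERENCE_GENES, CtMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelConfig:
    """Panel-selection and Ct-preprocessing parameters.

    ``min_expression``: absolute intensity floor — a gene below it in ALL
    samples is treated as noise.  ``min_fold``: minimum aged/young
    fold-change (max of ratio and inverse).  ``es_weight_exponent``: the
    running-sum weight exponent p.  ``lod_ct``: qPCR limit of detection in
    cycles; ``max_dropout``: cells failing more than this fraction of
    non-reference assays are excluded.
    """

    min_expression: float = 50.0
    min_fold: float = 1.5
    es_weight_exponent: float = 1.0
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    lod_ct: float = 30.0
    max_dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.min_fold <= 1.0:
            raise ValueError("min_fold must be > 1")
        if self.min_expression <= 0:
            raise ValueError("min_expression must be positive")
        if self.es_weight_exponent < 0:
            raise ValueError("es_weight_exponent must be >= 0")


def filter_genes(
    expr: pd.DataFrame, labels: pd.Series, config: PanelConfig = PanelConfig()
) -> tuple[list[str], list[str]]:
    """Candidate up-/down-with-age gene sets from a bulk expression matrix.

    ``expr`` is genes x samples; ``labels`` maps sample -> {young, aged}.
    A gene survives iff it exceeds ``min_expression`` in at least one
    sample AND its fold-change (max of aged/young mean ratio and its
    inverse) is >= ``min_fold``.  A zero young mean with non-zero aged mean
    is an infinite fold (retained, logged).
    """
    groups = set(labels.unique())
    if not {"young", "aged"}.issubset(groups):
        raise ValueError("labels must contain both 'young' and 'aged' samples")
    young_cols = labels.index[labels == "young"]
    aged_cols = labels.index[labels == "aged"]
    if len(young_cols) < 2 or len(aged_cols) < 2:
        raise ValueError("need >= 2 samples per age group for fold computation")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    expressed = (expr >= config.min_expression).any(axis=1)
    ym = expr[young_cols].mean(axis=1)
    am = expr[aged_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = am / ym
    inf_mask = (ym == 0) & (am > 0)
    if inf_mask.any():
        logger.info(
            "%d genes have zero young mean and non-zero aged mean; "
            "fold treated as +inf and retained", int(inf_mask.sum()),
        )
    ratio = ratio.where(~inf_mask, np.inf)
    both_zero = (ym == 0) & (am == 0)
    fold = pd.concat([ratio, 1.0 / ratio], axis=1).max(axis=1)
    fold = fold.where(~both_zero, 1.0)
    keep = expressed & (fold >= config.min_fold)
    up = expr.index[keep & (ratio > 1)].tolist()
    down = expr.index[keep & (ratio <= 1)].tolist()
    return up, down


@dataclass
class EnrichmentResult:
    es: float
    leading_edge: list[str]
    running_sum: np.ndarray = field(repr=False)
    peak_index: int = 0


def enrichment_score(
    ranking: pd.Series, gene_set: Sequence[str], p: float = 1.0
) -> EnrichmentResult:
    """Weighted running-sum enrichment score of a gene set in a ranking.

    ``ranking`` maps gene -> ranking statistic, already ordered from most
    up- to most down-regulated.  Walking down the list, hitting a set
    member increments the sum by |stat|^p normalised over the set's
    statistics (at p=0, 1/n_set); a miss decrements by 1/(N - n_set).  The
    enrichment score is the maximal-magnitude excursion; the leading edge
    is the set members at or before the peak (at or after it for a
    negative score).
    """
    genes = list(ranking.index)
    if len(set(genes)) != len(genes):
        raise ValueError("ranking contains duplicate genes")
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = set(gene_set) - set(genes)
    if missing:
        raise ValueError(f"gene set members absent from ranking: {sorted(missing)}")
    n = len(genes)
    n_set = len(gene_set)
    if n_set == n:
        raise ValueError("gene set equals the full ranked list")
    in_set = np.isin(np.array(genes, dtype=object), np.array(gene_set, dtype=object))
    stat = ranking.to_numpy(dtype=float)
    w = np.abs(stat[in_set]) ** p
    total = w.sum()
    if total == 0:  # all set statistics zero: fall back to unweighted steps
        hit_inc = np.full(n_set, 1.0 / n_set)
    else:
        hit_inc = w / total
    steps = np.where(in_set, 0.0, -1.0 / (n - n_set))
    steps[in_set] = hit_inc
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        le = [g for i, g in enumerate(genes) if in_set[i] and i <= peak]
    else:
        le = [g for i, g in enumerate(genes) if in_set[i] and i >= peak]
    return EnrichmentResult(es=es, leading_edge=le, running_sum=running, peak_index=peak)


def rank_by_log2fc(
    expr: pd.DataFrame, labels: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Genes ranked by log2(aged/young mean), descending (ageing-up first)."""
    ym = expr[labels.index[labels == "young"]].mean(axis=1)
    am = expr[labels.index[labels == "aged"]].mean(axis=1)
    lfc = np.log2((am + pseudocount) / (ym + pseudocount))
    return lfc.sort_values(ascending=False)


def select_age_panel(
    expr: pd.DataFrame, labels: pd.Series, config: PanelConfig = PanelConfig()
) -> dict:
    """Full panel selection: filters, enrichment of the up/down sets against
    the log2 fold-change ranking, leading-edge union plus reference genes."""
    up, down = filter_genes(expr, labels, config)
    ranking = rank_by_log2fc(expr, labels)
    out = {"up": up, "down": down}
    leading: list[str] = []
    if up:
        res_up = enrichment_score(ranking, up, p=config.es_weight_exponent)
        out["es_up"] = res_up
        leading += res_up.leading_edge
    if down:
        res_down = enrichment_score(ranking, down, p=config.es_weight_exponent)
        out["es_down"] = res_down
        leading += res_down.leading_edge
    out["panel"] = list(dict.fromkeys(leading)) + [
        g for g in config.reference_genes if g not in leading
    ]
    return out


def preprocess_ct(ct: CtMatrix, config: PanelConfig = PanelConfig()) -> pd.DataFrame:
    """Ct values -> reference-centred expression (cells x non-reference genes).

    Failed reactions are imputed at the limit of detection; expression is
    ``lod_ct - Ct`` (log2-like, higher = more expressed); each cell is
    centred by the mean expression of its reference genes, removing
    cell-level offsets.  Cells with more than ``max_dropout`` failed
    non-reference assays, or with all reference genes failed, are excluded
    (the latter raises, since centring is then undefined).
    """
    refs = [g for g in config.reference_genes if g in ct.values.columns]
    if len(refs) != len(config.reference_genes):
        raise ValueError("reference genes missing from Ct matrix columns")
    panel_genes = [g for g in ct.values.columns if g not in refs]
    vals = ct.values
    all_refs_failed = vals[refs].isna().all(axis=1)
    if all_refs_failed.all():
        raise ValueError("no cell has a measured reference gene; cannot centre")
    if all_refs_failed.any():
        # a cell with zero observed reference reactions cannot be centred;
        # treat like high-dropout cells and exclude it
        logger.warning(
            "excluding %d cells with all reference reactions failed",
            int(all_refs_failed.sum()),
        )
    dropout_frac = vals[panel_genes].isna().mean(axis=1) if panel_genes else 0.0
    keep = (dropout_frac <= config.max_dropout) & ~all_refs_failed
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d cells above %.0f%% assay dropout",
                    n_dropped, 100 * config.max_dropout)
    vals = vals.loc[keep]
    expr = config.lod_ct - vals.fillna(config.lod_ct)
    # centre on the observed reference reactions only: a failed housekeeping
    # assay is a technical dropout, not evidence of absent expression
    ref_expr = config.lod_ct - vals[refs]
    ref_mean = ref_expr.mean(axis=1, skipna=True)
    centred = expr[panel_genes].sub(ref_mean, axis=0)
    return centred


@dataclass
class PcaResult:
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


def pca_separation(
    expr: pd.DataFrame,
    groups: pd.Series,
    k: int = 2,
    *,
    ips_group: str = "iPS-HSC",
    young_group: str = "young",
    aged_group: str = "aged",
) -> tuple[PcaResult, dict]:
    """PCA on per-gene standardised expression plus a separation report.

    The report contains (i) centroid distances between every group pair in
    the top-``k`` score space and (ii) the fraction of ``ips_group`` cells
    whose nearest centroid — young vs aged centroids fit without the iPS
    cells — is the young one.
    """
    groups = groups.loc[expr.index]
    uniq = groups.unique()
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 3).any():
        raise ValueError("need >= 3 cells per group")
    if len(expr) < k:
        raise ValueError("fewer cells than components requested")
    X = expr.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    nonconstant = sd > 0
    Xs = (X[:, nonconstant] - mean[nonconstant]) / sd[nonconstant]
    n_comp = min(k, Xs.shape[0], Xs.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xs)
    score_df = pd.DataFrame(
        scores, index=expr.index, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    loadings = pd.DataFrame(
        pca.components_.T,
        index=expr.columns[nonconstant],
        columns=score_df.columns,
    )
    result = PcaResult(score_df, pca.explained_variance_ratio_, loadings)

    top = score_df.to_numpy()
    centroids = {g: top[(groups == g).to_numpy()].mean(axis=0) for g in uniq}
    pair_dist = {
        f"{a}|{b}": float(np.linalg.norm(centroids[a] - centroids[b]))
        for i, a in enumerate(uniq)
        for b in uniq[i + 1 :]
    }
    report: dict = {"centroid_distances": pair_dist}
    if ips_group in uniq and young_group in uniq and aged_group in uniq:
        ips_mask = (groups == ips_group).to_numpy()
        cy = top[((groups == young_group)).to_numpy()].mean(axis=0)
        ca = top[((groups == aged_group)).to_numpy()].mean(axis=0)
        ips_pts = top[ips_mask]
        d_young = np.linalg.norm(ips_pts - cy, axis=1)
        d_aged = np.linalg.norm(ips_pts - ca, axis=1)
        report["ips_nearest_young_fraction"] = float((d_young < d_aged).mean())
        report["n_ips_cells"] = int(ips_mask.sum())
    return result, report
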