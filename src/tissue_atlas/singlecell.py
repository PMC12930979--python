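"""Cell-type-resolved expression, entropy specificity, and protein-feature
by cell-type enrichment from labelled single-cell count matrices.

Clustering and label assignment are upstream concerns: cell-type labels
arrive as input metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CellMatrix, FeatureAnnotationTable
from .bulk import zscore_rows


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_kept: int
    removed_cell_ids: tuple[str, ...]

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


@dataclass(frozen=True)
class CellTypeProfile:
    """Genes x cell types mean log-normalized expression.

    ``cells_per_type`` counts the cells behind each retained type;
    ``excluded_types`` lists types dropped for having too few cells.
    """

    values: pd.DataFrame
    cells_per_type: Mapping[str, int]
    excluded_types: tuple[str, ...] = ()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class FeatureEnrichmentMatrix:
    """Feature tags x cell types mean within-gene Z, plus gene counts."""

    values: pd.DataFrame
    gene_counts: Mapping[str, int]


@dataclass(frozen=True)
class StageComparison:
    spearman_rho: float
    spearman_p: float
    rank_shift: pd.DataFrame  # per-gene ranks in each stage + delta


def qc_filter(
    cells: CellMatrix,
    min_features: int = 200,
    max_features: int = 6000,
    max_mito: float = 10.0,
) -> tuple[CellMatrix, QCReport]:
    """Keep cells with min_features <= n_features <= max_features and
    percent_mito strictly below ``max_mito`` (percent units)."""
    nf = cells.obs["n_features"].to_numpy()
    mito = cells.obs["percent_mito"].to_numpy(dtype=float)
    keep = (nf >= min_features) & (nf <= max_features) & (mito < max_mito)
    removed = tuple(np.asarray(cells.cell_ids)[~keep])
    return cells.subset_cells(keep), QCReport(cells.n_cells, int(keep.sum()), removed)


def lognormalize(cells: CellMatrix, scale: float = 10_000.0) -> pd.DataFrame:
    """ln(1 + count / cell_total * scale), per cell.

    Invariant to uniform scaling of a cell's counts; cells with zero total
    counts are an error.
    """
    counts = cells.counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = np.asarray(cells.cell_ids)[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    norm = np.log1p(counts / totals[:, None] * scale)
    return pd.DataFrame(norm, index=cells.cell_ids, columns=cells.gene_ids)


def celltype_means(
    normalized: pd.DataFrame,
    labels: Sequence[str],
    min_cells: int = 50,
) -> CellTypeProfile:
    """Mean normalized expression per cell type; scarce types are excluded.

    Types with fewer than ``min_cells`` cells are dropped and recorded in
    ``excluded_types`` rather than silently vanishing.
    """
    labels = np.asarray(list(labels))
    if labels.shape[0] != normalized.shape[0]:
        raise ValueError("one label per cell required")
    counts: dict[str, int] = {}
    for t in labels:
        counts[t] = counts.get(t, 0) + 1
    kept = [t for t in dict.fromkeys(labels) if counts[t] >= min_cells]
    excluded = tuple(t for t in dict.fromkeys(labels) if counts[t] < min_cells)
    cols = {}
    for t in kept:
        cols[t] = normalized.loc[labels == t].mean(axis=0)
    values = pd.DataFrame(cols, index=normalized.columns)
    return CellTypeProfile(values, {t: counts[t] for t in kept}, excluded)


def entropy_specificity(profile: CellTypeProfile) -> pd.DataFrame:
    """Entropy-based specificity per gene over cell types.

    p_c = m_c / sum(m); H = -sum p ln p (0 ln 0 := 0); S = 1 - H / ln(T).
    Genes with zero total signal get NaN for both H and S.
    """
    n_types = len(profile.cell_types)
    if n_types < 2:
        raise ValueError("specificity needs at least two cell types")
    m = profile.values.to_numpy(dtype=float)
    total = m.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = m / total[:, None]
        logp = np.where(p > 0, np.log(p), 0.0)
    h = -(np.where(p > 0, p, 0.0) * logp).sum(axis=1)
    s = 1.0 - h / np.log(n_types)
    h[total == 0] = np.nan
    s[total == 0] = np.nan
    return pd.DataFrame(
        {"entropy": h, "score": s, "n_types": n_types},
        index=profile.values.index,
    )


def aggregate_gene_set(
    profile: CellTypeProfile, gene_set: Sequence[str]
) -> pd.Series:
    """Cumulative (summed) mean expression of a gene set per cell type."""
    if len(gene_set) == 0:
        raise ValueError("gene set must be non-empty")
    missing = set(gene_set) - set(profile.gene_ids)
    if missing:
        raise KeyError(f"genes not in profile: {sorted(missing)}")
    out = profile.values.loc[list(gene_set)].sum(axis=0)
    out.name = "cumulative_score"
    return out


def feature_celltype_enrichment(
    profile: CellTypeProfile, features: FeatureAnnotationTable
) -> FeatureEnrichmentMatrix:
    """Mean within-gene Z per (feature, cell type).

    Each contributing gene's profile is Z-scored across cell types
    (zero-variance genes map to all-zero rows); a feature's row is the mean
    over genes carrying it that are present in the profile. Features with no
    detected gene are omitted with a warning.
    """
    z = zscore_rows(profile.values)
    present = set(profile.gene_ids)
    rows = {}
    gene_counts = {}
    for tag in features.tags:
        genes = [g for g in features.genes_with(tag) if g in present]
        if not genes:
            warnings.warn(f"feature {tag!r} has no detected genes; omitted")
            continue
        rows[tag] = z.loc[genes].mean(axis=0)
        gene_counts[tag] = len(genes)
    if not rows:
        raise ValueError("no feature has any detected gene")
    values = pd.DataFrame(rows).T
    values = values[profile.cell_types]
    return FeatureEnrichmentMatrix(values, gene_counts)


def stage_rank_comparison(
    scores_stage1: pd.Series, scores_stage2: pd.Series
) -> StageComparison:
    """Spearman rank correlation and per-gene rank shifts between stages.

    Only genes present (non-NaN) in both stages are compared; ties are
    mid-ranked.
    """
    common = scores_stage1.dropna().index.intersection(scores_stage2.dropna().index)
    if len(common) < 2:
        raise ValueError("need at least two genes shared between stages")
    x = scores_stage1.loc[common].to_numpy(dtype=float)
    y = scores_stage2.loc[common].to_numpy(dtype=float)
    rho, p = stats.spearmanr(x, y)
    rank1 = stats.rankdata(x)
    rank2 = stats.rankdata(y)
    shift = pd.DataFrame(
        {"rank_stage1": rank1, "rank_stage2": rank2, "rank_delta": rank2 - rank1},
        index=common,
    )
    return StageComparison(float(rho), float(p), shift)
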