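"""Tissue-enrichment analysis of a multi-tissue bulk FPKM matrix.

The stage identifies genes selectively expressed in a target tissue via a
triple filter (effect size, adjusted p-value, expression floor), scores
per-gene tissue specificity (tau), and provides the Z-profile / gene-set
score / PCA helpers used for downstream summaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, SampleTable


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Triple-filter cutoffs; all inequalities are strict."""

    min_log2fc: float = 0.58
    max_padj: float = 0.05
    min_target_fpkm: float = 0.1

    def __post_init__(self) -> None:
        if self.max_padj <= 0 or self.min_target_fpkm < 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class TissueMeans:
    """Per-gene mean FPKM per tissue (replicates averaged)."""

    values: pd.DataFrame  # genes x tissues

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class PCAEmbedding:
    ids: list[str]
    coordinates: np.ndarray  # observations x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        ev = self.explained_variance_ratio
        if np.any(ev < -1e-12) or np.any(ev > 1 + 1e-12):
            raise ValueError("explained-variance fractions must be in [0, 1]")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")


def select_rik_protein_coding(
    matrix: ExpressionMatrix, name_pattern: str = r"Rik$"
) -> ExpressionMatrix:
    """Retain genes whose name matches ``name_pattern`` and whose biotype is
    ``protein_coding``. Order is preserved; an empty result warns."""
    if matrix.annotation is None:
        raise ValueError("gene annotation required for biotype filtering")
    names = matrix.annotation.name_of()
    biotypes = matrix.annotation.biotype_of()
    pat = re.compile(name_pattern)
    keep = [
        g
        for g in matrix.gene_ids
        if pat.search(names.get(g, g)) and biotypes.get(g) == "protein_coding"
    ]
    if not keep:
        warnings.warn("no protein-coding genes matched the identifier pattern")
    return matrix.subset_genes(keep)


def tissue_means(matrix: ExpressionMatrix) -> TissueMeans:
    """Arithmetic mean of FPKM over the replicates of each tissue."""
    cols = {}
    for tissue in matrix.sample_table.tissues:
        samples = matrix.sample_table.samples_of(tissue)
        cols[tissue] = matrix.values[samples].mean(axis=1)
    return TissueMeans(pd.DataFrame(cols, index=matrix.values.index))


def log2fc_one_vs_rest(
    means: TissueMeans, target: str, pseudocount: float = 0.01
) -> pd.Series:
    """log2((target mean + eps) / (mean of the other tissues' means + eps)).

    "Rest" is the unweighted mean over the other tissues' per-tissue means,
    i.e. every non-target tissue counts equally regardless of replicate
    number.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if target not in means.tissue_ids:
        raise KeyError(f"unknown tissue: {target!r}")
    others = [t for t in means.tissue_ids if t != target]
    if not others:
        raise ValueError("one-vs-rest needs at least two tissues")
    t = means.values[target]
    rest = means.values[others].mean(axis=1)
    out = np.log2((t + pseudocount) / (rest + pseudocount))
    out.name = "log2fc"
    return out


def _welch_pvalues(target_vals: np.ndarray, rest_vals: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(target_vals, rest_vals, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: Welch t is 0/0; define p by the means
    nan = ~np.isfinite(p)
    if nan.any():
        same = np.isclose(target_vals.mean(axis=1), rest_vals.mean(axis=1))
        p[nan & same] = 1.0
        p[nan & ~same] = 0.0
    return p


def _moderated_pvalues(
    target_vals: np.ndarray,
    rest_vals: np.ndarray,
    prior_df: float,
    trend_window: int | None = None,
) -> np.ndarray:
    """Pooled-variance t with the per-gene variance squeezed toward a
    mean-dependent trend (running median over genes ranked by average
    expression), in the spirit of empirical-Bayes moderated statistics.

    With only two target replicates a per-gene variance estimate is too
    noisy to be usable; borrowing strength across genes restores power while
    keeping the test two-sided and calibrated.
    """
    n1 = target_vals.shape[1]
    n2 = rest_vals.shape[1]
    m1 = target_vals.mean(axis=1)
    m2 = rest_vals.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((target_vals - m1[:, None]) ** 2).sum(axis=1) + (
        (rest_vals - m2[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df
    amean = np.concatenate([target_vals, rest_vals], axis=1).mean(axis=1)
    order = np.argsort(amean, kind="stable")
    if trend_window is None:
        trend_window = max(101, len(s2) // 50) | 1
    trend_window = min(trend_window, max(1, len(s2)) | 1)
    s0_sorted = (
        pd.Series(s2[order])
        .rolling(trend_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    s0 = np.empty_like(s0_sorted)
    s0[order] = s0_sorted
    s2_mod = (prior_df * s0 + df * s2) / (prior_df + df)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    nan = ~np.isfinite(p)
    if nan.any():  # se == 0: all values constant in a neighbourhood
        same = np.isclose(m1, m2)
        p[nan & same] = 1.0
        p[nan & ~same] = 0.0
    return p


def enrichment_test(
    matrix: ExpressionMatrix,
    target: str,
    method: str = "moderated",
    prior_df: float = 100.0,
) -> pd.Series:
    """Two-sided one-vs-rest test on log2(FPKM + 1) per gene.

    ``method="welch"`` is a plain Welch t-test (target replicates vs all
    other samples pooled); ``method="moderated"`` (default) shrinks per-gene
    variances toward a mean-expression trend before the pooled t-test.
    Genes with zero variance in both groups and equal means get p = 1.
    """
    samples_t = matrix.sample_table.samples_of(target)
    samples_r = [s for s in matrix.sample_ids if s not in set(samples_t)]
    if len(samples_t) < 2 or len(samples_r) < 2:
        raise ValueError(
            "enrichment test needs >= 2 target replicates and >= 2 other samples"
        )
    logx = np.log2(matrix.values.to_numpy(dtype=float) + 1.0)
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    tv = logx[:, [cols[s] for s in samples_t]]
    rv = logx[:, [cols[s] for s in samples_r]]
    if method == "welch":
        p = _welch_pvalues(tv, rv)
    elif method == "moderated":
        p = _moderated_pvalues(tv, rv, prior_df=prior_df)
    else:
        raise ValueError(f"unknown test method: {method!r}")
    return pd.Series(np.clip(p, 0.0, 1.0), index=matrix.values.index, name="pvalue")


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment (original order preserved)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="padj")
    return out


def compute_tau(means: TissueMeans, transform: str = "log2") -> pd.Series:
    """Tissue-specificity index tau on transformed per-tissue means.

    tau = sum_t (1 - y_t / max_t y) / (T - 1), with y = log2(mean + 1) by
    default (``transform="none"`` uses the means as given). Genes whose
    transformed maximum is 0 have undefined tau and are reported as NaN.
    """
    if len(means.tissue_ids) < 2:
        raise ValueError("tau needs at least two tissues")
    x = means.values.to_numpy(dtype=float)
    if transform == "log2":
        y = np.log2(x + 1.0)
    elif transform == "none":
        y = x.copy()
    else:
        raise ValueError(f"unknown transform: {transform!r}")
    ymax = y.max(axis=1)
    n_t = y.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - y / ymax[:, None]).sum(axis=1) / (n_t - 1)
    tau[ymax == 0] = np.nan
    return pd.Series(tau, index=means.values.index, name="tau")


def compute_enrichment(
    matrix: ExpressionMatrix,
    target: str,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
    pseudocount: float = 0.01,
    method: str = "moderated",
) -> pd.DataFrame:
    """Full per-gene enrichment table for one target tissue.

    Columns: log2fc, pvalue, padj, mean_target_fpkm, tau, enriched.
    """
    means = tissue_means(matrix)
    log2fc = log2fc_one_vs_rest(means, target, pseudocount)
    pvalue = enrichment_test(matrix, target, method=method)
    padj = bh_adjust(pvalue)
    tau = compute_tau(means)
    records = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "mean_target_fpkm": means.values[target],
            "tau": tau,
        }
    )
    records["enriched"] = (
        (records["log2fc"] > thresholds.min_log2fc)
        & (records["padj"] < thresholds.max_padj)
        & (records["mean_target_fpkm"] > thresholds.min_target_fpkm)
    )
    records.index.name = "gene_id"
    return records


def filter_enriched(
    records: pd.DataFrame,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> list[str]:
    """Genes passing all three strict thresholds, in record order."""
    mask = (
        (records["log2fc"] > thresholds.min_log2fc)
        & (records["padj"] < thresholds.max_padj)
        & (records["mean_target_fpkm"] > thresholds.min_target_fpkm)
    )
    return list(records.index[mask])


def zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Row-standardise (sample sd, ddof=1); zero-variance rows map to 0."""
    x = frame.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=frame.index, columns=frame.columns)


def gene_set_score(means: TissueMeans, gene_set: list[str]) -> pd.Series:
    """Per-tissue mean of the gene set's row-Z of log2(mean FPKM + 1).

    The resulting profile sums to ~0 across tissues (Z rows are centred).
    """
    if not gene_set:
        raise ValueError("gene set must contain at least one gene")
    missing = set(gene_set) - set(means.gene_ids)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)}")
    z = zscore_rows(np.log2(means.values + 1.0))
    profile = z.loc[list(gene_set)].mean(axis=0)
    profile.name = "gene_set_score"
    return profile


def pca_embed(values: pd.DataFrame, n_components: int = 2) -> PCAEmbedding:
    """Centred-SVD principal components of the rows of ``values``.

    Deterministic up to nothing: the sign of each component is fixed so the
    largest-magnitude loading is positive.
    """
    ids = list(values.index)
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    total = (s**2).sum()
    ratios = (s**2) / total if total > 0 else np.zeros_like(s)
    k = min(n_components, s.size)
    return PCAEmbedding(ids, u[:, :k] * s[:k], ratios[:k])


def select_top_genes(records: pd.DataFrame, n: int) -> list[str]:
    """Top ``n`` genes by log2fc; ties broken by lexicographic gene_id."""
    keyed = sorted(
        zip(records.index.astype(str), records["log2fc"]),
        key=lambda gv: (-gv[1], gv[0]),
    )
    return [g for g, _ in keyed[:n]]
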