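"""Synthetic data generators with planted ground truth.

Three generators mirror the pipeline's three input layers:

* :func:`simulate_bulk` — negative-binomial bulk FPKM over tissues with a
  minority of strongly target-enriched genes planted;
* :func:`simulate_sc` — labelled single-cell counts with planted cell-type
  markers, planted feature/cell-type couplings, and recorded QC violators;
* :func:`simulate_protein_family` — a protein family diverging along a
  dated tree under a uniform substitution model with a closed-form expected
  pairwise identity (used as a test oracle).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AMINO_ACIDS,
    Alignment,
    CellMatrix,
    ExpressionMatrix,
    FeatureAnnotationTable,
    GeneAnnotation,
    SampleTable,
)
from .io_formats import read_newick

DEFAULT_TISSUES = (
    "retina",
    "eye",
    "brain",
    "heart",
    "liver",
    "kidney",
    "lung",
    "spleen",
    "muscle",
    "testis",
)

DEFAULT_CELL_TYPES = (
    "rod",
    "cone",
    "bipolar",
    "amacrine",
    "horizontal",
    "muller",
    "rgc",
    "microglia",
)

DEFAULT_FEATURE_MAP: dict[str, str] = {
    "SRCR": "cone",
    "CUB": "cone",
    "BTB": "amacrine",
    "helical": "amacrine",
    "NTR": "muller",
    "bromodomain": "muller",
    "KRAB": "bipolar",
}

#: six-taxon ultrametric tree (branch lengths in arbitrary time units,
#: shaped like a mammalian radiation; total depth 90).
DEFAULT_TREE_NEWICK = (
    "(((mouse:20,rat:20):62,rabbit:82):8,((human:28,macaque:28):32,pig:60):30);"
)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# bulk
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkTruth:
    """Planted structure behind a simulated bulk matrix."""

    enriched_genes: Mapping[str, float]  # gene -> true log2 effect
    housekeeping_genes: tuple[str, ...]
    tissues: tuple[str, ...]
    target: str
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.enriched_genes) & set(self.housekeeping_genes)
        if overlap:
            raise ValueError(f"planted sets overlap: {sorted(overlap)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "role": "enriched", "log2_effect": e}
            for g, e in self.enriched_genes.items()
        ] + [
            {"gene_id": g, "role": "housekeeping", "log2_effect": 0.0}
            for g in self.housekeeping_genes
        ]
        return pd.DataFrame(rows, columns=["gene_id", "role", "log2_effect"])


def simulate_bulk(
    n_genes: int = 5000,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    reps: int = 2,
    n_enriched: int = 50,
    effect_log2fc: float = 2.0,
    nb_dispersion: float = 0.1,
    seed: int = 0,
    target: Optional[str] = None,
    base_log_mean: float = float(np.log(50.0)),
    base_log_sigma: float = 0.8,
    base_mean_min: float = 1.0,
    n_housekeeping: int = 100,
    noncoding_fraction: float = 0.1,
) -> tuple[ExpressionMatrix, BulkTruth]:
    """Simulate a tissues x replicates FPKM matrix with planted enrichment.

    Baseline per-gene means are log-normal (floored at ``base_mean_min``);
    counts are negative binomial with variance mu + phi * mu^2 and are
    converted to FPKM assuming 1 kb genes and per-sample library sizes, so
    expected FPKM equals the planted mean. Planted genes have their
    target-tissue mean multiplied by ``2 ** effect_log2fc``.

    A gene annotation is attached: every gene gets a Rik-style name; planted
    genes are always protein_coding, and a ``noncoding_fraction`` of the
    background is labelled lncRNA (exercises the biotype filter without
    touching the planted truth).
    """
    if n_enriched >= n_genes:
        raise ValueError("n_enriched must be smaller than n_genes")
    if effect_log2fc < 0:
        raise ValueError("effect_log2fc must be non-negative")
    tissues = tuple(tissues)
    target = target or tissues[0]
    if target not in tissues:
        raise ValueError(f"target {target!r} not in tissue list")
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    base = np.maximum(
        np.exp(rng.normal(base_log_mean, base_log_sigma, n_genes)), base_mean_min
    )
    enriched_idx = rng.choice(n_genes, n_enriched, replace=False)
    background = np.setdiff1d(np.arange(n_genes), enriched_idx)
    n_housekeeping = min(n_housekeeping, len(background) // 2)
    housekeeping_idx = background[:n_housekeeping]

    sample_rows = []
    for t in tissues:
        for r in range(1, reps + 1):
            sample_rows.append((f"{t}_{r}", t, r))
    table = SampleTable.from_records(sample_rows)

    lib_sizes = rng.uniform(0.8e6, 1.2e6, len(sample_rows))
    values = np.empty((n_genes, len(sample_rows)))
    for j, (sid, tissue, _rep) in enumerate(sample_rows):
        mean_fpkm = base.copy()
        if tissue == target:
            mean_fpkm[enriched_idx] *= 2.0**effect_log2fc
        mu_counts = mean_fpkm * lib_sizes[j] / 1e6  # 1 kb genes
        counts = _nb_draw(rng, mu_counts, nb_dispersion)
        values[:, j] = counts * 1e6 / lib_sizes[j]

    pool = background[n_housekeeping:]
    n_noncoding = min(int(noncoding_fraction * len(background)), len(pool))
    noncoding = set(rng.choice(pool, n_noncoding, replace=False)) if n_noncoding else set()
    ann_rows = []
    for i, g in enumerate(gene_ids):
        biotype = "lncRNA" if i in noncoding else "protein_coding"
        ann_rows.append((g, f"{2900000 + i}C{i % 10:02d}Rik", biotype))
    annotation = GeneAnnotation.from_records(ann_rows)

    frame = pd.DataFrame(values, index=gene_ids, columns=[s[0] for s in sample_rows])
    matrix = ExpressionMatrix(frame, table, annotation)
    truth = BulkTruth(
        enriched_genes={gene_ids[i]: effect_log2fc for i in sorted(enriched_idx)},
        housekeeping_genes=tuple(gene_ids[i] for i in sorted(housekeeping_idx)),
        tissues=tissues,
        target=target,
        seed=seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SCTruth:
    """Planted structure behind a simulated single-cell matrix."""

    markers: Mapping[str, str]  # gene -> its cell type
    feature_coupling: Mapping[str, str]  # feature tag -> cell type
    qc_fail_cells: tuple[str, ...]
    cells_per_type: Mapping[str, int]
    seed: int

    def __post_init__(self) -> None:
        marked_types = set(self.markers.values())
        for tag, ctype in self.feature_coupling.items():
            if ctype not in marked_types:
                raise ValueError(
                    f"feature {tag!r} couples to {ctype!r}, which has no markers"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene_id": g, "cell_type": t} for g, t in self.markers.items()],
            columns=["gene_id", "cell_type"],
        )


def simulate_sc(
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    cells_per_type: int = 300,
    n_genes: int = 500,
    n_markers_per_type: int = 10,
    marker_fold: float = 8.0,
    feature_map: Mapping[str, str] = DEFAULT_FEATURE_MAP,
    seed: int = 0,
    stage: Optional[str] = None,
    nb_dispersion: float = 0.5,
    base_log_mean: float = float(np.log(0.5)),
    base_log_sigma: float = 0.7,
    qc_violation_fraction: float = 0.1,
    n_feature_tagged: int = 10,
    n_background_tags: int = 3,
) -> tuple[CellMatrix, SCTruth, FeatureAnnotationTable]:
    """Simulate labelled single-cell counts with planted markers.

    Marker genes have their mean multiplied by ``marker_fold`` in their
    assigned type. Per-cell QC covariates are drawn so that a
    ``qc_violation_fraction`` of cells falls outside the standard bounds
    (recorded in the truth, enabling exact-recovery tests). Each feature in
    ``feature_map`` tags up to ``n_feature_tagged`` markers of its coupled
    type plus ``n_background_tags`` random non-marker genes.
    """
    cell_types = tuple(cell_types)
    if n_markers_per_type * len(cell_types) > n_genes:
        raise ValueError("too many markers for the number of genes")
    for tag, ctype in feature_map.items():
        if ctype not in cell_types:
            raise ValueError(f"feature {tag!r} coupled to unknown type {ctype!r}")
    rng = np.random.default_rng(seed)

    gene_ids = [f"sg{i:04d}" for i in range(n_genes)]
    base = np.exp(rng.normal(base_log_mean, base_log_sigma, n_genes))

    marker_idx = rng.choice(n_genes, n_markers_per_type * len(cell_types), replace=False)
    markers: dict[str, str] = {}
    marker_of_type: dict[str, list[int]] = {t: [] for t in cell_types}
    for k, gi in enumerate(marker_idx):
        ctype = cell_types[k // n_markers_per_type]
        markers[gene_ids[gi]] = ctype
        marker_of_type[ctype].append(gi)

    type_means = {}
    for t in cell_types:
        mu = base.copy()
        mu[marker_of_type[t]] *= marker_fold
        type_means[t] = mu

    n_cells = cells_per_type * len(cell_types)
    cell_ids = []
    labels = []
    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    row = 0
    for t in cell_types:
        for c in range(cells_per_type):
            cell_ids.append(f"{t}_{c:04d}")
            labels.append(t)
            counts[row] = _nb_draw(rng, type_means[t], nb_dispersion)
            row += 1

    # QC covariates: violators are drawn strictly out of bounds
    violate = rng.random(n_cells) < qc_violation_fraction
    n_features = rng.integers(250, 5500, n_cells)
    percent_mito = rng.uniform(0.0, 9.0, n_cells)
    modes = rng.integers(0, 3, n_cells)
    for i in np.flatnonzero(violate):
        if modes[i] == 0:
            n_features[i] = rng.integers(10, 200)
        elif modes[i] == 1:
            n_features[i] = rng.integers(6001, 9000)
        else:
            percent_mito[i] = rng.uniform(10.0, 25.0)
    obs = pd.DataFrame(
        {
            "cell_type": labels,
            "n_features": n_features,
            "percent_mito": percent_mito,
        },
        index=cell_ids,
    )
    cells = CellMatrix(counts, cell_ids, gene_ids, obs, stage)

    feature_tags: dict[str, set[str]] = {g: set() for g in gene_ids}
    non_marker = sorted(set(range(n_genes)) - set(int(i) for i in marker_idx))
    for tag in feature_map:
        ctype = feature_map[tag]
        tagged = marker_of_type[ctype][:n_feature_tagged]
        for gi in tagged:
            feature_tags[gene_ids[gi]].add(tag)
        for gi in rng.choice(non_marker, n_background_tags, replace=False):
            feature_tags[gene_ids[gi]].add(tag)
    features = FeatureAnnotationTable(
        {g: frozenset(tags) for g, tags in feature_tags.items() if tags}
    )

    truth = SCTruth(
        markers=markers,
        feature_coupling=dict(feature_map),
        qc_fail_cells=tuple(np.asarray(cell_ids)[violate]),
        cells_per_type={t: cells_per_type for t in cell_types},
        seed=seed,
    )
    return cells, truth, features


# ---------------------------------------------------------------------------
# protein family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyTruth:
    ancestor: str
    tree_newick: str
    subst_rate: float
    seed: int


def expected_identity(rate: float, distance: float) -> float:
    """Closed-form expected pairwise identity between two tips separated by
    total branch length ``distance`` under the uniform 20-state model."""
    return 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-(20.0 / 19.0) * rate * distance)


def tip_distances(tree_newick: str) -> dict[tuple[str, str], float]:
    """Patristic distance for every unordered tip pair."""
    tree = read_newick(tree_newick)
    tips = tree.get_terminals()
    out = {}
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            a, b = sorted([tips[i].name, tips[j].name])
            out[(a, b)] = float(tree.distance(tips[i], tips[j]))
    return out


def simulate_protein_family(
    ancestor_length: int = 300,
    tree: str = DEFAULT_TREE_NEWICK,
    subst_rate: float = 0.003,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], Alignment, FamilyTruth]:
    """Evolve a protein family along a dated tree.

    Per site and branch, the number of substitution events is Poisson with
    mean ``subst_rate * branch_length``; each event replaces the residue by
    a uniform draw from the other 19 amino acids. Under this model the
    expected identity between tips at separation d is
    ``1/20 + (19/20) * exp(-(20/19) * rate * d)`` (see
    :func:`expected_identity`).

    With ``indel_rate > 0``, deletion events additionally remove short
    segments in individual lineages; deleted positions appear as gaps in the
    aligned output (the true alignment remains the positional one). With the
    default ``indel_rate = 0`` the aligned and unaligned outputs coincide.
    """
    if ancestor_length < 1:
        raise ValueError("ancestor_length must be positive")
    rng = np.random.default_rng(seed)
    phylo = read_newick(tree)

    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    ancestor = rng.integers(0, 20, ancestor_length)
    GAP_CODE = 20

    tip_seqs: dict[str, np.ndarray] = {}

    def evolve(seq: np.ndarray, branch_length: float) -> np.ndarray:
        out = seq.copy()
        alive = out != GAP_CODE
        n_events = rng.poisson(subst_rate * branch_length, ancestor_length)
        n_events[~alive] = 0
        for site in np.flatnonzero(n_events):
            for _ in range(n_events[site]):
                shift = rng.integers(1, 20)
                out[site] = (out[site] + shift) % 20
        if indel_rate > 0:
            for _ in range(rng.poisson(indel_rate * branch_length)):
                length = min(rng.geometric(1.0 / 3.0), ancestor_length)
                start = rng.integers(0, max(1, ancestor_length - length + 1))
                out[start : start + length] = GAP_CODE
        return out

    def walk(clade, seq: np.ndarray) -> None:
        for child in clade.clades:
            bl = child.branch_length or 0.0
            child_seq = evolve(seq, bl)
            if child.is_terminal():
                tip_seqs[child.name] = child_seq
            else:
                walk(child, child_seq)

    root = phylo.root
    root_seq = evolve(ancestor, root.branch_length or 0.0)
    if root.is_terminal():
        tip_seqs[root.name] = root_seq
    else:
        walk(root, root_seq)

    def decode(seq: np.ndarray, with_gaps: bool) -> str:
        chars = []
        for code in seq:
            if code == GAP_CODE:
                if with_gaps:
                    chars.append("-")
            else:
                chars.append(chr(aa[code]))
        return "".join(chars)

    names = sorted(tip_seqs)
    unaligned = [(name, decode(tip_seqs[name], with_gaps=False)) for name in names]
    aligned = Alignment(
        tuple(names), tuple(decode(tip_seqs[name], with_gaps=True) for name in names)
    )
    truth = FamilyTruth(
        ancestor=decode(ancestor, with_gaps=False),
        tree_newick=tree if "(" in str(tree) else str(tree),
        subst_rate=subst_rate,
        seed=seed,
    )
    return unaligned, aligned, truth
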