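"""Readers and writers for the plain-text formats the pipeline consumes.

All readers validate strictly and fail loudly with coordinates; none of them
filters rows silently. Every reader/writer pair is a lossless round trip on
valid files.

Formats
-------
TSV        expression matrix, sample table, gene annotation, ortholog table,
           feature table, cell metadata
FASTA      plain and aligned protein sequences (gap character ``-`` only)
MTX        coordinate-triplet sparse counts with genes/cells sidecar TSVs;
           a dense TSV is accepted as an alternative (detected by extension)
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import (
    Alignment,
    CellMatrix,
    DEFAULT_FEATURE_VOCAB,
    ExpressionMatrix,
    FeatureAnnotationTable,
    FormatError,
    GAP,
    GeneAnnotation,
    OrthologRecord,
    PROTEIN_ALPHABET,
    SampleTable,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# sample table / gene annotation / feature table
# ---------------------------------------------------------------------------

def read_sample_table(path: PathLike) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    frame["sample_id"] = frame["sample_id"].str.strip()
    frame["tissue"] = frame["tissue"].str.strip()
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path: PathLike) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: PathLike) -> GeneAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "gene_name", "biotype"):
        if col in frame:
            frame[col] = frame[col].str.strip()
    return GeneAnnotation(frame)


def write_gene_annotation(annotation: GeneAnnotation, path: PathLike) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


def read_feature_table(
    path: PathLike, vocabulary: frozenset[str] = DEFAULT_FEATURE_VOCAB
) -> FeatureAnnotationTable:
    """Read a gene -> feature-tag table.

    Expected columns: ``gene_id`` and ``features`` (comma-separated tags; an
    empty cell means the gene carries no features).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"gene_id", "features"} <= set(frame.columns):
        raise FormatError("feature table needs columns gene_id, features")
    mapping: dict[str, frozenset[str]] = {}
    for _, row in frame.iterrows():
        gene = row["gene_id"].strip()
        if gene in mapping:
            raise FormatError(f"duplicate gene_id in feature table: {gene!r}")
        tags = frozenset(t.strip() for t in row["features"].split(",") if t.strip())
        mapping[gene] = tags
    return FeatureAnnotationTable(mapping, vocabulary)


def write_feature_table(table: FeatureAnnotationTable, path: PathLike) -> None:
    rows = [
        {"gene_id": g, "features": ",".join(sorted(tags))}
        for g, tags in table.features.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "features"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: PathLike,
    sample_table: SampleTable,
    annotation: Optional[GeneAnnotation] = None,
) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV (first column gene_id).

    Every sample in ``sample_table`` must be present as a column, every
    column must be declared in the table, and all values must be finite and
    non-negative. Duplicated gene ids are an error, not a silent merge.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = [str(c).strip() for c in frame.columns]
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate gene_id in expression matrix: {dup!r}")
    declared = set(sample_table.sample_ids)
    extra = set(frame.columns) - declared
    if extra:
        raise FormatError(
            f"matrix columns not in sample table: {sorted(extra)}"
        )
    missing = declared - set(frame.columns)
    if missing:
        raise FormatError(f"sample column(s) missing from matrix: {sorted(missing)}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    frame.index.name = None
    return ExpressionMatrix(frame, sample_table, annotation)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_fasta(path: PathLike) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    current_id: Optional[str] = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append((current_id, "".join(chunks)))
                current_id = line[1:].split()[0].strip()
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    if current_id is not None:
        records.append((current_id, "".join(chunks)))
    return records


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read protein FASTA; sequences are uppercased and validated.

    The dot gap dialect is rejected: only ``-`` is a legal gap character.
    """
    out = []
    for rid, seq in _parse_fasta(path):
        seq = seq.upper()
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"illegal character(s) {sorted(bad)} in sequence {rid!r}"
            )
        out.append((rid, seq))
    return out


def read_aligned_fasta(path: PathLike) -> Alignment:
    """Read an aligned FASTA; all sequences must have equal length."""
    records = read_fasta(path)
    if not records:
        raise FormatError(f"{path}: empty alignment")
    ids, seqs = zip(*records)
    return Alignment(tuple(ids), tuple(seqs))


def write_fasta(
    records: Sequence[tuple[str, str]], path: PathLike, width: int = 60
) -> None:
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_aligned_fasta(alignment: Alignment, path: PathLike) -> None:
    write_fasta(list(zip(alignment.ids, alignment.sequences)), path)


# ---------------------------------------------------------------------------
# ortholog table
# ---------------------------------------------------------------------------

_ORTHOLOG_COLUMNS = [
    "source_gene",
    "species",
    "target_gene",
    "orthology_type",
    "percent_identity",
]


def read_ortholog_table(path: PathLike) -> list[OrthologRecord]:
    """Read an orthologue table; blank target_gene rows are kept and marked
    as "no orthologue detected"."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_ORTHOLOG_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"ortholog table missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        target = row["target_gene"].strip() or None
        pid_raw = row["percent_identity"].strip()
        if target is None:
            pid: Optional[float] = None
        elif pid_raw == "":
            pid = None
        else:
            try:
                pid = float(pid_raw)
            except ValueError as exc:
                raise FormatError(f"unparseable percent identity: {pid_raw!r}") from exc
        records.append(
            OrthologRecord(
                source_gene=row["source_gene"].strip(),
                species=row["species"].strip(),
                target_gene=target,
                orthology_type=row["orthology_type"].strip(),
                percent_identity=pid,
            )
        )
    return records


def write_ortholog_table(records: Sequence[OrthologRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "source_gene": r.source_gene,
                "species": r.species,
                "target_gene": r.target_gene or "",
                "orthology_type": r.orthology_type,
                "percent_identity": (
                    "" if r.percent_identity is None else f"{r.percent_identity:.10g}"
                ),
            }
        )
    pd.DataFrame(rows, columns=_ORTHOLOG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell matrix (MTX triplet or dense TSV)
# ---------------------------------------------------------------------------

def read_cell_matrix(
    path_matrix: PathLike,
    path_genes: PathLike,
    path_cells: PathLike,
    stage: Optional[str] = None,
) -> CellMatrix:
    """Read a cells x genes count matrix with sidecar gene/cell TSVs.

    ``path_matrix`` may be a Matrix Market triplet (``.mtx``) or a dense TSV
    (anything else); the sidecars are one-gene-per-row (``gene_id``) and
    one-cell-per-row (``cell_id``, ``cell_type``, ``n_features``,
    ``percent_mito``) TSVs. Dimensions must agree across the three files.
    """
    genes = pd.read_csv(path_genes, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError("genes sidecar needs a gene_id column")
    gene_ids = [g.strip() for g in genes["gene_id"]]

    cells = pd.read_csv(path_cells, sep="\t")
    if "cell_id" not in cells.columns:
        raise FormatError("cells sidecar needs a cell_id column")
    cells["cell_id"] = cells["cell_id"].astype(str).str.strip()
    cell_ids = list(cells["cell_id"])
    obs = cells.set_index("cell_id")

    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        raw = spio.mmread(str(path_matrix))
        dense = np.asarray(
            raw.todense() if sparse.issparse(raw) else raw
        )
    else:
        frame = pd.read_csv(path_matrix, sep="\t", index_col=0)
        frame.index = frame.index.astype(str).str.strip()
        if list(frame.index) != cell_ids:
            raise FormatError("dense matrix rows disagree with cells sidecar")
        if [str(c).strip() for c in frame.columns] != gene_ids:
            raise FormatError("dense matrix columns disagree with genes sidecar")
        dense = frame.to_numpy()

    if dense.shape != (len(cell_ids), len(gene_ids)):
        raise FormatError(
            f"matrix shape {dense.shape} disagrees with sidecars "
            f"({len(cell_ids)} cells, {len(gene_ids)} genes)"
        )
    as_int = np.rint(dense).astype(np.int64)
    if not np.allclose(dense, as_int, rtol=0, atol=0):
        raise FormatError("counts must be non-negative integers")
    return CellMatrix(as_int, cell_ids, gene_ids, obs, stage)


def write_cell_matrix(
    matrix: CellMatrix,
    path_matrix: PathLike,
    path_genes: PathLike,
    path_cells: PathLike,
) -> None:
    """Write counts (MTX if the path ends in .mtx, else dense TSV) plus
    genes/cells sidecar TSVs."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        spio.mmwrite(str(path_matrix), sparse.coo_matrix(matrix.counts))
    else:
        frame = pd.DataFrame(
            matrix.counts, index=matrix.cell_ids, columns=matrix.gene_ids
        )
        frame.index.name = "cell_id"
        frame.to_csv(path_matrix, sep="\t")
    pd.DataFrame({"gene_id": matrix.gene_ids}).to_csv(path_genes, sep="\t", index=False)
    obs = matrix.obs.copy()
    obs.insert(0, "cell_id", matrix.cell_ids)
    obs.to_csv(path_cells, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick (simulator input)
# ---------------------------------------------------------------------------

def read_newick(path_or_string: PathLike) -> "Bio.Phylo.BaseTree.Tree":  # noqa: F821
    """Parse a Newick tree (file path or literal string) via Biopython."""
    from io import StringIO

    from Bio import Phylo

    text: str
    p = Path(str(path_or_string))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_string)
    if "(" not in text:
        raise FormatError(f"not a Newick tree: {path_or_string!r}")
    return Phylo.read(StringIO(text), "newick")
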