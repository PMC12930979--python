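"""Shared data containers for the atlas pipeline.

Everything here is a thin, validated wrapper around pandas/numpy objects.
File parsing lives in :mod:`tissue_atlas.io_formats`; analysis operations in
:mod:`tissue_atlas.bulk`, :mod:`tissue_atlas.conservation` and
:mod:`tissue_atlas.singlecell`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residues accepted in protein sequences: the 20 standard amino acids,
#: the ambiguity code X, and the gap character.
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS) | {"X", GAP}

#: controlled vocabulary of protein-feature tags accepted by default.
DEFAULT_FEATURE_VOCAB = frozenset(
    {
        "SRCR",
        "CUB",
        "KRAB",
        "LRR",
        "LRRCT",
        "BTB",
        "bromodomain",
        "NTR",
        "disordered",
        "helical",
        "C2H2_ZF",
        "coiled_coil",
        "PPP3CA_binding",
    }
)


class FormatError(ValueError):
    """Raised when an input file or table violates its declared contract."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise FormatError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass(frozen=True)
class SampleTable:
    """Maps bulk RNA-seq samples to tissues.

    Parameters
    ----------
    frame
        DataFrame with columns ``sample_id``, ``tissue``, ``replicate``.
        Sample ids must be unique; replicates are positive integers.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        _check_unique(self.frame["sample_id"], "sample_id")
        if (self.frame["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")
        if self.frame["tissue"].isna().any() or (self.frame["tissue"] == "").any():
            raise FormatError("every sample needs a non-empty tissue label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["tissue"]))

    def samples_of(self, tissue: str) -> list[str]:
        if tissue not in set(self.frame["tissue"]):
            raise KeyError(f"unknown tissue: {tissue!r}")
        mask = self.frame["tissue"] == tissue
        return list(self.frame.loc[mask, "sample_id"])

    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["tissue"]))

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, int]]
    ) -> "SampleTable":
        return cls(
            pd.DataFrame(records, columns=["sample_id", "tissue", "replicate"])
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene name and biotype lookup (gene ids unique)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "gene_name", "biotype"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"gene annotation missing columns: {sorted(missing)}")
        _check_unique(self.frame["gene_id"], "gene_id")

    def biotype_of(self) -> dict[str, str]:
        return dict(zip(self.frame["gene_id"], self.frame["biotype"]))

    def name_of(self) -> dict[str, str]:
        return dict(zip(self.frame["gene_id"], self.frame["gene_name"]))

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, str]]
    ) -> "GeneAnnotation":
        return cls(pd.DataFrame(records, columns=["gene_id", "gene_name", "biotype"]))


@dataclass(frozen=True)
class FeatureAnnotationTable:
    """gene -> set of protein-feature tags, under a controlled vocabulary."""

    features: Mapping[str, frozenset[str]]
    vocabulary: frozenset[str] = DEFAULT_FEATURE_VOCAB

    def __post_init__(self) -> None:
        for gene, tags in self.features.items():
            bad = set(tags) - set(self.vocabulary)
            if bad:
                raise FormatError(
                    f"gene {gene!r} carries tags outside the vocabulary: {sorted(bad)}"
                )

    def genes_with(self, tag: str) -> list[str]:
        return sorted(g for g, tags in self.features.items() if tag in tags)

    @property
    def tags(self) -> list[str]:
        present: set[str] = set()
        for t in self.features.values():
            present |= t
        return sorted(present)


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with its sample map and annotation.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns;
    entries are finite and non-negative.
    """

    values: pd.DataFrame
    sample_table: SampleTable
    annotation: Optional[GeneAnnotation] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene_id")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        missing = set(self.sample_table.sample_ids) - set(self.values.columns)
        if missing:
            raise FormatError(f"samples absent from matrix: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(genes)], self.sample_table, self.annotation
        )


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped protein sequences."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise FormatError("ids and sequences differ in number")
        _check_unique(self.ids, "sequence id")
        if self.sequences:
            w = len(self.sequences[0])
            for sid, seq in zip(self.ids, self.sequences):
                if len(seq) != w:
                    raise FormatError(
                        f"aligned sequences must have equal length; "
                        f"{sid!r} has length {len(seq)}, expected {w}"
                    )
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - PROTEIN_ALPHABET
            if bad:
                raise FormatError(
                    f"illegal character(s) {sorted(bad)} in sequence {sid!r}"
                )

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(seq[j] for seq in self.sequences)


@dataclass(frozen=True)
class OrthologRecord:
    """One source-gene -> species mapping from an orthologue table.

    ``target_gene`` is ``None`` when no orthologue was detected in that
    species; in that case ``percent_identity`` is missing too.
    """

    source_gene: str
    species: str
    target_gene: Optional[str]
    orthology_type: str
    percent_identity: Optional[float]

    def __post_init__(self) -> None:
        if self.percent_identity is not None and not (
            0.0 <= self.percent_identity <= 100.0
        ):
            raise FormatError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"for {self.source_gene!r}/{self.species!r}"
            )
        if self.target_gene is None and self.percent_identity is not None:
            raise FormatError(
                "percent identity given without a target gene for "
                f"{self.source_gene!r}/{self.species!r}"
            )

    @property
    def absent(self) -> bool:
        """True when no orthologue was detected for this species."""
        return self.target_gene is None


@dataclass
class CellMatrix:
    """Cells x genes integer count matrix with per-cell metadata.

    ``obs`` is indexed by cell_id and carries ``cell_type``, ``n_features``
    and ``percent_mito``; ``stage`` optionally tags the dataset (e.g. a
    developmental time point).
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    obs: pd.DataFrame
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D cells x genes array")
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        _check_unique(self.cell_ids, "cell_id")
        _check_unique(self.gene_ids, "gene_id")
        required = {"cell_type", "n_features", "percent_mito"}
        missing = required - set(self.obs.columns)
        if missing:
            raise FormatError(f"cell metadata missing columns: {sorted(missing)}")
        if list(self.obs.index) != list(self.cell_ids):
            raise FormatError("cell metadata index must match cell_ids in order")
        if (self.obs["cell_type"].astype(str) == "").any():
            raise FormatError("cell_type labels must be non-empty")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CellMatrix(
            self.counts[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            self.obs.iloc[idx].copy(),
            self.stage,
        )
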