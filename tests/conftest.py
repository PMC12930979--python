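import numpy as np
import pandas as pd
import pytest

from tissue_atlas.core import (
    Alignment,
    ExpressionMatrix,
    GeneAnnotation,
    SampleTable,
)


@pytest.fixture
def sample_table() -> SampleTable:
    rows = []
    for tissue in ("retina", "brain", "liver"):
        for rep in (1, 2):
            rows.append((f"{tissue}_{rep}", tissue, rep))
    return SampleTable.from_records(rows)


@pytest.fixture
def annotation() -> GeneAnnotation:
    return GeneAnnotation.from_records(
        [
            ("g1", "1190005I06Rik", "protein_coding"),
            ("g2", "Gm123", "lncRNA"),
            ("g3", "4930447A16Rik", "pseudogene"),
            ("g4", "9130409I23Rik", "protein_coding"),
            ("g5", "Rho", "protein_coding"),
        ]
    )


@pytest.fixture
def expression(sample_table, annotation) -> ExpressionMatrix:
    values = pd.DataFrame(
        {
            "retina_1": [10.0, 1.0, 0.5, 8.0, 120.0],
            "retina_2": [12.0, 1.2, 0.4, 9.0, 110.0],
            "brain_1": [1.0, 1.1, 0.6, 0.5, 2.0],
            "brain_2": [0.9, 0.9, 0.5, 0.4, 1.5],
            "liver_1": [0.5, 1.0, 0.5, 0.2, 0.1],
            "liver_2": [0.4, 1.0, 0.6, 0.3, 0.2],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return ExpressionMatrix(values, sample_table, annotation)


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        ("s1", "s2", "s3"),
        ("ACDE", "ACDK", "AC-E"),
    )


def random_alignment(rng: np.random.Generator, n_seqs: int = 5, width: int = 30,
                     gap_fraction: float = 0.15) -> Alignment:
    from tissue_atlas.core import AMINO_ACIDS

    seqs = []
    for _ in range(n_seqs):
        chars = rng.choice(list(AMINO_ACIDS), width)
        gaps = rng.random(width) < gap_fraction
        seqs.append("".join("-" if g else c for c, g in zip(chars, gaps)))
    ids = tuple(f"r{i}" for i in range(n_seqs))
    return Alignment(ids, tuple(seqs))
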