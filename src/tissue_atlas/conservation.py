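"""Orthologue breadth, alignment identity, column conservation, and protein
composition.

Identity is computed pairwise over columns where both sequences are non-gap;
column conservation is the maximum residue frequency among non-gap residues.
A built-in affine-gap global aligner is provided as a fallback for cases
where no pre-computed alignment is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, Alignment, GAP, OrthologRecord

#: physicochemical residue classes. Class names follow common usage; H is
#: assigned to the polar class (single assignment required).
COMPOSITION_CLASSES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIMFW"),
    "polar": frozenset("STNQYCH"),
    "positive": frozenset("KR"),
    "negative": frozenset("DE"),
    "special": frozenset("PG"),
}


@dataclass(frozen=True)
class ConservationSummary:
    """Per-source-gene orthologue breadth and best identity per species."""

    source_gene: str
    breadth: int
    identity_by_species: Mapping[str, Optional[float]]


@dataclass(frozen=True)
class ConservationTrack:
    """Per-column conservation score and non-gap residue counts.

    All-gap columns are flagged missing (NaN score, count 0).
    """

    scores: np.ndarray
    nongap_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != self.nongap_counts.shape:
            raise ValueError("scores and counts must have equal length")


# ---------------------------------------------------------------------------
# ortholog table operations
# ---------------------------------------------------------------------------

def dedup_orthologs(records: Sequence[OrthologRecord]) -> list[OrthologRecord]:
    """Collapse to one record per (source_gene, species).

    The record with the highest percent identity is retained; ties break on
    lexicographically smallest target_gene. Rows with no detected
    orthologue never outrank a row with one.
    """
    best: dict[tuple[str, str], OrthologRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.source_gene, rec.species)
        if key not in best:
            best[key] = rec
            order.append(key)
            continue
        cur = best[key]
        if cur.absent and not rec.absent:
            best[key] = rec
        elif not cur.absent and not rec.absent:
            cur_pid = -1.0 if cur.percent_identity is None else cur.percent_identity
            new_pid = -1.0 if rec.percent_identity is None else rec.percent_identity
            if new_pid > cur_pid or (
                new_pid == cur_pid and (rec.target_gene or "") < (cur.target_gene or "")
            ):
                best[key] = rec
    return [best[k] for k in order]


def conservation_breadth(
    records: Sequence[OrthologRecord], species_list: Sequence[str]
) -> list[ConservationSummary]:
    """Count, per source gene, the species with a detected orthologue.

    ``records`` should already be deduplicated. Genes with no orthologue in
    any listed species get breadth 0 (lineage-restricted).
    """
    species_list = list(species_list)
    genes: list[str] = list(dict.fromkeys(r.source_gene for r in records))
    table: dict[str, dict[str, Optional[float]]] = {
        g: {s: None for s in species_list} for g in genes
    }
    present: dict[str, set[str]] = {g: set() for g in genes}
    for rec in records:
        if rec.species not in set(species_list):
            continue
        if not rec.absent:
            present[rec.source_gene].add(rec.species)
            table[rec.source_gene][rec.species] = rec.percent_identity
    return [
        ConservationSummary(g, len(present[g]), table[g]) for g in genes
    ]


def breadth_frame(summaries: Sequence[ConservationSummary]) -> pd.DataFrame:
    """Tabular view of conservation summaries (identity columns + breadth)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"source_gene": s.source_gene, "breadth": s.breadth}
        for sp, pid in s.identity_by_species.items():
            row[f"identity_{sp}"] = np.nan if pid is None else pid
        rows.append(row)
    return pd.DataFrame(rows).set_index("source_gene")


# ---------------------------------------------------------------------------
# alignment statistics
# ---------------------------------------------------------------------------

def pairwise_identity(alignment: Alignment, i: int, j: int) -> float:
    """Fraction of identical residues over columns where both rows are
    non-gap. Returns NaN when the two rows share no non-gap columns."""
    a = alignment.sequences[i]
    b = alignment.sequences[j]
    shared = 0
    same = 0
    for ca, cb in zip(a, b):
        if ca != GAP and cb != GAP:
            shared += 1
            if ca == cb:
                same += 1
    if shared == 0:
        return float("nan")
    return same / shared


def identity_matrix(alignment: Alignment) -> pd.DataFrame:
    """Symmetric pairwise-identity matrix with unit diagonal."""
    n = alignment.n_sequences
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(alignment, i, j)
    return pd.DataFrame(mat, index=alignment.ids, columns=alignment.ids)


def column_conservation(alignment: Alignment) -> ConservationTrack:
    """Max residue frequency among non-gap residues, per column."""
    w = alignment.width
    scores = np.full(w, np.nan)
    counts = np.zeros(w, dtype=int)
    for j in range(w):
        residues = [c for c in alignment.column(j) if c != GAP]
        counts[j] = len(residues)
        if residues:
            _, freq = np.unique(residues, return_counts=True)
            scores[j] = freq.max() / len(residues)
    return ConservationTrack(scores, counts)


# ---------------------------------------------------------------------------
# global alignment fallback (Gotoh affine-gap Needleman-Wunsch)
# ---------------------------------------------------------------------------

def _default_substitution_matrix():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def nw_align(
    seq_a: str,
    seq_b: str,
    substitution_matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[Alignment, float]:
    """Global alignment with affine gaps (gap of length L costs
    ``gap_open + (L - 1) * gap_extend``).

    Traceback is deterministic: on score ties the diagonal move is preferred
    over the vertical (gap in ``seq_b``), which is preferred over the
    horizontal. Returns the pairwise :class:`Alignment` (ids "a", "b") and
    the optimal score.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    if substitution_matrix is None:
        substitution_matrix = _default_substitution_matrix()
    n, m = len(seq_a), len(seq_b)
    neg = -np.inf
    # state 0 = match/mismatch (diagonal), 1 = gap in b (up), 2 = gap in a (left)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)  # predecessor state
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        ptr[1, i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        ptr[2, 0, j] = 0 if j == 1 else 2

    def _argbest(candidates: list[float]) -> int:
        # priority on ties: state order 0 (diag) > 1 (up) > 2 (left)
        best = 0
        for k in range(1, len(candidates)):
            if candidates[k] > candidates[best]:
                best = k
        return best

    for i in range(1, n + 1):
        sa = seq_a[i - 1]
        for j in range(1, m + 1):
            s = float(substitution_matrix[sa, seq_b[j - 1]])
            cand = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            k = _argbest(cand)
            M[i, j] = cand[k] + s
            ptr[0, i, j] = k

            cand = [M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                    Y[i - 1, j] - gap_open]
            k = _argbest(cand)
            X[i, j] = cand[k]
            ptr[1, i, j] = k

            cand = [M[i, j - 1] - gap_open, X[i, j - 1] - gap_open,
                    Y[i, j - 1] - gap_extend]
            k = _argbest(cand)
            Y[i, j] = cand[k]
            ptr[2, i, j] = k

    finals = [M[n, m], X[n, m], Y[n, m]]
    state = _argbest(finals)
    score = finals[state]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(seq_a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(seq_b[j - 1])
            j -= 1
        state = prev
    aligned = Alignment(("a", "b"), ("".join(reversed(out_a)), "".join(reversed(out_b))))
    return aligned, float(score)


# ---------------------------------------------------------------------------
# protein composition / length
# ---------------------------------------------------------------------------

def composition_profile(
    sequence: str,
    classes: Mapping[str, frozenset[str]] = COMPOSITION_CLASSES,
) -> dict[str, float]:
    """Fractions of the five physicochemical classes in a protein.

    Gaps and X are excluded from the denominator; an empty (or all-X)
    sequence is an error. Fractions sum to 1.
    """
    seq = sequence.upper().replace(GAP, "")
    residues = [c for c in seq if c in set(AMINO_ACIDS)]
    if not residues:
        raise ValueError("sequence contains no standard residues")
    unknown = set(seq) - set(AMINO_ACIDS) - {"X"}
    if unknown:
        raise ValueError(f"illegal residue(s): {sorted(unknown)}")
    total = len(residues)
    profile = {}
    for name, members in classes.items():
        profile[name] = sum(1 for c in residues if c in members) / total
    return profile


def length_table(groups: Mapping[str, Sequence[str]]) -> dict[str, list[int]]:
    """Ungapped sequence lengths per group (for downstream rank tests)."""
    out = {}
    for name, seqs in groups.items():
        if len(seqs) == 0:
            warnings.warn(f"group {name!r} is empty")
        out[name] = [len(s.replace(GAP, "")) for s in seqs]
    return out
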