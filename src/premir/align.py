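"""Pairwise alignment backends shared by the homology and annotation stages.

The exhaustive aligner is Biopython's Gotoh implementation
(:class:`Bio.Align.PairwiseAligner`); this module fixes the scoring scheme
(BLASTn-like: match +1, mismatch -2, gap of length k costs 5 + 2k), extracts
per-alignment counts (aligned columns, mismatches, gap positions) from the
alignment trace, and attaches Karlin-Altschul expectation values
E = K * m * n * exp(-lambda * S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats import to_dna

__all__ = [
    "AlignmentTrace",
    "KarlinParams",
    "nucleotide_aligner",
    "protein_aligner",
    "best_local_alignment",
    "trace_counts",
    "evalue",
    "global_identity",
]

# Karlin-Altschul parameters for the +1/-2 nucleotide scheme (ungapped
# BLASTn values) and a conventional gapped BLOSUM62 set for proteins.
NUC_LAMBDA = 1.28
NUC_K = 0.46
PROT_LAMBDA = 0.267
PROT_K = 0.041

_NUC_LETTERS = "ACGTN"


@dataclass(frozen=True)
class KarlinParams:
    lam: float
    k: float


NUC_KARLIN = KarlinParams(NUC_LAMBDA, NUC_K)
PROT_KARLIN = KarlinParams(PROT_LAMBDA, PROT_K)


def _nuc_matrix(match: float = 1.0, mismatch: float = -2.0):
    n = len(_NUC_LETTERS)
    arr = np.full((n, n), mismatch)
    for i, a in enumerate(_NUC_LETTERS):
        if a != "N":
            arr[i, i] = match
    # N never matches anything (also used for masking found hits)
    m = substitution_matrices.Array(alphabet=_NUC_LETTERS, dims=2)
    m[:, :] = arr
    return m


def nucleotide_aligner(
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
    mode: str = "local",
) -> Align.PairwiseAligner:
    """BLASTn-like aligner: gap of length k costs gap_open + k*gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _nuc_matrix(match, mismatch)
    # Biopython's open_gap_score is the score of the FIRST gap residue
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class AlignmentTrace:
    """Counts and coordinates read off one pairwise local alignment.

    ``columns`` includes gap columns; ``gaps`` counts gap positions on both
    sequences; spans are 0-based half-open on target (subject) and query.
    """

    score: float
    columns: int
    matches: int
    mismatches: int
    gaps: int
    target_span: tuple[int, int]
    query_span: tuple[int, int]


def trace_counts(alignment) -> AlignmentTrace:
    """Extract column/match/mismatch/gap counts from a Bio.Align alignment."""
    t_blocks, q_blocks = alignment.aligned
    target = str(alignment.target)
    query = str(alignment.query)
    matches = mismatches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_cols += te - ts
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b and a != "N":
                matches += 1
            else:
                mismatches += 1
    gaps = 0
    for k in range(1, len(t_blocks)):
        gaps += t_blocks[k][0] - t_blocks[k - 1][1]  # gap in query
        gaps += q_blocks[k][0] - q_blocks[k - 1][1]  # gap in target
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1])) if len(t_blocks) else (0, 0)
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1])) if len(q_blocks) else (0, 0)
    return AlignmentTrace(
        score=float(alignment.score),
        columns=aligned_cols + gaps,
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
        target_span=t_span,
        query_span=q_span,
    )


def best_local_alignment(aligner, subject: str, query: str):
    """Best-scoring local alignment or None when the score is <= 0."""
    subject = to_dna(subject)
    query = to_dna(query)
    if not subject or not query:
        return None
    alignments = aligner.align(subject, query)
    try:
        best = alignments[0]
    except (IndexError, StopIteration):
        return None
    if best.score <= 0:
        return None
    return best


def evalue(score: float, m: int, n: int, params: KarlinParams = NUC_KARLIN) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    return params.k * m * n * math.exp(-params.lam * score)


def min_score_for_evalue(
    emax: float, m: int, n: int, params: KarlinParams = NUC_KARLIN
) -> float:
    """Smallest score whose E-value is <= emax in an m x n search space."""
    return math.log(params.k * m * n / emax) / params.lam


def global_identity(a: str, b: str) -> float:
    """Identity of the glocal alignment of the shorter sequence onto the longer.

    Matches divided by alignment columns over the shorter sequence's
    extent (end gaps on the longer sequence are free and excluded).
    """
    a, b = to_dna(a), to_dna(b)
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    aligner = nucleotide_aligner(mode="global")
    # end gaps on the longer (target) sequence are free
    try:
        aligner.end_insertion_score = 0.0
    except AttributeError:  # pragma: no cover - older Biopython naming
        aligner.target_end_gap_score = 0.0
    alignments = aligner.align(longer, shorter)
    best = alignments[0]
    tr = trace_counts(best)
    if tr.columns == 0:
        return 0.0
    return tr.matches / tr.columns
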