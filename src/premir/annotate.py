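"""Annotation filters applied to candidate windows.

Windows overlapping protein-coding sequence are removed in prediction and
positive-compilation mode (``drop_coding``) or retained in decoy-compilation
mode (``keep_coding``): each window is translated in all six frames and the
translations are locally aligned (BLOSUM62) against the protein set; a
window is flagged when the best expectation value clears the threshold.
A second filter removes windows resembling rRNA or tRNA family sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .align import (
    PROT_KARLIN,
    best_local_alignment,
    evalue,
    nucleotide_aligner,
    protein_aligner,
    trace_counts,
)
from .formats import SeqRecord, reverse_complement, to_dna
from .homology import Window

logger = logging.getLogger(__name__)

__all__ = [
    "FilterDecision",
    "ProteinRecord",
    "coding_overlap_filter",
    "rna_family_filter",
    "score_coding_overlap",
]

MIN_ORF_AA = 20  # internal ORFs shorter than this are noise, not scored


@dataclass(frozen=True)
class ProteinRecord:
    """A protein database entry (NR-style)."""

    id: str
    seq: str


@dataclass(frozen=True)
class FilterDecision:
    window: Window
    flagged: bool
    best_evalue: float | None = None
    db_hit_id: str | None = None


def _six_frame_orfs(seq: str, min_aa: int = MIN_ORF_AA) -> list[str]:
    """Stop-free translation segments of length >= min_aa from all six frames."""
    seq = to_dna(seq)
    peptides: list[str] = []
    for strand_seq in (seq, reverse_complement(seq)):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            for segment in aa.split("*"):
                segment = segment.replace("X", "")
                if len(segment) >= min_aa:
                    peptides.append(segment)
    return peptides


def score_coding_overlap(
    window: Window, protein_db: list[SeqRecord] | list, evalue_max: float = 0.001
) -> FilterDecision:
    """Best translated-search hit of a window against the protein set."""
    peptides = _six_frame_orfs(window.seq)
    if not peptides or not protein_db:
        return FilterDecision(window, flagged=False)
    aligner = protein_aligner()
    search_space = sum(len(_protein_seq(p)) for p in protein_db)
    # translated-search convention: the query length entering the
    # expectation value is the window's total translated length, so the
    # E-value accounts for every frame segment tested
    query_space = sum(len(p) for p in peptides)
    best_e, best_id = None, None
    for prot in protein_db:
        pseq = _protein_seq(prot)
        for pep in peptides:
            aln = best_local_alignment(aligner, pseq, pep)
            if aln is None:
                continue
            e = evalue(aln.score, query_space, search_space, PROT_KARLIN)
            if best_e is None or e < best_e:
                best_e, best_id = e, _protein_id(prot)
    flagged = best_e is not None and best_e <= evalue_max
    return FilterDecision(
        window, flagged=flagged, best_evalue=best_e, db_hit_id=best_id if flagged else None
    )


def _protein_seq(p) -> str:
    return p.seq if hasattr(p, "seq") else str(p)


def _protein_id(p) -> str:
    return p.id if hasattr(p, "id") else "protein"


def coding_overlap_filter(
    windows: list[Window],
    protein_db: list,
    mode: str = "drop_coding",
    evalue_max: float = 0.001,
) -> list[Window]:
    """Partition windows by protein-coding overlap and keep one side.

    ``drop_coding`` returns windows without a significant translated hit;
    ``keep_coding`` returns windows with one (decoy compilation).
    """
    if mode not in ("drop_coding", "keep_coding"):
        raise ValueError(f"unknown coding-filter mode {mode!r}")
    if mode == "keep_coding" and not protein_db:
        logger.warning("keep_coding with an empty protein set: no window can qualify")
        return []
    kept = []
    for w in windows:
        decision = score_coding_overlap(w, protein_db, evalue_max)
        if decision.flagged == (mode == "keep_coding"):
            kept.append(w)
    return kept


def rna_family_filter(
    windows: list[Window],
    rfam_records: list[SeqRecord],
    identity_min: float = 0.85,
    coverage_min: float = 0.8,
) -> list[Window]:
    """Remove windows locally matching an rRNA/tRNA family sequence.

    A window is removed when some family record aligns at
    >= identity_min identity over >= coverage_min of the record length.
    """
    if not rfam_records:
        return list(windows)
    aligner = nucleotide_aligner()
    kept = []
    for w in windows:
        hit = False
        for fam in rfam_records:
            for target in (w.seq, reverse_complement(w.seq)):
                aln = best_local_alignment(aligner, target, fam.seq)
                if aln is None:
                    continue
                tr = trace_counts(aln)
                if tr.columns == 0:
                    continue
                identity = tr.matches / tr.columns
                coverage = (tr.query_span[1] - tr.query_span[0]) / len(fam.seq)
                if identity >= identity_min and coverage >= coverage_min:
                    hit = True
                    break
            if hit:
                break
        if not hit:
            kept.append(w)
    return kept
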