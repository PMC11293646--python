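"""Homology-guided candidate discovery.

Reference miRNAs (queries) are aligned against the input sequences on both
strands; each hit carries the query length Q, alignment length Qa (columns,
gaps included), total gap positions G and mismatches M, from which the level
of dissimilarity is

    LD = Q - Qa + G + M

i.e. unaligned query nucleotides plus gaps plus mismatches.  Hits are then
selected by mode (positive compilation: perfect full-length matches only;
decoy compilation: E <= 0.001 and 5 <= LD <= 6; prediction: E and LD caps,
default LD <= 3), extended into flanked genomic windows, and de-redundified
with a greedy longest-first clustering.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .align import (
    NUC_KARLIN,
    best_local_alignment,
    evalue,
    min_score_for_evalue,
    nucleotide_aligner,
    trace_counts,
    global_identity,
)
from .formats import Interval, SeqRecord, reverse_complement, to_dna

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "Window",
    "HomologyParams",
    "compute_ld",
    "find_hits",
    "select_hits",
    "extract_window",
    "cluster_representatives",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-subject local alignment with the LD ingredients."""

    query_id: str
    Q: int
    Qa: int
    G: int
    M: int
    evalue: float
    subject_interval: Interval
    aligned_query_span: tuple[int, int]  # 1-based inclusive on the query

    def __post_init__(self):
        if self.Qa <= 0:
            raise ValueError("alignment length must be positive")
        if self.Qa > self.Q + self.G:
            raise ValueError("Qa cannot exceed Q + G")
        if self.G < 0 or self.M < 0:
            raise ValueError("gap and mismatch counts must be non-negative")

    @property
    def ld(self) -> int:
        return compute_ld(self)


@dataclass(frozen=True)
class Window:
    """A flanked genomic window around a hit, oriented 5'->3' for the hit."""

    interval: Interval
    seq: str
    hit_span_in_window: tuple[int, int]  # 1-based inclusive
    flank: int
    hit: AlignmentHit | None = None

    def __post_init__(self):
        s, e = self.hit_span_in_window
        if not (1 <= s <= e <= len(self.seq)):
            raise ValueError("hit span outside the window")

    @property
    def hit_seq(self) -> str:
        s, e = self.hit_span_in_window
        return self.seq[s - 1 : e]


@dataclass(frozen=True)
class HomologyParams:
    evalue_max: float = 0.001
    ld_max: int = 3
    max_hits_per_strand: int = 50
    min_anchor_score: float = 8.0  # never consider alignments below this score


def compute_ld(hit: AlignmentHit) -> int:
    """Level of dissimilarity: LD = Q - Qa + G + M."""
    return hit.Q - hit.Qa + hit.G + hit.M


# ---------------------------------------------------------------------------
# hit finding


def _search_strand(
    aligner,
    query: SeqRecord,
    subject: SeqRecord,
    strand: str,
    search_space: int,
    params: HomologyParams,
) -> list[AlignmentHit]:
    """Greedy iterated best-local-alignment with masking of found hits."""
    subj_seq = to_dna(subject.seq)
    if strand == "-":
        subj_seq = reverse_complement(subj_seq)
    q = to_dna(query.seq)
    L = len(subj_seq)
    hits: list[AlignmentHit] = []
    min_score = max(
        params.min_anchor_score,
        min_score_for_evalue(max(params.evalue_max, 10.0), len(q), search_space),
    )
    work = subj_seq
    for _ in range(params.max_hits_per_strand):
        aln = best_local_alignment(aligner, work, q)
        if aln is None or aln.score < min_score:
            break
        tr = trace_counts(aln)
        ts, te = tr.target_span
        qs, qe = tr.query_span
        if strand == "+":
            start, end = ts, te
        else:  # coordinates on the forward strand
            start, end = L - te, L - ts
        hit = AlignmentHit(
            query_id=query.id,
            Q=len(q),
            Qa=tr.columns,
            G=tr.gaps,
            M=tr.mismatches,
            evalue=evalue(tr.score, len(q), search_space, NUC_KARLIN),
            subject_interval=Interval(subject.id, start, end, strand),
            aligned_query_span=(qs + 1, qe),
        )
        hits.append(hit)
        work = work[:ts] + "N" * (te - ts) + work[te:]
    return hits


def find_hits(
    queries: list[SeqRecord],
    subjects: list[SeqRecord],
    params: HomologyParams | None = None,
    backend: str = "builtin",
) -> list[AlignmentHit]:
    """Local alignments of every query against both strands of every subject.

    ``backend='blastn'`` shells out to NCBI blastn when available and falls
    back to the built-in exhaustive aligner (Gotoh local alignment,
    match +1 / mismatch -2 / gap 5+2k, Karlin-Altschul E-values) otherwise.
    """
    if not queries:
        raise ValueError("empty query set")
    if not subjects:
        raise ValueError("empty subject list")
    params = params or HomologyParams()
    if backend == "blastn":
        if shutil.which("blastn"):
            return _blastn_hits(queries, subjects, params)
        logger.warning("blastn binary not found; falling back to builtin aligner")
    elif backend != "builtin":
        raise ValueError(f"unknown homology backend {backend!r}")

    aligner = nucleotide_aligner()
    search_space = 2 * sum(len(s) for s in subjects)
    hits: list[AlignmentHit] = []
    for subject in subjects:
        for query in queries:
            for strand in "+-":
                hits.extend(
                    _search_strand(aligner, query, subject, strand, search_space, params)
                )
    hits.sort(
        key=lambda h: (
            h.subject_interval.seq_id,
            h.subject_interval.start,
            h.subject_interval.strand,
            h.query_id,
        )
    )
    return hits


def _blastn_hits(
    queries: list[SeqRecord], subjects: list[SeqRecord], params: HomologyParams
) -> list[AlignmentHit]:
    """External adapter: blastn-short with tabular output."""
    from .formats import write_fasta

    with tempfile.TemporaryDirectory() as td:
        qf = Path(td) / "q.fa"
        sf = Path(td) / "s.fa"
        qf.write_text(
            write_fasta([SeqRecord(r.id, to_dna(r.seq)) for r in queries])
        )
        sf.write_text(
            write_fasta([SeqRecord(r.id, to_dna(r.seq)) for r in subjects])
        )
        out = subprocess.run(
            [
                "blastn",
                "-task",
                "blastn-short",
                "-query",
                str(qf),
                "-subject",
                str(sf),
                "-evalue",
                "10",
                "-outfmt",
                "6 qseqid sseqid qlen length mismatch gaps evalue qstart qend sstart send",
            ],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    hits = []
    for line in out.splitlines():
        (qid, sid, qlen, length, mism, gaps, ev, qs, qe, ss, se) = line.split("\t")
        ss, se = int(ss), int(se)
        strand = "+" if ss <= se else "-"
        lo, hi = (ss, se) if strand == "+" else (se, ss)
        hits.append(
            AlignmentHit(
                query_id=qid,
                Q=int(qlen),
                Qa=int(length),
                G=int(gaps),
                M=int(mism),
                evalue=float(ev),
                subject_interval=Interval(sid, lo - 1, hi, strand),
                aligned_query_span=(int(qs), int(qe)),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# hit selection


def select_hits(
    hits: list[AlignmentHit], mode: str, config: HomologyParams | None = None
) -> list[AlignmentHit]:
    """Filter hits by compilation mode.

    ``positive``   -- perfect full-length matches only (LD = 0, Qa = Q).
    ``decoy``      -- E <= 0.001 and LD in the [5, 6] dissimilarity band.
    ``prediction`` -- E <= evalue_max and LD <= ld_max (default 3).
    """
    config = config or HomologyParams()
    if mode == "positive":
        return [h for h in hits if h.ld == 0 and h.Qa == h.Q and h.G == 0 and h.M == 0]
    if mode == "decoy":
        return [h for h in hits if h.evalue <= 0.001 and 5 <= h.ld <= 6]
    if mode == "prediction":
        return [h for h in hits if h.evalue <= config.evalue_max and h.ld <= config.ld_max]
    raise ValueError(f"unknown selection mode {mode!r}")


# ---------------------------------------------------------------------------
# window extraction


def extract_window(
    hit: AlignmentHit, subjects: list[SeqRecord], flank: int
) -> Window:
    """Extend a hit by ``flank`` nt on each side, clipped at sequence ends.

    Minus-strand windows are reverse-complemented so the hit reads 5'->3'.
    """
    by_id = {s.id: s for s in subjects}
    subject = by_id[hit.subject_interval.seq_id]
    iv = hit.subject_interval
    start = max(0, iv.start - flank)
    end = min(len(subject.seq), iv.end + flank)
    seq = to_dna(subject.seq[start:end])
    if iv.strand == "-":
        seq = reverse_complement(seq)
        span_start = end - iv.end + 1
    else:
        span_start = iv.start - start + 1
    span = (span_start, span_start + len(iv) - 1)
    return Window(
        interval=Interval(iv.seq_id, start, end, iv.strand),
        seq=seq,
        hit_span_in_window=span,
        flank=flank,
        hit=hit,
    )


# ---------------------------------------------------------------------------
# redundancy removal


def cluster_representatives(
    records: list[SeqRecord], identity_threshold: float = 0.9
) -> list[SeqRecord]:
    """Greedy longest-first clustering; returns one representative per cluster.

    A record joins the first existing representative whose glocal identity
    (matches / aligned columns of the shorter onto the longer, best of the
    two strands) reaches the threshold; otherwise it founds a new cluster.
    Ties on equal length break lexicographically on the id (deterministic).
    """
    if not 0.8 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in (0.8, 1.0]")
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    reps: list[SeqRecord] = []
    for rec in ordered:
        placed = False
        for rep in reps:
            ident = max(
                global_identity(rec.seq, rep.seq),
                global_identity(reverse_complement(rec.seq), rep.seq),
            )
            if ident >= identity_threshold:
                placed = True
                break
        if not placed:
            reps.append(rec)
    return reps
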