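"""Compilation of positive and negative (decoy) feature datasets.

Positive pipeline: perfect full-length stem-loop hits -> 20-nt-flank
windows -> redundancy removal -> coding filter (drop) -> rRNA/tRNA filter
-> folding -> structural qualification -> feature extraction, label 1.
A pre-miRNA may contribute several rows (one per qualified structure).

Negative pipeline: mature-miRNA hits in the dissimilarity band
(E <= 0.001, 5 <= LD <= 6) -> windows with lengths sampled from the
positive length distribution -> coding filter (keep) -> folding ->
the same qualification rules -> feature extraction -> seeded subsample
to the positive count, label 0.

The presumed mature on a window comes from the provided stem-loop->mature
mapping when available (miRBase-style); otherwise the homology hit span
extended to the full query length stands in for it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import coding_overlap_filter, rna_family_filter
from .config import QualConfig
from .features import extract_features, feature_names, gc_percent
from .folding import FoldParams, fold_all
from .hairpin import (
    StarInferenceError,
    disqualify,
    duplex_stats,
    infer_star,
    locate_hit,
)
from .homology import (
    HomologyParams,
    Window,
    cluster_representatives,
    extract_window,
    find_hits,
    select_hits,
)
from .formats import SeqRecord, to_dna

logger = logging.getLogger(__name__)

__all__ = ["BuildConfig", "build_positive", "build_negative", "candidate_rows"]

META_COLUMNS = (
    "meta_query",
    "meta_seq_id",
    "meta_window_start",
    "meta_window_end",
    "meta_strand",
    "meta_structure_rank",
)


@dataclass(frozen=True)
class BuildConfig:
    engine: str = "auto"
    flank_positive: int = 20
    identity_threshold: float = 0.9
    coding_evalue_max: float = 0.001
    rfam_identity_min: float = 0.85
    rfam_coverage_min: float = 0.8
    qual: QualConfig = field(default_factory=QualConfig)
    homology: HomologyParams = field(default_factory=HomologyParams)
    fold: FoldParams = field(default_factory=lambda: FoldParams(max_structures=5))
    seed: int = 0


def _dedupe(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows whose features are identical for the same window."""
    keys = [c for c in table.columns if c != "meta_structure_rank"]
    return table.drop_duplicates(subset=keys).reset_index(drop=True)


def _empty_table() -> pd.DataFrame:
    cols = list(feature_names()) + ["label"] + list(META_COLUMNS)
    return pd.DataFrame(columns=cols)


def _mature_span_from_mapping(window: Window, mature_seq: str) -> tuple[int, int] | None:
    """Locate a known mature sequence inside the window (exact, forward)."""
    pos = to_dna(window.seq).find(to_dna(mature_seq))
    if pos < 0:
        return None
    return (pos + 1, pos + len(mature_seq))


def _mature_span_from_hit(window: Window) -> tuple[int, int]:
    """Presumed mature: hit span extended to the full query length."""
    hs, he = window.hit_span_in_window
    hit = window.hit
    if hit is None:
        return (hs, he)
    qs, qe = hit.aligned_query_span
    lo = max(1, hs - (qs - 1))
    hi = min(len(window.seq), he + (hit.Q - qe))
    return (lo, hi)


def candidate_rows(
    window: Window,
    mature_span: tuple[int, int],
    label: int,
    config: BuildConfig,
    query_meta: dict | None = None,
) -> list[dict]:
    """Fold a window, qualify each structure, and emit feature rows."""
    rows: list[dict] = []
    try:
        structures = fold_all(window.seq, engine=config.engine, params=config.fold)
    except ValueError:
        return rows
    hit = window.hit
    if query_meta is None:
        query_meta = {}
        if hit is not None:
            query_meta = {
                "query_len": hit.Q,
                "query_gc_pct": gc_percent(window.hit_seq),
                "ld": hit.ld,
                "evalue": hit.evalue,
            }
    genomic_meta = {
        "start": window.interval.start,
        "end": window.interval.end,
        "strand": window.interval.strand,
    }
    for rank, structure in enumerate(structures):
        ctx = locate_hit(structure, mature_span)
        verdict = disqualify(structure, ctx, config.qual)
        if not verdict.accepted:
            continue
        try:
            star = infer_star(structure, mature_span)
            stats = duplex_stats(structure, mature_span, star)
        except (StarInferenceError, ValueError):
            continue
        fv = extract_features(
            structure, ctx, stats, query_meta, genomic_meta, verdict=verdict
        )
        row = dict(zip(fv.names, fv.values))
        row["label"] = label
        row["meta_query"] = hit.query_id if hit else ""
        row["meta_seq_id"] = window.interval.seq_id
        row["meta_window_start"] = window.interval.start
        row["meta_window_end"] = window.interval.end
        row["meta_strand"] = window.interval.strand
        row["meta_structure_rank"] = rank
        rows.append(row)
    return rows


def build_positive(
    stemloops: list[SeqRecord],
    genome: list[SeqRecord] | SeqRecord,
    protein_db: list,
    rfam: list[SeqRecord],
    config: BuildConfig | None = None,
    matures: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Compile the positive feature dataset (label 1) from stem-loop queries.

    ``matures`` optionally maps stem-loop ids to their mature sequences;
    when a mapping is present the qualification and duplex statistics are
    evaluated on the mature, as annotated references provide it.
    """
    if not stemloops:
        warnings.warn("empty stem-loop set: returning an empty positive table")
        return _empty_table()
    config = config or BuildConfig()
    subjects = [genome] if isinstance(genome, SeqRecord) else list(genome)
    hits = find_hits(stemloops, subjects, config.homology)
    hits = select_hits(hits, "positive")
    windows = [extract_window(h, subjects, config.flank_positive) for h in hits]

    # redundancy removal on the window sequences
    tagged = [SeqRecord(f"w{i}", w.seq) for i, w in enumerate(windows)]
    reps = cluster_representatives(tagged, config.identity_threshold)
    keep_ids = {r.id for r in reps}
    windows = [w for i, w in enumerate(windows) if f"w{i}" in keep_ids]

    windows = coding_overlap_filter(
        windows, protein_db, "drop_coding", config.coding_evalue_max
    )
    windows = rna_family_filter(
        windows, rfam, config.rfam_identity_min, config.rfam_coverage_min
    )

    # the reference-query feature family describes the mature reference in
    # every compilation mode, so positive rows carry the mature's length,
    # GC and alignment statistics rather than the stem-loop query's
    from .align import evalue as _evalue

    search_space = 2 * sum(len(s.seq) for s in subjects)
    rows: list[dict] = []
    for w in windows:
        span = None
        query_meta = None
        if matures and w.hit is not None and w.hit.query_id in matures:
            mature_seq = matures[w.hit.query_id]
            span = _mature_span_from_mapping(w, mature_seq)
            if span is not None:
                query_meta = {
                    "query_len": len(mature_seq),
                    "query_gc_pct": gc_percent(mature_seq),
                    "ld": 0,
                    "evalue": _evalue(len(mature_seq), len(mature_seq), search_space),
                }
        if span is None:
            span = _mature_span_from_hit(w)
        rows.extend(candidate_rows(w, span, 1, config, query_meta=query_meta))
    if not rows:
        warnings.warn("no qualified positive structures survived the pipeline")
        return _empty_table()
    return _dedupe(pd.DataFrame(rows))


def build_negative(
    mature_mirnas: list[SeqRecord],
    genome: list[SeqRecord] | SeqRecord,
    protein_db: list,
    positive_lengths: list[int],
    config: BuildConfig | None = None,
    n_target: int | None = None,
) -> pd.DataFrame:
    """Compile the decoy feature dataset (label 0).

    Window lengths are drawn (seeded, with replacement) from the positive
    length distribution so that the two classes match; qualified decoys are
    subsampled (seeded, without replacement) to ``n_target`` rows (default:
    the number of length observations provided).
    """
    if not positive_lengths:
        raise ValueError("positive_lengths must be non-empty")
    config = config or BuildConfig()
    rng = np.random.default_rng(config.seed)
    subjects = [genome] if isinstance(genome, SeqRecord) else list(genome)
    hits = find_hits(mature_mirnas, subjects, config.homology)
    hits = select_hits(hits, "decoy")

    windows = []
    for h in hits:
        target_len = int(rng.choice(positive_lengths))
        flank = max(0, round((target_len - len(h.subject_interval)) / 2))
        windows.append(extract_window(h, subjects, flank))

    windows = coding_overlap_filter(
        windows, protein_db, "keep_coding", config.coding_evalue_max
    )

    rows: list[dict] = []
    for w in windows:
        span = _mature_span_from_hit(w)
        rows.extend(candidate_rows(w, span, 0, config))
    if not rows:
        warnings.warn("no qualified decoy structures survived the pipeline")
        return _empty_table()
    table = _dedupe(pd.DataFrame(rows))
    want = n_target if n_target is not None else len(positive_lengths)
    if len(table) > want:
        pick = rng.choice(len(table), size=want, replace=False)
        table = table.iloc[np.sort(pick)].reset_index(drop=True)
    elif len(table) < want:
        warnings.warn(
            f"only {len(table)} qualified decoys available for a target of {want}"
        )
    return table
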