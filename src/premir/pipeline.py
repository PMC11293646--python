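"""Pipeline orchestration: homology search through rule-based selection.

Stages: align the reference matures against the input sequences and select
acceptable hits (E-value and LD caps); extract flanked genomic windows and
remove redundancy; drop windows overlapping coding sequence or rRNA/tRNA;
predict secondary structures; qualify each structure, infer the star
strand and the duplex statistics; extract features and score them with the
discriminator; and finally verify each candidate against the rule engine.
Every stage logs its input/output counts, and the report carries the full
attrition table - an empty result is a report, never a crash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import coding_overlap_filter, rna_family_filter
from .config import QualConfig, RuleConfig, dump_config
from .datasets import _mature_span_from_hit
from .features import FeatureVector, extract_features, feature_names, gc_percent
from .folding import FoldParams, fold_all
from .formats import (
    Interval,
    SecondaryStructure,
    SeqRecord,
    dot_bracket,
    write_bed6,
    write_ct,
    write_fasta,
)
from .hairpin import (
    StarInferenceError,
    Verdict,
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

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Candidate", "PredictionReport", "run_pipeline", "emit_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and thresholds of a prediction run.

    ``model`` is a fitted discriminator exposing ``decision_scores`` (or
    None to skip classification); every threshold is the published default:
    flank 200 nt, E <= 0.001, LD <= 3, probability >= 0.5, rule engine per
    the accepted plant miRNA criteria.
    """

    inputs: tuple[SeqRecord, ...]
    reference_matures: tuple[SeqRecord, ...]
    proteins: tuple = ()
    rfam: tuple[SeqRecord, ...] = ()
    model: object | None = None
    flank: int = 200
    prob_threshold: float = 0.5
    engine: str = "auto"
    identity_threshold: float = 0.9
    coding_evalue_max: float = 0.001
    rfam_identity_min: float = 0.85
    rfam_coverage_min: float = 0.8
    homology: HomologyParams = field(default_factory=HomologyParams)
    qual: QualConfig = field(default_factory=QualConfig)
    rules: RuleConfig = field(default_factory=RuleConfig)
    fold: FoldParams = field(default_factory=lambda: FoldParams(max_structures=5))
    seed: int = 0


@dataclass(frozen=True)
class Candidate:
    """One accepted pre-miRNA prediction."""

    candidate_id: str
    query_id: str
    window: Window
    structure: SecondaryStructure
    structure_rank: int
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    precursor_span: tuple[int, int]
    probability: float | None
    features: FeatureVector
    verdict: Verdict

    @property
    def mature_seq(self) -> str:
        a, b = self.mature_span
        return self.structure.seq[a - 1 : b]

    @property
    def precursor_seq(self) -> str:
        a, b = self.precursor_span
        return self.structure.seq[a - 1 : b]

    @property
    def genomic_interval(self) -> Interval:
        """Precursor position on the input sequence (strand-adjusted)."""
        iv = self.window.interval
        a, b = self.precursor_span
        if iv.strand == "+":
            return Interval(iv.seq_id, iv.start + a - 1, iv.start + b, iv.strand)
        return Interval(iv.seq_id, iv.end - b, iv.end - a + 1, iv.strand)


@dataclass
class PredictionReport:
    candidates: list[Candidate]
    attrition: dict[str, int]
    config: PipelineConfig
    log_lines: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            iv = c.genomic_interval
            rows.append(
                {
                    "candidate_id": c.candidate_id,
                    "query_id": c.query_id,
                    "seq_id": iv.seq_id,
                    "start": iv.start,
                    "end": iv.end,
                    "strand": iv.strand,
                    "probability": c.probability,
                    "mature": c.mature_seq,
                    "precursor": c.precursor_seq,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PredictionReport:
    """Run all pipeline stages and return the prediction report."""
    if not config.inputs:
        raise ValueError("config error: missing key 'inputs'")
    if not config.reference_matures:
        raise ValueError("config error: missing key 'reference_matures'")
    subjects = list(config.inputs)
    att: dict[str, int] = {}
    log_lines: list[str] = [f"seed={config.seed} engine={config.engine} flank={config.flank}"]

    def stage(name: str, n: int):
        att[name] = n
        line = f"stage {name}: {n}"
        log_lines.append(line)
        logger.info(line)

    hits = find_hits(list(config.reference_matures), subjects, config.homology)
    stage("hits", len(hits))
    hits = select_hits(hits, "prediction", config.homology)
    stage("selected_hits", len(hits))

    windows = [extract_window(h, subjects, config.flank) for h in hits]
    stage("windows", len(windows))

    tagged = [SeqRecord(f"w{i}", w.seq) for i, w in enumerate(windows)]
    reps = (
        cluster_representatives(tagged, config.identity_threshold) if tagged else []
    )
    keep = {r.id for r in reps}
    windows = [w for i, w in enumerate(windows) if f"w{i}" in keep]
    stage("representative_windows", len(windows))

    windows = coding_overlap_filter(
        windows, list(config.proteins), "drop_coding", config.coding_evalue_max
    )
    stage("after_coding_filter", len(windows))
    windows = rna_family_filter(
        windows, list(config.rfam), config.rfam_identity_min, config.rfam_coverage_min
    )
    stage("after_rna_family_filter", len(windows))

    n_structures = 0
    qualified = []  # (window, rank, structure, spans, stats, features, verdict)
    for w in windows:
        try:
            structures = fold_all(w.seq, engine=config.engine, params=config.fold)
        except ValueError:
            continue
        n_structures += len(structures)
        mature_span = _mature_span_from_hit(w)
        hit = w.hit
        query_meta = {
            "query_len": hit.Q if hit else len(w.hit_seq),
            "query_gc_pct": gc_percent(w.hit_seq),
            "ld": hit.ld if hit else 0,
            "evalue": hit.evalue if hit else None,
        }
        genomic_meta = {
            "start": w.interval.start,
            "end": w.interval.end,
            "strand": w.interval.strand,
        }
        for rank, structure in enumerate(structures):
            ctx = locate_hit(structure, mature_span)
            verdict = disqualify(structure, ctx, config.qual)
            if not verdict.accepted:
                continue
            try:
                star = infer_star(structure, mature_span)
                stats = duplex_stats(
                    structure, mature_span, star, config.rules.wobble_is_pair
                )
            except (StarInferenceError, ValueError):
                continue
            fv = extract_features(
                structure, ctx, stats, query_meta, genomic_meta, verdict=verdict
            )
            qualified.append((w, rank, structure, mature_span, star, stats, fv))
    stage("folded_structures", n_structures)
    stage("qualified_structures", len(qualified))

    # classification
    if config.model is not None and qualified:
        X = np.vstack([fv.values for *_, fv in qualified])
        probs = config.model.decision_scores(X)
    else:
        probs = [None] * len(qualified)
    classified = [
        (entry, p)
        for entry, p in zip(qualified, probs)
        if p is None or p >= config.prob_threshold
    ]
    stage("classified", len(classified))

    # final rule engine
    from .hairpin import apply_rules

    candidates: list[Candidate] = []
    for (w, rank, structure, mspan, sspan, stats, fv), p in classified:
        verdict = apply_rules(stats, config.rules)
        if not verdict.accepted:
            continue
        pre_span = (min(mspan[0], sspan[0]), max(mspan[1], sspan[1]))
        cid = (
            f"{w.hit.query_id if w.hit else 'q'}|{w.interval.seq_id}:"
            f"{w.interval.start}-{w.interval.end}({w.interval.strand})|s{rank}"
        )
        candidates.append(
            Candidate(
                candidate_id=cid,
                query_id=w.hit.query_id if w.hit else "",
                window=w,
                structure=structure,
                structure_rank=rank,
                mature_span=mspan,
                star_span=sspan,
                precursor_span=pre_span,
                probability=None if p is None else float(p),
                features=fv,
                verdict=verdict,
            )
        )
    stage("rule_passed", len(candidates))
    return PredictionReport(
        candidates=candidates, attrition=att, config=config, log_lines=log_lines
    )


def emit_report(report: PredictionReport, outdir) -> dict[str, Path]:
    """Write the report files: FASTAs, structures, features, BED, attrition."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    files: dict[str, Path] = {}
    cands = report.candidates

    precursors = [
        SeqRecord(c.candidate_id, c.precursor_seq) for c in cands
    ]
    matures = [SeqRecord(c.candidate_id, c.mature_seq) for c in cands]
    files["precursors"] = outdir / "precursors.fasta"
    files["precursors"].write_text(write_fasta(precursors) if precursors else "")
    files["matures"] = outdir / "matures.fasta"
    files["matures"].write_text(write_fasta(matures) if matures else "")

    ct_text = []
    db_text = []
    for c in cands:
        ct_text.append(write_ct(c.structure, name=c.candidate_id))
        db_text.append(f">{c.candidate_id}\n{c.structure.seq}\n{dot_bracket(c.structure)}\n")
    files["structures_ct"] = outdir / "structures.ct"
    files["structures_ct"].write_text("".join(ct_text))
    files["structures_db"] = outdir / "structures.dbn"
    files["structures_db"].write_text("".join(db_text))

    feat = pd.DataFrame(
        [dict(zip(c.features.names, c.features.values)) for c in cands],
        columns=list(feature_names()),
    )
    feat.insert(0, "candidate_id", [c.candidate_id for c in cands])
    files["features"] = outdir / "features.tsv"
    feat.to_csv(files["features"], sep="\t", index=False)

    files["predictions"] = outdir / "predictions.bed"
    files["predictions"].write_text(
        write_bed6(
            [
                (
                    c.genomic_interval,
                    c.candidate_id,
                    c.probability if c.probability is not None else 0.0,
                )
                for c in cands
            ]
        )
    )

    att = pd.DataFrame(
        list(report.attrition.items()), columns=["stage", "count"]
    )
    files["attrition"] = outdir / "attrition.tsv"
    att.to_csv(files["attrition"], sep="\t", index=False)

    files["log"] = outdir / "run.log"
    cfg = report.config
    files["log"].write_text(
        "\n".join(
            report.log_lines
            + [dump_config(cfg.rules, cfg.qual, {"flank": cfg.flank, "engine": cfg.engine, "seed": cfg.seed})]
        )
    )
    return files
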