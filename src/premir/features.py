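"""The 170-feature record computed for every qualified candidate structure.

Features are organized in 8 named families with fixed sizes:

====================  ====
primary                  7
reference_query          4
genomic_positions        5
nucleotide_composition   4
energy                   8
linear_sequence         23
pair_composition        36
major_structural        83
====================  ====

The exact member list is fixed by this package and shipped as a
machine-readable schema (``data/feature_schema.tsv``); the family sizes and
row descriptions are the binding contract.  Undefined numeric values carry
the sentinel -1 (documented per feature in the schema file).

Notes on interpretation: the nucleotide-composition family holds the four
GC contents (whole window, main branch, pre-miRNA, mature); full
tetranucleotide frequencies cannot fit a 4-feature family and are emitted
to an optional side table instead (:func:`tetranucleotide_table`).
The "crucial positions" of the pair-composition family are the mature
5'-end positions 1-8 (seed included), the central positions 9-11, the
mature 3'-end triplet, and the first/last two star positions - the
segments adjacent to the DICER cut sites plus the seed region.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .formats import SecondaryStructure
from .folding import eval_energy
from .hairpin import DuplexStats, HitContext, Verdict

__all__ = [
    "FeatureVector",
    "FAMILY_SIZES",
    "feature_names",
    "feature_families",
    "schema_table",
    "compute_energy_features",
    "compute_composition",
    "extract_features",
    "tetranucleotide_table",
]

FAMILY_SIZES = {
    "primary": 7,
    "reference_query": 4,
    "genomic_positions": 5,
    "nucleotide_composition": 4,
    "energy": 8,
    "linear_sequence": 23,
    "pair_composition": 36,
    "major_structural": 83,
}

SENTINEL = -1.0

_ARM_CODE = {"5p": 1, "3p": 2, "loop": 3, "crossing": 4}
_BASE_CODE = {"A": 1, "C": 2, "G": 3, "U": 4, "N": 0}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

_MAX_MISMATCH_SLOTS = 12
_MAX_BULGE_SLOTS = 8
_MAX_LOOP_SLOTS = 6


def _schema() -> list[tuple[str, str, str]]:
    """(name, family, description) rows, in canonical order."""
    rows: list[tuple[str, str, str]] = []

    def add(family, name, desc):
        rows.append((name, family, desc))

    # primary
    add("primary", "pf_qualified", "1 when the structure passed disqualification and the primary filter")
    add("primary", "pf_hit_paired_pct", "percentage of hit positions paired (complementarity of the hit region)")
    add("primary", "pf_hit_longest_unpaired_run", "longest run of unpaired positions inside the hit")
    add("primary", "pf_arm", "predicted mature arm: 1=5p 2=3p 3=loop 4=crossing")
    add("primary", "pf_terminal_structures", "hairpin loops distal to the hit on its branch")
    add("primary", "pf_hit_n_pairs", "number of paired positions inside the hit")
    add("primary", "pf_hit_len", "hit length (nt)")
    # reference query
    add("reference_query", "rq_query_len", "length of the reference miRNA query (nt)")
    add("reference_query", "rq_query_gc_pct", "GC content of the reference query (0-100)")
    add("reference_query", "rq_ld", "level of dissimilarity of the homology hit (Q - Qa + G + M)")
    add("reference_query", "rq_neglog10_evalue", "-log10 expectation value of the hit (capped at 300)")
    # genomic positions
    add("genomic_positions", "gp_window_start", "window start on the input sequence (0-based)")
    add("genomic_positions", "gp_window_end", "window end on the input sequence (exclusive)")
    add("genomic_positions", "gp_strand", "+1 forward, -1 reverse")
    add("genomic_positions", "gp_hit_start_in_window", "hit start as a percentage of the window length")
    add("genomic_positions", "gp_mature_start_in_precursor", "1-based mature start within the pre-miRNA")
    # nucleotide composition
    add("nucleotide_composition", "nc_gc_window_pct", "GC content of the whole window (0-100)")
    add("nucleotide_composition", "nc_gc_main_branch_pct", "GC content of the main branch")
    add("nucleotide_composition", "nc_gc_premirna_pct", "GC content of the pre-miRNA span")
    add("nucleotide_composition", "nc_gc_mature_pct", "GC content of the mature sequence")
    # energy
    add("energy", "en_fe_window", "free energy of the whole window structure (kcal/mol)")
    add("energy", "en_mfei_window", "MFEI of the whole window (AMFE / GC%)")
    add("energy", "en_fe_main_branch", "free energy of the main branch substructure")
    add("energy", "en_amfe_main_branch", "AMFE of the main branch ((FE/L)*100)")
    add("energy", "en_mfei_main_branch", "MFEI of the main branch")
    add("energy", "en_fe_premirna", "free energy of the pre-miRNA substructure")
    add("energy", "en_amfe_premirna", "AMFE of the pre-miRNA")
    add("energy", "en_mfei_premirna", "MFEI of the pre-miRNA")
    # linear sequence: spans on the folded window (1-based inclusive)
    for what in (
        "hit",
        "mature",
        "star",
        "premirna",
        "main_branch",
        "terminal_loop",
        "duplex_guide",
        "duplex_star",
        "longest_stem",
    ):
        add("linear_sequence", f"ls_{what}_start", f"start of the {what.replace('_', ' ')}, relative to the precursor start (1-based)")
        add("linear_sequence", f"ls_{what}_end", f"end of the {what.replace('_', ' ')}, relative to the precursor start (1-based)")
    add("linear_sequence", "ls_window_len", "window length (nt)")
    add("linear_sequence", "ls_mature_offset_in_precursor", "mature start relative to the precursor (1-based)")
    add("linear_sequence", "ls_star_offset_in_precursor", "star start relative to the precursor (1-based)")
    add("linear_sequence", "ls_loop_len", "terminal loop length (nt)")
    add("linear_sequence", "ls_main_branch_len", "main branch length (nt)")
    # pair composition at crucial positions
    for label in _crucial_labels():
        add("pair_composition", f"pc_{label}_state", "pair state: 0 unpaired, 1 Watson-Crick, 2 G:U wobble, 3 other")
        add("pair_composition", f"pc_{label}_partner", "partner base: 0 none, 1 A, 2 C, 3 G, 4 U")
    # major structural
    for name, desc in (
        ("ms_n_mismatch", "mismatched duplex positions (unpaired guide + passenger excess)"),
        ("ms_n_asym", "nucleotides in asymmetric duplex bulges"),
        ("ms_n_sym_mismatch", "symmetric mismatched positions (min side of every duplex gap)"),
        ("ms_n_bulges", "one-sided duplex gaps (bulges)"),
        ("ms_n_internal_loops", "two-sided duplex gaps (internal loops)"),
        ("ms_n_hairpin_loops", "hairpin loops in the whole window structure"),
        ("ms_n_multiloops", "multibranch loops in the whole window structure"),
        ("ms_n_stems", "stems in the whole window structure"),
        ("ms_secondary_stem", "1 when a duplex position pairs outside the opposite strand span"),
        ("ms_largest_loop", "largest duplex gap side (nt)"),
        ("ms_largest_bulge", "largest one-sided duplex gap (nt)"),
        ("ms_apical_loop_size", "terminal loop size (nt)"),
        ("ms_apical_loop_start", "terminal loop start relative to the precursor (1-based)"),
        ("ms_apical_loop_end", "terminal loop end relative to the precursor (1-based)"),
        ("ms_overhang_5p", "3' overhang at the 5p-arm strand (nt)"),
        ("ms_overhang_3p", "3' overhang at the 3p-arm strand (nt)"),
        ("ms_mature_len", "mature length (nt)"),
        ("ms_star_len", "star length (nt)"),
        ("ms_precursor_len", "pre-miRNA length (nt)"),
        ("ms_duplex_pairs", "paired positions in the duplex"),
        ("ms_longest_stem", "longest stem in the window structure (pairs)"),
        ("ms_mean_stem_len", "mean stem length in the window structure (pairs)"),
        ("ms_duplex_paired_pct", "percentage of guide duplex-region positions paired"),
    ):
        add("major_structural", name, desc)
    for k in range(1, _MAX_MISMATCH_SLOTS + 1):
        add("major_structural", f"ms_mismatch_pos_{k}", f"mature-relative position of mismatch #{k} (-1 when absent)")
    for k in range(1, _MAX_BULGE_SLOTS + 1):
        add("major_structural", f"ms_bulge_{k}_pos", f"mature-relative position of duplex bulge #{k} (-1 when absent)")
        add("major_structural", f"ms_bulge_{k}_size", f"size of duplex bulge #{k} (nt, -1 when absent)")
        add("major_structural", f"ms_bulge_{k}_side", f"side of duplex bulge #{k}: 1 guide, 2 passenger (-1 when absent)")
    for k in range(1, _MAX_LOOP_SLOTS + 1):
        add("major_structural", f"ms_iloop_{k}_pos", f"mature-relative position of internal loop #{k} (-1 when absent)")
        add("major_structural", f"ms_iloop_{k}_left", f"guide-side size of internal loop #{k} (-1 when absent)")
        add("major_structural", f"ms_iloop_{k}_right", f"passenger-side size of internal loop #{k} (-1 when absent)")
        add("major_structural", f"ms_iloop_{k}_asym", f"asymmetry |left-right| of internal loop #{k} (-1 when absent)")
    return rows


def _crucial_labels() -> list[str]:
    labels = [f"mat{i}" for i in range(1, 9)]          # 5' end + seed (2-8)
    labels += [f"mat{i}" for i in (9, 10, 11)]          # central cut-adjacent
    labels += ["mat_end2", "mat_end1", "mat_end0"]      # mature 3' triplet
    labels += ["star_first1", "star_first2", "star_last2", "star_last1"]
    return labels


_SCHEMA = _schema()
_NAMES = tuple(r[0] for r in _SCHEMA)
_FAMILIES = tuple(r[1] for r in _SCHEMA)

assert len(_NAMES) == 170 and len(set(_NAMES)) == 170
for fam, size in FAMILY_SIZES.items():
    assert _FAMILIES.count(fam) == size, fam


def feature_names() -> tuple[str, ...]:
    return _NAMES


def feature_families() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {fam: [] for fam in FAMILY_SIZES}
    for name, fam, _ in _SCHEMA:
        out[fam].append(name)
    return out


def schema_table() -> pd.DataFrame:
    return pd.DataFrame(_SCHEMA, columns=["name", "family", "description"])


def write_schema_file(path) -> None:
    schema_table().to_csv(path, sep="\t", index=False)


def packaged_schema() -> pd.DataFrame:
    with resources.files("premir").joinpath("data/feature_schema.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def families(self) -> dict[str, list[str]]:
        return feature_families()


# ---------------------------------------------------------------------------


def gc_percent(seq: str) -> float:
    if not seq:
        return SENTINEL
    return 100.0 * sum(1 for c in seq.upper() if c in "GC") / len(seq)


def compute_composition(seq_segments: dict[str, str]) -> dict[str, float]:
    """GC content (0-100) of the window, main branch, pre-miRNA and mature."""
    return {
        "nc_gc_window_pct": gc_percent(seq_segments.get("window", "")),
        "nc_gc_main_branch_pct": gc_percent(seq_segments.get("main_branch", "")),
        "nc_gc_premirna_pct": gc_percent(seq_segments.get("premirna", "")),
        "nc_gc_mature_pct": gc_percent(seq_segments.get("mature", "")),
    }


def _amfe(fe: float, length: int) -> float:
    return (fe / length) * 100.0 if length else 0.0


def _mfei(amfe: float, gc_pct: float) -> float:
    return amfe / gc_pct if gc_pct > 0 else 0.0


def compute_energy_features(
    structure: SecondaryStructure,
    ctx: HitContext,
    premirna_span: tuple[int, int],
) -> dict[str, float]:
    """FE/AMFE/MFEI for the main branch and pre-miRNA, FE/MFEI for the window.

    AMFE = (FE / L) * 100; MFEI = AMFE / GC% with GC on the 0-100 scale
    (defined as 0 when GC = 0).
    """
    fe_whole = structure.energy if structure.energy is not None else eval_energy(structure)
    gc_whole = gc_percent(structure.seq)
    out = {
        "en_fe_window": fe_whole,
        "en_mfei_window": _mfei(_amfe(fe_whole, len(structure)), gc_whole),
    }
    if ctx.main_branch is not None:
        a, b = ctx.main_branch
        sub = structure.substructure(a, b)
        fe = eval_energy(sub)
        amfe = _amfe(fe, len(sub))
        out.update(
            en_fe_main_branch=fe,
            en_amfe_main_branch=amfe,
            en_mfei_main_branch=_mfei(amfe, gc_percent(sub.seq)),
        )
    else:
        out.update(
            en_fe_main_branch=0.0, en_amfe_main_branch=0.0, en_mfei_main_branch=0.0
        )
    a, b = premirna_span
    sub = structure.substructure(a, b)
    fe = eval_energy(sub)
    amfe = _amfe(fe, len(sub))
    out.update(
        en_fe_premirna=fe,
        en_amfe_premirna=amfe,
        en_mfei_premirna=_mfei(amfe, gc_percent(sub.seq)),
    )
    return out


def _pair_state(structure: SecondaryStructure, pos: int | None) -> tuple[float, float]:
    if pos is None or not (1 <= pos <= len(structure)):
        return (SENTINEL, SENTINEL)
    q = structure.partner(pos)
    if q == 0:
        return (0.0, 0.0)
    duo = (structure.seq[pos - 1], structure.seq[q - 1])
    if duo in _WC:
        state = 1.0
    elif duo in _WOBBLE:
        state = 2.0
    else:
        state = 3.0
    return (state, float(_BASE_CODE.get(structure.seq[q - 1], 0)))


def extract_features(
    structure: SecondaryStructure,
    ctx: HitContext,
    stats: DuplexStats,
    query_meta: dict | None = None,
    genomic_meta: dict | None = None,
    verdict: Verdict | None = None,
) -> FeatureVector:
    """Assemble the complete 170-feature record for a qualified candidate.

    ``verdict``, when given, must be an accepted disqualification verdict;
    an unqualified candidate is a contract error.  ``query_meta`` carries
    reference-query information (query_len, query_gc_pct, ld, evalue);
    ``genomic_meta`` carries window coordinates (start, end, strand).
    """
    if verdict is not None and not verdict.accepted:
        raise ValueError(
            "cannot extract features from an unqualified candidate; "
            "run disqualify first and pass an accepted verdict"
        )
    query_meta = query_meta or {}
    genomic_meta = genomic_meta or {}
    vals: dict[str, float] = {}

    hs, he = ctx.hit_span
    hit_len = he - hs + 1
    paired_hit = [p for p in range(hs, he + 1) if structure.partner(p)]
    run = best_run = 0
    for p in range(hs, he + 1):
        if structure.partner(p) == 0:
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0

    vals["pf_qualified"] = 1.0
    vals["pf_hit_paired_pct"] = 100.0 * len(paired_hit) / hit_len
    vals["pf_hit_longest_unpaired_run"] = float(best_run)
    vals["pf_arm"] = float(_ARM_CODE.get(ctx.arm, SENTINEL))
    vals["pf_terminal_structures"] = float(ctx.terminal_structure_count)
    vals["pf_hit_n_pairs"] = float(len(paired_hit))
    vals["pf_hit_len"] = float(hit_len)

    vals["rq_query_len"] = float(query_meta.get("query_len", SENTINEL))
    vals["rq_query_gc_pct"] = float(query_meta.get("query_gc_pct", SENTINEL))
    vals["rq_ld"] = float(query_meta.get("ld", SENTINEL))
    ev = query_meta.get("evalue")
    vals["rq_neglog10_evalue"] = (
        SENTINEL if ev is None else min(300.0, -np.log10(max(ev, 1e-300)))
    )

    vals["gp_window_start"] = float(genomic_meta.get("start", SENTINEL))
    vals["gp_window_end"] = float(genomic_meta.get("end", SENTINEL))
    strand = genomic_meta.get("strand")
    vals["gp_strand"] = SENTINEL if strand is None else (1.0 if strand == "+" else -1.0)
    vals["gp_hit_start_in_window"] = 100.0 * hs / len(structure)

    ms, me = stats.mir_span
    ss, se = stats.star_span
    pre_lo = min(ms, ss)
    pre_hi = max(me, se)
    vals["gp_mature_start_in_precursor"] = float(ms - pre_lo + 1)

    mb = ctx.main_branch
    segs = {
        "window": structure.seq,
        "main_branch": structure.seq[mb[0] - 1 : mb[1]] if mb else "",
        "premirna": structure.seq[pre_lo - 1 : pre_hi],
        "mature": structure.seq[ms - 1 : me],
    }
    vals.update(compute_composition(segs))
    vals.update(compute_energy_features(structure, ctx, (pre_lo, pre_hi)))

    # structure elements of the whole window
    from .hairpin import decompose

    elements = decompose(structure)
    stems = [e for e in elements if e.kind == "stem"]
    stem_lens = [len(e.positions) // 2 for e in stems]
    longest_stem = max(stems, key=lambda e: len(e.positions), default=None)

    duplex_guide = [
        p for p in range(ms, me + 1) if ss <= structure.partner(p) <= se
    ]
    d_lo = duplex_guide[0] if duplex_guide else None
    d_hi = duplex_guide[-1] if duplex_guide else None
    star_partners = sorted(structure.partner(p) for p in duplex_guide)

    spans: dict[str, tuple[float, float]] = {
        "hit": (hs, he),
        "mature": (ms, me),
        "star": (ss, se),
        "premirna": (pre_lo, pre_hi),
        "main_branch": mb if mb else (SENTINEL, SENTINEL),
        "terminal_loop": ctx.terminal_loop if ctx.terminal_loop else (SENTINEL, SENTINEL),
        "duplex_guide": (d_lo, d_hi) if duplex_guide else (SENTINEL, SENTINEL),
        "duplex_star": (star_partners[0], star_partners[-1])
        if star_partners
        else (SENTINEL, SENTINEL),
        "longest_stem": (
            (longest_stem.positions[0], longest_stem.positions[-1])
            if longest_stem
            else (SENTINEL, SENTINEL)
        ),
    }
    # linear positions are anchored on the precursor start so that they do
    # not scale with the (configurable) window flank
    for what, (a, b) in spans.items():
        if a == SENTINEL:
            vals[f"ls_{what}_start"] = SENTINEL
            vals[f"ls_{what}_end"] = SENTINEL
        else:
            vals[f"ls_{what}_start"] = float(a - pre_lo + 1)
            vals[f"ls_{what}_end"] = float(b - pre_lo + 1)
    vals["ls_window_len"] = float(len(structure))
    vals["ls_mature_offset_in_precursor"] = float(ms - pre_lo + 1)
    vals["ls_star_offset_in_precursor"] = float(ss - pre_lo + 1)
    tl = ctx.terminal_loop
    vals["ls_loop_len"] = float(tl[1] - tl[0] + 1) if tl else SENTINEL
    vals["ls_main_branch_len"] = float(mb[1] - mb[0] + 1) if mb else SENTINEL

    # pair composition at crucial positions
    mat_positions: list[int | None] = [
        ms + i - 1 if ms + i - 1 <= me else None for i in range(1, 9)
    ]
    mat_positions += [ms + i - 1 if ms + i - 1 <= me else None for i in (9, 10, 11)]
    mat_positions += [me - 2 if me - 2 >= ms else None, me - 1 if me - 1 >= ms else None, me]
    star_positions = [ss, ss + 1 if ss + 1 <= se else None,
                      se - 1 if se - 1 >= ss else None, se]
    for label, pos in zip(_crucial_labels(), mat_positions + star_positions):
        state, partner = _pair_state(structure, pos)
        vals[f"pc_{label}_state"] = state
        vals[f"pc_{label}_partner"] = partner

    # major structural
    gaps = stats.internal_loops  # (mature pos, left, right)
    bulges = [(p, l + r, 1 if l else 2) for p, l, r in gaps if (l == 0) != (r == 0)]
    iloops = [(p, l, r) for p, l, r in gaps if l > 0 and r > 0]
    hairpin_loops = [e for e in elements if e.kind == "hairpin_loop"]
    multiloops = [e for e in elements if e.kind == "multiloop"]

    vals["ms_n_mismatch"] = float(stats.n_mismatch)
    vals["ms_n_asym"] = float(stats.n_asym)
    vals["ms_n_sym_mismatch"] = float(sum(min(l, r) for _, l, r in gaps))
    vals["ms_n_bulges"] = float(len(bulges))
    vals["ms_n_internal_loops"] = float(len(iloops))
    vals["ms_n_hairpin_loops"] = float(len(hairpin_loops))
    vals["ms_n_multiloops"] = float(len(multiloops))
    vals["ms_n_stems"] = float(len(stems))
    vals["ms_secondary_stem"] = 1.0 if stats.secondary_stem else 0.0
    vals["ms_largest_loop"] = float(stats.largest_loop)
    vals["ms_largest_bulge"] = float(max((s for _, s, _ in bulges), default=0))
    vals["ms_apical_loop_size"] = float(tl[1] - tl[0] + 1) if tl else SENTINEL
    vals["ms_apical_loop_start"] = float(tl[0] - pre_lo + 1) if tl else SENTINEL
    vals["ms_apical_loop_end"] = float(tl[1] - pre_lo + 1) if tl else SENTINEL
    vals["ms_overhang_5p"] = float(stats.overhang_5p_side)
    vals["ms_overhang_3p"] = float(stats.overhang_3p_side)
    vals["ms_mature_len"] = float(stats.mir_len)
    vals["ms_star_len"] = float(stats.star_len)
    vals["ms_precursor_len"] = float(stats.precursor_len)
    vals["ms_duplex_pairs"] = float(stats.n_duplex_pairs)
    vals["ms_longest_stem"] = float(max(stem_lens, default=0))
    vals["ms_mean_stem_len"] = float(np.mean(stem_lens)) if stem_lens else 0.0
    dup_region = (d_hi - d_lo + 1) if duplex_guide else 0
    vals["ms_duplex_paired_pct"] = (
        100.0 * stats.n_duplex_pairs / dup_region if dup_region else 0.0
    )

    mism = list(stats.mismatch_positions)[:_MAX_MISMATCH_SLOTS]
    for k in range(1, _MAX_MISMATCH_SLOTS + 1):
        vals[f"ms_mismatch_pos_{k}"] = float(mism[k - 1]) if k <= len(mism) else SENTINEL
    for k in range(1, _MAX_BULGE_SLOTS + 1):
        if k <= len(bulges):
            p, s, side = bulges[k - 1]
            vals[f"ms_bulge_{k}_pos"] = float(p)
            vals[f"ms_bulge_{k}_size"] = float(s)
            vals[f"ms_bulge_{k}_side"] = float(side)
        else:
            vals[f"ms_bulge_{k}_pos"] = SENTINEL
            vals[f"ms_bulge_{k}_size"] = SENTINEL
            vals[f"ms_bulge_{k}_side"] = SENTINEL
    for k in range(1, _MAX_LOOP_SLOTS + 1):
        if k <= len(iloops):
            p, l, r = iloops[k - 1]
            vals[f"ms_iloop_{k}_pos"] = float(p)
            vals[f"ms_iloop_{k}_left"] = float(l)
            vals[f"ms_iloop_{k}_right"] = float(r)
            vals[f"ms_iloop_{k}_asym"] = float(abs(l - r))
        else:
            vals[f"ms_iloop_{k}_pos"] = SENTINEL
            vals[f"ms_iloop_{k}_left"] = SENTINEL
            vals[f"ms_iloop_{k}_right"] = SENTINEL
            vals[f"ms_iloop_{k}_asym"] = SENTINEL

    values = np.array([vals[name] for name in _NAMES], dtype=float)
    return FeatureVector(names=_NAMES, values=values)


def tetranucleotide_table(seq: str) -> pd.Series:
    """Optional side table: frequencies of all 256 tetranucleotides."""
    from itertools import product

    seq = seq.upper().replace("T", "U")
    counts = {"".join(p): 0 for p in product("ACGU", repeat=4)}
    total = 0
    for i in range(len(seq) - 3):
        word = seq[i : i + 4]
        if word in counts:
            counts[word] += 1
            total += 1
    return pd.Series(
        {k: (v / total if total else 0.0) for k, v in counts.items()}
    )
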