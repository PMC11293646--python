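"""Hairpin structure analysis: decomposition, hit location, qualification,
miRNA* inference, duplex statistics, and the final rule engine.

Positions throughout are 1-based on the folded window (CT convention).
The guide/passenger duplex is walked between the mature span and the star
span; a gap between consecutive duplex pairs with l unpaired guide
nucleotides and r passenger nucleotides contributes

* ``min`` side as symmetric mismatched positions,
* ``|l - r|`` to the asymmetric-bulge count,

so ``n_mismatch = sum(l) + sum(max(0, r - l))`` (guide positions unpaired
within the duplex plus passenger-side excess) and
``n_asym = sum(|l - r|)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import QualConfig, RuleConfig
from .formats import SecondaryStructure

__all__ = [
    "StructureElement",
    "HitContext",
    "DuplexStats",
    "Verdict",
    "StarInferenceError",
    "decompose",
    "locate_hit",
    "disqualify",
    "infer_star",
    "duplex_stats",
    "apply_rules",
]

WOBBLE = {("G", "U"), ("U", "G")}


class StarInferenceError(ValueError):
    """The mature span has no paired positions to anchor the star on."""


@dataclass(frozen=True)
class StructureElement:
    kind: str  # stem | hairpin_loop | internal_loop | bulge | multiloop | exterior
    positions: tuple[int, ...]


@dataclass(frozen=True)
class HitContext:
    structure: SecondaryStructure
    hit_span: tuple[int, int]
    arm: str  # 5p | 3p | loop | crossing
    main_branch: tuple[int, int] | None
    terminal_structure_count: int
    terminal_loop: tuple[int, int] | None


@dataclass(frozen=True)
class DuplexStats:
    mir_span: tuple[int, int]
    star_span: tuple[int, int]
    n_mismatch: int
    n_asym: int
    largest_loop: int
    secondary_stem: bool
    overhang_5p_side: int
    overhang_3p_side: int
    mir_len: int
    star_len: int
    precursor_len: int
    mismatch_positions: tuple[int, ...] = ()  # mature-relative, 1-based
    internal_loops: tuple[tuple[int, int, int], ...] = ()  # (mature pos, l, r)
    n_duplex_pairs: int = 0


@dataclass(frozen=True)
class Verdict:
    accepted: bool
    violated: tuple[str, ...]
    stage: str

    def __post_init__(self):
        if self.accepted != (len(self.violated) == 0):
            raise ValueError("accepted must mirror an empty violation list")


# ---------------------------------------------------------------------------
# decomposition


def _pair_children(structure: SecondaryStructure):
    """Map each pair (i,j) -> list of directly nested pairs; None -> top level."""
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for i, j in structure.paired_positions():
        while stack and not (stack[-1][0] < i and j < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append((i, j))
        children.setdefault((i, j), [])
        stack.append((i, j))
    return children


def decompose(structure: SecondaryStructure) -> list[StructureElement]:
    """Partition positions 1..L into stems, loops, and the exterior.

    Stems are maximal runs of stacked pairs; a bulge is a one-sided
    internal loop; the hairpin loop sits under a childless pair; unpaired
    positions under a pair with several children form a multiloop; unpaired
    positions outside every pair are exterior.
    """
    L = len(structure)
    children = _pair_children(structure)
    elements: list[StructureElement] = []

    # stems: walk helices, grouping stacked pairs
    visited: set[tuple[int, int]] = set()
    for pair in structure.paired_positions():
        if pair in visited:
            continue
        run = [pair]
        visited.add(pair)
        cur = pair
        while True:
            kids = children.get(cur, [])
            if len(kids) == 1:
                k, l = kids[0]
                if k == cur[0] + 1 and l == cur[1] - 1:
                    run.append((k, l))
                    visited.add((k, l))
                    cur = (k, l)
                    continue
            break
        positions = tuple(sorted(p for ij in run for p in ij))
        elements.append(StructureElement("stem", positions))

    # loops
    for closing, kids in children.items():
        if closing is None:
            continue
        i, j = closing
        if not kids:
            span = tuple(range(i + 1, j))
            elements.append(StructureElement("hairpin_loop", span))
        elif len(kids) == 1:
            k, l = kids[0]
            left = tuple(range(i + 1, k))
            right = tuple(range(l + 1, j))
            if not left and not right:
                continue  # stacked pair, already inside a stem
            kind = "bulge" if (not left or not right) else "internal_loop"
            elements.append(StructureElement(kind, left + right))
        else:
            unpaired = []
            covered = set()
            for k, l in kids:
                covered.update(range(k, l + 1))
            for p in range(i + 1, j):
                if p not in covered and structure.partner(p) == 0:
                    unpaired.append(p)
            elements.append(StructureElement("multiloop", tuple(unpaired)))

    # exterior
    top_covered: set[int] = set()
    for i, j in children[None]:
        top_covered.update(range(i, j + 1))
    exterior = tuple(
        p for p in range(1, L + 1) if p not in top_covered and structure.partner(p) == 0
    )
    if exterior:
        elements.append(StructureElement("exterior", exterior))
    return elements


# ---------------------------------------------------------------------------
# hit location


def _terminal_loops_within(structure: SecondaryStructure, span: tuple[int, int]) -> list[tuple[int, int]]:
    """Hairpin loops (childless closing pairs) fully inside a 1-based span."""
    children = _pair_children(structure)
    out = []
    for pair, kids in children.items():
        if pair is None or kids:
            continue
        i, j = pair
        if span[0] <= i and j <= span[1]:
            out.append((i + 1, j - 1))
    return sorted(out)


def locate_hit(structure: SecondaryStructure, hit_span: tuple[int, int]) -> HitContext:
    """Place the homology hit on a folded window: arm, branch, apex count."""
    hs, he = hit_span
    if not (1 <= hs <= he <= len(structure)):
        raise ValueError("hit span outside the structure")
    paired = [p for p in range(hs, he + 1) if structure.partner(p)]
    if not paired:
        return HitContext(structure, hit_span, "loop", None, 0, None)

    # innermost pair with an endpoint inside the hit
    cand = []
    for p in paired:
        q = structure.partner(p)
        i, j = (p, q) if p < q else (q, p)
        cand.append((j - i, i, j))
    _, ii, jj = min(cand)

    # main branch: the top-level ancestor of the innermost hit pair
    children = _pair_children(structure)
    main = None
    for i, j in children[None]:
        if i <= ii and jj <= j:
            main = (i, j)
            break

    # descend to the terminal loop under the innermost hit pair
    loops = _terminal_loops_within(structure, (ii, jj))
    terminal = loops[0] if loops else None
    count = len(loops)

    if terminal is None:
        # hit pair closes no hairpin loop inside it (cannot happen for valid
        # pairs: every pair encloses at least one hairpin loop)
        terminal = (ii + 1, jj - 1)
        count = 1
    has5 = any(p < terminal[0] for p in paired)
    has3 = any(p > terminal[1] for p in paired)
    if has5 and has3:
        arm = "crossing"
    elif has5:
        arm = "5p"
    elif has3:
        arm = "3p"
    else:  # paired positions only inside the loop span: treat as loop
        arm = "loop"
    return HitContext(structure, hit_span, arm, main, count, terminal)


# ---------------------------------------------------------------------------
# disqualification and primary filter


def disqualify(
    structure: SecondaryStructure,
    ctx: HitContext,
    config: QualConfig | None = None,
) -> Verdict:
    """Apply the six structural disqualification rules plus the primary filter.

    Rules (violation ids): the hit is not involved in a double-stranded
    stem (i); only a few residues in complementarity (ii); no continuous
    complementary region (iii); inner branches in the hit (iv);
    complementary to a branched region (v); hit not entirely on one side
    of the duplex (vi).  Primary filter: at most ``max_terminal_structures``
    terminal structures on the branch and no large internal loops in the
    duplex region.  All violations are accumulated, never short-circuited.
    """
    config = config or QualConfig()
    hs, he = ctx.hit_span
    n = he - hs + 1
    paired = [p for p in range(hs, he + 1) if structure.partner(p)]
    frac = len(paired) / n

    violated: list[str] = []
    if frac <= config.min_stem_frac:
        violated.append("i")
    if frac < config.min_paired_frac:
        violated.append("ii")
    # longest unpaired run in the hit
    run = best = 0
    for p in range(hs, he + 1):
        if structure.partner(p) == 0:
            run += 1
            best = max(best, run)
        else:
            run = 0
    if best > config.max_unpaired_run:
        violated.append("iii")
    # inner branches: a complete pair inside the hit span
    if any(
        hs <= i and j <= he for i, j in structure.paired_positions()
    ):
        violated.append("iv")
    # complementary region branched
    if paired:
        partners = [structure.partner(p) for p in paired]
        lo, hi = min(partners), max(partners)
        for i, j in structure.paired_positions():
            if lo <= i and j <= hi:
                if not (hs <= i <= he or hs <= j <= he):
                    violated.append("v")
                    break
    if ctx.arm == "crossing":
        violated.append("vi")

    stage = "disqualification"
    if not violated:
        stage = "primary_filter"
        if ctx.terminal_structure_count > config.max_terminal_structures:
            violated.append("primary_terminal_structures")
        if paired:
            gaps = _duplex_gaps(structure, paired)
            if any(
                max(l, r) > config.max_internal_loop_side for l, r in gaps
            ):
                violated.append("primary_large_loop")
    return Verdict(accepted=not violated, violated=tuple(violated), stage=stage)


def _duplex_gaps(structure: SecondaryStructure, paired: list[int]):
    """(left, right) sizes of gaps between consecutive paired hit positions."""
    gaps = []
    for a, b in zip(paired, paired[1:]):
        l = b - a - 1
        r = abs(structure.partner(a) - structure.partner(b)) - 1
        if l or r:
            gaps.append((l, r))
    return gaps


# ---------------------------------------------------------------------------
# star inference


def infer_star(structure: SecondaryStructure, mir_span: tuple[int, int]) -> tuple[int, int]:
    """Infer the passenger (miRNA*) span from the duplex 2-nt 3'-overhang rule.

    The star 3' end is the partner of the mature 5' end offset by +2; the
    star 5' end is the partner of the mature position ``end - 2``.  Unpaired
    mature end positions are resolved by scanning inward to the nearest
    paired position and re-applying the offset.  The result is clipped to
    the structure bounds.
    """
    ms, me = mir_span
    L = len(structure)
    if not (1 <= ms <= me <= L):
        raise ValueError("mature span outside the structure")
    if not any(structure.partner(p) for p in range(ms, me + 1)):
        raise StarInferenceError("mature span has no paired positions")

    # star 3' end from the mature 5' end
    p = ms
    while p <= me and structure.partner(p) == 0:
        p += 1
    star_3p = structure.partner(p) + (p - ms) + 2

    # star 5' end from the mature 3' end minus the overhang
    q = me - 2
    while q >= ms and structure.partner(q) == 0:
        q -= 1
    if q < ms:  # all pairs sit beyond me-2; scan forward instead
        q = ms
        while structure.partner(q) == 0:
            q += 1
    star_5p = structure.partner(q) - ((me - 2) - q)

    lo, hi = sorted((star_5p, star_3p))
    return (max(1, lo), min(L, hi))


# ---------------------------------------------------------------------------
# duplex statistics


def duplex_stats(
    structure: SecondaryStructure,
    mir_span: tuple[int, int],
    star_span: tuple[int, int],
    wobble_is_pair: bool = True,
) -> DuplexStats:
    """Walk the guide/passenger duplex and count its imperfections."""
    ms, me = mir_span
    ss, se = star_span
    if max(ms, ss) <= min(me, se):
        raise ValueError("mature and star spans must be disjoint")

    def pairs_to_star(p: int) -> bool:
        q = structure.partner(p)
        if not (ss <= q <= se):
            return False
        if not wobble_is_pair and (structure.seq[p - 1], structure.seq[q - 1]) in WOBBLE:
            return False
        return True

    duplex = [p for p in range(ms, me + 1) if pairs_to_star(p)]
    if not duplex:
        raise StarInferenceError("no duplex pairs between the mature and star spans")

    gaps = []
    for a, b in zip(duplex, duplex[1:]):
        l = b - a - 1
        r = abs(structure.partner(a) - structure.partner(b)) - 1
        gaps.append((a, l, r))

    n_unpaired_guide = sum(l for _, l, _ in gaps)
    n_excess_star = sum(max(0, r - l) for _, l, r in gaps)
    n_mismatch = n_unpaired_guide + n_excess_star
    n_asym = sum(abs(l - r) for _, l, r in gaps)
    largest = max((max(l, r) for _, l, r in gaps), default=0)

    mismatch_positions = tuple(
        p - ms + 1
        for p in range(duplex[0], duplex[-1] + 1)
        if p not in set(duplex)
    )
    internal_loops = tuple(
        (a - ms + 1, l, r) for a, l, r in gaps if l or r
    )

    # secondary stems: duplex-region positions paired outside the opposite span
    sec = False
    dms, dme = duplex[0], duplex[-1]
    for p in range(dms, dme + 1):
        q = structure.partner(p)
        if q and not (ss <= q <= se):
            sec = True
    star_paired = [structure.partner(p) for p in duplex]
    s_lo, s_hi = min(star_paired), max(star_paired)
    for p in range(s_lo, s_hi + 1):
        q = structure.partner(p)
        if q and not (ms <= q <= me):
            sec = True

    o_mir = me - dme
    o_star = se - s_hi
    if ms < ss:  # mature on the 5' arm
        o5, o3 = o_mir, o_star
    else:
        o5, o3 = o_star, o_mir
    return DuplexStats(
        mir_span=mir_span,
        star_span=star_span,
        n_mismatch=n_mismatch,
        n_asym=n_asym,
        largest_loop=largest,
        secondary_stem=sec,
        overhang_5p_side=o5,
        overhang_3p_side=o3,
        mir_len=me - ms + 1,
        star_len=se - ss + 1,
        precursor_len=max(me, se) - min(ms, ss) + 1,
        mismatch_positions=mismatch_positions,
        internal_loops=internal_loops,
        n_duplex_pairs=len(duplex),
    )


# ---------------------------------------------------------------------------
# rule engine


def apply_rules(stats: DuplexStats, config: RuleConfig | None = None) -> Verdict:
    """The final rule-based verification of a candidate duplex.

    Defaults encode the generally accepted plant miRNA criteria: 2-nt 3'
    overhangs on both duplex ends, no secondary stems, at most 6 mismatched
    positions with at most 3 in asymmetric bulges, precursor <= 300 nt,
    mature length 20-24 nt, plus optional banned mismatch positions on the
    mature sequence.  All violations are reported.
    """
    config = config or RuleConfig()
    violated: list[str] = []
    if (
        stats.overhang_5p_side != config.overhang_nt
        or stats.overhang_3p_side != config.overhang_nt
    ):
        violated.append("overhang")
    if stats.secondary_stem and not config.allow_secondary_stems:
        violated.append("secondary_stem")
    if stats.n_mismatch > config.max_mismatch:
        violated.append("mismatch_limit")
    if stats.n_asym > config.max_asym:
        violated.append("asym_limit")
    if stats.precursor_len > config.max_precursor_len:
        violated.append("precursor_length")
    if not (config.min_mature_len <= stats.mir_len <= config.max_mature_len):
        violated.append("mature_length")
    if config.banned_mismatch_positions and any(
        p in config.banned_mismatch_positions for p in stats.mismatch_positions
    ):
        violated.append("banned_position")
    return Verdict(accepted=not violated, violated=tuple(violated), stage="rule_engine")
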