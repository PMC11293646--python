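"""Synthetic fixtures with planted ground truth.

Three generators cover every input the pipeline needs:

* :func:`make_hairpin` emits a pre-miRNA precursor sequence together with
  its *intended* secondary structure (no folding involved) and a truth
  record of every planted quantity - duplex mismatches, bulges, overhangs,
  spans.  It is the oracle for the structure-analysis and feature modules.
* :func:`make_genome` plants hairpin loci, coding regions, LD-band decoy
  copies and tRNA-like segments into a random background genome and
  returns all pipeline inputs (genome, reference miRNA sets, protein set,
  rRNA/tRNA set) plus a truth table.  It is the end-to-end oracle.
* :func:`make_feature_table` draws labeled two-cluster data matching the
  published feature schema.  It is the classifier oracle.

The generated data emulate the *composition* of real inputs (hairpin loci
with near-perfect duplexes, coding context for decoys, controlled
dissimilarity bands); they do not emulate genome-scale repeat content,
base composition bias, or miRNA family structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import ProteinRecord
from .features import feature_names
from .formats import Interval, SecondaryStructure, SeqRecord, reverse_complement, to_rna

__all__ = [
    "HairpinParams",
    "HairpinTruth",
    "GenomeFixture",
    "ProteinRecord",
    "make_hairpin",
    "make_genome",
    "make_feature_table",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_DNA_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one unambiguous codon per amino acid
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}


@dataclass(frozen=True)
class HairpinParams:
    """Planted hairpin geometry.

    Mature-relative positions are 1-based; mismatches and bulges must stay
    inside the paired duplex region (2 .. mature_len - overhang_mir - 1).
    ``bulges`` entries are (mature_pos, size, side) with side in
    {'mir', 'star'}; a star bulge sits between mature_pos and
    mature_pos + 1.  ``ext_stem`` adds a perfectly paired lower stem
    (loop-distal) beyond the duplex.
    """

    loop_size: int = 6
    flank5: int = 5
    flank3: int = 5
    ext_stem: int = 0
    mismatch_positions: tuple[int, ...] = ()
    bulges: tuple[tuple[int, int, str], ...] = ()
    overhang_mir: int = 2
    overhang_star: int = 2
    arm: str = "5p"


@dataclass(frozen=True)
class HairpinTruth:
    mir_span: tuple[int, int]
    star_span: tuple[int, int]
    arm: str
    n_mismatch: int
    n_asym: int
    largest_loop: int
    overhang_5p_side: int
    overhang_3p_side: int
    mir_len: int
    star_len: int
    precursor_len: int
    mismatch_positions: tuple[int, ...]
    loop_span: tuple[int, int]


def _validate_params(mir_len: int, p: HairpinParams) -> None:
    if p.arm not in ("5p", "3p"):
        raise ValueError(f"arm must be '5p' or '3p', got {p.arm!r}")
    if p.loop_size < 3:
        raise ValueError("loop_size must be at least 3")
    if not (0 <= p.overhang_mir <= 4 and 0 <= p.overhang_star <= 4):
        raise ValueError("overhangs must be in 0..4")
    paired_hi = mir_len - p.overhang_mir
    for pos in p.mismatch_positions:
        if not (2 <= pos <= paired_hi - 1):
            raise ValueError(f"mismatch position {pos} outside the paired interior")
    bulge_positions = set()
    for pos, size, side in p.bulges:
        if side not in ("mir", "star"):
            raise ValueError(f"bulge side must be 'mir' or 'star', got {side!r}")
        if size < 1:
            raise ValueError("bulge size must be positive")
        lo = 2 if side == "mir" else 1
        if not (lo <= pos <= paired_hi - 1 - (size if side == "mir" else 0)):
            raise ValueError(f"bulge at {pos} does not fit the paired interior")
        span = range(pos, pos + size) if side == "mir" else (pos,)
        bulge_positions.update(span)
    if bulge_positions & set(p.mismatch_positions):
        raise ValueError("inconsistent params: mismatch at a bulge position")
    if len(p.mismatch_positions) != len(set(p.mismatch_positions)):
        raise ValueError("duplicate mismatch positions")


def _noncomplement(base: str, rng) -> str:
    # same base never Watson-Crick pairs and never wobbles with itself
    return base


def make_hairpin(
    mir_seq: str, params: HairpinParams | None = None, seed: int = 0
):
    """Construct a precursor with a planted miRNA/miRNA* duplex.

    Returns ``(SeqRecord, SecondaryStructure, HairpinTruth)``.  The
    structure is the intended one, emitted directly from the parameters.
    """
    params = params or HairpinParams()
    rng = np.random.default_rng(seed)
    mature = to_rna(mir_seq)
    if len(mature) < 16:
        raise ValueError("mature sequence shorter than 16 nt")
    _validate_params(len(mature), params)
    Lm = len(mature)
    paired_hi = Lm - params.overhang_mir

    mir_bulge = {}   # first unpaired mature pos -> size
    star_bulge = {}  # mature pos -> size (insert after this position's partner)
    for pos, size, side in params.bulges:
        if side == "mir":
            mir_bulge[pos] = size
        else:
            star_bulge[pos] = size

    mir_skip = set()
    for pos, size in mir_bulge.items():
        mir_skip.update(range(pos, pos + size))

    # build the star strand 5'->3' by walking mature positions descending
    star_units: list[tuple[str, int | None]] = []  # (base, mature pos or None)
    for i in range(paired_hi, 0, -1):
        if i in mir_skip:
            continue
        if i in params.mismatch_positions:
            star_units.append((_noncomplement(mature[i - 1], rng), None))
        else:
            star_units.append((_COMPLEMENT[mature[i - 1]], i))
        if (i - 1) in star_bulge:
            for _ in range(star_bulge[i - 1]):
                star_units.append((str(rng.choice(["A", "C"])), None))
    for _ in range(params.overhang_star):
        star_units.append((str(rng.choice(["A", "C"])), None))
    star_seq = "".join(b for b, _ in star_units)
    Ls = len(star_seq)

    def rand_rna(n):
        return "".join(rng.choice(list("ACGU"), n)) if n else ""

    loop = rand_rna(params.loop_size)
    ext5 = rand_rna(params.ext_stem)
    ext3 = "".join(_COMPLEMENT[c] for c in reversed(ext5))
    f5 = rand_rna(params.flank5)
    f3 = rand_rna(params.flank3)

    if params.arm == "5p":
        segs = [f5, ext5, mature, loop, star_seq, ext3, f3]
        mat_off = len(f5) + len(ext5)
        star_off = mat_off + Lm + len(loop)
    else:
        segs = [f5, ext5, star_seq, loop, mature, ext3, f3]
        star_off = len(f5) + len(ext5)
        mat_off = star_off + Ls + len(loop)
    seq = "".join(segs)
    L = len(seq)
    pairs = np.zeros(L, dtype=np.int64)

    def set_pair(a: int, b: int):
        pairs[a - 1] = b
        pairs[b - 1] = a

    for k, (_, mat_i) in enumerate(star_units, start=1):
        if mat_i is not None:
            set_pair(mat_off + mat_i, star_off + k)
    for k in range(1, params.ext_stem + 1):
        e5 = len(f5) + k
        e3 = L - len(f3) - params.ext_stem + (params.ext_stem - k + 1)
        set_pair(e5, e3)

    structure = SecondaryStructure(seq=seq, pairs=pairs)

    # truth: recompute the duplex gap list from the parameters
    paired_mature = [
        i
        for i in range(1, paired_hi + 1)
        if i not in mir_skip and i not in params.mismatch_positions
    ]
    gaps = []
    for a, b in zip(paired_mature, paired_mature[1:]):
        l = b - a - 1
        r = (
            sum(1 for i in range(a + 1, b) if i in params.mismatch_positions)
            + sum(size for pos, size in star_bulge.items() if a <= pos < b)
        )
        if l or r:
            gaps.append((l, r))
    n_unpaired_guide = sum(l for l, _ in gaps)
    n_mismatch = n_unpaired_guide + sum(max(0, r - l) for l, r in gaps)
    n_asym = sum(abs(l - r) for l, r in gaps)
    largest = max((max(l, r) for l, r in gaps), default=0)

    mir_span = (mat_off + 1, mat_off + Lm)
    star_span = (star_off + 1, star_off + Ls)
    if params.arm == "5p":
        o5, o3 = params.overhang_mir, params.overhang_star
        loop_span = (mir_span[1] - params.overhang_mir + 1, star_span[0] - 1)
    else:
        o5, o3 = params.overhang_star, params.overhang_mir
        loop_span = (star_span[1] - params.overhang_star + 1, mir_span[0] - 1)
    mism_sorted = tuple(sorted(params.mismatch_positions))
    truth = HairpinTruth(
        mir_span=mir_span,
        star_span=star_span,
        arm=params.arm,
        n_mismatch=n_mismatch,
        n_asym=n_asym,
        largest_loop=largest,
        overhang_5p_side=o5,
        overhang_3p_side=o3,
        mir_len=Lm,
        star_len=Ls,
        precursor_len=max(mir_span[1], star_span[1]) - min(mir_span[0], star_span[0]) + 1,
        mismatch_positions=mism_sorted,
        loop_span=loop_span,
    )
    record = SeqRecord(id=f"hairpin_{params.arm}", seq=seq)
    return record, structure, truth


# ---------------------------------------------------------------------------
# genome fixture


@dataclass
class GenomeFixture:
    genome: SeqRecord
    matures: list[SeqRecord]
    stemloops: list[SeqRecord]
    proteins: list[ProteinRecord]
    rfam: list[SeqRecord]
    truth: list[tuple[Interval, str, str]]  # (interval, kind, name)

    def truth_of(self, kind: str) -> list[Interval]:
        return [iv for iv, k, _ in self.truth if k == kind]

    def truth_bed(self) -> str:
        from .formats import write_bed6

        return write_bed6([(iv, f"{k}:{name}", 0.0) for iv, k, name in self.truth])


def _random_peptide(rng, n_aa: int) -> str:
    return "".join(rng.choice(list(_AA20), n_aa))


def _codons(pep: str) -> str:
    return "".join(_CODON[a] for a in pep)


def _destop(cds: str, protect: range | None = None) -> str:
    """Mutate in-frame stop codons (3rd base -> C), except protected bases."""
    out = list(cds)
    for k in range(0, len(cds) - 2, 3):
        if "".join(out[k : k + 3]) in _STOPS:
            pos = k + 2
            if protect is not None and pos in protect:
                continue
            out[pos] = "C"
    return "".join(out)


def _corrupt_prefix(mature_dna: str, n: int, rng) -> str:
    """Replace the first n bases so that every replaced base differs."""
    shift = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return "".join(shift[c] for c in mature_dna[:n]) + mature_dna[n:]


def make_genome(
    n_loci: int = 5,
    n_cds: int = 5,
    n_decoys: int = 5,
    seed: int = 0,
    genome_len: int = 100_000,
    n_trna: int = 0,
    decoy_ld: int = 5,
    mature_len: int = 21,
) -> GenomeFixture:
    """A random genome with planted hairpin loci, coding regions and decoys.

    * ``n_loci`` clean pre-miRNA loci (exact homologs of the emitted
      reference matures/stemloops, perfect duplexes, 2-nt overhangs);
    * ``n_cds`` hairpins embedded between the two halves of a planted ORF
      whose half-translations populate the protein set (these must be
      removed by the coding filter);
    * ``n_decoys`` LD-band decoys: end-truncated corrupted copies of
      reference matures (exact ``mature_len - decoy_ld`` core => LD =
      ``decoy_ld``) substituted in-frame inside a long planted ORF;
    * ``n_trna`` tRNA-like segments mirrored into the rRNA/tRNA set.
    """
    if min(n_loci, n_cds, n_decoys) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    matures: list[SeqRecord] = []
    stemloops: list[SeqRecord] = []
    proteins: list[ProteinRecord] = []
    rfam: list[SeqRecord] = []
    elements: list[tuple[str, str, str]] = []  # (kind, name, dna sequence)
    offsets_meta: list[dict] = []

    def locus_params() -> HairpinParams:
        # mild per-locus variation, well inside the duplex rule bounds;
        # mismatches stay in the duplex interior (positions 5-15): a
        # mismatch at position 3-4 isolates a 2-bp terminal helix that no
        # realistic fold retains, which would break the planted 2-nt
        # overhang geometry and make the locus not cleanly rule-satisfying
        n_mm = int(rng.integers(0, 3))
        mm = tuple(
            sorted(int(x) for x in rng.choice(np.arange(5, 16), n_mm, replace=False))
        )
        return HairpinParams(
            loop_size=int(rng.integers(5, 9)),
            flank5=int(rng.integers(10, 15)),
            flank3=int(rng.integers(10, 15)),
            ext_stem=int(rng.integers(12, 17)),
            mismatch_positions=mm,
            overhang_mir=2,
            overhang_star=2,
        )

    def new_mature(i):
        return "".join(rng.choice(list("ACGU"), mature_len))

    clean_matures: list[str] = []
    for i in range(n_loci):
        mat = new_mature(i)
        clean_matures.append(mat)
        rec, _, truth = make_hairpin(mat, locus_params(), seed=int(rng.integers(2**31)))
        dna = rec.seq.replace("U", "T")
        matures.append(SeqRecord(f"mir-{i + 1}", mat))
        stemloops.append(SeqRecord(f"pre-mir-{i + 1}", rec.seq))
        elements.append(("mirna_locus", f"mir-{i + 1}", dna))
        offsets_meta.append({"mature_offset": truth.mir_span[0] - 1,
                             "mature_len": mature_len})

    for i in range(n_cds):
        mat = new_mature(100 + i)
        rec, _, truth = make_hairpin(mat, locus_params(), seed=int(rng.integers(2**31)))
        hp_dna = rec.seq.replace("U", "T")
        pep1 = _random_peptide(rng, 60)
        pep2 = _random_peptide(rng, 60)
        cds = _destop(_codons(pep1) + hp_dna + _codons(pep2))
        # reference mature re-read from the (possibly de-stopped) genome copy
        off = len(_codons(pep1)) + truth.mir_span[0] - 1
        mat_planted = cds[off : off + mature_len].replace("T", "U")
        matures.append(SeqRecord(f"mir-cds-{i + 1}", mat_planted))
        stemloops.append(
            SeqRecord(
                f"pre-mir-cds-{i + 1}",
                cds[len(_codons(pep1)) : len(_codons(pep1)) + len(hp_dna)].replace("T", "U"),
            )
        )
        from Bio.Seq import Seq

        aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        for k, seg in enumerate(s for s in aa.split("*") if len(s) >= 20):
            proteins.append(ProteinRecord(f"prot-cds-{i + 1}-{k}", seg))
        elements.append(("cds_locus", f"mir-cds-{i + 1}", cds))
        offsets_meta.append({"mature_offset": off, "mature_len": mature_len})

    for i in range(n_decoys):
        # decoys corrupt dedicated reference matures: deriving them from the
        # planted clean loci would let the decoy ORF's translation share
        # peptide content with a clean locus and cross-flag it as coding
        ref = new_mature(200 + i)
        matures.append(SeqRecord(f"mir-ref-{i + 1}", ref))
        corrupted = _corrupt_prefix(ref.replace("U", "T"), decoy_ld, rng)
        # decoy hairpin: corrupted copy + loop + its reverse complement, so
        # the locus folds like a pre-miRNA while sitting inside coding sequence
        loop = "".join(rng.choice(_DNA_BASES, 8))
        hp = corrupted + loop + reverse_complement(corrupted)
        pep = _random_peptide(rng, 150)
        cds = _codons(pep)
        at = 3 * (len(cds) // 6)
        cds = cds[:at] + hp + cds[at + len(hp) :]
        core = range(at + decoy_ld, at + len(corrupted))
        cds = _destop(cds, protect=core)
        from Bio.Seq import Seq

        aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        for k, seg in enumerate(s for s in aa.split("*") if len(s) >= 20):
            proteins.append(ProteinRecord(f"prot-decoy-{i + 1}-{k}", seg))
        elements.append(("decoy_locus", f"decoy-{i + 1}", cds))
        offsets_meta.append({"mature_offset": at, "mature_len": mature_len})

    for i in range(n_trna):
        trna = "".join(rng.choice(list("ACGT"), 75))
        rfam.append(SeqRecord(f"trna-{i + 1}", trna))
        elements.append(("trna_locus", f"trna-{i + 1}", trna))
        offsets_meta.append({})

    total_planted = sum(len(e[2]) for e in elements)
    n_elem = len(elements)
    min_len = total_planted + (n_elem + 1) * 600
    if genome_len < min_len:
        raise ValueError(
            f"genome_len {genome_len} too small for {n_elem} planted elements "
            f"(need >= {min_len})"
        )

    background = "".join(rng.choice(_DNA_BASES, genome_len))
    # evenly spaced slots with jitter; deterministic order shuffle
    order = rng.permutation(n_elem) if n_elem else []
    gap = (genome_len - total_planted) // (n_elem + 1) if n_elem else 0
    genome_parts: list[str] = []
    truth: list[tuple[Interval, str, str]] = []
    cursor = 0
    pos = 0
    for idx in order:
        kind, name, dna = elements[idx]
        jitter = int(rng.integers(0, max(1, gap // 4)))
        lead = gap - jitter if gap > jitter else gap
        genome_parts.append(background[cursor : cursor + lead])
        pos += lead
        genome_parts.append(dna)
        iv = Interval("chr1", pos, pos + len(dna), "+")
        truth.append((iv, kind, name))
        meta = offsets_meta[idx]
        if "mature_offset" in meta:
            ms = pos + meta["mature_offset"]
            truth.append(
                (Interval("chr1", ms, ms + meta["mature_len"], "+"), f"{kind}_mature", name)
            )
        pos += len(dna)
        cursor += lead
    genome_parts.append(background[cursor:])
    genome_seq = "".join(genome_parts)[:genome_len]
    if len(genome_seq) < genome_len:
        genome_seq += "".join(rng.choice(_DNA_BASES, genome_len - len(genome_seq)))
    genome = SeqRecord("chr1", genome_seq)
    return GenomeFixture(
        genome=genome,
        matures=matures,
        stemloops=stemloops,
        proteins=proteins,
        rfam=rfam,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# classifier fixture


def make_feature_table(
    n_per_class: int,
    class_sep: float,
    noise: float = 0.0,
    seed: int = 0,
    direction_seed: int | None = None,
) -> pd.DataFrame:
    """Two 170-dimensional Gaussian clusters under the published schema.

    Class means differ by ``class_sep`` along a random unit direction;
    coordinates have unit variance.  ``noise`` flips that fraction of
    labels.  ``direction_seed`` fixes the separation direction separately
    from the sampling seed, so several tables can share one generative
    model (species-like groups).  Columns are the schema feature names
    plus ``label``.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be at least 10")
    rng = np.random.default_rng(seed)
    names = list(feature_names())
    d = len(names)
    dir_rng = (
        np.random.default_rng(direction_seed) if direction_seed is not None else rng
    )
    u = dir_rng.normal(size=d)
    u /= np.linalg.norm(u)
    X0 = rng.normal(size=(n_per_class, d))
    X1 = rng.normal(size=(n_per_class, d)) + class_sep * u
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    if noise > 0:
        flip = rng.random(len(y)) < noise
        y = np.where(flip, 1 - y, y)
    df = pd.DataFrame(X, columns=names)
    df["label"] = y
    return df
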