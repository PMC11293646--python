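"""Secondary-structure prediction with pluggable engines.

The production path shells out to an external folding engine (RNAfold is
wired concretely; Mfold, CONTRAfold and MXFold2 slots exist in the registry
and fall back when their binaries are absent).  The built-in reference
folder is a dynamic-programming maximum-weight nested-pairing model
(GC=3, AU=2, GU=1, minimum hairpin loop 3) whose traceback enumerates
co-optimal structures (capped, stacking-preferring deterministic
tie-break); returned structures are then ranked by the built-in
nearest-neighbor energy model of :func:`eval_energy`.

Energy model (``param_set='builtin'``): a simplified additive
nearest-neighbor set.  Stacking two pairs contributes
``-(w(p1) + w(p2))`` kcal/mol with pair strengths w(GC)=1.6, w(AU)=0.9,
w(GU)=0.45; hairpin, bulge, internal and multibranch loops pay
logarithmic size penalties.  An all-unpaired chain has energy 0.
``param_set='rnaeval'`` delegates to the ViennaRNA ``RNAeval`` binary.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import sys
from dataclasses import dataclass

import numpy as np

from .formats import MIN_LOOP, SecondaryStructure, dot_bracket, to_rna

logger = logging.getLogger(__name__)

__all__ = ["FoldParams", "fold_all", "eval_energy", "fold_builtin", "EngineUnavailable"]

PAIR_WEIGHT = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "U"): 2.0,
    ("U", "A"): 2.0,
    ("G", "U"): 1.0,
    ("U", "G"): 1.0,
}

PAIR_STRENGTH = {  # kcal/mol per pair, used in the stacking term
    ("G", "C"): 1.6,
    ("C", "G"): 1.6,
    ("A", "U"): 0.9,
    ("U", "A"): 0.9,
    ("G", "U"): 0.45,
    ("U", "G"): 0.45,
}

MIN_FOLD_LEN = 12


class EngineUnavailable(RuntimeError):
    """The requested external folding engine binary is not on PATH."""


@dataclass(frozen=True)
class FoldParams:
    max_structures: int = 20


# ---------------------------------------------------------------------------
# built-in reference folder


def _weight_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            P[i, j] = PAIR_WEIGHT.get((seq[i], seq[j]), 0.0)
    return P


def _fill(P: np.ndarray) -> np.ndarray:
    """Maximum-weight nested pairing table, vectorized over the 5' index."""
    n = P.shape[0]
    W = np.zeros((n, n))
    for l in range(1, n):
        I = np.arange(0, n - l)
        J = I + l
        best = np.maximum(W[I + 1, J], W[I, J - 1])
        if l >= MIN_LOOP + 1:
            inner = W[I + 1, J - 1]
            pairw = P[I, J]
            best = np.maximum(best, np.where(pairw > 0, inner + pairw, -np.inf))
        for kk in range(1, l):
            best = np.maximum(best, W[I, I + kk] + W[I + kk + 1, J])
        W[I, J] = best
    return W


def _enumerate_cooptimal(
    seq: str, P: np.ndarray, W: np.ndarray, cap: int
) -> list[frozenset[tuple[int, int]]]:
    """Up to ``cap`` distinct co-optimal pair sets, pairing-first DFS order.

    Exploring the pair decision before the unpaired/bifurcation decisions
    makes the first traceback reconstruct contiguous helices.
    """
    n = len(seq)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 50 * n + 1000))
    memo: dict[tuple[int, int], list[frozenset]] = {}
    eps = 1e-9

    def enum(i: int, j: int) -> list[frozenset]:
        if i >= j:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        target = W[i, j]
        out: list[frozenset] = []
        seen: set[frozenset] = set()

        def add(s: frozenset) -> bool:
            if s not in seen:
                seen.add(s)
                out.append(s)
            return len(out) >= cap

        done = False
        if P[i, j] > 0 and abs(W[i + 1, j - 1] + P[i, j] - target) < eps:
            for sub in enum(i + 1, j - 1):
                if add(sub | {(i, j)}):
                    done = True
                    break
        if not done and abs(W[i + 1, j] - target) < eps:
            for sub in enum(i + 1, j):
                if add(sub):
                    done = True
                    break
        if not done and abs(W[i, j - 1] - target) < eps:
            for sub in enum(i, j - 1):
                if add(sub):
                    done = True
                    break
        if not done:
            for k in range(i + 1, j):
                if abs(W[i, k] + W[k + 1, j] - target) < eps:
                    for left in enum(i, k):
                        for right in enum(k + 1, j):
                            if add(left | right):
                                done = True
                                break
                        if done:
                            break
                if done:
                    break
        memo[key] = out
        return out

    return enum(0, n - 1)


def fold_builtin(seq: str, params: FoldParams | None = None) -> list[SecondaryStructure]:
    """Reference folder: co-optimal maximum-weight nested pairings."""
    params = params or FoldParams()
    rna = to_rna(seq)
    P = _weight_matrix(rna)
    W = _fill(P)
    structures = []
    for pairset in _enumerate_cooptimal(rna, P, W, params.max_structures):
        pairs = np.zeros(len(rna), dtype=np.int64)
        for i, j in pairset:
            pairs[i] = j + 1
            pairs[j] = i + 1
        s = SecondaryStructure(seq=rna, pairs=pairs)
        s.energy = eval_energy(s)
        structures.append(s)
    structures.sort(key=lambda s: (s.energy, dot_bracket(s)))
    return structures


# ---------------------------------------------------------------------------
# external adapters


def _fold_rnafold(seq: str) -> list[SecondaryStructure]:
    if not shutil.which("RNAfold"):
        raise EngineUnavailable("RNAfold binary not found on PATH")
    from .formats import from_dot_bracket

    rna = to_rna(seq)
    out = subprocess.run(
        ["RNAfold", "--noPS"],
        input=f">q\n{rna}\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    lines = [ln for ln in out.splitlines() if ln.strip()]
    # last line: "...((..)).. ( -12.30)"
    struct_line = lines[-1]
    db = struct_line.split()[0]
    energy = float(struct_line[struct_line.rindex("(") + 1 : struct_line.rindex(")")])
    return [from_dot_bracket(rna, db, energy=energy)]


_EXTERNAL_ENGINES = {
    "rnafold": _fold_rnafold,
    # Adapter slots whose binaries are not shipped in this environment.
    "mfold": None,
    "contrafold": None,
    "mxfold2": None,
}


def fold_all(
    seq: str, engine: str = "builtin", params: FoldParams | None = None
) -> list[SecondaryStructure]:
    """Predict one or more secondary structures, sorted by energy ascending.

    Engines: ``builtin`` (reference folder), ``rnafold`` (ViennaRNA
    adapter), ``auto`` (RNAfold when available, else builtin), plus
    declared ``mfold``/``contrafold``/``mxfold2`` slots.  A missing engine
    binary falls back to the built-in folder with a logged notice.
    Duplicate pair tables are removed.
    """
    if len(seq) < MIN_FOLD_LEN:
        raise ValueError(f"sequence shorter than {MIN_FOLD_LEN} nt cannot be folded")
    params = params or FoldParams()
    engine = engine.lower()
    if engine == "auto":
        # ensemble of optimal structures: the thermodynamic MFE (when an
        # external engine is available) plus the max-pairing co-optimals,
        # mirroring the multiple-optimal-structure analysis of the pipeline
        structures = []
        if shutil.which("RNAfold"):
            structures = fold_all(seq, "rnafold", params)
        rest = max(1, params.max_structures - len(structures))
        structures += fold_builtin(seq, FoldParams(max_structures=rest))
        return _finalize(structures, params)
    if engine == "builtin":
        structures = fold_builtin(seq, params)
    elif engine in _EXTERNAL_ENGINES:
        fn = _EXTERNAL_ENGINES[engine]
        try:
            if fn is None:
                raise EngineUnavailable(f"no {engine} binary available")
            structures = fn(seq)
        except (EngineUnavailable, OSError, subprocess.CalledProcessError) as exc:
            logger.warning("engine %s unavailable (%s); using built-in folder", engine, exc)
            structures = fold_builtin(seq, params)
    else:
        raise ValueError(f"unknown folding engine {engine!r}")
    return _finalize(structures, params)


def _finalize(structures, params: FoldParams):
    """Dedupe identical pair tables and sort by energy ascending."""
    seen = set()
    unique = []
    for s in structures:
        key = tuple(int(x) for x in s.pairs)
        if key not in seen:
            seen.add(key)
            if s.energy is None:
                s.energy = eval_energy(s)
            unique.append(s)
    unique.sort(key=lambda s: (s.energy, dot_bracket(s)))
    return unique[: params.max_structures]


# ---------------------------------------------------------------------------
# energy evaluation


def _loop_tree(structure: SecondaryStructure):
    """(closing pair, direct child pairs) for every pair, plus exterior kids."""
    pairs = structure.paired_positions()
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for i, j in sorted(pairs):
        while stack and not (stack[-1][0] < i and j < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append((i, j))
        children.setdefault((i, j), [])
        stack.append((i, j))
    return children


def _bp(structure: SecondaryStructure, pair: tuple[int, int]) -> tuple[str, str]:
    i, j = pair
    return (structure.seq[i - 1], structure.seq[j - 1])


def _hairpin_penalty(n: int) -> float:
    return 4.5 + 1.75 * math.log(max(n, MIN_LOOP) / 3.0)


def _bulge_penalty(n: int) -> float:
    return 3.3 + 1.75 * math.log(n)


def _internal_penalty(left: int, right: int) -> float:
    return 1.8 + 1.3 * math.log(left + right) + 0.5 * abs(left - right)


def _multiloop_penalty(branches: int, unpaired: int) -> float:
    return 3.4 + 0.4 * branches + 0.1 * unpaired


def eval_energy(structure: SecondaryStructure, param_set: str = "builtin") -> float:
    """Free energy (kcal/mol) of a structure under a nearest-neighbor model.

    ``builtin`` walks the loop decomposition and sums stack and loop terms
    (see module docstring); ``rnaeval`` delegates to ViennaRNA's RNAeval.
    """
    if param_set == "rnaeval":
        return _rnaeval(structure)
    if param_set != "builtin":
        raise ValueError(f"unknown energy parameter set {param_set!r}")
    children = _loop_tree(structure)
    energy = 0.0
    for closing, kids in children.items():
        if closing is None:
            continue
        i, j = closing
        if not kids:
            energy += _hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            left = k - i - 1
            right = j - l - 1
            if left == 0 and right == 0:
                w1 = PAIR_STRENGTH.get(_bp(structure, closing), 0.0)
                w2 = PAIR_STRENGTH.get(_bp(structure, kids[0]), 0.0)
                energy += -(w1 + w2)
            elif left == 0 or right == 0:
                energy += _bulge_penalty(left + right)
            else:
                energy += _internal_penalty(left, right)
        else:
            span_unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            energy += _multiloop_penalty(len(kids), span_unpaired)
    return round(energy, 6)


def _rnaeval(structure: SecondaryStructure) -> float:
    if not shutil.which("RNAeval"):
        raise EngineUnavailable("RNAeval binary not found on PATH")
    out = subprocess.run(
        ["RNAeval"],
        input=f"{structure.seq}\n{dot_bracket(structure)}\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    line = [ln for ln in out.splitlines() if ln.strip()][-1]
    return float(line[line.rindex("(") + 1 : line.rindex(")")])
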