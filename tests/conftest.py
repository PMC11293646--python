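"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from premir.formats import SecondaryStructure


def random_nested_structure(rng: np.random.Generator, n: int) -> SecondaryStructure:
    """A random valid structure built by repeated nested-pair insertion.

    Pairs are inserted only when they neither cross nor touch existing
    pairs and honour the minimum hairpin loop of 3 nt; this construction is
    independent of any folding code.
    """
    seq = "".join(rng.choice(list("ACGU"), n))
    pairs = np.zeros(n, dtype=np.int64)
    for _ in range(2 * n):
        i = int(rng.integers(1, n - 3))
        j = int(rng.integers(i + 4, n + 1))
        if pairs[i - 1] or pairs[j - 1]:
            continue
        # nestedness: every existing pair must be fully inside or outside
        ok = True
        for a in range(1, n + 1):
            b = int(pairs[a - 1])
            if b <= a:
                continue
            inside = i < a and b < j
            outside = b < i or j < a
            contains = a < i and j < b
            if not (inside or outside or contains):
                ok = False
                break
        if ok:
            pairs[i - 1] = j
            pairs[j - 1] = i
    return SecondaryStructure(seq=seq, pairs=pairs)


def brute_force_element_kinds(structure: SecondaryStructure) -> dict[int, str]:
    """Independent per-position classification of structure elements.

    Paired positions are 'stem'.  An unpaired position takes its kind from
    the innermost enclosing pair: none -> exterior; 0 nested branches ->
    hairpin_loop; 1 branch -> bulge/internal_loop by sidedness; >=2 ->
    multiloop.
    """
    n = len(structure)
    pairs = [(i, structure.partner(i)) for i in range(1, n + 1) if structure.partner(i) > i]
    kinds: dict[int, str] = {}
    for p in range(1, n + 1):
        if structure.partner(p):
            kinds[p] = "stem"
            continue
        enclosing = [(i, j) for i, j in pairs if i < p < j]
        if not enclosing:
            kinds[p] = "exterior"
            continue
        i, j = min(enclosing, key=lambda ij: ij[1] - ij[0])
        branches = [
            (a, b) for a, b in pairs if i < a and b < j
            and not any(c < a and b < d for c, d in pairs if i < c and d < j)
        ]
        if not branches:
            kinds[p] = "hairpin_loop"
        elif len(branches) == 1:
            a, b = branches[0]
            left = a - i - 1
            right = j - b - 1
            kinds[p] = "bulge" if (left == 0 or right == 0) else "internal_loop"
        else:
            kinds[p] = "multiloop"
    return kinds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mature(rng):
    def make(n=21):
        return "".join(rng.choice(list("ACGU"), n))

    return make
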