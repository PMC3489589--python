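"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from functools import lru_cache

import pytest

from ligbias.folding import MIN_HAIRPIN_LOOP, PAIR_SCORE, STACK_BONUS
from ligbias.sequences import AdapterSet

RNA_BASES = "ACGU"


@pytest.fixture
def toy_adapters() -> AdapterSet:
    """Short standard adapters for desk-scale construct tests."""
    return AdapterSet("GUUCAGAGUU", "AUCUCGUAUG", tag_length=0)


@pytest.fixture
def toy_hd_adapters() -> AdapterSet:
    """Short HD adapters (4 nt degenerate tags)."""
    return AdapterSet("GUUCAGAGUU", "AUCUCGUAUG", tag_length=4)


def random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(RNA_BASES) for _ in range(length))


def structure_score(seq: str, pairs: frozenset[tuple[int, int]]) -> float:
    """Score of one structure under the built-in folder's model:
    per-pair scores plus a stacking bonus whenever (i+1, j-1) is also
    paired with itself."""
    score = 0.0
    for i, j in pairs:
        score += PAIR_SCORE[(seq[i], seq[j])]
        if (i + 1, j - 1) in pairs:
            score += STACK_BONUS
    return score


def enumerate_structures(seq: str):
    """Exhaustively enumerate every non-crossing structure (min loop 3).

    Independent of the dynamic program: plain recursive enumeration of
    nested pair sets, feasible for sequences up to ~12 nt.
    """

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple[frozenset, ...]:
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return (frozenset(),)
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) not in PAIR_SCORE:
                continue
            for left in region(i + 1, k - 1):
                for right in region(k + 1, j):
                    out.append(frozenset({(i, k)}) | left | right)
        return tuple(out)

    return region(0, len(seq) - 1) if seq else (frozenset(),)


def brute_force_best_score(seq: str) -> float:
    """Optimal structure score by exhaustive enumeration."""
    return max(structure_score(seq, s) for s in enumerate_structures(seq))
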