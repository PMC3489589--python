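"""High-definition (HD) adapter combinatorics and diagnostics.

An HD adapter set carries a fully degenerate tag of length t at the
ligation-proximal end of each adapter, so ligation is performed by a
pool of 4^t adapter variants per side (256 per side, 65,536 pairs, for
t = 4).  Because each tag combination folds differently with a given
insert, the pool presents many alternative structural contexts and
averages out the structure preference of the ligases.  This module
enumerates the tag space, measures the structural diversity an insert
explores across tag combinations, and summarizes how many distinct tag
(barcode) pairs actually captured each insert in a sequenced library.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

from . import folding
from .folding import Engine, fold
from .profiles import build_construct
from .sequences import AdapterSet, as_rna

RNA_BASES = "ACGU"


@dataclass(frozen=True)
class TagPair:
    """One 5'-tag / 3'-tag combination of an HD adapter pair."""

    tag5: str
    tag3: str

    def __post_init__(self) -> None:
        # empty tags are the degenerate tag_length = 0 (standard adapter) case
        object.__setattr__(self, "tag5", as_rna(self.tag5) if self.tag5 else "")
        object.__setattr__(self, "tag3", as_rna(self.tag3) if self.tag3 else "")
        if len(self.tag5) != len(self.tag3):
            raise ValueError("tag5 and tag3 must have equal lengths")


def enumerate_tag_space(tag_length: int) -> tuple[int, int]:
    """(number of adapter variants per side, number of tag pairs).

    A degenerate tag of length t yields 4^t adapters per side and
    (4^t)^2 pairs: 256 and 65,536 for the HD configuration t = 4.
    """
    if tag_length < 0:
        raise ValueError("tag_length must be non-negative")
    n_adapters = 4**tag_length
    return n_adapters, n_adapters**2


def all_tag_pairs(tag_length: int) -> list[TagPair]:
    """Every tag pair of the given length, in lexicographic order."""
    tags = ["".join(p) for p in product(RNA_BASES, repeat=tag_length)] or [""]
    return [TagPair(t5, t3) for t5 in tags for t3 in tags]


@dataclass
class StructuralDiversity:
    """Distinct MFE structures of one insert across tag combinations.

    ``n_distinct`` counts distinct dot-bracket strings restricted to the
    insert positions (the biologically relevant portion);
    ``n_distinct_full`` counts distinct full-construct structures.
    """

    n_distinct: int
    census: dict[str, int]
    n_distinct_full: int
    n_evaluated: int

    def write_census_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["insert_dotbracket", "n_tag_pairs"])
            for db, c in sorted(self.census.items(), key=lambda kv: (-kv[1], kv[0])):
                w.writerow([db, c])


def structural_diversity(
    insert: str,
    adapters: AdapterSet,
    engine: Engine = "builtin",
    temperature: float = folding.REFERENCE_TEMPERATURE,
    tag_subset: Sequence[TagPair] | None = None,
    allow_full_space: bool = False,
) -> StructuralDiversity:
    """Fold the full construct under every tag pair and tally structures.

    The full tag space is evaluated by default only for ``tag_length <=
    2`` (at most 256 folds); larger spaces (65,536 pairs for the HD
    t = 4 set) require an explicit ``tag_subset`` or
    ``allow_full_space=True``, since a full sweep is minutes of CPU.
    """
    t = adapters.tag_length
    if tag_subset is None:
        if t > 2 and not allow_full_space:
            raise ValueError(
                f"tag_length {t} spans {4 ** (2 * t)} pairs; pass tag_subset "
                "or allow_full_space=True"
            )
        tag_subset = all_tag_pairs(t)
    census: Counter[str] = Counter()
    full_structures: set[str] = set()
    for pair in tag_subset:
        if len(pair.tag5) != t:
            raise ValueError("tag pair length does not match adapters.tag_length")
        seq, ctx = build_construct(
            insert, adapters, "full_construct",
            tag5=pair.tag5 or None, tag3=pair.tag3 or None,
        )
        db = fold(seq, temperature, engine).dotbracket
        census[db[ctx.junction5 : ctx.junction3]] += 1
        full_structures.add(db)
    return StructuralDiversity(
        n_distinct=len(census),
        census=dict(census),
        n_distinct_full=len(full_structures),
        n_evaluated=len(tag_subset),
    )


@dataclass
class BarcodeCapture:
    """How many distinct tag (barcode) pairs captured each insert."""

    pairs_per_insert: dict[str, int]
    #: fraction of inserts captured by fewer than k pairs, k in {2,5,10,100}
    fraction_below: dict[int, float]

    def write_tsv(self, path: str | Path) -> None:
        hist = Counter(self.pairs_per_insert.values())
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["pairs_captured", "n_inserts"])
            for k in sorted(hist):
                w.writerow([k, hist[k]])


def barcode_capture_histogram(
    tagged_reads: Iterable[tuple[str, TagPair]],
    thresholds: Sequence[int] = (2, 5, 10, 100),
) -> BarcodeCapture:
    """Count the distinct tag pairs observed per insert.

    Repeated observations of the same (insert, tag pair) combination
    count once.  The summary gives, for each threshold k, the fraction
    of inserts captured by fewer than k distinct pairs — a skew toward
    small values means individual adapter variants have strong
    preferences for particular sequences.
    """
    seen: defaultdict[str, set[TagPair]] = defaultdict(set)
    for insert, pair in tagged_reads:
        seen[insert].add(pair)
    per_insert = {ins: len(pairs) for ins, pairs in seen.items()}
    n = len(per_insert)
    fraction_below = {
        k: (sum(1 for v in per_insert.values() if v < k) / n if n else 0.0)
        for k in thresholds
    }
    return BarcodeCapture(per_insert, fraction_below)
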