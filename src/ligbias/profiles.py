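"""Junction-anchored secondary-structure profiles.

RNA ligases are sensitive to the structure context at the ligation
junction: T4 Rnl1 (the 5'-adapter step) strongly prefers single-stranded
ligation sites, while truncated T4 Rnl2 (the 3'-adapter step) prefers a
double-stranded context immediately upstream of the junction.  This
module folds insert/adapter concatenations and computes per-position
base-pairing frequencies over a set of molecules, the junction-adjacent
pairing fractions, profile-vs-profile similarity (R^2), and the
correlation between a sequence's predicted folding stability (MFE) and
its abundance in a library.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import folding
from .folding import Engine, fold
from .sequences import AdapterSet, ReadCountTable, as_rna

MODES = ("insert_only", "insert_plus_3", "full_construct")


@dataclass(frozen=True)
class FoldingContext:
    """Which segments were concatenated, and where the junctions sit.

    Junction positions are 0-based offsets into the concatenated
    sequence; each junction is indexed at the first base of its
    downstream segment.  For HD adapters the ligation junction lies
    between the degenerate tag and the insert (the tag is the ligated
    end of the adapter).
    """

    mode: str
    junction5: int | None = None
    junction3: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "full_construct" and (self.junction5 is None or self.junction3 is None):
            raise ValueError("full_construct requires both junctions")
        if self.mode == "insert_plus_3" and (self.junction5 is not None or self.junction3 is None):
            raise ValueError("insert_plus_3 has exactly the 3' junction")
        if self.mode == "insert_only" and (self.junction5 is not None or self.junction3 is not None):
            raise ValueError("insert_only has no junctions")


@dataclass
class PairingProfile:
    """Per-position base-pairing frequency over a set of molecules."""

    frequency: np.ndarray
    n_molecules: int
    min_rep: np.ndarray | None = None
    max_rep: np.ndarray | None = None
    context: FoldingContext | None = None

    def __len__(self) -> int:
        return len(self.frequency)


def build_construct(
    insert: str,
    adapters: AdapterSet,
    mode: str,
    tag5: str | None = None,
    tag3: str | None = None,
) -> tuple[str, FoldingContext]:
    """Concatenate adapter/tag/insert segments for folding.

    Segment order is ``adapter5 + tag5 + insert + tag3 + adapter3``, with
    segments dropped according to ``mode`` (``insert_only``,
    ``insert_plus_3``, ``full_construct``).  Tags must be supplied
    exactly when ``adapters.tag_length > 0``, and must have that length.
    """
    insert = as_rna(insert)
    t = adapters.tag_length
    for name, tag, needed in (
        ("tag5", tag5, mode == "full_construct"),
        ("tag3", tag3, mode in ("insert_plus_3", "full_construct")),
    ):
        if not needed:
            continue
        if t == 0:
            if tag:
                raise ValueError(f"{name} supplied but tag_length is 0")
        else:
            if tag is None or len(tag) != t:
                raise ValueError(f"{name} must have length {t}")
    tag5 = as_rna(tag5) if tag5 else ""
    tag3 = as_rna(tag3) if tag3 else ""

    if mode == "insert_only":
        return insert, FoldingContext("insert_only")
    if mode == "insert_plus_3":
        seq = insert + tag3 + adapters.adapter3
        return seq, FoldingContext("insert_plus_3", junction3=len(insert))
    if mode == "full_construct":
        prefix = adapters.adapter5 + tag5
        seq = prefix + insert + tag3 + adapters.adapter3
        return seq, FoldingContext(
            "full_construct",
            junction5=len(prefix),
            junction3=len(prefix) + len(insert),
        )
    raise ValueError(f"unknown mode {mode!r}")


def pairing_profile(
    molecules: Sequence[tuple[str, FoldingContext]],
    engine: Engine = "builtin",
    temperature: float = folding.REFERENCE_TEMPERATURE,
) -> PairingProfile:
    """Fold each molecule and average the per-position pairing indicators.

    All constructs must have the same length (fixed-length inserts);
    ``frequency[i]`` is the fraction of molecules whose MFE structure
    base-pairs position i.
    """
    if not molecules:
        raise ValueError("no molecules supplied")
    lengths = {len(seq) for seq, _ in molecules}
    if len(lengths) != 1:
        raise ValueError(f"mixed construct lengths {sorted(lengths)}")
    total = np.zeros(lengths.pop())
    for seq, _ in molecules:
        total += np.asarray(fold(seq, temperature, engine).paired_mask(), dtype=float)
    ctx = molecules[0][1]
    return PairingProfile(total / len(molecules), len(molecules), context=ctx)


def combine_replicates(profiles: Sequence[PairingProfile]) -> PairingProfile:
    """Average replicate profiles, recording per-position min/max bands."""
    if not profiles:
        raise ValueError("no profiles supplied")
    freqs = np.vstack([p.frequency for p in profiles])
    return PairingProfile(
        freqs.mean(axis=0),
        sum(p.n_molecules for p in profiles),
        min_rep=freqs.min(axis=0),
        max_rep=freqs.max(axis=0),
        context=profiles[0].context,
    )


def junction_pairing_fraction(
    profile: PairingProfile, junction: int, side: str = "upstream"
) -> float:
    """Pairing frequency of the base immediately flanking a ligation point.

    ``side="upstream"`` reads position ``junction - 1`` (the last base 5'
    of the junction); ``side="downstream"`` reads position ``junction``.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    if not 0 <= junction <= len(profile.frequency):
        raise ValueError("junction outside profile")
    pos = junction - 1 if side == "upstream" else junction
    if not 0 <= pos < len(profile.frequency):
        raise ValueError(f"no {side} base at junction {junction}")
    return float(profile.frequency[pos])


def profile_similarity(a: PairingProfile, b: PairingProfile) -> float:
    """Squared Pearson correlation between two pairing-frequency vectors."""
    x, y = np.asarray(a.frequency), np.asarray(b.frequency)
    if len(x) != len(y):
        raise ValueError("profiles have different lengths")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def top_abundant(table: ReadCountTable, m: int) -> ReadCountTable:
    """Sub-table of the m most abundant sequences (ties lexicographic).

    Every retained sequence has a count at least as large as every
    excluded sequence's count.
    """
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ReadCountTable(dict(ranked[:m]))


def mfe_abundance_correlation(
    table: ReadCountTable,
    adapters: AdapterSet,
    engine: Engine = "builtin",
    temperature: float = folding.REFERENCE_TEMPERATURE,
) -> float:
    """R^2 between predicted folding stability and observed abundance.

    Each distinct sequence is folded together with the 3' adapter core
    and its MFE is correlated with log10(count + 1).  A strong
    relationship (more stable construct -> more reads) is the signature
    of structure-dependent ligation bias.
    """
    if not table.counts:
        raise ValueError("empty read-count table")
    seqs = sorted(table.counts)
    mfes = np.array(
        [fold(s + adapters.adapter3, temperature, engine).mfe for s in seqs]
    )
    logc = np.log10(np.array([table.counts[s] for s in seqs], dtype=float) + 1.0)
    if np.ptp(logc) == 0 or np.ptp(mfes) == 0:
        raise ValueError("correlation undefined: constant counts or MFEs")
    r = np.corrcoef(mfes, logc)[0, 1]
    return float(r * r)


def segment_labels(ctx: FoldingContext, length: int, tag_length: int = 0) -> list[str]:
    """Per-position segment label for profile reports."""
    labels = ["insert"] * length
    if ctx.junction5 is not None:
        for i in range(ctx.junction5):
            labels[i] = "tag" if i >= ctx.junction5 - tag_length else "adapter5"
    if ctx.junction3 is not None:
        for i in range(ctx.junction3, length):
            labels[i] = "tag" if i < ctx.junction3 + tag_length else "adapter3"
    return labels


def write_profile_tsv(
    profile: PairingProfile, path: str | Path, tag_length: int = 0
) -> None:
    """Plot-ready long-format TSV: position, segment, frequency, min, max."""
    ctx = profile.context or FoldingContext("insert_only")
    labels = segment_labels(ctx, len(profile.frequency), tag_length)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["position", "segment", "frequency", "min", "max"])
        for i, f in enumerate(profile.frequency):
            lo = profile.min_rep[i] if profile.min_rep is not None else ""
            hi = profile.max_rep[i] if profile.max_rep is not None else ""
            w.writerow([i, labels[i], f"{f:.6g}", lo, hi])
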