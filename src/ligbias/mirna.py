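"""miRNA quantification, arm-switch detection, and candidate filtering.

Quantities here are protocol-comparison tools: reads-per-million (RPM)
normalization and ranking, detection-threshold curves, fold-change
concordance between adapter protocols, detection of arm switches (a
change in which strand of a miRNA duplex dominates between protocols),
and the fold-change / star-strand filter applied to newly predicted
miRNA candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def rpm_normalize(counts: Mapping[str, int], library_total: int) -> dict[str, float]:
    """Reads-per-million: ``count / library_total * 1e6``.

    ``library_total`` is the normalization denominator (by default the
    total reads assigned to known miRNAs in the library) and must be
    positive and at least the sum of the counts.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if sum(counts.values()) > library_total:
        raise ValueError("counts exceed library_total")
    return {name: c / library_total * 1e6 for name, c in counts.items()}


def rank_expression(counts: Mapping[str, int], library_total: int) -> pd.DataFrame:
    """Ranked expression table: name, raw count, RPM, rank (1 = top).

    Ties in count are broken lexicographically by name so that ranks are
    a permutation.  Ranks are invariant to uniform depth scaling.
    """
    rpm = rpm_normalize(counts, library_total)
    df = pd.DataFrame(
        {"name": list(counts), "count": list(counts.values())}
    )
    df["rpm"] = df["name"].map(rpm)
    df = df.sort_values(["count", "name"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def detection_curve(
    counts: Mapping[str, int] | Sequence[int], thresholds: Sequence[float]
) -> dict[float, int]:
    """Number of species with count >= threshold, per threshold.

    The curve is non-increasing in the threshold; comparing curves at
    equal depth between protocols shows which adapter set detects more
    miRNAs at any given cutoff.
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
    return {t: sum(1 for v in values if v >= t) for t in thresholds}


def fold_change_concordance(
    a_wt: Mapping[str, float],
    a_ko: Mapping[str, float],
    b_wt: Mapping[str, float],
    b_ko: Mapping[str, float],
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-miRNA log2 fold changes under two protocols, and their R^2.

    For each miRNA present in both protocols, computes
    ``log2((wt + pseudocount) / (ko + pseudocount))`` per protocol; the
    pseudocount keeps ratios finite when a condition has zero reads.
    Returns the paired table and the squared Pearson correlation.
    Protocol-specific ligation bias cancels within a protocol, so fold
    changes are expected to agree even when absolute levels do not.
    """
    shared = sorted(set(a_wt) & set(a_ko) & set(b_wt) & set(b_ko))
    if not shared:
        raise ValueError("no miRNAs shared between protocols")
    lfc_a = [math.log2((a_wt[m] + pseudocount) / (a_ko[m] + pseudocount)) for m in shared]
    lfc_b = [math.log2((b_wt[m] + pseudocount) / (b_ko[m] + pseudocount)) for m in shared]
    df = pd.DataFrame({"name": shared, "log2fc_a": lfc_a, "log2fc_b": lfc_b})
    if np.ptp(lfc_a) == 0 or np.ptp(lfc_b) == 0:
        if np.allclose(lfc_a, lfc_b):
            return df, 1.0
        raise ValueError("correlation undefined: constant fold changes")
    r = np.corrcoef(lfc_a, lfc_b)[0, 1]
    return df, float(r * r)


@dataclass
class MirnaDuplexCounts:
    """Per-library counts for the two strands of one miRNA precursor."""

    precursor: str
    seq5p: str = ""
    seq3p: str = ""
    counts5p: dict[str, int] = field(default_factory=dict)
    counts3p: dict[str, int] = field(default_factory=dict)
    mature_arm: str | None = None  # currently annotated mature strand

    def summed(self, libraries: Sequence[str]) -> tuple[int, int]:
        """Cumulative (5p, 3p) counts over replicate libraries."""
        c5 = sum(self.counts5p.get(lib, 0) for lib in libraries)
        c3 = sum(self.counts3p.get(lib, 0) for lib in libraries)
        return c5, c3


@dataclass
class ArmSwitchCall:
    """Arm-dominance comparison for one precursor between two protocols.

    ``direction`` is +1 when the dominant strand agrees, -1 on an arm
    switch, and 0 for a tie (no call).
    """

    precursor: str
    dominant_a: str | None
    dominant_b: str | None
    direction: int
    log2_ratio_a: float
    log2_ratio_b: float


def detect_arm_switch(
    duplexes: Iterable[MirnaDuplexCounts],
    libraries_a: Sequence[str],
    libraries_b: Sequence[str],
    totals_a: Mapping[str, int],
    totals_b: Mapping[str, int],
    rpm_threshold: float = 10.0,
    pseudocount: float = 1.0,
) -> tuple[list[ArmSwitchCall], int]:
    """Find duplexes whose dominant strand differs between protocols.

    Replicate libraries are summed per protocol.  Only duplexes whose
    more abundant strand exceeds ``rpm_threshold`` reads per million in
    at least one protocol are analysed.  Within each protocol the
    dominant strand is the one with the higher cumulative count; equal
    counts give no call (direction 0).  Returns the calls for all
    analysed duplexes and the number analysed.
    """
    if rpm_threshold < 0:
        raise ValueError("rpm_threshold must be non-negative")
    total_a = sum(totals_a.get(lib, 0) for lib in libraries_a)
    total_b = sum(totals_b.get(lib, 0) for lib in libraries_b)
    if total_a <= 0 or total_b <= 0:
        raise ValueError("protocol library totals must be positive")

    calls: list[ArmSwitchCall] = []
    for dup in duplexes:
        a5, a3 = dup.summed(libraries_a)
        b5, b3 = dup.summed(libraries_b)
        rpm_a = max(a5, a3) / total_a * 1e6
        rpm_b = max(b5, b3) / total_b * 1e6
        if rpm_a <= rpm_threshold and rpm_b <= rpm_threshold:
            continue
        dom_a = "5p" if a5 > a3 else "3p" if a3 > a5 else None
        dom_b = "5p" if b5 > b3 else "3p" if b3 > b5 else None
        if dom_a is None or dom_b is None:
            direction = 0
        else:
            direction = 1 if dom_a == dom_b else -1
        calls.append(
            ArmSwitchCall(
                precursor=dup.precursor,
                dominant_a=dom_a,
                dominant_b=dom_b,
                direction=direction,
                log2_ratio_a=math.log2((a5 + pseudocount) / (a3 + pseudocount)),
                log2_ratio_b=math.log2((b5 + pseudocount) / (b3 + pseudocount)),
            )
        )
    return calls, len(calls)


def arm_switch_table(calls: Sequence[ArmSwitchCall]) -> pd.DataFrame:
    """Arm-switch calls as a DataFrame (log2 5p/3p ratios, direction)."""
    return pd.DataFrame(
        {
            "precursor": [c.precursor for c in calls],
            "dominant_a": [c.dominant_a for c in calls],
            "dominant_b": [c.dominant_b for c in calls],
            "log2_ratio_a": [c.log2_ratio_a for c in calls],
            "log2_ratio_b": [c.log2_ratio_b for c in calls],
            "direction": [c.direction for c in calls],
        }
    )


@dataclass(frozen=True)
class NewMirnaCandidate:
    """A hairpin-discovery candidate awaiting the downstream filter."""

    name: str
    wt_count: float
    ko_count: float
    star_seen: bool


def filter_new_candidates(
    candidates: Iterable[NewMirnaCandidate],
    fc_min: float = 1.4,
    pseudocount: float = 1.0,
) -> list[NewMirnaCandidate]:
    """Retain candidates supported as genuine Dicer products.

    A candidate passes when its wild-type / Dicer-knockout fold change
    (pseudocount-protected) strictly exceeds ``fc_min`` AND a star
    (passenger) strand has been observed.  Dicer dependence and a
    detectable duplex partner are the two hallmarks distinguishing real
    miRNAs from degradation fragments.
    """
    if fc_min <= 0:
        raise ValueError("fc_min must be positive")
    kept = []
    for c in candidates:
        fc = (c.wt_count + pseudocount) / (c.ko_count + pseudocount)
        if fc > fc_min and c.star_seen:
            kept.append(c)
    return kept
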