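"""Poisson sampling model for degenerate-library read counts.

Sequencing a nominally equimolar pool of p possible molecules to a depth
of n reads is a sampling process in which each molecule's read count is
approximately Poisson with rate lambda = n / p.  Departures from this
null — heavy upper tails, missing sequences — are the signature of
ligation bias, and are quantified here with a Pearson chi-square
goodness-of-fit test on the multiplicity histogram (the number of
distinct sequences observed exactly k times).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .sequences import ReadCountTable


@dataclass
class CountDistributionSummary:
    """Poisson goodness-of-fit summary for one library."""

    multiplicity_histogram: dict[int, int]
    n: int
    p: int
    lam: float
    chi2: float
    dof: int
    pvalue: float

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["multiplicity_histogram"] = {str(k): v for k, v in sorted(d["multiplicity_histogram"].items())}
        Path(path).write_text(json.dumps(d, indent=2))


def poisson_expected_histogram(n: int, p: int, max_count: int) -> np.ndarray:
    """Expected number of distinct sequences at each read count under Poisson.

    Returns an array of length ``max_count + 1`` where entry k (k <
    max_count) is ``p * PoissonPMF(k; n/p)`` and the final entry pools
    the entire upper tail, so the expectations sum to p exactly.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    if max_count < 0:
        raise ValueError("max_count must be non-negative")
    lam = n / p
    k = np.arange(max_count + 1)
    expected = p * stats.poisson.pmf(k, lam)
    expected[max_count] = p * stats.poisson.sf(max_count - 1, lam) if max_count > 0 else p
    return expected


def _full_observed(observed: Mapping[int, int], n: int, p: int) -> np.ndarray:
    """Observed histogram as a dense array including the zero-count class."""
    obs = dict(observed)
    mass = sum(k * v for k, v in obs.items())
    if mass != n:
        raise ValueError(f"histogram mass {mass} does not match n = {n}")
    if 0 not in obs:
        seen = sum(obs.values())
        if seen > p:
            raise ValueError("more distinct sequences than library size p")
        obs[0] = p - seen
    if sum(obs.values()) != p:
        raise ValueError("histogram frequencies do not sum to p")
    max_count = max(obs)
    arr = np.zeros(max_count + 1)
    for k, v in obs.items():
        if k < 0 or v < 0:
            raise ValueError("negative count or frequency in histogram")
        arr[k] = v
    return arr


def chi2_poisson_gof(
    observed: Mapping[int, int],
    n: int,
    p: int,
    min_expected: float = 5.0,
) -> tuple[float, int, float]:
    """Pearson chi-square test of the Poisson(n/p) count-distribution null.

    ``observed`` maps read-count values to numbers of distinct sequences;
    the zero-count class is filled in as ``p - (#distinct observed)`` when
    absent.  Bins with expected frequency below ``min_expected`` are
    pooled inward from both extremes of the count range (both Poisson
    tails are thin), and the test has ``#bins - 1`` degrees of freedom.

    Returns ``(chi2, dof, pvalue)``.
    """
    obs = _full_observed(observed, n, p)
    max_count = len(obs) - 1
    exp = poisson_expected_histogram(n, p, max_count)

    # greedy pooling from the tail inward: walk count values from high to
    # low, merging adjacent bins until each pooled bin reaches the minimum
    # expectation (the leftover low-count remainder joins its neighbour)
    groups: list[tuple[float, float]] = []
    acc_o = acc_e = 0.0
    for k in range(len(exp) - 1, -1, -1):
        acc_o += obs[k]
        acc_e += exp[k]
        if acc_e >= min_expected:
            groups.append((acc_o, acc_e))
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if groups:
            o, e = groups.pop()
            groups.append((o + acc_o, e + acc_e))
        else:
            groups.append((acc_o, acc_e))
    if len(groups) < 2:
        raise ValueError("fewer than 2 adequate bins after pooling; test is degenerate")

    obs_a = np.array([o for o, _ in groups])
    exp_a = np.array([e for _, e in groups])
    chi2 = float(np.sum((obs_a - exp_a) ** 2 / exp_a))
    dof = len(exp_a) - 1
    pvalue = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, pvalue


def summarize_counts(table: ReadCountTable, p: int) -> CountDistributionSummary:
    """Full Poisson goodness-of-fit summary for a read-count table."""
    hist = table.multiplicity_histogram()
    n = table.total_reads
    chi2, dof, pvalue = chi2_poisson_gof(hist, n, p)
    return CountDistributionSummary(hist, n, p, n / p, chi2, dof, pvalue)


def capture_fraction(table: ReadCountTable, p: int) -> float:
    """Fraction of the p possible sequences observed at least once.

    Every sequence length must be consistent with a pool of p distinct
    molecules (4^length >= p); a full N_k pool (p = 4^k) therefore
    requires every sequence to be at least k long.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    for s in table.counts:
        if 4 ** len(s) < p:
            raise ValueError(
                f"sequence length {len(s)} inconsistent with pool size {p}"
            )
    distinct = sum(1 for c in table.counts.values() if c >= 1)
    if distinct > p:
        raise ValueError("more distinct sequences than library size p")
    return distinct / p


def abundance_curve(table: ReadCountTable, top_m: int) -> list[int]:
    """Read counts of the ``top_m`` most abundant sequences, descending.

    Ties are broken lexicographically by sequence so the curve is
    reproducible.  Tables with fewer than ``top_m`` entries return all
    counts.
    """
    if top_m < 1:
        raise ValueError("top_m must be at least 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [c for _, c in ranked[:top_m]]
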