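"""Synthetic degenerate-pool sequencing under a ligation-bias model.

The generator emulates sequencing a degenerate RNA pool (N9- or
N21-style) through a two-step adapter ligation whose per-molecule
efficiency depends on predicted secondary structure at the two ligation
junctions.  The bias model encodes the two ligase rules seen in such
data: the 3'-adapter ligase (truncated T4 Rnl2) favours a base-paired
(double-stranded) context immediately upstream of its junction, and the
5'-adapter ligase (T4 Rnl1) favours a single-stranded site immediately
downstream of its junction.

Each pool molecule receives a Boltzmann-like ligation weight

    w = exp(beta3 * s3 + beta5 * s5 - gamma_mfe * MFE)

where s3 = +1 if the base upstream of the 3' junction is paired in the
construct's MFE structure (else -1), s5 = +1 if the base downstream of
the 5' junction is unpaired (else -1), and the optional MFE term lets
overall folding stability boost capture.  Reads are then a multinomial
sample of the normalized weights; beta3 = beta5 = gamma_mfe = 0 gives
exactly uniform (unbiased) sampling, under which per-sequence counts
follow the Poisson null.  For HD adapters, each molecule's weight is
averaged over uniformly sampled degenerate-tag pairs — the mechanism by
which the tag pool evens out the bias.

A single seed drives all randomness; identical seeds give bitwise
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .folding import Engine, fold
from .hd import TagPair
from .mirna import MirnaDuplexCounts
from .profiles import build_construct
from .sequences import AdapterSet, ReadCountTable

RNA_BASES = "ACGU"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    Defaults emulate an N9 degenerate pool (all 4^9 = 262,144 molecules)
    sequenced to a depth of one million reads, unbiased.  ``beta3`` /
    ``beta5`` are the 3'- and 5'-junction bias strengths (0 = no bias),
    ``gamma_mfe`` the optional stability bias, ``tag_length`` the HD
    degenerate-tag length (0 = standard adapters), and ``tag_samples``
    how many tag pairs are drawn per molecule when averaging HD weights.
    """

    insert_length: int = 9
    pool_size: int = 4**9
    depth: int = 10**6
    beta3: float = 0.0
    beta5: float = 0.0
    gamma_mfe: float = 0.0
    tag_length: int = 0
    tag_samples: int = 16
    seed: int = 0
    engine: Engine = "builtin"
    temperature: float = 22.0

    def __post_init__(self) -> None:
        if self.insert_length < 1 or self.pool_size < 1 or self.depth < 1:
            raise ValueError("insert_length, pool_size and depth must be positive")
        if self.pool_size > 4**self.insert_length:
            raise ValueError(
                f"pool_size {self.pool_size} exceeds 4^{self.insert_length}"
            )
        if self.beta3 < 0 or self.beta5 < 0 or self.gamma_mfe < 0:
            raise ValueError("bias strengths must be non-negative")


@dataclass
class GroundTruth:
    """Per-molecule truth for a simulated library."""

    inserts: list[str]
    weights: np.ndarray  # normalized ligation weights, sum to 1


@dataclass
class SimulatedLibrary:
    """One simulated sequencing run with its ground truth."""

    table: ReadCountTable
    truth: GroundTruth
    config: SimulationConfig
    #: (insert, tag pair) -> read count; populated for HD runs only
    tagged_counts: dict[tuple[str, TagPair], int] = field(default_factory=dict)

    def iter_tagged_reads(self) -> Iterator[tuple[str, TagPair]]:
        for (insert, pair), c in self.tagged_counts.items():
            for _ in range(c):
                yield insert, pair


def _int_to_seq(x: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(RNA_BASES[x & 3])
        x >>= 2
    return "".join(reversed(out))


def _draw_pool(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Uniform sample of distinct insert sequences."""
    space = 4**cfg.insert_length
    if cfg.pool_size == space:
        ids = np.arange(space)
    elif space <= 2**24:
        ids = rng.choice(space, size=cfg.pool_size, replace=False)
    else:  # N21-scale space: rejection sampling of distinct integers
        seen: set[int] = set()
        while len(seen) < cfg.pool_size:
            for x in rng.integers(0, space, size=cfg.pool_size):
                seen.add(int(x))
                if len(seen) == cfg.pool_size:
                    break
        ids = np.fromiter(seen, dtype=np.int64)
        ids.sort()
    return [_int_to_seq(int(x), cfg.insert_length) for x in ids]


def _random_tag(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA_BASES[i] for i in rng.integers(0, 4, size=length))


def _construct_weight(
    insert: str,
    adapters: AdapterSet,
    cfg: SimulationConfig,
    tag5: str | None,
    tag3: str | None,
) -> float:
    """Ligation weight (unnormalized) of one insert/tag combination."""
    mode = "full_construct" if cfg.beta5 > 0 else "insert_plus_3"
    seq, ctx = build_construct(insert, adapters, mode, tag5=tag5, tag3=tag3)
    ss = fold(seq, cfg.temperature, cfg.engine)
    paired = ss.paired_mask()
    s3 = 1.0 if paired[ctx.junction3 - 1] else -1.0
    arg = cfg.beta3 * s3 - cfg.gamma_mfe * ss.mfe
    if ctx.junction5 is not None:
        s5 = 1.0 if not paired[ctx.junction5] else -1.0
        arg += cfg.beta5 * s5
    return float(np.exp(arg))


def _molecule_weights(
    pool: Sequence[str],
    adapters: AdapterSet,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[list[tuple[TagPair, float]]] | None]:
    """Per-molecule weights; for HD also each molecule's sampled tag pairs."""
    unbiased = cfg.beta3 == 0 and cfg.beta5 == 0 and cfg.gamma_mfe == 0
    t = adapters.tag_length
    if t == 0:
        if unbiased:
            w = np.ones(len(pool))
        else:
            w = np.array(
                [_construct_weight(s, adapters, cfg, None, None) for s in pool]
            )
        return w / w.sum(), None

    # HD: average the weight over uniformly sampled degenerate-tag pairs
    per_mol: list[list[tuple[TagPair, float]]] = []
    w = np.empty(len(pool))
    for i, insert in enumerate(pool):
        pairs = [
            TagPair(_random_tag(rng, t), _random_tag(rng, t))
            for _ in range(cfg.tag_samples)
        ]
        if unbiased:
            pw = [1.0] * len(pairs)
        else:
            pw = [
                _construct_weight(insert, adapters, cfg, p.tag5, p.tag3)
                for p in pairs
            ]
        per_mol.append(list(zip(pairs, pw)))
        w[i] = float(np.mean(pw))
    return w / w.sum(), per_mol


def simulate_library(
    cfg: SimulationConfig,
    adapters: AdapterSet | None = None,
    _pool: Sequence[str] | None = None,
    _rng: np.random.Generator | None = None,
) -> SimulatedLibrary:
    """Simulate one sequenced library under the ligation-bias model.

    Draws ``pool_size`` distinct inserts uniformly, computes each
    molecule's structure-dependent ligation weight (averaged over
    sampled tag pairs for HD adapters), and samples ``depth`` reads
    from the normalized weights.  Returns the read-count table, the
    ground-truth weights, and — for HD runs — per-read tag-pair
    provenance aggregated into ``tagged_counts``.
    """
    if adapters is None:
        adapters = AdapterSet.illumina() if cfg.tag_length == 0 else AdapterSet.hd()
    if adapters.tag_length != cfg.tag_length:
        raise ValueError("cfg.tag_length must match adapters.tag_length")
    rng = _rng if _rng is not None else np.random.default_rng(cfg.seed)
    pool = list(_pool) if _pool is not None else _draw_pool(cfg, rng)
    weights, per_mol_tags = _molecule_weights(pool, adapters, cfg, rng)
    counts = rng.multinomial(cfg.depth, weights)

    table = ReadCountTable(
        {pool[i]: int(c) for i, c in enumerate(counts) if c > 0}
    )
    tagged: dict[tuple[str, TagPair], int] = {}
    if per_mol_tags is not None:
        for i, c in enumerate(counts):
            if c == 0:
                continue
            pairs = per_mol_tags[i]
            pw = np.array([w for _, w in pairs])
            split = rng.multinomial(int(c), pw / pw.sum())
            for (pair, _), k in zip(pairs, split):
                if k > 0:
                    key = (pool[i], pair)
                    tagged[key] = tagged.get(key, 0) + int(k)
    return SimulatedLibrary(table, GroundTruth(pool, weights), cfg, tagged)


@dataclass
class HdComparison:
    """Paired standard-vs-HD simulation from one shared pool."""

    standard: SimulatedLibrary
    hd: SimulatedLibrary
    capture_standard: float
    capture_hd: float


def simulate_hd_vs_standard(
    cfg: SimulationConfig,
    adapters_standard: AdapterSet | None = None,
    adapters_hd: AdapterSet | None = None,
) -> HdComparison:
    """Sequence the same pool with standard and with HD adapters.

    Both arms share the insert pool (and the seed-derived random
    streams are fixed per arm), so differences in capture fraction and
    abundance-curve shape isolate the adapter effect.
    """
    adapters_standard = adapters_standard or AdapterSet.illumina()
    adapters_hd = adapters_hd or AdapterSet.hd()
    if adapters_hd.tag_length == 0:
        raise ValueError("adapters_hd must have a positive tag_length")
    ss = np.random.SeedSequence(cfg.seed)
    rng_pool, rng_std, rng_hd = (np.random.default_rng(s) for s in ss.spawn(3))
    pool = _draw_pool(cfg, rng_pool)
    cfg_std = replace(cfg, tag_length=0)
    cfg_hd = replace(cfg, tag_length=adapters_hd.tag_length)
    lib_std = simulate_library(cfg_std, adapters_standard, _pool=pool, _rng=rng_std)
    lib_hd = simulate_library(cfg_hd, adapters_hd, _pool=pool, _rng=rng_hd)
    return HdComparison(
        standard=lib_std,
        hd=lib_hd,
        capture_standard=lib_std.table.n_distinct / cfg.pool_size,
        capture_hd=lib_hd.table.n_distinct / cfg.pool_size,
    )


def make_read(
    insert: str,
    adapters: AdapterSet,
    tag5: str = "",
    tag3: str = "",
) -> str:
    """Assemble the sequenced strand for an insert: used to exercise trimming.

    The read begins at the 5' tag (HD) or directly at the insert
    (standard) and runs into the 3' tag and 3' adapter core, mimicking
    a read long enough to reach the adapter.
    """
    t = adapters.tag_length
    if len(tag5) != t or len(tag3) != t:
        raise ValueError(f"tags must have length {t}")
    return tag5 + insert + tag3 + adapters.adapter3


def write_reads_fasta(
    lib: SimulatedLibrary,
    adapters: AdapterSet,
    path: str | Path,
    max_reads: int | None = None,
) -> int:
    """Emit raw (untrimmed) reads as FASTA; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        if lib.tagged_counts:
            items: Iterator = (
                (ins, p.tag5, p.tag3, c)
                for (ins, p), c in sorted(
                    lib.tagged_counts.items(),
                    key=lambda kv: (kv[0][0], kv[0][1].tag5, kv[0][1].tag3),
                )
            )
        else:
            items = ((ins, "", "", c) for ins, c in sorted(lib.table.counts.items()))
        for ins, t5, t3, c in items:
            read = make_read(ins, adapters, t5, t3)
            for _ in range(c):
                if max_reads is not None and n >= max_reads:
                    return n
                n += 1
                fh.write(f">read_{n}\n{read}\n")
    return n


def simulate_duplex_counts(
    n_precursors: int = 122,
    arm_switch_fraction: float = 0.12,
    mean_expression: float = 500.0,
    seed: int = 0,
    n_replicates: int = 2,
) -> tuple[list[MirnaDuplexCounts], set[str], dict[str, int], dict[str, int]]:
    """Two-protocol miRNA duplex count tables with known arm switches.

    Each precursor gets a log-normal expression level and a dominant-arm
    share drawn from [0.75, 0.95].  Protocol A observes the true
    dominance; in a known ``arm_switch_fraction`` of precursors protocol
    B sees the dominance inverted (a simulated protocol-dependent arm
    switch).  Counts are Poisson per replicate library.  Returns the
    duplex records, the set of truly switched precursor names, and the
    per-library totals for the two protocols.
    """
    if not 0 <= arm_switch_fraction <= 1:
        raise ValueError("arm_switch_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_switch = round(n_precursors * arm_switch_fraction)
    switched_idx = set(
        rng.choice(n_precursors, size=n_switch, replace=False).tolist()
    )
    libs_a = [f"protoA_rep{r + 1}" for r in range(n_replicates)]
    libs_b = [f"protoB_rep{r + 1}" for r in range(n_replicates)]
    duplexes: list[MirnaDuplexCounts] = []
    switched_names: set[str] = set()
    for i in range(n_precursors):
        name = f"mir-{i + 1:04d}"
        expr = mean_expression * rng.lognormal(0.0, 1.0)
        share = rng.uniform(0.75, 0.95)  # dominant arm share of duplex reads
        dom_is_5p = bool(rng.integers(0, 2))
        frac5_a = share if dom_is_5p else 1.0 - share
        frac5_b = 1.0 - frac5_a if i in switched_idx else frac5_a
        if i in switched_idx:
            switched_names.add(name)
        c5a = {lib: int(rng.poisson(expr * frac5_a)) for lib in libs_a}
        c3a = {lib: int(rng.poisson(expr * (1 - frac5_a))) for lib in libs_a}
        c5b = {lib: int(rng.poisson(expr * frac5_b)) for lib in libs_b}
        c3b = {lib: int(rng.poisson(expr * (1 - frac5_b))) for lib in libs_b}
        duplexes.append(
            MirnaDuplexCounts(
                precursor=name,
                counts5p={**c5a, **c5b},
                counts3p={**c3a, **c3b},
                mature_arm="5p" if dom_is_5p else "3p",
            )
        )
    totals_a = {
        lib: sum(d.counts5p.get(lib, 0) + d.counts3p.get(lib, 0) for d in duplexes)
        for lib in libs_a
    }
    totals_b = {
        lib: sum(d.counts5p.get(lib, 0) + d.counts3p.get(lib, 0) for d in duplexes)
        for lib in libs_b
    }
    return duplexes, switched_names, totals_a, totals_b
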