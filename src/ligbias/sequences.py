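"""Core sequence types and I/O for small-RNA library analysis.

All internal sequence handling uses the RNA alphabet {A, C, G, U}; DNA
input is normalized on read (T -> U).  Reads are represented either as
raw strings or aggregated into a :class:`ReadCountTable`, the central
container mapping each distinct insert sequence to its observed read
count.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Illumina-style small-RNA adapter cores (v1.5-era kit sequences), used
#: as defaults throughout.  The 3' adapter is pre-adenylated DNA in the
#: wet protocol; here it is stored in the RNA alphabet like everything else.
ILLUMINA_ADAPTER5 = "GUUCAGAGUUCUACAGUCCGACGAUC"
ILLUMINA_ADAPTER3 = "AUCUCGUAUGCCGUCUUCUGCUUG"


class SequenceError(ValueError):
    """Raised for alphabet violations or malformed sequence input."""


def as_rna(seq: str, *, allow_n: bool = False) -> str:
    """Normalize a nucleotide string to the uppercase RNA alphabet.

    T is converted to U.  Raises :class:`SequenceError` on empty input or
    characters outside {A, C, G, U} (plus N when ``allow_n``).
    """
    if not seq:
        raise SequenceError("empty sequence")
    out = seq.upper().replace("T", "U")
    allowed = RNA_ALPHABET | {"N"} if allow_n else RNA_ALPHABET
    bad = set(out) - allowed
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in sequence {seq!r}")
    return out


@dataclass(frozen=True)
class AdapterSet:
    """A 5'/3' adapter pair plus the length of the degenerate tag.

    ``tag_length = 0`` is the standard (Illumina-style) configuration;
    ``tag_length = 4`` is the high-definition (HD) configuration in which
    each adapter carries four fully degenerate nucleotides at its
    ligation-proximal end, so that ligation is performed by a pool of
    4^4 = 256 adapter variants per side.
    """

    adapter5: str
    adapter3: str
    tag_length: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "adapter5", as_rna(self.adapter5))
        object.__setattr__(self, "adapter3", as_rna(self.adapter3))
        if self.tag_length < 0:
            raise ValueError("tag_length must be non-negative")

    @classmethod
    def illumina(cls) -> "AdapterSet":
        return cls(ILLUMINA_ADAPTER5, ILLUMINA_ADAPTER3, tag_length=0)

    @classmethod
    def hd(cls) -> "AdapterSet":
        return cls(ILLUMINA_ADAPTER5, ILLUMINA_ADAPTER3, tag_length=4)


@dataclass
class ReadCountTable:
    """Mapping from insert sequence to observed read count.

    Invariant: ``total_reads`` equals the sum of counts.  ``n_dropped``
    records reads discarded on input (ambiguous bases).
    """

    counts: dict[str, int] = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def insert_length(self) -> int | str:
        """Common length of all inserts, or ``"mixed"``."""
        lengths = {len(s) for s in self.counts}
        if len(lengths) == 1:
            return lengths.pop()
        return "mixed"

    def multiplicity_histogram(self) -> dict[int, int]:
        """Map each count value to the number of distinct sequences with it."""
        return dict(Counter(self.counts.values()))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], n_dropped: int = 0) -> "ReadCountTable":
        return cls(dict(Counter(seqs)), n_dropped=n_dropped)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["sequence", "count"])
            for seq in sorted(self.counts):
                w.writerow([seq, self.counts[seq]])


def read_sequences(path: str | Path, format: str = "fasta") -> ReadCountTable:
    """Read sequences into a :class:`ReadCountTable`.

    Parameters
    ----------
    path
        Input file.
    format
        ``"fasta"``, ``"fastq"``, or ``"tsv-counts"`` (two columns,
        sequence and count, with a header line).

    Identical sequences are aggregated; T is normalized to U.  Records
    containing ambiguous bases (N) are dropped and counted in
    ``n_dropped`` with a logged warning.  An empty input is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    counts: Counter[str] = Counter()
    dropped = 0
    if format in ("fasta", "fastq"):
        n_records = 0
        for rec in SeqIO.parse(str(path), format):
            n_records += 1
            seq = as_rna(str(rec.seq), allow_n=True)
            if "N" in seq:
                dropped += 1
                continue
            counts[seq] += 1
        if n_records == 0:
            raise SequenceError(f"no records found in {path}")
        if dropped:
            logger.warning("dropped %d record(s) containing ambiguous bases", dropped)
    elif format == "tsv-counts":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            rows = list(reader)
        if not rows:
            raise SequenceError(f"empty table {path}")
        body = rows[1:] if not rows[0][-1].strip().lstrip("-").isdigit() else rows
        if not body:
            raise SequenceError(f"no data rows in {path}")
        for i, row in enumerate(body, start=2):
            if len(row) < 2:
                raise SequenceError(f"{path}: malformed record at line {i}")
            try:
                c = int(row[1])
            except ValueError as exc:
                raise SequenceError(f"{path}: non-integer count at line {i}") from exc
            if c < 0:
                raise SequenceError(f"{path}: negative count at line {i}")
            seq = as_rna(row[0], allow_n=True)
            if "N" in seq:
                dropped += 1
                continue
            counts[seq] += c
        if dropped:
            logger.warning("dropped %d row(s) containing ambiguous bases", dropped)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ReadCountTable(dict(counts), n_dropped=dropped)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of adapter/tag trimming for one read."""

    insert: str | None
    status: str  # "ok", "no-adapter", or "too-short"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def trim_read(
    raw_read: str,
    adapters: AdapterSet,
    min_insert: int = 16,
    match_length: int = 8,
) -> TrimResult:
    """Strip adapter and degenerate-tag sequence from a raw read.

    The read is assumed to start at the insert (standard adapters) or at
    the 5' degenerate tag (HD adapters).  The 3' adapter core is located
    by exact match of its first ``match_length`` nucleotides (leftmost
    occurrence); everything from the match onward is removed, together
    with the ``tag_length`` nucleotides immediately preceding the match
    (the 3' tag) and the ``tag_length`` nucleotides at the read start
    (the 5' tag).

    Returns a :class:`TrimResult` whose status is ``"ok"``,
    ``"no-adapter"`` (no exact adapter-prefix match) or ``"too-short"``
    (insert below ``min_insert`` after trimming).
    """
    read = as_rna(raw_read)
    probe = adapters.adapter3[:match_length]
    if len(probe) < match_length:
        raise ValueError("adapter3 shorter than the required match length")
    pos = read.find(probe)
    if pos < 0:
        return TrimResult(None, "no-adapter")
    t = adapters.tag_length
    start = t
    end = pos - t
    if end < start:
        return TrimResult(None, "too-short")
    insert = read[start:end]
    if len(insert) < min_insert:
        return TrimResult(None, "too-short")
    return TrimResult(insert, "ok")


def count_kmers(k: int, alphabet_size: int = 4) -> int:
    """Number of distinct k-mers over an alphabet: ``alphabet_size ** k``.

    For the fully degenerate N9 pool this is 4^9 = 262,144; for N21,
    4^21 ~ 4.4e12.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be at least 1")
    return alphabet_size**k


def write_rejection_report(
    results: Mapping[str, TrimResult] | Iterable[tuple[str, TrimResult]],
    path: str | Path,
) -> None:
    """Write a TSV of (read, status) for trimming rejections."""
    items = results.items() if isinstance(results, Mapping) else results
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["read", "status"])
        for read, res in items:
            if not res.ok:
                w.writerow([read, res.status])
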