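"""RNA secondary-structure prediction.

Two engines sit behind one contract:

* ``"builtin"`` — a deterministic Nussinov-style dynamic program with
  stacking-weighted base-pair scores.  It exists so that every pipeline
  stage is testable hermetically; its energies are on a kcal/mol-like
  scale but are not Turner free energies.
* ``"vienna"`` — delegates to the ViennaRNA ``RNA`` Python bindings
  (RNAfold's library) and returns that engine's minimum free energy
  verbatim.  This is the engine to use when thermodynamic realism
  matters.

Both return a single optimal structure (no suboptimal ensemble) as a
:class:`SecondaryStructure` with a dot-bracket string and an MFE in
kcal/mol.  Watson-Crick pairs and the G.U wobble are allowed; the
minimum hairpin loop is 3 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

from .sequences import as_rna

MIN_HAIRPIN_LOOP = 3

#: Base-pair scores for the built-in folder, loosely proportional to pair
#: stability (hydrogen-bond count): G-C strongest, G.U wobble weakest.
PAIR_SCORE = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "U"): 2,
    ("U", "A"): 2,
    ("G", "U"): 1,
    ("U", "G"): 1,
}
#: Bonus added when a pair stacks directly on the previous helix pair.
STACK_BONUS = 1
#: kcal/mol-like energy per score unit at the reference temperature.
ENERGY_PER_SCORE = 0.5
REFERENCE_TEMPERATURE = 22.0


class StructureError(ValueError):
    """Raised for malformed dot-bracket strings."""


@dataclass(frozen=True)
class SecondaryStructure:
    """One predicted secondary structure.

    ``dotbracket`` uses matched parentheses for base pairs and dots for
    unpaired positions; ``mfe`` is the structure's minimum free energy in
    kcal/mol (non-positive whenever at least one pair forms).
    """

    dotbracket: str
    mfe: float
    temperature: float = REFERENCE_TEMPERATURE

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def paired_mask(self) -> list[bool]:
        """True at every position that is base paired."""
        return [c != "." for c in self.dotbracket]


def pair_table(structure: SecondaryStructure | str) -> list[int | None]:
    """Partner index per position (0-based); ``None`` where unpaired.

    The mapping is symmetric: ``pt[i] == j`` implies ``pt[j] == i``.
    Raises :class:`StructureError` on unbalanced brackets.
    """
    db = structure.dotbracket if isinstance(structure, SecondaryStructure) else structure
    pt: list[int | None] = [None] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[j] = i
            pt[i] = j
        elif c != ".":
            raise StructureError(f"invalid character {c!r} at position {i}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return pt


def from_pair_table(pt: list[int | None]) -> str:
    """Inverse of :func:`pair_table` for non-crossing pairings."""
    out = ["."] * len(pt)
    for i, j in enumerate(pt):
        if j is None:
            continue
        if pt[j] != i:
            raise StructureError("pair table is not symmetric")
        if i < j:
            out[i], out[j] = "(", ")"
    db = "".join(out)
    pair_table(db)  # validates nesting
    return db


def _temperature_scale(temperature: float) -> float:
    # Energies scale with inverse absolute temperature relative to 22 C;
    # the chosen structure is unaffected (documented limitation of the
    # built-in engine).
    return (REFERENCE_TEMPERATURE + 273.15) / (temperature + 273.15)


def _fold_builtin(seq: str, temperature: float) -> SecondaryStructure:
    n = len(seq)
    NEG = float("-inf")

    def pscore(i: int, j: int) -> float:
        return PAIR_SCORE.get((seq[i], seq[j]), NEG)

    # P[i][j]: best score of i..j with (i,j) paired; M[i][j]: best overall.
    M = [[0.0] * n for _ in range(n)]
    P = [[NEG] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            w = pscore(i, j)
            if w > NEG:
                inner = M[i + 1][j - 1] if j - 1 > i + 1 else 0.0
                best = inner
                if P[i + 1][j - 1] > NEG:
                    best = max(best, P[i + 1][j - 1] + STACK_BONUS)
                P[i][j] = w + best
            best = M[i][j - 1]  # j unpaired
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                if P[k][j] > NEG:
                    left = M[i][k - 1] if k > i else 0.0
                    cand = left + P[k][j]
                    if cand > best:
                        best = cand
            M[i][j] = best

    db = ["."] * n

    def trace_pair(i: int, j: int) -> None:
        db[i], db[j] = "(", ")"
        if j - 1 <= i + 1:
            return
        w = pscore(i, j)
        # prefer extending the helix (stacking) over any bifurcation
        if P[i + 1][j - 1] > NEG and P[i][j] == w + P[i + 1][j - 1] + STACK_BONUS:
            trace_pair(i + 1, j - 1)
        else:
            trace_region(i + 1, j - 1)

    def trace_region(i: int, j: int) -> None:
        if j - i < MIN_HAIRPIN_LOOP + 1 or M[i][j] == 0.0:
            return
        # prefer pairing (k, j) with the smallest k over leaving j unpaired
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            if P[k][j] > NEG:
                left = M[i][k - 1] if k > i else 0.0
                if left + P[k][j] == M[i][j]:
                    trace_pair(k, j)
                    if k > i:
                        trace_region(i, k - 1)
                    return
        trace_region(i, j - 1)

    if n > MIN_HAIRPIN_LOOP + 1:
        trace_region(0, n - 1)
    score = M[0][n - 1] if n > 1 else 0.0
    mfe = -score * ENERGY_PER_SCORE * _temperature_scale(temperature) if score else 0.0
    return SecondaryStructure("".join(db), mfe, temperature)


@lru_cache(maxsize=8)
def _vienna_model(temperature: float):
    import RNA  # ViennaRNA python bindings

    md = RNA.md()
    md.temperature = temperature
    return md


def _fold_vienna(seq: str, temperature: float) -> SecondaryStructure:
    import RNA

    fc = RNA.fold_compound(seq, _vienna_model(temperature))
    db, mfe = fc.mfe()
    return SecondaryStructure(db, float(mfe), temperature)


Engine = str | Callable[[str, float], SecondaryStructure]


def fold(
    seq: str,
    temperature: float = REFERENCE_TEMPERATURE,
    engine: Engine = "builtin",
) -> SecondaryStructure:
    """Predict one minimum-free-energy structure for an RNA sequence.

    Parameters
    ----------
    seq
        RNA sequence (T accepted and normalized to U).
    temperature
        Folding temperature in degrees Celsius (default 22).
    engine
        ``"builtin"``, ``"vienna"``, or any callable
        ``(sequence, temperature) -> SecondaryStructure``.

    The built-in engine breaks ties deterministically: pairing is
    preferred over bifurcation, then the pair with the smallest 5'
    index and the largest 3' index.
    """
    seq = as_rna(seq)
    if callable(engine):
        return engine(seq, temperature)
    if engine == "builtin":
        return _fold_builtin(seq, temperature)
    if engine == "vienna":
        return _fold_vienna(seq, temperature)
    raise ValueError(f"unknown folding engine {engine!r}")


def vienna_available() -> bool:
    """True when the ViennaRNA python bindings can be imported."""
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True
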