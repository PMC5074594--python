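"""Secondary-structure handling: dot-bracket parsing, structural-element
decomposition, and the pluggable minimum-free-energy folding adapter.

The decomposition follows the standard nested-RNA element taxonomy: a
*helix* is a maximal run of consecutively stacked base pairs
(i,j),(i+1,j-1),...; a *stack* is one adjacent pair-step inside a helix,
so the stack count equals total pairs minus helix count; a pair directly
enclosing exactly one pair is a bulge (gap on one strand) or an interior
loop (gaps on both strands); a pair enclosing none closes a hairpin loop;
a pair enclosing two or more branches closes a multiloop.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairTable",
    "StructuralElements",
    "parse_dotbracket",
    "decompose",
    "fold",
    "RNAfoldEngine",
    "get_engine",
    "FoldingError",
]

UNPAIRED = -1


class FoldingError(RuntimeError):
    """Raised when no folding engine is configured or the engine fails."""


@dataclass(frozen=True)
class PairTable:
    """Base-pair table of a nested secondary structure.

    ``pairs[i]`` holds the 0-based partner index of position ``i``, or -1
    when position ``i`` is unpaired.  Tables built from dot-bracket strings
    are always nested (pseudoknot-free) and symmetric.
    """

    pairs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=np.int64)
        object.__setattr__(self, "pairs", p)
        for i, j in enumerate(p):
            if j == UNPAIRED:
                continue
            if j == i:
                raise ValueError(f"position {i + 1} pairs with itself")
            if not (0 <= j < len(p)) or p[j] != i:
                raise ValueError(f"asymmetric pair table at position {i + 1}")

    @property
    def length(self) -> int:
        return int(len(self.pairs))

    @property
    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.pairs >= 0) // 2)

    def partner(self, i: int) -> int | None:
        """0-based partner of position ``i``, or None if unpaired."""
        j = int(self.pairs[i])
        return None if j == UNPAIRED else j

    def is_paired(self, i: int) -> bool:
        return self.pairs[i] != UNPAIRED

    def pair_list(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, sorted by i (0-based)."""
        return [(i, int(j)) for i, j in enumerate(self.pairs) if j > i]

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j == UNPAIRED else ("(" if j > i else ")"))
        return "".join(out)


@dataclass(frozen=True)
class StructuralElements:
    """Element counts of one nested structure (feature class E substrate)."""

    helices: tuple[tuple[tuple[int, int], ...], ...]
    n_helix: int
    n_stack: int
    n_interior: int
    n_bulge: int
    n_hairpin: int
    n_multiloop: int
    n_pairs: int


def parse_dotbracket(db: str) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Only ``.``, ``(`` and ``)`` are accepted; brackets must balance.
    """
    pairs = np.full(len(db), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at position {i + 1}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return PairTable(pairs)


def _direct_branches(pt: PairTable, i: int, j: int) -> list[tuple[int, int]]:
    """Pairs directly enclosed by (i, j), left to right."""
    branches = []
    k = i + 1
    while k < j:
        p = pt.partner(k)
        if p is not None:
            branches.append((k, p))
            k = p + 1
        else:
            k += 1
    return branches


def decompose(pt: PairTable) -> StructuralElements:
    """Decompose a nested pair table into helices and loop counts."""
    pair_list = [(i, int(j)) for i, j in enumerate(pt.pairs) if j > i]
    pair_set = set(pair_list)

    helices: list[list[tuple[int, int]]] = []
    for i, j in pair_list:
        if (i - 1, j + 1) in pair_set:
            helices[-1].append((i, j))  # continues the run started outward
        else:
            helices.append([(i, j)])
    n_pairs = len(pair_list)
    n_helix = len(helices)
    n_stack = n_pairs - n_helix

    n_interior = n_bulge = n_hairpin = n_multi = 0
    for i, j in pair_list:
        branches = _direct_branches(pt, i, j)
        if not branches:
            n_hairpin += 1
        elif len(branches) == 1:
            (k, p) = branches[0]
            gap5 = k - i - 1
            gap3 = j - p - 1
            if gap5 > 0 and gap3 > 0:
                n_interior += 1
            elif gap5 > 0 or gap3 > 0:
                n_bulge += 1
            # both gaps zero: stacked step, part of a helix
        else:
            n_multi += 1

    return StructuralElements(
        helices=tuple(tuple(h) for h in helices),
        n_helix=n_helix,
        n_stack=n_stack,
        n_interior=n_interior,
        n_bulge=n_bulge,
        n_hairpin=n_hairpin,
        n_multiloop=n_multi,
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# Folding adapter


class RNAfoldEngine:
    """Adapter around an RNAfold-compatible command-line MFE folder.

    Calls ``<executable> --noPS`` with the sequence on stdin and parses the
    dot-bracket + energy line.  Deterministic for a fixed engine version.
    """

    def __init__(self, executable: str = "RNAfold") -> None:
        path = shutil.which(executable)
        if path is None:
            raise FoldingError(
                f"folding executable {executable!r} not found on PATH; "
                "use precomputed structures instead"
            )
        self.executable = path

    def __call__(self, sequence: str) -> tuple[str, float]:
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=sequence + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
        # last line: "((((...)))) ( -4.20)" — energy may abut the bracket
        last = lines[-1]
        db = last.split(None, 1)[0]
        energy_txt = last[len(db):].strip().strip("()")
        mfe = float(energy_txt) if energy_txt else 0.0
        return db, mfe


def get_engine(spec: str | None):
    """Resolve an engine spec: None/'none' → no engine; 'rnafold' or an
    executable path → :class:`RNAfoldEngine`; a callable is passed through."""
    if spec is None or spec == "none":
        return None
    if callable(spec):
        return spec
    if spec == "rnafold":
        return RNAfoldEngine()
    return RNAfoldEngine(spec)


def fold(sequence: str, engine=None) -> tuple[str, float]:
    """Predict the MFE structure of ``sequence`` with the configured engine.

    Returns (dot-bracket, mfe kcal/mol).  Raises :class:`FoldingError` when
    no engine is configured — every pipeline path accepts precomputed
    structures precisely so that this is never required.
    """
    if engine is None:
        raise FoldingError(
            "no folding engine configured; provide precomputed structures "
            "or pass engine='rnafold'"
        )
    bad = set(sequence.upper()) - set("ACGU")
    if bad:
        raise ValueError(f"sequence contains non-ACGU characters: {sorted(bad)}")
    db, mfe = engine(sequence)
    if len(db) != len(sequence):
        raise FoldingError("engine returned structure of mismatched length")
    return db, mfe
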