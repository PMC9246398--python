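"""Domain types and the single-cell score/direction update.

Smith-Waterman local alignment scores a cell ``w = H(i, j)`` from its three
already-computed neighbours — diagonal ``x = H(i-1, j-1)``, vertical
``y = H(i-1, j)`` and horizontal ``v = H(i, j-1)`` — under a linear gap
penalty ``gamma``:

    w = max(0, x + P(s_i, q_j), y - gamma, v - gamma)

Alongside the score, every cell records *which* term won as a 2-bit
direction code (``D`` matrix), so that traceback never has to re-derive the
winning neighbour from ``H``:

    2 = diagonal (match/mismatch step)
    1 = vertical (gap rendered in the query q)
    3 = horizontal (gap rendered in the database s)
    0 = the zero floor won; traceback stops here

Tie rules, chosen once and applied everywhere: the diagonal wins any tie it
participates in; a vertical/horizontal tie resolves to horizontal (3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .errors import AlphabetError, ContractViolation, InputError

__all__ = [
    "Alphabet",
    "DNA",
    "PROTEIN",
    "Sequence",
    "ScoringScheme",
    "CellUpdate",
    "substitution_score",
    "cell_update",
    "DIRECTION_STOP",
    "DIRECTION_VERTICAL",
    "DIRECTION_DIAGONAL",
    "DIRECTION_HORIZONTAL",
    "DIRECTION_LEVELS",
    "DIRECTION_BITS",
    "pack_directions",
    "unpack_directions",
]

# Direction codes: a 4-level alphabet, hence exactly 2 bits per cell.
DIRECTION_STOP = 0
DIRECTION_VERTICAL = 1
DIRECTION_DIAGONAL = 2
DIRECTION_HORIZONTAL = 3
DIRECTION_LEVELS = (0, 1, 2, 3)
DIRECTION_BITS = 2


@dataclass(frozen=True)
class Alphabet:
    """A finite symbol set over which sequences are validated."""

    name: str
    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise InputError("alphabet must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise InputError(f"alphabet {self.name!r} has duplicate symbols")
        object.__setattr__(self, "_members", frozenset(self.symbols))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._members  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def custom(cls, symbols: str, name: str = "custom") -> "Alphabet":
        return cls(name, symbols)


DNA = Alphabet("DNA", "ACGT")
PROTEIN = Alphabet("PROTEIN", "ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Sequence:
    """A validated symbol string over a declared alphabet.

    Houses the query ``q`` (length N) and database ``s`` (length M)
    sequences; every symbol must belong to ``alphabet`` and the length must
    be at least 1.
    """

    symbols: str
    alphabet: Alphabet = DNA
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise InputError(
                f"sequence {self.name!r} is empty; length must be >= 1"
            )
        members = self.alphabet._members  # type: ignore[attr-defined]
        for pos, sym in enumerate(self.symbols):
            if sym not in members:
                raise AlphabetError(
                    f"symbol {sym!r} at position {pos} of sequence "
                    f"{self.name!r} is not in the {self.alphabet.name} alphabet"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, index):
        return self.symbols[index]

    def __iter__(self):
        return iter(self.symbols)


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters: match alpha, mismatch beta, linear gap gamma.

    Without an explicit substitution matrix, ``P(a, b)`` is ``match_score``
    when ``a == b`` and ``mismatch_score`` otherwise. ``gap_penalty`` is a
    non-negative magnitude that is *subtracted* for every gap symbol. A full
    substitution matrix (mapping ``(a, b) -> int``) may be supplied instead;
    it must cover the whole alphabet square and is not assumed symmetric.

    Defaults are the demonstration parameters match=5, mismatch=-5, gap=1.
    """

    match_score: int = 5
    mismatch_score: int = -5
    gap_penalty: int = 1
    alphabet: Alphabet = DNA
    substitution_matrix: Mapping[tuple[str, str], int] | None = None

    def __post_init__(self) -> None:
        if self.gap_penalty < 0:
            raise ContractViolation(
                f"gap_penalty must be non-negative, got {self.gap_penalty}"
            )
        if self.substitution_matrix is not None:
            for a in self.alphabet.symbols:
                for b in self.alphabet.symbols:
                    if (a, b) not in self.substitution_matrix:
                        raise ContractViolation(
                            "substitution matrix is missing an entry for "
                            f"pair ({a!r}, {b!r})"
                        )

    def score(self, a: str, b: str) -> int:
        return substitution_score(a, b, self)


def substitution_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Similarity score P(a, b) for one symbol pair under ``scheme``."""
    if a not in scheme.alphabet:
        raise AlphabetError(
            f"first symbol {a!r} is not in the {scheme.alphabet.name} alphabet"
        )
    if b not in scheme.alphabet:
        raise AlphabetError(
            f"second symbol {b!r} is not in the {scheme.alphabet.name} alphabet"
        )
    if scheme.substitution_matrix is not None:
        return scheme.substitution_matrix[(a, b)]
    return scheme.match_score if a == b else scheme.mismatch_score


class CellUpdate(NamedTuple):
    """Outcome of one DP cell: a non-negative score plus a direction code.

    ``direction == 0`` holds exactly when ``score == 0`` (the zero floor
    won); otherwise the code records the winning recurrence term.
    """

    score: int
    direction: int


def _update(x: int, y: int, v: int, sub: int, gamma: int) -> tuple[int, int]:
    # Hot path shared with the matrix fill loops: no validation here.
    cd = x + sub
    cy = y - gamma
    cv = v - gamma
    if cd >= cy and cd >= cv:
        if cd > 0:
            return cd, DIRECTION_DIAGONAL
        return 0, DIRECTION_STOP  # cd is the max and <= 0, so all are
    if cy > cv:
        if cy > 0:
            return cy, DIRECTION_VERTICAL
        return 0, DIRECTION_STOP
    if cv > 0:
        return cv, DIRECTION_HORIZONTAL
    return 0, DIRECTION_STOP


def cell_update(x: int, y: int, v: int, sub: int, gamma: int) -> CellUpdate:
    """Score and direction of one cell from its three neighbours.

    Parameters
    ----------
    x, y, v:
        Prior H values: diagonal H(i-1, j-1), vertical H(i-1, j) and
        horizontal H(i, j-1). All must be non-negative.
    sub:
        Substitution score P(s_i, q_j) for this cell (may be negative).
    gamma:
        Non-negative linear gap penalty, subtracted from y and v.

    Returns
    -------
    CellUpdate
        ``score = max(0, x + sub, y - gamma, v - gamma)`` and the direction
        code of the winning term (diagonal wins ties; a vertical/horizontal
        tie resolves to horizontal; 0 when the zero floor wins).
    """
    if x < 0 or y < 0 or v < 0:
        raise ContractViolation(
            f"prior cell values must be non-negative, got x={x}, y={y}, v={v}"
        )
    if gamma < 0:
        raise ContractViolation(f"gamma must be non-negative, got {gamma}")
    return CellUpdate(*_update(x, y, v, sub, gamma))


def pack_directions(directions) -> np.ndarray:
    """Pack direction codes into 2 bits per cell (four codes per byte).

    Accepts any array-like of codes in {0, 1, 2, 3}; the flattened codes are
    stored little-end-first within each byte. The packed array together with
    the original element count round-trips through :func:`unpack_directions`.
    """
    flat = np.ascontiguousarray(directions, dtype=np.uint8).ravel()
    if flat.size and flat.max() > 3:
        raise ContractViolation("direction codes must be in {0, 1, 2, 3}")
    pad = (-flat.size) % 4
    if pad:
        flat = np.concatenate([flat, np.zeros(pad, dtype=np.uint8)])
    quads = flat.reshape(-1, 4)
    packed = (
        quads[:, 0]
        | (quads[:, 1] << 2)
        | (quads[:, 2] << 4)
        | (quads[:, 3] << 6)
    )
    return packed.astype(np.uint8)


def unpack_directions(packed: np.ndarray, count: int) -> np.ndarray:
    """Inverse of :func:`pack_directions`; ``count`` is the cell count."""
    packed = np.asarray(packed, dtype=np.uint8)
    out = np.empty(packed.size * 4, dtype=np.uint8)
    for k in range(4):
        out[k::4] = (packed >> (2 * k)) & 0b11
    if count > out.size:
        raise ContractViolation(
            f"packed buffer holds at most {out.size} codes, {count} requested"
        )
    return out[:count]
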