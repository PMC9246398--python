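"""Sequential forward fill and direction-chain traceback.

The forward stage populates the (M+1) x (N+1) score matrix ``H`` and, in
the same pass, a direction matrix ``D`` whose 2-bit codes record the
winning recurrence term of every cell, while tracking the global maximum
score and its position. Rows are indexed by the database sequence ``s``
(1-based ``i``), columns by the query ``q`` (1-based ``j``); row 0 and
column 0 are the zero border. The fill runs column-major (``j`` outer,
``i`` inner), and the maximum is updated with a strict ``>``, so on ties
the *first* maximum in column-major order is the one reported.

Because ``D`` pre-organises the alignment, traceback is a pure chain walk:
start at the maximum-score cell, repeatedly read the stored code (2 move
diagonally, 1 move up, 3 move left) and stop on reading 0. No score
comparisons are repeated during traceback.

This module is the behavioural oracle the systolic simulator must match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DIRECTION_DIAGONAL,
    DIRECTION_HORIZONTAL,
    DIRECTION_VERTICAL,
    ScoringScheme,
    Sequence,
    _update,
    pack_directions,
    substitution_score,
)
from .errors import AlphabetError, ContractViolation

__all__ = [
    "ForwardResult",
    "Alignment",
    "forward_fill",
    "backtrack",
    "align",
    "cigar_from_codes",
    "alignment_score",
]

GAP = "-"

_CIGAR_OP = {DIRECTION_DIAGONAL: "M", DIRECTION_HORIZONTAL: "I", DIRECTION_VERTICAL: "D"}


@dataclass(eq=False)
class ForwardResult:
    """Filled score matrix H, direction matrix D and the maximum record.

    ``H`` and ``D`` are (M+1) x (N+1) with a zero border in row 0 and
    column 0. ``max_row``/``max_col`` are 1-based matrix coordinates of the
    first global maximum in column-major order; the all-zero matrix reports
    value 0 at (1, 1) by convention.
    """

    H: np.ndarray
    D: np.ndarray
    max_value: int
    max_row: int
    max_col: int

    @property
    def database_length(self) -> int:
        return self.H.shape[0] - 1

    @property
    def query_length(self) -> int:
        return self.H.shape[1] - 1

    @property
    def cell_count(self) -> int:
        """Number of interior (computed) cells: M x N."""
        return self.database_length * self.query_length

    def packed_directions(self) -> np.ndarray:
        """Interior of D packed at 2 bits per cell (four cells per byte)."""
        return pack_directions(self.D[1:, 1:])


@dataclass(frozen=True)
class Alignment:
    """A traced local alignment.

    ``pairs`` lists (q-symbol-or-dash, s-symbol-or-dash) in left-to-right
    alignment order; ``path_codes`` lists the direction codes in the order
    visited during traceback (reverse alignment order), excluding the
    terminal 0 sentinel. Coordinates are 1-based matrix positions: the
    alignment covers cells from (start_row, start_col) to
    (end_row, end_col) inclusive, the latter being the maximum-score cell.
    CIGAR follows SAM semantics with q as the query: 2 -> M, 3 -> I
    (q consumed, s gapped), 1 -> D (s consumed, q gapped).
    """

    path_codes: tuple[int, ...]
    pairs: tuple[tuple[str, str], ...]
    cigar: str
    score: int
    start_row: int
    start_col: int
    end_row: int
    end_col: int

    @property
    def raw_path(self) -> tuple[int, ...]:
        """Traceback code list including the terminal 0 sentinel."""
        return self.path_codes + (0,)

    @property
    def aligned_query(self) -> str:
        return "".join(a for a, _ in self.pairs)

    @property
    def aligned_database(self) -> str:
        return "".join(b for _, b in self.pairs)

    def match_line(self) -> str:
        """'|' for identities, '.' for substitutions, ' ' at gaps."""
        out = []
        for a, b in self.pairs:
            if GAP in (a, b):
                out.append(" ")
            elif a == b:
                out.append("|")
            else:
                out.append(".")
        return "".join(out)


def _check_alphabets(q: Sequence, s: Sequence, scheme: ScoringScheme) -> None:
    for seq, role in ((q, "query"), (s, "database")):
        missing = set(seq.symbols) - set(scheme.alphabet.symbols)
        if missing:
            raise AlphabetError(
                f"{role} sequence {seq.name!r} uses symbols "
                f"{sorted(missing)} outside the scoring scheme's "
                f"{scheme.alphabet.name} alphabet"
            )


def forward_fill(q: Sequence, s: Sequence, scheme: ScoringScheme) -> ForwardResult:
    """Fill H and D and track the maximum score and its position.

    Evaluation order is column-major (query position outer, database
    position inner); the maximum record keeps the first tie in that order.
    """
    _check_alphabets(q, s, scheme)
    N, M = len(q), len(s)
    gamma = scheme.gap_penalty
    sub_of = {
        (a, b): substitution_score(a, b, scheme)
        for a in set(s.symbols)
        for b in set(q.symbols)
    }
    H = [[0] * (N + 1) for _ in range(M + 1)]
    D = [[0] * (N + 1) for _ in range(M + 1)]
    max_value, max_row, max_col = 0, 1, 1
    s_syms = s.symbols
    update = _update
    for j in range(1, N + 1):
        qj = q.symbols[j - 1]
        for i in range(1, M + 1):
            score, direction = update(
                H[i - 1][j - 1],
                H[i - 1][j],
                H[i][j - 1],
                sub_of[(s_syms[i - 1], qj)],
                gamma,
            )
            H[i][j] = score
            D[i][j] = direction
            if score > max_value:
                max_value, max_row, max_col = score, i, j
    return ForwardResult(
        H=np.asarray(H, dtype=np.int64),
        D=np.asarray(D, dtype=np.uint8),
        max_value=max_value,
        max_row=max_row,
        max_col=max_col,
    )


def backtrack(fw: ForwardResult, q: Sequence, s: Sequence) -> Alignment:
    """Walk the stored direction chain from the maximum-score cell.

    Codes consume symbols as: 2 -> one from each sequence (diagonal);
    3 -> a q symbol against a dash in s (left); 1 -> an s symbol against a
    dash in q (up). The walk stops on reading code 0 (the border rows are
    all 0, so leaving the matrix interior also stops it).
    """
    M, N = fw.database_length, fw.query_length
    if not (1 <= fw.max_row <= M and 1 <= fw.max_col <= N):
        raise ContractViolation(
            f"maximum position ({fw.max_row}, {fw.max_col}) is outside the "
            f"{M}x{N} matrix interior"
        )
    if fw.H[fw.max_row, fw.max_col] != fw.max_value:
        raise ContractViolation(
            "recorded max_value does not match H at the recorded position"
        )
    D = fw.D
    i, j = fw.max_row, fw.max_col
    codes: list[int] = []
    pairs_rev: list[tuple[str, str]] = []
    start_row, start_col = fw.max_row, fw.max_col
    while True:
        code = int(D[i, j])
        if code == 0:
            break
        codes.append(code)
        start_row, start_col = i, j
        if code == DIRECTION_DIAGONAL:
            pairs_rev.append((q[j - 1], s[i - 1]))
            i -= 1
            j -= 1
        elif code == DIRECTION_HORIZONTAL:
            pairs_rev.append((q[j - 1], GAP))
            j -= 1
        elif code == DIRECTION_VERTICAL:
            pairs_rev.append((GAP, s[i - 1]))
            i -= 1
        else:  # pragma: no cover - D invariant guarantees codes in 0..3
            raise ContractViolation(f"invalid direction code {code} in D")
    return Alignment(
        path_codes=tuple(codes),
        pairs=tuple(reversed(pairs_rev)),
        cigar=cigar_from_codes(reversed(codes)),
        score=int(fw.max_value),
        start_row=start_row,
        start_col=start_col,
        end_row=fw.max_row,
        end_col=fw.max_col,
    )


def align(
    q: Sequence, s: Sequence, scheme: ScoringScheme
) -> tuple[ForwardResult, Alignment]:
    """Forward fill followed by traceback."""
    fw = forward_fill(q, s, scheme)
    return fw, backtrack(fw, q, s)


def cigar_from_codes(codes) -> str:
    """Run-length CIGAR over {M, I, D} from left-to-right direction codes."""
    out: list[str] = []
    run_op, run_len = "", 0
    for code in codes:
        op = _CIGAR_OP[code]
        if op == run_op:
            run_len += 1
        else:
            if run_len:
                out.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    if run_len:
        out.append(f"{run_len}{run_op}")
    return "".join(out)


def alignment_score(
    pairs, scheme: ScoringScheme
) -> int:
    """Recompute an alignment's score from its rendered gapped pairs.

    Substitution score per dash-free pair, minus gamma per dash. Equals the
    reported maximum score for any alignment produced by :func:`backtrack`.
    """
    total = 0
    for a, b in pairs:
        if a == GAP or b == GAP:
            total -= scheme.gap_penalty
        else:
            total += substitution_score(a, b, scheme)
    return total
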