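"""Cycle-stepped simulation of the systolic processing-element array.

One processing element (PE) per query symbol computes one column of the
score matrix. Data flows left-to-right along the chain in lock-step: at
wavefront step ``t`` (0-based), PE ``j`` computes cell
``(i = t - j + 1, j + 1)`` whenever ``0 <= t - j < M``. Each PE keeps two
registers — its own previous output (the vertical dependency ``y``) and a
one-step-delayed copy of the upstream PE's output (the diagonal dependency
``x``) — and reads the upstream PE's latest output directly (the horizontal
dependency ``v``). All register writes commit simultaneously at the end of
each step, as in hardware.

Every computed direction code is written once to the PE's private direction
memory (one RAM of M codes per PE, write mode during the forward phase).
The running (value, row, col) maximum is chained down the PE array with
strict-greater replacement, which reproduces the sequential column-major
first-tie rule. When the last cell finishes, the traceback flag is raised,
all memories switch to read mode and the backtracking chain walks the
stored codes: code 2 decrements memory address and PE, code 3 keeps the
address and decrements the PE, code 1 decrements the address within the
same PE; the walk stops on reading 0 or on leaving PE 0 / address 0.

The model is idealised — one cell per PE per cycle, so the forward phase
takes exactly M + N - 1 cycles — and the simulator asserts bit-for-bit
agreement with the sequential aligner through its reassembled outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aligner import (
    GAP,
    Alignment,
    ForwardResult,
    cigar_from_codes,
)
from .core import (
    DIRECTION_DIAGONAL,
    DIRECTION_HORIZONTAL,
    DIRECTION_VERTICAL,
    ScoringScheme,
    Sequence,
    _update,
    substitution_score,
)
from .errors import ConfigurationError, ConstraintError, ContractViolation

__all__ = [
    "MaxRecord",
    "PEState",
    "TraceEvent",
    "ForwardPhase",
    "SimResult",
    "simulate_forward",
    "simulate_backtrack",
    "simulate",
    "format_trace",
]


@dataclass(frozen=True)
class MaxRecord:
    """Running maximum: score value and its 1-based (row, col) position."""

    value: int
    row: int
    col: int


@dataclass(frozen=True)
class TraceEvent:
    """One PE activation: wavefront step, PE index, cell, score, direction."""

    step: int
    pe: int
    row: int
    col: int
    score: int
    direction: int


@dataclass
class PEState:
    """State of one processing element (one column of the matrix).

    ``prev_score_column_register`` is the last score this PE emitted (its
    vertical dependency); ``diag_register`` delays the upstream PE's output
    by one extra cycle to supply the diagonal dependency. The direction
    memory holds M codes, written exactly once each during the forward
    phase and readable only after the traceback flag is raised.
    """

    index: int
    held_q_symbol: str
    memory_size: int
    prev_score_column_register: int = 0
    diag_register: int = 0
    row_counter: int = 0
    local_max: MaxRecord = field(default=None)  # type: ignore[assignment]
    direction_memory: list = field(default_factory=list)
    score_column: list = field(default_factory=list)
    write_log: list = field(default_factory=list)
    read_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.local_max is None:
            self.local_max = MaxRecord(0, 1, self.index + 1)
        if not self.direction_memory:
            self.direction_memory = [None] * self.memory_size

    def write_direction(self, addr: int, code: int, step: int) -> None:
        if self.direction_memory[addr] is not None:
            raise ContractViolation(
                f"PE {self.index}: direction memory address {addr} "
                "written twice"
            )
        self.direction_memory[addr] = code
        self.write_log.append((step, addr))

    def read_direction(self, addr: int, traceback_raised: bool) -> int:
        if not traceback_raised:
            raise ContractViolation(
                f"PE {self.index}: direction memory read before the "
                "traceback flag was raised"
            )
        self.read_log.append(addr)
        code = self.direction_memory[addr]
        if code is None:
            raise ContractViolation(
                f"PE {self.index}: read of unwritten memory address {addr}"
            )
        return code


@dataclass
class ForwardPhase:
    """Output of the forward wavefront: PE array, chained max, cycle count."""

    pes: list
    max_record: MaxRecord
    cycles: int
    traceback_raised: bool
    query_length: int
    database_length: int
    trace: list | None = None

    def to_forward_result(self) -> ForwardResult:
        """Reassemble H and D from the PE score traces and memories."""
        M, N = self.database_length, self.query_length
        H = np.zeros((M + 1, N + 1), dtype=np.int64)
        D = np.zeros((M + 1, N + 1), dtype=np.uint8)
        for pe in self.pes:
            H[1:, pe.index + 1] = pe.score_column
            D[1:, pe.index + 1] = pe.direction_memory
        return ForwardResult(
            H=H,
            D=D,
            max_value=self.max_record.value,
            max_row=self.max_record.row,
            max_col=self.max_record.col,
        )


@dataclass
class SimResult:
    """Systolic simulation output: forward result, alignment, cycle counts."""

    forward: ForwardResult
    alignment: Alignment
    forward_cycles: int
    backtrack_cycles: int
    pe_count: int
    swapped: bool = False
    trace: list | None = None


def _validate_inputs(
    q: Sequence, s: Sequence, pe_count: int | None, enforce_length: bool
) -> int:
    N, M = len(q), len(s)
    if pe_count is None:
        pe_count = N
    if pe_count != N:
        raise ConfigurationError(
            f"pe_count must equal the query length (one PE per query "
            f"symbol): got {pe_count} PEs for |q| = {N}"
        )
    if enforce_length and M < N:
        raise ConstraintError(
            f"database length {M} is shorter than query length {N}; the "
            "array requires |s| >= |q| — swap the sequences or set the "
            "swap flag"
        )
    return pe_count


def simulate_forward(
    q: Sequence,
    s: Sequence,
    scheme: ScoringScheme,
    pe_count: int | None = None,
    record_trace: bool = False,
    enforce_length_constraint: bool = True,
) -> ForwardPhase:
    """Run the forward wavefront across the PE chain.

    Returns the array of final PE states plus the chained maximum record.
    The phase takes M + N - 1 cycles; every direction code is written to
    the owning PE's memory at address row - 1 during its activation step.
    The |s| >= |q| requirement mirrors the hardware loading convention and
    is enforced by default; the wavefront itself is well-defined for any
    M, N >= 1, and ``enforce_length_constraint=False`` lifts the check.
    """
    pe_count = _validate_inputs(q, s, pe_count, enforce_length_constraint)
    N, M = len(q), len(s)
    gamma = scheme.gap_penalty
    sub_of = {
        (a, b): substitution_score(a, b, scheme)
        for a in set(s.symbols)
        for b in set(q.symbols)
    }
    pes = [
        PEState(index=j, held_q_symbol=q[j], memory_size=M)
        for j in range(N)
    ]
    trace: list | None = [] if record_trace else None
    total_steps = M + N - 1
    for t in range(total_steps):
        j_lo = max(0, t - M + 1)
        j_hi = min(N - 1, t)
        # Read phase: snapshot upstream registers before any commit.
        staged = []
        for j in range(j_lo, j_hi + 1):
            pe = pes[j]
            upstream_prev = pes[j - 1].prev_score_column_register if j else 0
            x = pe.diag_register
            y = pe.prev_score_column_register
            v = upstream_prev
            i = t - j  # 0-based database index; matrix row is i + 1
            sub = sub_of[(s[i], pe.held_q_symbol)]
            score, direction = _update(x, y, v, sub, gamma)
            staged.append((pe, i, upstream_prev, score, direction))
        # Commit phase: all registers and memories update in lock-step.
        for pe, i, upstream_prev, score, direction in staged:
            row, col = i + 1, pe.index + 1
            pe.diag_register = upstream_prev
            pe.prev_score_column_register = score
            pe.score_column.append(score)
            pe.write_direction(i, direction, t)
            pe.row_counter += 1
            if score > pe.local_max.value:
                pe.local_max = MaxRecord(score, row, col)
            if trace is not None:
                trace.append(TraceEvent(t, pe.index, row, col, score, direction))
    # Chain the per-PE maxima down the array: strict-greater replacement,
    # so the earliest column (and, per PE, the earliest row) wins ties —
    # the same cell the sequential column-major scan reports.
    chained = pes[0].local_max
    for pe in pes[1:]:
        if pe.local_max.value > chained.value:
            chained = pe.local_max
    return ForwardPhase(
        pes=pes,
        max_record=chained,
        cycles=total_steps,
        traceback_raised=True,
        query_length=N,
        database_length=M,
        trace=trace,
    )


def simulate_backtrack(
    phase: ForwardPhase, q: Sequence, s: Sequence
) -> tuple[Alignment, int]:
    """Walk the backtracking chain over the PE direction memories.

    The start address first propagates from PE N-1 down to the PE holding
    the maximum-score column (one cycle per hop, skipped when the matrix is
    all zero); each memory read then costs one cycle, including a
    terminating read of a 0 code. A walk that exits by crossing PE 0 /
    address 0 stops without a further read (the border needs no fetch).
    """
    if not phase.traceback_raised:
        raise ContractViolation("backtracking started before the traceback flag")
    rec = phase.max_record
    M, N = phase.database_length, phase.query_length
    if not (1 <= rec.row <= M and 1 <= rec.col <= N):
        raise ContractViolation(
            f"maximum record ({rec.row}, {rec.col}) is outside the matrix"
        )
    pe_idx = rec.col - 1
    addr = rec.row - 1
    cycles = (N - 1) - pe_idx if rec.value > 0 else 0  # PE-location hops
    codes: list[int] = []
    pairs_rev: list[tuple[str, str]] = []
    start_row, start_col = rec.row, rec.col
    while True:
        cycles += 1  # one memory read
        code = phase.pes[pe_idx].read_direction(addr, phase.traceback_raised)
        if code == 0:
            break
        codes.append(code)
        start_row, start_col = addr + 1, pe_idx + 1
        if code == DIRECTION_DIAGONAL:
            pairs_rev.append((q[pe_idx], s[addr]))
            addr -= 1
            pe_idx -= 1
        elif code == DIRECTION_HORIZONTAL:
            pairs_rev.append((q[pe_idx], GAP))
            pe_idx -= 1
        elif code == DIRECTION_VERTICAL:
            pairs_rev.append((GAP, s[addr]))
            addr -= 1
        else:  # pragma: no cover - memory invariant keeps codes in 0..3
            raise ContractViolation(f"invalid direction code {code}")
        if pe_idx < 0 or addr < 0:
            break  # left PE 0 / address 0: the border terminates the walk
    alignment = Alignment(
        path_codes=tuple(codes),
        pairs=tuple(reversed(pairs_rev)),
        cigar=cigar_from_codes(reversed(codes)),
        score=int(rec.value),
        start_row=start_row,
        start_col=start_col,
        end_row=rec.row,
        end_col=rec.col,
    )
    return alignment, cycles


def simulate(
    q: Sequence,
    s: Sequence,
    scheme: ScoringScheme,
    pe_count: int | None = None,
    allow_swap: bool = False,
    record_trace: bool = False,
    enforce_length_constraint: bool = True,
) -> SimResult:
    """Full systolic run: forward wavefront then backtracking chain.

    Requires |s| >= |q|; with ``allow_swap=True`` a shorter database is
    handled by swapping the roles of the two sequences (the result's
    ``swapped`` flag records this).
    """
    swapped = False
    if len(s) < len(q) and allow_swap:
        q, s = s, q
        swapped = True
        if pe_count is not None:
            pe_count = len(q)
    phase = simulate_forward(
        q, s, scheme, pe_count, record_trace=record_trace,
        enforce_length_constraint=enforce_length_constraint,
    )
    alignment, bt_cycles = simulate_backtrack(phase, q, s)
    return SimResult(
        forward=phase.to_forward_result(),
        alignment=alignment,
        forward_cycles=phase.cycles,
        backtrack_cycles=bt_cycles,
        pe_count=len(q),
        swapped=swapped,
        trace=phase.trace,
    )


def format_trace(events) -> str:
    """Render trace events as tab-separated text (one line per activation)."""
    lines = ["step\tpe\trow\tcol\tscore\tdirection"]
    for ev in events:
        lines.append(
            f"{ev.step}\t{ev.pe}\t{ev.row}\t{ev.col}\t{ev.score}\t{ev.direction}"
        )
    return "\n".join(lines) + "\n"
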