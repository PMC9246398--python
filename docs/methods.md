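# Methods

## Model

The package computes Smith-Waterman local alignment under a *linear* gap
model: every gap symbol costs the same non-negative magnitude γ,
subtracted from the running score. This is the special case of the affine
model in which gap opening and extension cost the same; the general
affine recursion (separate E/F matrices with distinct opening/extension
penalties) is deliberately out of scope. Scores are integers throughout —
there is no floating-point anywhere in the scoring path.

Each interior cell `(i, j)` (row `i` indexes the database sequence `s`,
column `j` the query `q`; both 1-based, with a zero border at row 0 and
column 0) is computed from its three neighbours `x = H(i-1, j-1)`,
`y = H(i-1, j)`, `v = H(i, j-1)`:

```
cd = x + P(s_i, q_j)      # diagonal candidate
cy = y - γ                # vertical candidate (gap in q)
cv = v - γ                # horizontal candidate (gap in s)
H(i,j) = max(0, cd, cy, cv)
```

and the winning term is recorded in a direction matrix `D` as a 2-bit
code: 2 diagonal, 1 vertical, 3 horizontal, 0 when the zero floor wins.
`D(i,j) = 0` holds exactly when `H(i,j) = 0`, which is what lets the
traceback loop terminate by reading a single code.

### Tie rules

Ties are a genuine design choice; the ones adopted, applied identically
in the sequential aligner and the simulator, are:

* the diagonal wins any tie it participates in (`cd ≥ cy` and `cd ≥ cv`
  suffice for code 2, provided `cd > 0`);
* a vertical/horizontal tie (`cy == cv > cd`) resolves to horizontal
  (code 3);
* the reported maximum is the *first* maximum in column-major order
  (query position outer, database position inner) — the maximum tracker
  uses a strict `>`;
* an all-zero matrix reports value 0 at position (1, 1) by convention and
  yields an empty alignment.

A consequence worth knowing: tie resolution is orientation-dependent.
Swapping the roles of q and s always preserves the maximum *score*
(tested), but when a traceback path crosses a vertical/horizontal tie
cell, the two orientations can trace different co-optimal paths, so
CIGARs are not guaranteed to be exact I↔D mirror images in the presence
of such ties. The suite checks the mirror property on a tie-free case
only.

### Traceback

Traceback starts at the recorded maximum cell and repeatedly reads `D`:
code 2 consumes one symbol from each sequence and moves diagonally, code
3 consumes a query symbol against a dash in the database and moves left,
code 1 consumes a database symbol against a dash in the query and moves
up; reading 0 stops. Pairs are reported left-to-right; `path_codes` keeps
the codes in traceback (reverse) order, and `raw_path` appends the
terminal 0 sentinel. CIGAR uses SAM semantics with q as the query:
2 → M, 3 → I, 1 → D; match and mismatch are both M.

## The systolic model

The simulator models an array of N processing elements, one per query
symbol, each computing one matrix column. At wavefront step `t` (0-based)
PE `j` computes cell `(t - j + 1, j + 1)` when `0 ≤ t - j < M`. Each PE
holds two registers: its own previous output (the vertical dependency)
and a one-cycle-delayed copy of the upstream PE's output (the diagonal
dependency); the horizontal dependency is the upstream PE's latest
output. All register updates commit simultaneously at the end of each
step, so the simulation is a faithful synchronous-hardware abstraction.
Direction codes are written once each into a per-PE memory of M two-bit
entries; memories switch from write to read mode only when the last cell
finishes (the traceback flag), and both disciplines are asserted at run
time — a double write or an early read raises, and the test suite
verifies the scheduling from the event trace.

The per-PE running maximum uses a strict `>` over ascending rows, and the
per-PE records are then chained down the array with strict-greater
replacement, so an earlier column survives a tie. This reproduces exactly
the sequential column-major first-tie rule; the identity suite asserts
bit-for-bit equality of H, D, the maximum record and the alignment over
hundreds of random inputs.

### Cycle accounting

The model is idealised: one cell per PE per cycle, no register-stage or
routing latency, so the forward phase always takes `M + N - 1` cycles.
This is the idealisation the peak-throughput formula
(`PEs × clock × 1e-9` GCUPS) presumes. Backtracking is charged one cycle
per hop while the start address propagates from PE N−1 down to the
maximum-score PE (skipped for an all-zero matrix — there is nothing to
locate, leaving the single terminating read), plus one cycle per memory
read, including a terminating 0-read; a walk that exits by crossing
PE 0 / address 0 stops without a border fetch. The hop-count convention
is ours; the real pipeline latencies of any concrete hardware are not
modelled.

The `|s| ≥ |q|` requirement mirrors the hardware loading convention (the
PE count is pinned to the query length, and each PE's memory is sized by
the database length). The wavefront itself is well-defined for any
M, N ≥ 1, so the check can be lifted explicitly
(`enforce_length_constraint=False`); the CLI instead auto-assigns the
shorter sequence as the query with a logged notice, while the library
raises unless `allow_swap=True` — silent swapping in the library would
hide caller intent.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `match_score` (α) | reward for `a == b` | 5 | integer |
| `mismatch_score` (β) | penalty for `a != b` | −5 | integer, usually ≤ 0 |
| `gap_penalty` (γ) | per-gap-symbol cost | 1 | non-negative magnitude, subtracted |
| `substitution_matrix` | full `P(a,b)` table | none | overrides α/β; no symmetry assumed |
| `pe_count` | PEs in the array | `len(q)` | must equal the query length |
| `clock_hz` | nominal frequency | none | only for GCUPS reporting |

The defaults are the demonstration operating point (match 5, mismatch −5,
gap 1, 128 PEs against an 8192-symbol database), at which the matrix has
1,048,576 interior cells and the wavefront takes 8319 cycles.

## Synthetic data

`generate_sequences(n, m, alphabet, seed)` draws uniform i.i.d. symbols
over the chosen alphabet (DNA by default; a 20-letter protein alphabet
and custom alphabets are supported) from a single seeded NumPy generator.
This emulates randomly generated validation inputs: it exercises every
code path (matches, mismatches, both gap orientations, zero regions,
ties) but has no homology structure, composition bias or repeats, so
passing tests demonstrate algorithmic correctness, not biological
retrieval performance on real databases. Real-sequence behaviour enters
only through the scoring scheme the caller supplies.

## Verification strategy

Three independent routes check the engine:

1. a textbook rolling-row Smith-Waterman DP (scores only, written
   directly against the recurrence) on random inputs;
2. exhaustive enumeration of all gapped alignments of all substring pairs
   for tiny sequences (lengths ≤ 6);
3. Biopython's `PairwiseAligner` in local mode as an external
   cross-check.

The single-cell rule is additionally swept exhaustively over a small
integer grid against a four-term argmax re-derivation, and the systolic
simulator is held to bit-for-bit identity with the sequential aligner.
Score-path consistency — recomputing the score from the rendered gapped
pairs (substitution per pair, −γ per dash) — closes the loop between the
forward maximum and the traceback output.

## Numerical and degenerate-input choices

* Integer arithmetic only; H is stored as int64, D as uint8 (packed
  storage at 2 bits per cell via `pack_directions`).
* γ = 0 is legal (gaps free); β ≥ 0 is legal (the scheme does not force
  penalties), and the oracles cover both.
* Sequences of length 1 are valid; empty sequences are rejected at
  construction.
* A full substitution matrix must cover the whole alphabet square and may
  be asymmetric; nothing assumes `P(a,b) = P(b,a)`.
* Ambiguity codes (e.g. `N` under DNA) are rejected strictly rather than
  scored.

## Known limitations

Affine gaps, multi-pass operation for queries longer than the PE array,
co-optimal alignment enumeration, banded/vectorised acceleration,
bit-width and clock-domain modelling, and FPGA resource estimation are
all out of scope. GCUPS figures computed from the host's wall clock
describe this Python implementation, not any hardware.
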