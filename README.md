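# swsystolic

Smith-Waterman local alignment with a separately stored 2-bit direction
matrix and a cycle-stepped simulator of a systolic processing-element
array.

## The problem and who this is for

Local alignment finds the highest-scoring pairing of substrings of two
biological sequences — a query `q` of length `N` and a database sequence
`s` of length `M` — allowing gaps, with scores floored at zero. The
Smith-Waterman recurrence under a linear gap penalty `γ` fills a score
matrix `H` (zero border in row 0 / column 0):

```
H(i,j) = max{ 0,
              H(i-1,j-1) + P(s_i, q_j),
              H(i-1,j) - γ,
              H(i,j-1) - γ }
```

where `P(a,b)` is `α` (match) when `a = b` and `β` (mismatch) otherwise,
or a full substitution matrix. The twist this package implements: the
forward fill also stores, per cell, *which* recurrence term won, as a
2-bit code in a direction matrix `D` (2 = diagonal, 1 = vertical gap in
`q`, 3 = horizontal gap in `s`, 0 = the zero floor — stop). Traceback then
never re-derives the winner: starting from the maximum-score cell it just
walks the stored chain until it reads a 0. This mirrors hardware designs
in which one processing element (PE) per query symbol computes one matrix
column, data flows between neighbours along anti-diagonal wavefronts, and
each PE keeps its column of `D` in a private RAM of `M` two-bit entries.

The package is for people studying or prototyping such accelerator
designs — it provides a trusted sequential reference, a cycle-stepped
simulation of the PE array that is tested to match the reference
bit-for-bit, and GCUPS (giga cell updates per second) accounting
(`cells / seconds / 1e9` for achieved throughput; `PEs × clock × 1e-9`
for the array's peak).

## Worked example

```python
from swsystolic import ScoringScheme, Sequence, align, simulate

scheme = ScoringScheme(match_score=5, mismatch_score=-5, gap_penalty=1)
fw, aln = align(Sequence("ACT"), Sequence("AT"), scheme)
print(aln.score, aln.cigar, aln.aligned_query, aln.aligned_database)
# 9 1M1I1M ACT A-T

res = simulate(Sequence("ACGT"), Sequence("ACGTACGT"), scheme)
print(res.forward_cycles, res.backtrack_cycles, res.alignment.score)
# 11 4 20
```

The `C` of the query aligns against a dash in the database (one horizontal
step, CIGAR `I`), giving 5 + 5 − 1 = 9. The systolic run confirms the
wavefront cycle law: a 4-PE array sweeps an 8×4 matrix in
M + N − 1 = 11 cycles.

The same is available from the shell (all coordinates are 1-based matrix
positions: `Row` indexes the database `s`, `Column` the query `q`):

```
$ swsystolic align -q AC -s AC
Query:    AC
          ||
Database: AC
Row: 1
Column: 1
Maximum Value: 10
CIGAR: 2M
```

Subcommands: `align` (sequential), `simulate` (systolic run with cycle
counts, optional `--clock-mhz` for GCUPS and `--trace` for a per-cycle
TSV event log with columns `step pe row col score direction`),
`generate` (random FASTA pairs), `selftest` (simulator-vs-reference
cross-check). JSON and TSV output via `--format`.

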