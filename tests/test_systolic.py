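"""Systolic-array simulator: identity with the sequential aligner,
wavefront scheduling, memory discipline and cycle accounting."""

import numpy as np
import pytest

from swsystolic import (
    ConfigurationError,
    ConstraintError,
    ContractViolation,
    Sequence,
    align,
    simulate,
    simulate_backtrack,
    simulate_forward,
)
from swsystolic.systolic import format_trace

from conftest import random_pair, random_scheme


def assert_same_forward(fw, sim_fw):
    assert np.array_equal(fw.H, sim_fw.H)
    assert np.array_equal(fw.D, sim_fw.D)
    assert (fw.max_value, fw.max_row, fw.max_col) == (
        sim_fw.max_value, sim_fw.max_row, sim_fw.max_col,
    )


class TestSequentialIdentity:
    @pytest.mark.parametrize("seed", range(4))
    def test_forward_and_alignment_bit_identical(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            q, s = random_pair(rng, database_at_least_query=True)
            scheme = random_scheme(rng)
            fw, aln = align(q, s, scheme)
            res = simulate(q, s, scheme)
            assert_same_forward(fw, res.forward)
            assert res.alignment == aln
            assert res.forward_cycles == len(s) + len(q) - 1

    def test_cycle_law_spans_shapes(self):
        for n, m in [(1, 1), (1, 9), (4, 6), (8, 8), (3, 17)]:
            rng = np.random.default_rng(n * 100 + m)
            q = Sequence("".join(rng.choice(list("ACGT"), n)))
            s = Sequence("".join(rng.choice(list("ACGT"), m)))
            res = simulate(q, s, random_scheme(rng))
            assert res.forward_cycles == m + n - 1


class TestExamples:
    def test_ac_ac_memories_and_max(self, demo_scheme):
        phase = simulate_forward(Sequence("AC"), Sequence("AC"), demo_scheme)
        assert phase.pes[0].direction_memory == [2, 1]
        assert phase.pes[1].direction_memory == [3, 2]
        assert (phase.max_record.value, phase.max_record.row,
                phase.max_record.col) == (10, 2, 2)
        assert phase.cycles == 3

    def test_single_matching_cell(self, demo_scheme):
        phase = simulate_forward(Sequence("A"), Sequence("A"), demo_scheme)
        assert len(phase.pes) == 1
        assert phase.pes[0].direction_memory == [2]
        assert (phase.max_record.value, phase.max_record.row,
                phase.max_record.col) == (5, 1, 1)
        assert phase.cycles == 1

    def test_act_at_walk(self, demo_scheme):
        # |q| > |s| here; the wavefront itself is well-defined, so the
        # length constraint is lifted explicitly for this worked case.
        q, s = Sequence("ACT"), Sequence("AT")
        res = simulate(q, s, demo_scheme, enforce_length_constraint=False)
        assert res.alignment.cigar == "1M1I1M"
        assert res.alignment.score == 9
        assert res.alignment.path_codes == (2, 3, 2)
        _, aln = align(q, s, demo_scheme)
        assert res.alignment == aln

    def test_all_zero_matrix_single_terminating_read(self, demo_scheme):
        res = simulate(Sequence("A"), Sequence("TT"), demo_scheme)
        assert res.alignment.pairs == ()
        assert res.alignment.score == 0
        assert res.backtrack_cycles == 1


class TestCycleAccounting:
    def test_backtrack_cycles_hops_plus_reads(self, demo_scheme):
        # AC vs AC: max at PE 1 (= N-1), so 0 hops; two reads (codes 2, 2),
        # after which the walk crosses PE 0 and stops without a border fetch
        res = simulate(Sequence("AC"), Sequence("AC"), demo_scheme)
        assert res.backtrack_cycles == 2

    def test_location_hops_charged_when_max_not_in_last_pe(self, demo_scheme):
        # q = AATT vs s = AAGG: best alignment 'AA' ends in column 2, so the
        # start address hops from PE 3 down to PE 1 (2 cycles), then reads
        # codes 2, 2 before crossing PE 0 (2 cycles).
        res = simulate(Sequence("AATT"), Sequence("AAGG"), demo_scheme)
        assert res.alignment.cigar == "2M"
        assert res.forward.max_col == 2
        assert res.backtrack_cycles == 2 + 2


class TestWavefrontDiscipline:
    def test_no_cell_reads_an_unproduced_value(self, demo_scheme):
        rng = np.random.default_rng(21)
        q, s = random_pair(rng, min_len=4, max_len=12,
                           database_at_least_query=True)
        phase = simulate_forward(q, s, demo_scheme, record_trace=True)
        produced_at = {(ev.row, ev.col): ev.step for ev in phase.trace}
        for ev in phase.trace:
            for dep in [(ev.row - 1, ev.col - 1), (ev.row - 1, ev.col),
                        (ev.row, ev.col - 1)]:
                if dep in produced_at:  # border cells are constants
                    assert produced_at[dep] < ev.step

    def test_every_cell_computed_once(self, demo_scheme):
        rng = np.random.default_rng(22)
        q, s = random_pair(rng, database_at_least_query=True)
        phase = simulate_forward(q, s, demo_scheme, record_trace=True)
        cells = [(ev.row, ev.col) for ev in phase.trace]
        assert len(cells) == len(set(cells)) == len(q) * len(s)

    def test_memory_written_once_and_read_after_traceback(self, demo_scheme):
        q, s = Sequence("ACGT"), Sequence("ACGTT")
        phase = simulate_forward(q, s, demo_scheme)
        for pe in phase.pes:
            addrs = [a for _, a in pe.write_log]
            assert sorted(addrs) == list(range(len(s)))
            assert len(set(addrs)) == len(addrs)
            assert pe.read_log == []  # nothing read during forward
        simulate_backtrack(phase, q, s)
        reads = sum(len(pe.read_log) for pe in phase.pes)
        assert reads >= 1

    def test_read_before_traceback_flag_rejected(self, demo_scheme):
        phase = simulate_forward(Sequence("AC"), Sequence("AC"), demo_scheme)
        with pytest.raises(ContractViolation):
            phase.pes[0].read_direction(0, traceback_raised=False)


class TestValidation:
    def test_pe_count_must_match_query_length(self, demo_scheme):
        with pytest.raises(ConfigurationError):
            simulate(Sequence("ACGT"), Sequence("ACGTACGT"), demo_scheme,
                     pe_count=8)

    def test_short_database_rejected_without_swap(self, demo_scheme):
        with pytest.raises(ConstraintError, match="swap"):
            simulate(Sequence("ACGT"), Sequence("AC"), demo_scheme)

    def test_swap_flag_exchanges_roles(self, demo_scheme):
        res = simulate(Sequence("ACGT"), Sequence("AC"), demo_scheme,
                       allow_swap=True)
        assert res.swapped
        assert res.pe_count == 2
        ref_fw, ref_aln = align(Sequence("AC"), Sequence("ACGT"), demo_scheme)
        assert res.alignment == ref_aln

    def test_backtrack_requires_traceback_flag(self, demo_scheme):
        phase = simulate_forward(Sequence("AC"), Sequence("AC"), demo_scheme)
        phase.traceback_raised = False
        with pytest.raises(ContractViolation):
            simulate_backtrack(phase, Sequence("AC"), Sequence("AC"))


def test_trace_format_is_tab_separated(demo_scheme):
    res = simulate(Sequence("AC"), Sequence("ACG"), demo_scheme,
                   record_trace=True)
    text = format_trace(res.trace)
    lines = text.strip().split("\n")
    assert lines[0] == "step\tpe\trow\tcol\tscore\tdirection"
    assert len(lines) == 1 + 2 * 3  # header + one line per computed cell
    assert all(len(line.split("\t")) == 6 for line in lines)
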