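"""Junction-shift optimization: variant order, metric, guarantees."""

import numpy as np
import pytest

from dnapartition.constraint_scan import max_direct_repeat
from dnapartition.fixtures import Implant, implant_motif, random_sequence
from dnapartition.model import DesignRecord, JunctionState
from dnapartition.params import PartitionParams
from dnapartition.partition import build_design, virtually_assemble
from dnapartition.thr_optimize import (
    JunctionPool,
    displacement_stats,
    junction_variants,
    optimize_design,
)

from _oracles import oracle_cross_shared, oracle_direct_repeat, oracle_hairpin


def _state(original=1000, visited=()):
    from dnapartition.model import AssemblyUnit

    left = AssemblyUnit("block", (0, 0), 0, original)
    right = AssemblyUnit("block", (0, 1), original, 2 * original, thr_left=80)
    st = JunctionState(
        junction_id="j",
        tier="block",
        pool_id="seg0",
        left=left,
        right=right,
        overlap=80,
        original=original,
        position=original,
    )
    st.visited.update(visited)
    return st


class TestJunctionVariants:
    def test_enumeration_order_smallest_shift_first(self):
        offsets = [p - 1000 for p in junction_variants(_state(), max_shift=3)]
        assert offsets == [1, -1, 2, -2, 3, -3]

    def test_visited_positions_excluded(self):
        offsets = [p - 1000 for p in junction_variants(_state(visited={1001}), 3)]
        assert offsets == [-1, 2, -2, 3, -3]

    def test_clipping_caps_positive_offsets(self):
        positions = junction_variants(_state(), 5, bounds=(995, 1002))
        assert max(positions) == 1002
        assert min(positions) == 995

    def test_exhausted_state_yields_empty(self):
        st = _state(visited={999, 1001, 998, 1002})
        assert junction_variants(st, 2) == []


class TestEvaluateAndOptimize:
    def _pooled_design(self, seq):
        record = DesignRecord("opt", seq).validate()
        return build_design(record, PartitionParams())

    def test_constraint_free_junction_is_global_optimum(self):
        seq = random_sequence(20000, 0.5, 21)
        design = self._pooled_design(seq)
        seg = design.segments[0]
        pool = JunctionPool(seq, seg.children, "block", design.params, seg.key)
        for idx in range(len(pool.states)):
            score = pool.score(idx)
            assert score == (0, score[1], 0)
            assert score[1] <= 8

    def test_implanted_repeat_scores_its_length(self, rng):
        seq = random_sequence(20000, 0.5, 22)
        design = self._pooled_design(seq)
        pos = design.junctions["block"][1].position
        seq = implant_motif(seq, Implant("direct_repeat", 15, (pos - 70, pos - 40)), rng)
        design = self._pooled_design(seq)
        seg = design.segments[0]
        pool = JunctionPool(seq, seg.children, "block", design.params, seg.key)
        violations, max_feature, disp = pool.score(1)
        assert violations >= 1
        assert max_feature >= 15
        assert disp == 0

    def test_repeat_straddling_junction_is_removed(self, rng):
        """A 15-mer repeated inside one block THR forces a nonzero shift and
        the optimized pool is verified clean by the independent oracles."""
        seq = random_sequence(20000, 0.5, 23)
        design = self._pooled_design(seq)
        target = design.junctions["block"][2]
        pos = target.position
        seq = implant_motif(seq, Implant("direct_repeat", 15, (pos - 70, pos - 40)), rng)
        record = DesignRecord("opt", seq).validate()
        optimized = optimize_design(build_design(record, PartitionParams()))
        moved = optimized.junctions["block"][2]
        assert moved.displacement != 0
        for st in optimized.junctions["block"]:
            thr = st.thr_sequence(seq)
            assert oracle_direct_repeat(thr) <= 8
            assert oracle_hairpin(thr, 3) <= 8
            assert st.resolved

    def test_clean_design_keeps_zero_displacement(self):
        record = DesignRecord("clean", random_sequence(20000, 0.5, 1)).validate()
        optimized = optimize_design(build_design(record))
        assert all(st.displacement == 0 for st in optimized.all_junctions())

    def test_tandem_array_reported_unresolved(self):
        """A perfect 10-mer tandem array spanning every feasible shift cannot
        be fixed; the junction keeps its last position and is flagged."""
        unitseq = random_sequence(10, 0.5, 24)
        flank_l = random_sequence(9000, 0.5, 25)
        flank_r = random_sequence(9800, 0.5, 26)
        seq = (flank_l + unitseq * 120 + flank_r)[:20000]
        record = DesignRecord("tandem", seq).validate()
        optimized = optimize_design(build_design(record, PartitionParams()))
        unresolved = [st for st in optimized.all_junctions() if not st.resolved]
        assert unresolved
        for st in unresolved:
            assert st.report is not None and not st.report.passes

    def test_optimization_preserves_assembly_identity(self, rng):
        seq = random_sequence(30000, 0.6, 27)
        design = build_design(DesignRecord("vi", seq).validate())
        pos = design.junctions["block"][1].position
        seq = implant_motif(seq, Implant("direct_repeat", 15, (pos - 70, pos - 40)), rng)
        record = DesignRecord("vi", seq).validate()
        optimized = optimize_design(build_design(record))
        assert virtually_assemble(optimized) == seq

    def test_restart_safety(self, rng):
        seq = random_sequence(20000, 0.5, 28)
        design = build_design(DesignRecord("rs", seq).validate())
        pos = design.junctions["block"][0].position
        seq = implant_motif(seq, Implant("direct_repeat", 12, (pos - 65, pos - 30)), rng)
        record = DesignRecord("rs", seq).validate()
        once = optimize_design(build_design(record))
        twice = optimize_design(once)
        assert [(st.junction_id, st.position) for st in once.all_junctions()] == [
            (st.junction_id, st.position) for st in twice.all_junctions()
        ]

    def test_no_position_evaluated_twice_as_move_target(self, rng):
        seq = random_sequence(20000, 0.5, 29)
        design = build_design(DesignRecord("nr", seq).validate())
        pos = design.junctions["block"][1].position
        seq = implant_motif(seq, Implant("direct_repeat", 15, (pos - 70, pos - 40)), rng)
        record = DesignRecord("nr", seq).validate()
        optimized = optimize_design(build_design(record))
        for st in optimized.all_junctions():
            assert st.position in st.visited
            assert len(st.visited) == len(set(st.visited))

    def test_resolved_junctions_pass_all_thresholds(self, rng):
        seq = random_sequence(40000, 0.7, 30)
        optimized = optimize_design(build_design(DesignRecord("hi", seq).validate()))
        for st in optimized.all_junctions():
            if st.resolved:
                thr = st.thr_sequence(seq)
                assert oracle_direct_repeat(thr) <= 8
                assert oracle_hairpin(thr, 3) <= 8

    def test_size_caps_hold_after_optimization(self, rng):
        seq = random_sequence(40000, 0.7, 31)
        optimized = optimize_design(build_design(DesignRecord("caps", seq).validate()))
        for unit in optimized.iter_all_units():
            cap = optimized.params.cap(unit.tier)
            assert unit.full_length(seq) <= cap
            assert unit.core_len >= 1


class TestDisplacementStats:
    def test_all_zero(self):
        record = DesignRecord("z", random_sequence(20000, 0.5, 1)).validate()
        stats = displacement_stats(optimize_design(build_design(record)))
        assert stats["block"]["mean"] == 0.0
        assert stats["block"]["sd"] == 0.0

    def test_arithmetic(self):
        record = DesignRecord("a", random_sequence(20000, 0.5, 1)).validate()
        design = build_design(record)
        design.junctions["block"][0].position += 3
        design.junctions["block"][1].position -= 5
        stats = displacement_stats(design)
        assert stats["block"]["count"] == 4
        assert stats["block"]["mean"] == pytest.approx((3 + 5) / 4)
        assert stats["block"]["max"] == 5

    def test_empty_tier_reports_zero_count(self):
        record = DesignRecord("t", random_sequence(800, 0.5, 2)).validate()
        stats = displacement_stats(build_design(record))
        assert stats["segment"] == {"count": 0, "mean": 0.0, "sd": 0.0, "max": 0.0}
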