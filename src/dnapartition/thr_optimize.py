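"""Junction-shift optimization of terminal homology regions.

Within each co-assembly pool (the segments of the design, the blocks of
one segment, the subblocks of one block) every junction THR is screened
for direct repeats, hairpin stems and substrings shared with sibling
THRs.  A violating junction is moved: candidate positions are enumerated
outwards from the original equidistant position (+1, -1, +2, -2, ...),
clipped so both flanking units stay within their size caps, and scored by
the tuple

    (number of violated constraint classes, longest feature in bp,
     |displacement|)

compared lexicographically -- a variant free of repeats and unique in
sequence that requires the least repositioning wins.  One optimization
cycle re-evaluates the pool worst-junction-first and moves each violating
junction once; the search path is non-recurring (a position is never
evaluated as a move target twice) and stops when the pool is clean or
after ``max_opt_cycles`` (built-in 20) cycles.  Junctions still violating
at that point keep their last position and are flagged unresolved.

Sibling THRs are compared at their *current* positions: the pool
co-evolves during optimization.
"""

from __future__ import annotations

import statistics
from typing import Callable

from . import partition
from .constraint_scan import (
    ConstraintThresholds,
    ThrReport,
    count_occurrences,
    max_cross_shared_substring,
    max_direct_repeat,
    max_hairpin_stem,
    reverse_complement,
)
from .model import AssemblyUnit, JunctionState, PartitionDesign
from .params import PartitionParams

Score = tuple[int, int, int]


def junction_variants(
    state: JunctionState,
    max_shift: int,
    bounds: tuple[int, int] | None = None,
) -> list[int]:
    """Unvisited candidate positions, smallest repositioning first.

    Offsets are enumerated +1, -1, +2, -2, ... relative to the *original*
    junction position (displacement is what the metric penalizes), then
    clipped to ``bounds`` and filtered against the visited set.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    lo, hi = bounds if bounds is not None else (state.original - max_shift, state.original + max_shift)
    out: list[int] = []
    for d in range(1, max_shift + 1):
        for pos in (state.original + d, state.original - d):
            if lo <= pos <= hi and pos not in state.visited:
                out.append(pos)
    return out


class JunctionPool:
    """Optimization context for the sibling junctions of one parent unit."""

    def __init__(
        self,
        design_seq: str,
        units: list[AssemblyUnit],
        tier: str,
        params: PartitionParams,
        pool_id: str,
    ) -> None:
        self.seq = design_seq
        self.units = units
        self.tier = tier
        self.params = params
        self.pool_id = pool_id
        self.overlap = params.overlap_for(tier)
        self.cap = params.cap(tier)
        self.adapter_load = params.adapter_total(tier)
        self.max_shift = params.shift_limit(tier)
        self.thresholds = params.thresholds
        self.states = partition._make_static_junctions(units, tier, pool_id, self.overlap)

    # -- geometry ----------------------------------------------------------
    def bounds(self, idx: int) -> tuple[int, int]:
        """Feasible position range for junction ``idx`` at the current layout."""
        st = self.states[idx]
        left, right = st.left, st.right
        lo = max(
            left.core_start + self.overlap,  # THR must fit inside the left core
            right.core_end - (self.cap - self.overlap - self.adapter_load),
            st.original - self.max_shift,
        )
        hi = min(
            left.core_start + (self.cap - left.thr_left - self.adapter_load),
            st.original + self.max_shift,
        )
        if idx + 1 < len(self.states):
            hi = min(hi, self.states[idx + 1].position - self.overlap)
        else:
            hi = min(hi, right.core_end - 1)
        return lo, hi

    # -- scoring -----------------------------------------------------------
    def thr_at(self, idx: int, position: int | None = None) -> str:
        pos = self.states[idx].position if position is None else position
        return self.seq[pos - self.overlap : pos]

    def _genome_nonunique(self, thr: str) -> int:
        """Longest substring of ``thr`` occurring >= 2x in the whole design."""
        lo, hi = 0, len(thr)
        rc_seq = reverse_complement(self.seq)

        def check(k: int) -> bool:
            for i in range(len(thr) - k + 1):
                sub = thr[i : i + k]
                if count_occurrences(self.seq, sub) + count_occurrences(rc_seq, sub) > 1:
                    return True
            return False

        while lo < hi:
            mid = (lo + hi + 1) // 2
            if check(mid):
                lo = mid
            else:
                hi = mid - 1
        return lo

    def evaluate(self, idx: int, position: int | None = None) -> ThrReport:
        """ThrReport for junction ``idx`` with its THR at ``position``.

        Sibling THRs are taken at their current positions.
        """
        thr = self.thr_at(idx, position)
        th = self.thresholds
        cross = 0
        if self.params.unique_scope == "genome":
            cross = self._genome_nonunique(thr)
        else:
            for other_idx, other_state in enumerate(self.states):
                if other_idx == idx:
                    continue
                cross = max(
                    cross,
                    max_cross_shared_substring(
                        thr, self.thr_at(other_idx), include_rc=True
                    ),
                )
        dr = max_direct_repeat(thr)
        hp = max_hairpin_stem(thr, th.hairpin_min_loop)
        return ThrReport(
            junction_id=self.states[idx].junction_id,
            max_direct_repeat=dr,
            max_hairpin_stem=hp,
            max_cross_shared=cross,
            passes=(
                dr <= th.repeat_limit
                and hp <= th.hairpin_stem_limit
                and cross <= th.nonunique_limit
            ),
        )

    def score(self, idx: int, position: int | None = None) -> Score:
        pos = self.states[idx].position if position is None else position
        report = self.evaluate(idx, pos)
        return (
            report.violation_count(self.thresholds),
            report.max_feature,
            abs(pos - self.states[idx].original),
        )

    # -- moves -------------------------------------------------------------
    def _apply(self, idx: int, position: int) -> None:
        st = self.states[idx]
        st.position = position
        st.visited.add(position)
        st.left.core_end = position
        st.right.core_start = position

    def optimize(self, max_cycles: int | None = None) -> list[JunctionState]:
        max_cycles = max_cycles if max_cycles is not None else self.params.max_opt_cycles
        for _cycle in range(max_cycles):
            scores = [self.score(i) for i in range(len(self.states))]
            violating = [i for i, sc in enumerate(scores) if sc[0] > 0]
            if not violating:
                break
            violating.sort(
                key=lambda i: (-scores[i][0], -scores[i][1], self.states[i].position)
            )
            moved = False
            for idx in violating:
                if self.score(idx)[0] == 0:  # fixed as a side effect of earlier moves
                    continue
                candidates = junction_variants(
                    self.states[idx], self.max_shift, self.bounds(idx)
                )
                best_pos: int | None = None
                best_score: Score | None = None
                for pos in candidates:
                    sc = self.score(idx, pos)
                    if best_score is None or sc < best_score:
                        best_pos, best_score = pos, sc
                        if sc[0] == 0:
                            # A constraint-free variant passes outright;
                            # candidates are enumerated by smallest
                            # repositioning first, so this is the passing
                            # variant of least displacement.
                            break
                if best_pos is None:
                    continue  # search path exhausted for this junction
                self._apply(idx, best_pos)
                moved = True
            if not moved:
                break
        for idx, st in enumerate(self.states):
            st.report = self.evaluate(idx)
            st.resolved = st.report.passes
        return self.states


def evaluate_variant(
    pool: JunctionPool, idx: int, position: int, thresholds: ConstraintThresholds | None = None
) -> Score:
    """Score tuple (violations, max feature bp, |displacement|) for a variant."""
    if thresholds is not None and thresholds != pool.thresholds:
        pool = JunctionPool(
            pool.seq, pool.units, pool.tier,
            pool.params.with_(thresholds=thresholds), pool.pool_id,
        )
    return pool.score(idx, position)


def _pool_optimizer_factory(
    max_cycles: int | None = None,
    on_pool: Callable[[str, list[JunctionState]], None] | None = None,
):
    def optimizer(seq, units, tier, params, pool_id):
        pool = JunctionPool(seq, units, tier, params, pool_id)
        states = pool.optimize(max_cycles)
        if on_pool is not None:
            on_pool(pool_id, states)
        return states

    return optimizer


def optimize_design(
    design: PartitionDesign,
    thresholds: ConstraintThresholds | None = None,
    max_cycles: int | None = None,
    progress: Callable[[str, int, int], None] | None = None,
) -> PartitionDesign:
    """Re-plan the design with THR optimization at every tier.

    Returns a new :class:`PartitionDesign`; the input design is left
    untouched.  The procedure is deterministic, so optimizing an
    already-optimized design reproduces it exactly.
    """
    params = design.params
    if thresholds is not None:
        params = params.with_(thresholds=thresholds)
    return partition._build_tree(
        design.record,
        params,
        pool_optimizer=_pool_optimizer_factory(max_cycles),
        progress=progress,
    )


def displacement_stats(design: PartitionDesign) -> dict[str, dict[str, float]]:
    """Per-tier mean, standard deviation and maximum of |displacement|."""
    out: dict[str, dict[str, float]] = {}
    for tier in ("segment", "block", "subblock"):
        d = [abs(st.displacement) for st in design.junctions[tier]]
        if not d:
            out[tier] = {"count": 0, "mean": 0.0, "sd": 0.0, "max": 0.0}
            continue
        out[tier] = {
            "count": len(d),
            "mean": float(statistics.fmean(d)),
            "sd": float(statistics.pstdev(d)) if len(d) > 1 else 0.0,
            "max": float(max(d)),
        }
    return out
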