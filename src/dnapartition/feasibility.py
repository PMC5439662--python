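"""Assembly-feasibility statistics for one sequence or a batch.

Quantifies how much of a design can be assembled "risk-free": a segment
passes when neither its own junction THRs nor any THR of its descendant
blocks and subblocks violates the repeat / hairpin / non-unique
thresholds.  Each sequence is analyzed once with equidistant junctions
and (optionally) once with THR optimization, which is how the pass-rate
gain of optimization is measured.  A segment-tier junction THR is
attributed to the segment whose core physically contains it (the left
neighbor).
"""

from __future__ import annotations

import statistics as _stats
from dataclasses import dataclass, field

import pandas as pd

from .constraint_scan import gc_fraction
from .model import DesignRecord, PartitionDesign
from .params import PartitionParams
from .partition import build_design
from .thr_optimize import displacement_stats, optimize_design

_CLASSES = ("direct_repeat", "hairpin", "nonunique")


@dataclass
class TierSummary:
    count: int
    mean_size: float
    min_size: int
    max_size: int
    junctions: int
    violations: dict[str, int] = field(default_factory=dict)


@dataclass
class FeasibilityStats:
    """All per-sequence partitioning and constraint metrics."""

    identifier: str
    length: int
    gc: float
    optimized: bool
    tiers: dict[str, TierSummary]
    segments_passing: int
    segments_failing: int
    gc_passing: float | None
    gc_failing: float | None
    displacement: dict[str, dict[str, float]]
    block_size_variance: float  # population variance of block core sizes, bp^2

    @property
    def pass_fraction(self) -> float:
        total = self.segments_passing + self.segments_failing
        return self.segments_passing / total if total else 0.0

    @property
    def total_violations(self) -> int:
        return sum(sum(t.violations.values()) for t in self.tiers.values())


def _classify(report, thresholds) -> list[str]:
    classes = []
    if report.max_direct_repeat > thresholds.repeat_limit:
        classes.append("direct_repeat")
    if report.max_hairpin_stem > thresholds.hairpin_stem_limit:
        classes.append("hairpin")
    if report.max_cross_shared > thresholds.nonunique_limit:
        classes.append("nonunique")
    return classes


def analyze_design(design: PartitionDesign) -> FeasibilityStats:
    """Feasibility statistics for an already-built design."""
    from .constraint_scan import scan_thr_set

    params = design.params
    seq = design.sequence
    th = params.thresholds

    # scan every THR pool; map each violating junction to its segment
    failing_segments: set[int] = set()
    tier_violations: dict[str, dict[str, int]] = {
        t: {c: 0 for c in _CLASSES} for t in ("segment", "block", "subblock")
    }
    tier_junctions = {t: 0 for t in ("segment", "block", "subblock")}
    for tier in ("segment", "block", "subblock"):
        for states in design.junction_pools(tier).values():
            thrs = [(st.junction_id, st.thr_sequence(seq)) for st in states]
            for live, report in zip(states, scan_thr_set(thrs, th)):
                live.report = report
                live.resolved = report.passes
                tier_junctions[tier] += 1
                for cls in _classify(report, th):
                    tier_violations[tier][cls] += 1
                if not report.passes:
                    failing_segments.add(live.left.index[0])

    tiers: dict[str, TierSummary] = {}
    for tier in ("segment", "block", "subblock"):
        units = design.units(tier)
        sizes = [u.full_length(seq) for u in units]
        tiers[tier] = TierSummary(
            count=len(units),
            mean_size=float(_stats.fmean(sizes)),
            min_size=min(sizes),
            max_size=max(sizes),
            junctions=tier_junctions[tier],
            violations=tier_violations[tier],
        )

    passing = [s for s in design.segments if s.index[0] not in failing_segments]
    failing = [s for s in design.segments if s.index[0] in failing_segments]

    def mean_gc(units):
        if not units:
            return None
        return float(
            _stats.fmean(gc_fraction(seq[u.core_start : u.core_end]) for u in units)
        )

    block_cores = [b.core_len for b in design.units("block")]
    return FeasibilityStats(
        identifier=design.record.identifier,
        length=design.record.length,
        gc=gc_fraction(seq),
        optimized=design.optimized,
        tiers=tiers,
        segments_passing=len(passing),
        segments_failing=len(failing),
        gc_passing=mean_gc(passing),
        gc_failing=mean_gc(failing),
        displacement=displacement_stats(design),
        block_size_variance=float(_stats.pvariance(block_cores))
        if len(block_cores) > 1
        else 0.0,
    )


def analyze_sequence(
    record: DesignRecord,
    params: PartitionParams | None = None,
    optimize: bool = False,
) -> FeasibilityStats:
    """Partition ``record`` (equidistant, optionally THR-optimized) and score it."""
    params = params or PartitionParams()
    design = build_design(record, params)
    if optimize:
        design = optimize_design(design)
    return analyze_design(design)


def stats_row(stats: FeasibilityStats) -> dict:
    row = {
        "identifier": stats.identifier,
        "length_bp": stats.length,
        "gc": round(stats.gc, 4),
        "optimized": stats.optimized,
        "segments": stats.tiers["segment"].count,
        "blocks": stats.tiers["block"].count,
        "subblocks": stats.tiers["subblock"].count,
        "segments_passing": stats.segments_passing,
        "pass_fraction": round(stats.pass_fraction, 4),
        "block_size_variance_bp2": round(stats.block_size_variance, 2),
        "gc_passing": None if stats.gc_passing is None else round(stats.gc_passing, 4),
        "gc_failing": None if stats.gc_failing is None else round(stats.gc_failing, 4),
    }
    for tier in ("segment", "block", "subblock"):
        t = stats.tiers[tier]
        row[f"{tier}_mean_size"] = round(t.mean_size, 1)
        row[f"{tier}_min_size"] = t.min_size
        row[f"{tier}_max_size"] = t.max_size
        for cls in _CLASSES:
            row[f"{tier}_{cls}_violations"] = t.violations[cls]
        row[f"{tier}_mean_abs_displacement"] = round(stats.displacement[tier]["mean"], 2)
        row[f"{tier}_sd_abs_displacement"] = round(stats.displacement[tier]["sd"], 2)
    return row


def summarize_batch(stats_list: list[FeasibilityStats]) -> pd.DataFrame:
    """One row per sequence plus an aggregate mean row."""
    if not stats_list:
        raise ValueError("summarize_batch requires at least one FeasibilityStats")
    frame = pd.DataFrame([stats_row(s) for s in stats_list])
    numeric = frame.select_dtypes("number")
    mean_row = {c: numeric[c].mean() for c in numeric.columns}
    mean_row["identifier"] = "MEAN"
    frame = pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)
    return frame
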