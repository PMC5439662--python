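"""Hierarchical partition planning: segments, blocks, subblocks.

The planner works top-down.  The whole design is split into the least
number of segments whose size (core + THR + worst-case adapter load) fits
under (1 + 10%) x the segment limit, with core sizes as equal as possible
(spread <= 1 bp).  Each segment's *covered interval* -- its core plus its
left THR extension -- is then split into blocks the same way, and each
block's covered interval into subblocks.  Because every tier re-partitions
core-plus-THR, assembling children by their exact THR duplications
reproduces the parent's sequence byte for byte ("virtual assembly").

Junction THR ownership: the overlap is the terminal bases of the left
sibling's core, duplicated as a prefix extension of the right sibling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

from .constraint_scan import reverse_complement
from .errors import CapViolationError, ParameterError
from .model import AssemblyUnit, DesignRecord, JunctionState, Part, PartitionDesign
from .params import AdapterSet, PartitionParams

logger = logging.getLogger("dnapartition")

#: Pool-optimizer hook: (design_seq, units, tier, params, pool_id) -> junction states.
PoolOptimizer = Callable[..., list[JunctionState]]


@dataclass(frozen=True)
class TierPlan:
    n: int
    core_sizes: tuple[int, ...]


def plan_tier_counts(
    L: int,
    tier_max: int,
    overlap: int,
    adapter_total: int = 0,
    tolerance: float = 0.10,
) -> TierPlan:
    """Least unit count for a stretch of ``L`` bp at one tier.

    ``n`` is the smallest integer such that
    ``ceil(L/n) + overlap + adapter_total <= (1 + tolerance) * tier_max``;
    core sizes are as equal as possible (differ by <= 1 bp) and sum to L.
    """
    if L < 1:
        raise ParameterError("cannot partition an empty stretch")
    cap = int(tier_max * (1.0 + tolerance) + 1e-9)
    core_max = cap - overlap - adapter_total
    if core_max < 1:
        raise ParameterError(
            f"tier size limit {tier_max} bp leaves no room for a {overlap} bp "
            f"overlap plus {adapter_total} bp of adapters"
        )
    n = -(-L // core_max)  # ceil
    base, rem = divmod(L, n)
    sizes = (base + 1,) * rem + (base,) * (n - rem)
    return TierPlan(n=n, core_sizes=sizes)


def _chain_units(
    tier: str,
    parent_index: tuple[int, ...],
    start: int,
    sizes: tuple[int, ...],
    overlap: int,
) -> list[AssemblyUnit]:
    units: list[AssemblyUnit] = []
    pos = start
    for i, size in enumerate(sizes):
        units.append(
            AssemblyUnit(
                tier=tier,
                index=parent_index + (i,),
                core_start=pos,
                core_end=pos + size,
                thr_left=overlap if i > 0 else 0,
            )
        )
        pos += size
    return units


def _make_static_junctions(
    units: list[AssemblyUnit], tier: str, pool_id: str, overlap: int
) -> list[JunctionState]:
    states = []
    for left, right in zip(units, units[1:]):
        states.append(
            JunctionState(
                junction_id=f"{left.key}|{right.key}",
                tier=tier,
                pool_id=pool_id,
                left=left,
                right=right,
                overlap=overlap,
                original=left.core_end,
                position=left.core_end,
            )
        )
    return states


def advanced_boundaries(
    parts: list[Part],
    segment_max: int,
    overlap: int,
    adapter_total: int = 0,
    tolerance: float = 0.10,
) -> list[int]:
    """Segment end positions snapped to biological-part boundaries.

    Greedy left-to-right accumulation: the current segment is extended
    part by part while core + overlap + adapters stays under the cap; no
    part is ever split.  A single part exceeding the cap becomes its own
    oversized segment (logged as a warning).
    """
    if not parts:
        raise ParameterError("advanced mode requires part annotations")
    cap = int(segment_max * (1.0 + tolerance) + 1e-9)
    budget = cap - overlap - adapter_total
    bounds: list[int] = []
    seg_start = parts[0].start
    for part in parts:
        if part.end - seg_start > budget and part.start > seg_start:
            bounds.append(part.start)
            seg_start = part.start
        if part.end - seg_start > budget:
            # single oversized part: it becomes its own segment
            logger.warning(
                "part %r is %d bp and exceeds the segment budget of %d bp; "
                "it becomes an oversized segment",
                part.label,
                part.length,
                budget,
            )
            bounds.append(part.end)
            seg_start = part.end
    if not bounds or bounds[-1] != parts[-1].end:
        bounds.append(parts[-1].end)
    return bounds


def _segment_intervals(record: DesignRecord, params: PartitionParams) -> list[tuple[int, int]]:
    if params.mode == "advanced":
        bounds = advanced_boundaries(
            record.parts,
            params.segment_max,
            params.segment_overlap,
            params.adapter_total("segment"),
            params.tolerance,
        )
        starts = [0] + bounds[:-1]
        return list(zip(starts, bounds))
    plan = plan_tier_counts(
        record.length,
        params.segment_max,
        params.segment_overlap,
        params.adapter_total("segment"),
        params.tolerance,
    )
    intervals = []
    pos = 0
    for size in plan.core_sizes:
        intervals.append((pos, pos + size))
        pos += size
    return intervals


def _build_tree(
    record: DesignRecord,
    params: PartitionParams,
    pool_optimizer: PoolOptimizer | None = None,
    progress: Callable[[str, int, int], None] | None = None,
) -> PartitionDesign:
    seq = record.sequence
    design = PartitionDesign(record=record, params=params, optimized=pool_optimizer is not None)

    segments = [
        AssemblyUnit(
            tier="segment",
            index=(i,),
            core_start=s,
            core_end=e,
            thr_left=params.segment_overlap if i > 0 else 0,
        )
        for i, (s, e) in enumerate(_segment_intervals(record, params))
    ]
    design.segments = segments

    # Segment junctions are shifted only in equidistant mode: in advanced
    # mode they are pinned to part boundaries.
    if (
        pool_optimizer is not None
        and params.optimize_segments
        and params.mode == "equidistant"
        and len(segments) > 1
    ):
        design.junctions["segment"] = pool_optimizer(seq, segments, "segment", params, "design")
    else:
        design.junctions["segment"] = _make_static_junctions(
            segments, "segment", "design", params.segment_overlap
        )

    n_seg = len(segments)
    for si, seg in enumerate(segments):
        cov_start, cov_end = seg.full_start, seg.core_end
        blk_plan = plan_tier_counts(
            cov_end - cov_start,
            params.block_max,
            params.block_overlap,
            params.adapter_total("block"),
            params.tolerance,
        )
        blocks = _chain_units("block", seg.index, cov_start, blk_plan.core_sizes, params.block_overlap)
        if pool_optimizer is not None and len(blocks) > 1:
            design.junctions["block"].extend(pool_optimizer(seq, blocks, "block", params, seg.key))
        else:
            design.junctions["block"].extend(
                _make_static_junctions(blocks, "block", seg.key, params.block_overlap)
            )
        seg.children = blocks

        for blk in blocks:
            sub_plan = plan_tier_counts(
                blk.core_end - blk.full_start,
                params.subblock_max,
                params.subblock_overlap,
                params.adapter_total("subblock"),
                params.tolerance,
            )
            subs = _chain_units(
                "subblock", blk.index, blk.full_start, sub_plan.core_sizes, params.subblock_overlap
            )
            if pool_optimizer is not None and len(subs) > 1:
                design.junctions["subblock"].extend(
                    pool_optimizer(seq, subs, "subblock", params, blk.key)
                )
            else:
                design.junctions["subblock"].extend(
                    _make_static_junctions(subs, "subblock", blk.key, params.subblock_overlap)
                )
            blk.children = subs
        if progress is not None:
            progress("segment", si + 1, n_seg)
    return design


def build_design(record: DesignRecord, params: PartitionParams | None = None) -> PartitionDesign:
    """Plan the full three-tier tree with equidistant (unoptimized) junctions."""
    return _build_tree(record, params or PartitionParams(), pool_optimizer=None)


def attach_adapters(
    design: PartitionDesign, adapters: AdapterSet | None = None
) -> PartitionDesign:
    """Attach nested adapter stacks to every unit, in place.

    Every unit carries its own tier's adapters outermost.  Units that form
    a terminus of their parent additionally carry the parent tier's
    adapter on that side, nested inside (and so on up the hierarchy), so
    that type IIS release and re-assembly of children reconstitutes the
    parent including its adapters.  Sizes are re-checked against the
    (1 + tolerance) x tier-limit caps after attachment.
    """
    adset = adapters if adapters is not None else design.params.adapters
    seq = design.sequence
    seg_a, blk_a, sub_a = adset.segment, adset.block, adset.subblock

    def stacks(own, outer_prefixes, outer_suffixes):
        prefix = [own.prefix] + outer_prefixes if own.prefix else list(outer_prefixes)
        suffix = list(outer_suffixes) + ([own.suffix] if own.suffix else [])
        return [p for p in prefix if p], [s for s in suffix if s]

    for seg in design.segments:
        first_seg = seg.index[-1] == 0
        last_seg = seg.index[-1] == len(design.segments) - 1
        seg.prefix_stack = [seg_a.prefix] if seg_a.prefix else []
        seg.suffix_stack = [seg_a.suffix] if seg_a.suffix else []
        n_blk = len(seg.children)
        for blk in seg.children:
            first_blk = blk.index[-1] == 0
            last_blk = blk.index[-1] == n_blk - 1
            blk.prefix_stack, blk.suffix_stack = stacks(
                blk_a,
                [seg_a.prefix] if first_blk and seg_a.prefix else [],
                [seg_a.suffix] if last_blk and seg_a.suffix else [],
            )
            n_sub = len(blk.children)
            for sub in blk.children:
                first_sub = sub.index[-1] == 0
                last_sub = sub.index[-1] == n_sub - 1
                inner_pre = []
                if first_sub and blk_a.prefix:
                    inner_pre.append(blk_a.prefix)
                if first_sub and first_blk and seg_a.prefix:
                    inner_pre.append(seg_a.prefix)
                inner_suf = []
                if last_sub and last_blk and seg_a.suffix:
                    inner_suf.append(seg_a.suffix)
                if last_sub and blk_a.suffix:
                    inner_suf.append(blk_a.suffix)
                sub.prefix_stack, sub.suffix_stack = stacks(sub_a, inner_pre, inner_suf)

    for unit in design.iter_all_units():
        cap = design.params.cap(unit.tier)
        if unit.full_length(seq) > cap:
            raise CapViolationError(
                f"unit {unit.key} is {unit.full_length(seq)} bp after adapter "
                f"attachment, exceeding the {cap} bp cap for {unit.tier}s"
            )
    return design


def check_forbidden_sites(
    design: PartitionDesign,
    sites: list[tuple[str, str]] | None = None,
) -> list[tuple[str, str, int]]:
    """All occurrences of forbidden recognition sites in the partition sequence.

    Scans the input (core) sequence on both strands; adapter sequences are
    excluded -- they are *supposed* to contain the release sites.  Returns
    ``(enzyme, strand, 0-based position)`` tuples; an empty list means the
    design is safe for the given enzyme set.  Palindromic sites are
    reported once, on the plus strand.
    """
    sites = sites if sites is not None else list(design.params.adapters.forbidden_sites)
    seq = design.sequence
    hits: list[tuple[str, str, int]] = []
    for name, site in sites:
        site = site.upper()
        rc = reverse_complement(site)
        i = seq.find(site)
        while i != -1:
            hits.append((name, "+", i))
            i = seq.find(site, i + 1)
        if rc != site:
            i = seq.find(rc)
            while i != -1:
                hits.append((name, "-", i))
                i = seq.find(rc, i + 1)
    hits.sort(key=lambda h: (h[2], h[0]))
    return hits


def virtually_assemble(design: PartitionDesign) -> str:
    """Reverse the partitioning: merge subblock regions by their THRs.

    Walks the subblocks in order, checks that each unit's left THR
    extension is identical to the tail of the sequence assembled so far
    (the homology that directs end joining), and concatenates.  For a
    correct design the result equals the input sequence byte for byte.
    """
    subs = design.units("subblock")
    seq = design.sequence
    out = subs[0].region_sequence(seq)
    end = subs[0].core_end
    for unit in subs[1:]:
        region = unit.region_sequence(seq)
        ov = end - unit.full_start
        if ov < 0:
            raise AssertionError(f"gap before unit {unit.key}")
        if ov and region[:ov] != out[-ov:]:
            raise AssertionError(f"THR mismatch at unit {unit.key}")
        out += region[ov:]
        end = unit.core_end
    return out
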