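"""In-memory model of a partitioned DNA design.

Coordinates are 0-based half-open on the input sequence everywhere in
memory; GenBank files use 1-based inclusive positions on disk and the
conversion happens exclusively in :mod:`dnapartition.sequence_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .constraint_scan import ThrReport
from .errors import AlphabetError, DesignSizeError
from .params import MAX_DESIGN_LENGTH, PartitionParams


@dataclass(frozen=True)
class Part:
    """One annotated biological part: [start, end) with a free-text label."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid part interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DesignRecord:
    """A validated input design: identifier, A/C/G/T sequence, parts."""

    identifier: str
    sequence: str
    parts: list[Part] = field(default_factory=list)
    linear: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> "DesignRecord":
        if self.length > MAX_DESIGN_LENGTH:
            raise DesignSizeError(
                f"design is {self.length:,} bp; the maximum is {MAX_DESIGN_LENGTH:,} bp"
            )
        bad = [i for i, c in enumerate(self.sequence) if c not in "ACGT"]
        if bad:
            raise AlphabetError(bad)
        for part in self.parts:
            if part.end > self.length:
                raise ValueError(f"part {part.label!r} extends past the design end")
        return self


@dataclass
class AssemblyUnit:
    """One segment, block or subblock.

    ``core`` is the unit's own interval on the design; ``thr_left`` bases
    immediately upstream of the core (the tail of the left sibling's core)
    are duplicated into this unit as its terminal homology region.  The
    synthesizable sequence is::

        concat(prefix_stack) + design[core_start - thr_left : core_end] + concat(suffix_stack)

    ``prefix_stack`` is ordered outermost -> innermost and
    ``suffix_stack`` innermost -> outermost, so simple concatenation puts
    higher-tier adapters innermost on both sides (nested adapters).
    """

    tier: str
    index: tuple[int, ...]
    core_start: int
    core_end: int
    thr_left: int = 0
    prefix_stack: list[str] = field(default_factory=list)
    suffix_stack: list[str] = field(default_factory=list)
    children: list["AssemblyUnit"] = field(default_factory=list)

    @property
    def key(self) -> str:
        labels = ("seg", "blk", "sub")
        return "_".join(f"{lab}{i}" for lab, i in zip(labels, self.index))

    @property
    def core_len(self) -> int:
        return self.core_end - self.core_start

    @property
    def full_start(self) -> int:
        return self.core_start - self.thr_left

    def region_sequence(self, design_seq: str) -> str:
        """Core plus left-THR extension (no adapters)."""
        return design_seq[self.full_start : self.core_end]

    def full_sequence(self, design_seq: str) -> str:
        return (
            "".join(self.prefix_stack)
            + self.region_sequence(design_seq)
            + "".join(self.suffix_stack)
        )

    def full_length(self, design_seq: str) -> int:
        return (
            sum(len(s) for s in self.prefix_stack)
            + (self.core_end - self.full_start)
            + sum(len(s) for s in self.suffix_stack)
        )


@dataclass
class JunctionState:
    """Position and optimization history of one sibling junction.

    The junction sits at the boundary between the left and right units'
    cores; its THR is the last ``overlap`` bases of the left core,
    duplicated as the right unit's left extension.  ``displacement`` is
    the signed shift from the original (equidistant) position.
    """

    junction_id: str
    tier: str
    pool_id: str
    left: AssemblyUnit
    right: AssemblyUnit
    overlap: int
    original: int
    position: int
    visited: set[int] = field(default_factory=set)
    resolved: bool = True
    report: ThrReport | None = None

    def __post_init__(self) -> None:
        self.visited.add(self.position)

    @property
    def displacement(self) -> int:
        return self.position - self.original

    @property
    def thr_interval(self) -> tuple[int, int]:
        return (self.position - self.overlap, self.position)

    def thr_sequence(self, design_seq: str) -> str:
        lo, hi = self.thr_interval
        return design_seq[lo:hi]


@dataclass
class PartitionDesign:
    """The full three-tier partition tree plus junction bookkeeping."""

    record: DesignRecord
    params: PartitionParams
    segments: list[AssemblyUnit] = field(default_factory=list)
    junctions: dict[str, list[JunctionState]] = field(
        default_factory=lambda: {"segment": [], "block": [], "subblock": []}
    )
    optimized: bool = False

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def units(self, tier: str) -> list[AssemblyUnit]:
        if tier == "segment":
            return list(self.segments)
        if tier == "block":
            return [b for s in self.segments for b in s.children]
        if tier == "subblock":
            return [u for s in self.segments for b in s.children for u in b.children]
        raise KeyError(tier)

    def iter_all_units(self) -> Iterator[AssemblyUnit]:
        for tier in ("segment", "block", "subblock"):
            yield from self.units(tier)

    def all_junctions(self) -> Iterator[JunctionState]:
        for tier in ("segment", "block", "subblock"):
            yield from self.junctions[tier]

    def junction_pools(self, tier: str) -> dict[str, list[JunctionState]]:
        """Junction states grouped by their co-assembly pool."""
        pools: dict[str, list[JunctionState]] = {}
        for state in self.junctions[tier]:
            pools.setdefault(state.pool_id, []).append(state)
        return pools
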