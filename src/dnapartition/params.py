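"""User-settable and built-in parameters of the partitioning pipeline.

The three partition tiers and their defaults follow the standard
overlap-assembly workflow: ~1 kb subblocks (chemical synthesis), ~4 kb
blocks (isothermal in vitro assembly), ~20 kb segments (yeast homologous
recombination).  Tier size limits are understood as the partition sequence
*plus* flanking adapter sequences, with a fixed 10% size-variation
allowance on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .constraint_scan import ConstraintThresholds
from .errors import ParameterError

#: Hard cap on input design length (bp).
MAX_DESIGN_LENGTH = 10_000_000

#: Fixed relative size-variation allowance at every tier.
TOLERANCE = 0.10

TIERS = ("segment", "block", "subblock")


@dataclass(frozen=True)
class TierAdapters:
    """5' prefix and 3' suffix adapter for one tier (either may be empty)."""

    prefix: str = ""
    suffix: str = ""

    def __post_init__(self) -> None:
        for text in (self.prefix, self.suffix):
            if set(text) - set("ACGT"):
                raise ParameterError(f"adapter sequence {text!r} is not over A/C/G/T")

    @property
    def total(self) -> int:
        return len(self.prefix) + len(self.suffix)


@dataclass(frozen=True)
class AdapterSet:
    """Per-tier adapter sequences plus named restriction sites to screen.

    ``forbidden_sites`` lists ``(enzyme_name, recognition_sequence)`` pairs
    that must be absent from the partition sequence itself, because the
    corresponding enzymes release assembly units from their cloning
    vectors.
    """

    segment: TierAdapters = field(default_factory=TierAdapters)
    block: TierAdapters = field(default_factory=TierAdapters)
    subblock: TierAdapters = field(default_factory=TierAdapters)
    forbidden_sites: tuple[tuple[str, str], ...] = ()

    def for_tier(self, tier: str) -> TierAdapters:
        return getattr(self, tier)

    @classmethod
    def empty(cls) -> "AdapterSet":
        return cls()

    @classmethod
    def preset(cls) -> "AdapterSet":
        """Built-in adapter preset.

        The preset assigns the conventional enzyme roles -- BbsI release for
        subblocks, BspQI for blocks, PacI/PmeI for segments -- with the
        recognition site embedded in short neutral flanks standing in for
        vector homology.  These flanking sequences are synthetic
        placeholders (the vector-specific adapters of any real cloning
        system should be supplied by the user); the recognition sites are
        the real ones.
        """
        return cls(
            segment=TierAdapters(
                prefix="CAGTACGCAGGTTCATTAATTAAGT",  # PacI TTAATTAA
                suffix="ACGTTTAAACTTCAGGCATGACGTC",  # PmeI GTTTAAAC
            ),
            block=TierAdapters(
                prefix="TCACGAGGTGCTCTTCAACT",  # BspQI GCTCTTC
                suffix="TGAAGAGCACGGATCACTGA",  # BspQI site on reverse strand
            ),
            subblock=TierAdapters(
                prefix="TCGTGAAGACTG",  # BbsI GAAGAC
                suffix="GAGTCTTCTGCA",  # BbsI site on reverse strand
            ),
            forbidden_sites=(
                ("BbsI", "GAAGAC"),
                ("BspQI", "GCTCTTC"),
                ("PacI", "TTAATTAA"),
                ("PmeI", "GTTTAAAC"),
            ),
        )


@dataclass(frozen=True)
class PrimerParams:
    """Diagnostic-primer search settings.

    Primers are fixed 20-mers searched inside a window flanking each
    junction THR.  On failure the window grows by ``window_step`` and the
    pair Tm-difference bound relaxes by ``dtm_step``, up to
    ``max_iterations`` escalations.
    """

    primer_len: int = 20
    window: int = 150
    window_step: int = 50
    dtm_max: float = 1.0
    dtm_step: float = 1.0
    max_iterations: int = 6
    three_prime_unique_len: int = 8
    max_self_feature: int = 4
    max_cross_homology: int = 7
    max_three_prime_complementarity: int = 3
    #: Tm model conditions: monovalent salt (mM) and primer concentration (nM).
    na_mM: float = 50.0
    oligo_nM: float = 500.0

    def __post_init__(self) -> None:
        if self.primer_len != 20:
            raise ParameterError("primer length is fixed at 20 bp")
        if min(self.window, self.window_step, self.max_iterations) <= 0:
            raise ParameterError("primer window settings must be positive")
        if self.dtm_max <= 0 or self.dtm_step <= 0:
            raise ParameterError("dTm settings must be positive")


@dataclass(frozen=True)
class PartitionParams:
    """Everything that shapes a partitioning run.

    Size limits count the core sequence plus left THR extension plus
    adapter sequences; units may exceed the limit by at most the fixed
    10% tolerance.  Recommended input ranges (mirroring the interactive
    defaults): blocks 2,000-5,000 bp, subblocks 500-2,000 bp, segment
    overlaps 35-200 bp, block/subblock overlaps 15-200 bp.
    """

    segment_max: int = 20_000
    block_max: int = 4_000
    subblock_max: int = 1_000
    segment_overlap: int = 120
    block_overlap: int = 80
    subblock_overlap: int = 35
    adapters: AdapterSet = field(default_factory=AdapterSet)
    mode: str = "equidistant"  # or "advanced"
    thresholds: ConstraintThresholds = field(default_factory=ConstraintThresholds)
    max_opt_cycles: int = 20
    #: Maximal junction displacement; None = floor(0.05 x tier size limit),
    #: which can never push a flanking unit past the 10% cap.
    max_shift: int | None = None
    optimize_segments: bool = True
    #: THR uniqueness comparison scope: against sibling THRs of the same
    #: parent ("pool") or against the whole design sequence ("genome").
    unique_scope: str = "pool"
    primers: PrimerParams = field(default_factory=PrimerParams)

    tolerance: float = TOLERANCE

    def __post_init__(self) -> None:
        if not (self.subblock_max < self.block_max < self.segment_max):
            raise ParameterError("tier size limits must satisfy subblock < block < segment")
        for tier in TIERS:
            if self.overlap_for(tier) >= self.tier_max(tier):
                raise ParameterError(f"{tier} overlap must be smaller than its size limit")
            if self.overlap_for(tier) < 1:
                raise ParameterError(f"{tier} overlap must be >= 1 bp")
        if self.mode not in ("equidistant", "advanced"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.unique_scope not in ("pool", "genome"):
            raise ParameterError(f"unknown unique_scope {self.unique_scope!r}")
        if self.max_opt_cycles < 1:
            raise ParameterError("max_opt_cycles must be >= 1")
        if abs(self.tolerance - TOLERANCE) > 1e-9:
            raise ParameterError("the size-variation tolerance is fixed at 10%")

    # -- tier accessors ----------------------------------------------------
    def tier_max(self, tier: str) -> int:
        return {"segment": self.segment_max, "block": self.block_max, "subblock": self.subblock_max}[tier]

    def overlap_for(self, tier: str) -> int:
        return {
            "segment": self.segment_overlap,
            "block": self.block_overlap,
            "subblock": self.subblock_overlap,
        }[tier]

    def cap(self, tier: str) -> int:
        """Absolute unit-size cap for a tier: floor((1 + tolerance) x limit)."""
        return math.floor(self.tier_max(tier) * (1.0 + self.tolerance) + 1e-9)

    def adapter_total(self, tier: str) -> int:
        """Worst-case adapter load for a unit of ``tier``.

        Terminal units inherit the adapters of every enclosing tier, so
        planning reserves room for the full nested stack.
        """
        load = self.adapters.for_tier(tier).total
        if tier in ("block", "subblock"):
            load += self.adapters.segment.total
        if tier == "subblock":
            load += self.adapters.block.total
        return load

    def shift_limit(self, tier: str) -> int:
        if self.max_shift is not None:
            return self.max_shift
        return math.floor(0.05 * self.tier_max(tier))

    def with_(self, **changes) -> "PartitionParams":
        return replace(self, **changes)
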