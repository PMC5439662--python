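"""Tier planning, adapter nesting, forbidden sites and assembly identity."""

import pytest

from dnapartition.errors import CapViolationError, ParameterError
from dnapartition.fixtures import random_sequence
from dnapartition.model import DesignRecord, Part
from dnapartition.params import AdapterSet, PartitionParams, TierAdapters
from dnapartition.partition import (
    advanced_boundaries,
    attach_adapters,
    build_design,
    check_forbidden_sites,
    plan_tier_counts,
    virtually_assemble,
)


class TestPlanTierCounts:
    @pytest.mark.parametrize(
        "L,tier_max,overlap,expected_n",
        [
            (20000, 4000, 80, 5),  # one 20 kb segment -> five 4 kb blocks
            (4080, 1000, 35, 4),  # block incl. its THR -> four subblocks
            (900, 4000, 80, 1),  # fits in a single unit
            (100000, 20000, 120, 5),
        ],
    )
    def test_examples(self, L, tier_max, overlap, expected_n):
        plan = plan_tier_counts(L, tier_max, overlap)
        assert plan.n == expected_n
        assert sum(plan.core_sizes) == L
        assert max(plan.core_sizes) - min(plan.core_sizes) <= 1

    def test_minimality_exhaustive(self):
        """For every L up to 50 kb, n-1 units would break the size cap."""
        for tier_max, overlap in ((1000, 35), (4000, 80), (20000, 120)):
            cap = int(tier_max * 1.1)
            for L in range(1, 50001, 1):
                n = plan_tier_counts(L, tier_max, overlap).n
                assert -(-L // n) + overlap <= cap
                if n > 1:
                    assert -(-L // (n - 1)) + overlap > cap

    def test_adapters_consume_core_budget(self):
        with_ad = plan_tier_counts(20000, 4000, 80, adapter_total=400)
        assert with_ad.n > plan_tier_counts(20000, 4000, 80).n or max(
            with_ad.core_sizes
        ) + 80 + 400 <= 4400

    def test_infeasible_parameters(self):
        with pytest.raises(ParameterError):
            plan_tier_counts(1000, 100, 90, adapter_total=50)


class TestBuildDesign:
    def test_worked_example_counts(self, record_20k, default_params):
        design = build_design(record_20k, default_params)
        assert len(design.units("segment")) == 1
        assert len(design.units("block")) == 5
        assert len(design.units("subblock")) == 20

    def test_100kb_segment_count(self, record_100k, default_params):
        design = build_design(record_100k, default_params)
        assert len(design.units("segment")) == 5

    def test_degenerate_single_unit_chain(self):
        record = DesignRecord("tiny", random_sequence(800, 0.5, 3)).validate()
        design = build_design(record)
        assert [len(design.units(t)) for t in ("segment", "block", "subblock")] == [1, 1, 1]
        assert all(not design.junctions[t] for t in ("segment", "block", "subblock"))
        assert design.units("subblock")[0].thr_left == 0

    def test_children_tile_parent_covered_interval(self, record_20k, default_params):
        design = build_design(record_20k, default_params)
        for seg in design.segments:
            assert seg.children[0].core_start == seg.full_start
            assert seg.children[-1].core_end == seg.core_end
            for left, right in zip(seg.children, seg.children[1:]):
                assert left.core_end == right.core_start
            for blk in seg.children:
                assert blk.children[0].core_start == blk.full_start
                assert blk.children[-1].core_end == blk.core_end

    def test_core_spread_within_one_bp(self, record_100k, default_params):
        design = build_design(record_100k, default_params)
        seg_sizes = [s.core_len for s in design.segments]
        assert max(seg_sizes) - min(seg_sizes) <= 1
        for seg in design.segments:
            sizes = [b.core_len for b in seg.children]
            assert max(sizes) - min(sizes) <= 1

    def test_determinism(self, record_20k, default_params):
        d1 = build_design(record_20k, default_params)
        d2 = build_design(record_20k, default_params)
        assert [(u.key, u.core_start, u.core_end) for u in d1.iter_all_units()] == [
            (u.key, u.core_start, u.core_end) for u in d2.iter_all_units()
        ]


class TestVirtualAssembly:
    @pytest.mark.parametrize("length,seed", [(900, 1), (5000, 2), (20000, 3), (61234, 4)])
    def test_identity(self, length, seed):
        record = DesignRecord("va", random_sequence(length, 0.5, seed)).validate()
        design = build_design(record)
        assert virtually_assemble(design) == record.sequence


class TestAttachAdapters:
    SYMBOLIC = AdapterSet(
        segment=TierAdapters("CCCCT", "AGGGG"),
        block=TierAdapters("GGGGA", "TCCCC"),
        subblock=TierAdapters("TTTTC", "GAAAA"),
    )

    @pytest.fixture()
    def design(self, record_20k):
        params = PartitionParams(adapters=self.SYMBOLIC)
        return attach_adapters(build_design(record_20k, params))

    def test_terminal_subblock_nesting_order(self, design):
        """Outermost subblock adapter, then block, then segment, then core."""
        first = design.units("subblock")[0]
        assert first.prefix_stack == ["TTTTC", "GGGGA", "CCCCT"]
        last = design.units("subblock")[-1]
        assert last.suffix_stack == ["AGGGG", "TCCCC", "GAAAA"]

    def test_interior_subblock_carries_only_its_own(self, design):
        interior = next(
            u for u in design.units("subblock") if u.index == (0, 1, 2)
        )
        assert interior.prefix_stack == ["TTTTC"]
        assert interior.suffix_stack == ["GAAAA"]

    def test_block_start_subblock_carries_block_prefix(self, design):
        unit = next(u for u in design.units("subblock") if u.index == (0, 1, 0))
        assert unit.prefix_stack == ["TTTTC", "GGGGA"]

    def test_full_sequence_composition(self, design):
        seq = design.sequence
        for unit in design.iter_all_units():
            assert unit.full_sequence(seq) == (
                "".join(unit.prefix_stack)
                + seq[unit.full_start : unit.core_end]
                + "".join(unit.suffix_stack)
            )

    def test_empty_adapters_are_identity(self, record_20k, default_params):
        design = attach_adapters(build_design(record_20k, default_params))
        seq = design.sequence
        for unit in design.iter_all_units():
            assert unit.full_sequence(seq) == seq[unit.full_start : unit.core_end]

    def test_cap_violation_names_unit(self, record_20k):
        design = build_design(record_20k, PartitionParams())  # no adapter budget
        huge = AdapterSet(subblock=TierAdapters("A" * 90, "T" * 90))
        with pytest.raises(CapViolationError, match="sub"):
            attach_adapters(design, huge)


class TestForbiddenSites:
    def test_implanted_site_found(self, rng):
        seq = random_sequence(5000, 0.5, 11, forbid_sites=("GAAGAC",))
        seq = seq[:1200] + "GAAGAC" + seq[1206:]
        design = build_design(DesignRecord("fs", seq).validate())
        hits = check_forbidden_sites(design, [("BbsI", "GAAGAC")])
        assert ("BbsI", "+", 1200) in hits

    def test_reverse_strand_hit(self):
        seq = random_sequence(3000, 0.5, 12, forbid_sites=("GAAGAC",))
        seq = seq[:700] + "GTCTTC" + seq[706:]  # rc(GAAGAC)
        design = build_design(DesignRecord("fs", seq).validate())
        hits = check_forbidden_sites(design, [("BbsI", "GAAGAC")])
        assert ("BbsI", "-", 700) in hits

    def test_screened_fixture_is_clean(self):
        sites = AdapterSet.preset().forbidden_sites
        seq = random_sequence(20000, 0.5, 13, forbid_sites=tuple(s for _, s in sites))
        design = build_design(DesignRecord("clean", seq).validate())
        assert check_forbidden_sites(design, list(sites)) == []


class TestAdvancedBoundaries:
    def test_parts_grouped_under_cap(self):
        parts = [Part(0, 8000, "p1"), Part(8000, 16000, "p2"), Part(16000, 24000, "p3")]
        assert advanced_boundaries(parts, 20000, 120) == [16000, 24000]

    def test_single_small_part(self):
        assert advanced_boundaries([Part(0, 5000, "p1")], 20000, 120) == [5000]

    def test_oversized_part_is_own_segment(self, caplog):
        parts = [Part(0, 25000, "big"), Part(25000, 30000, "p2")]
        with caplog.at_level("WARNING", logger="dnapartition"):
            bounds = advanced_boundaries(parts, 20000, 120)
        assert bounds == [25000, 30000]
        assert any("oversized" in m for m in caplog.messages)

    def test_advanced_build_keeps_parts_whole(self):
        sizes = (9000, 9000, 9000, 9000)
        seq = random_sequence(36000, 0.5, 14)
        parts = []
        pos = 0
        for i, s in enumerate(sizes, 1):
            parts.append(Part(pos, pos + s, f"synthetic part:{i}"))
            pos += s
        record = DesignRecord("adv", seq, parts=parts).validate()
        design = build_design(record, PartitionParams(mode="advanced"))
        boundaries = {seg.core_end for seg in design.segments}
        part_ends = {p.end for p in parts}
        assert boundaries <= part_ends
        assert virtually_assemble(design) == seq
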