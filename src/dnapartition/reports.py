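"""Human-readable statistics, run log and run manifest.

Everything printed here is recomputed from the design tree at render
time -- there are no cached aggregates that could go stale.  The
before/after constraint comparison rebuilds the equidistant counterpart
of an optimized design from the same record and parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import statistics as _stats
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import yaml

from .model import PartitionDesign
from .thr_optimize import displacement_stats

if TYPE_CHECKING:  # pragma: no cover
    from .primer_design import PrimerPair


@dataclass
class LogEvent:
    message: str
    level: str = "INFO"
    timestamp: float = field(default_factory=time.time)

    def render(self) -> str:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S", time.localtime(self.timestamp))
        return f"{stamp}\t{self.level}\t{self.message}"


class RunLog:
    """Ordered event collector for logfile.txt."""

    def __init__(self) -> None:
        self.events: list[LogEvent] = []

    def info(self, message: str) -> None:
        self.events.append(LogEvent(message))

    def warning(self, message: str) -> None:
        self.events.append(LogEvent(message, level="WARNING"))

    def lines(self) -> list[str]:
        return [e.render() for e in self.events]

    @property
    def warnings(self) -> list[LogEvent]:
        return [e for e in self.events if e.level == "WARNING"]


def write_logfile(events: list[LogEvent] | RunLog, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(events, RunLog):
        events = events.events
    path.write_text("\n".join(e.render() for e in events) + "\n")
    return path


def synthesis_effort(design: PartitionDesign) -> int:
    """Total bp to order: sum of subblock full lengths including adapters."""
    seq = design.sequence
    return sum(u.full_length(seq) for u in design.units("subblock"))


def _constraint_counts(design: PartitionDesign) -> dict[str, int]:
    from .feasibility import analyze_design

    stats = analyze_design(design)
    out = {"direct_repeat": 0, "hairpin": 0, "nonunique": 0}
    for tier_summary in stats.tiers.values():
        for cls, n in tier_summary.violations.items():
            out[cls] += n
    out["segments_passing"] = stats.segments_passing
    out["segments_total"] = stats.tiers["segment"].count
    return out


def render_statistics(
    design: PartitionDesign,
    primer_tables: dict[str, list["PrimerPair"]] | None = None,
) -> str:
    """The statistics report: per-tier sizes, displacements, synthesis effort
    and a before/after constraint comparison."""
    from .partition import build_design

    seq = design.sequence
    params = design.params
    lines: list[str] = []
    lines.append(f"Partitioning statistics for {design.record.identifier}")
    lines.append(f"input length: {design.record.length} bp")
    lines.append("")
    lines.append("tier      units  min_size  mean_size  max_size  overlap_bp")
    for tier in ("segment", "block", "subblock"):
        units = design.units(tier)
        sizes = [u.full_length(seq) for u in units]
        lines.append(
            f"{tier:<9} {len(units):>5} {min(sizes):>9} "
            f"{_stats.fmean(sizes):>10.1f} {max(sizes):>9} "
            f"{params.overlap_for(tier):>11}"
        )
    lines.append("")
    lines.append(f"DNA synthesis effort (sum of subblock lengths): {synthesis_effort(design)} bp")
    lines.append("")
    disp = displacement_stats(design)
    lines.append("tier      junctions  mean|d|  sd|d|  max|d|")
    for tier in ("segment", "block", "subblock"):
        d = disp[tier]
        lines.append(
            f"{tier:<9} {int(d['count']):>9} {d['mean']:>8.2f} {d['sd']:>6.2f} {d['max']:>7.0f}"
        )
    lines.append("")

    after = _constraint_counts(design)
    if design.optimized:
        before = _constraint_counts(build_design(design.record, params))
    else:
        before = after
    lines.append("assembly constraints (THR violations)   before  after")
    for cls in ("direct_repeat", "hairpin", "nonunique"):
        lines.append(f"{cls:<39} {before[cls]:>6} {after[cls]:>6}")
    lines.append(
        f"{'risk-free segments':<39} "
        f"{before['segments_passing']:>3}/{before['segments_total']:<3} "
        f"{after['segments_passing']:>3}/{after['segments_total']:<3}"
    )

    unresolved = [st for st in design.all_junctions() if not st.resolved]
    if unresolved:
        lines.append("")
        lines.append("unresolved junctions (last THR position kept):")
        for st in unresolved:
            rep = st.report
            lines.append(
                f"  {st.tier} {st.junction_id} at {st.position} "
                f"(d={st.displacement:+d}; repeat={rep.max_direct_repeat}, "
                f"hairpin={rep.max_hairpin_stem}, shared={rep.max_cross_shared})"
            )
    if primer_tables is not None:
        lines.append("")
        lines.append("primer pairs per tier:")
        for tier in ("segment", "block", "subblock"):
            lines.append(f"  {tier}: {len(primer_tables.get(tier, []))}")
    return "\n".join(lines) + "\n"


@dataclass
class RunManifest:
    """Provenance summary of one partitioning run."""

    input_path: str
    parameters: dict
    files: dict[str, dict]  # name -> {records, sha256}
    unit_counts: dict[str, int]
    size_ranges: dict[str, tuple[int, int]]
    synthesis_effort_bp: int
    constraints_before: dict[str, int]
    constraints_after: dict[str, int]
    unresolved_junctions: list[str]
    wall_time_s: float

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def build_manifest(
    design: PartitionDesign,
    input_path: str | Path,
    out_dir: str | Path,
    file_records: dict[str, int],
    wall_time_s: float,
) -> RunManifest:
    seq = design.sequence
    out_dir = Path(out_dir)
    files = {}
    for name, count in sorted(file_records.items()):
        digest = hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
        files[name] = {"records": count, "sha256": digest}
    after = _constraint_counts(design)
    if design.optimized:
        from .partition import build_design

        before = _constraint_counts(build_design(design.record, design.params))
    else:
        before = after
    return RunManifest(
        input_path=str(input_path),
        parameters=dataclasses.asdict(design.params),
        files=files,
        unit_counts={t: len(design.units(t)) for t in ("segment", "block", "subblock")},
        size_ranges={
            t: (
                min(u.full_length(seq) for u in design.units(t)),
                max(u.full_length(seq) for u in design.units(t)),
            )
            for t in ("segment", "block", "subblock")
        },
        synthesis_effort_bp=synthesis_effort(design),
        constraints_before=before,
        constraints_after=after,
        unresolved_junctions=[
            st.junction_id for st in design.all_junctions() if not st.resolved
        ],
        wall_time_s=wall_time_s,
    )
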