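"""Reading and writing of designs and partitioning artifacts.

GenBank parsing/serialization is delegated to Biopython's ``SeqIO``; this
module owns validation, the coordinate convention (0-based half-open in
memory, 1-based inclusive on disk) and the layout of the output bundle:

* ``segments.fasta`` / ``blocks.fasta`` / ``subblocks.fasta`` -- full
  synthesizable sequences including THR extensions and adapters, one
  record per unit, named ``seg{S}[_blk{B}[_sub{U}]]``, wrapped at 70
  columns;
* ``partition_design.gb`` -- the input sequence annotated with one
  ``misc_feature`` per unit (``/label``, ``/tier`` qualifiers);
* ``parameters.yaml``, ``statistics.txt``, ``logfile.txt``;
* ``segment_primers.txt`` / ``block_primers.txt`` / ``subblock_primers.txt``
  (tab-separated) when primer design was run.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, OutputError
from .model import DesignRecord, Part, PartitionDesign

if TYPE_CHECKING:  # pragma: no cover
    from .primer_design import PrimerPair

logger = logging.getLogger("dnapartition")

PRIMER_COLUMNS = (
    "junction_id",
    "fw_seq",
    "fw_start",
    "tm_fw",
    "rv_seq",
    "rv_start",
    "tm_rv",
    "dTm",
    "amplicon_len",
    "iteration",
)


def read_design(path: str | Path, advanced: bool = False) -> DesignRecord:
    """Parse and validate a single-entry GenBank design file.

    In advanced mode, ``source`` features carrying a ``/note`` qualifier
    are interpreted as ordered biological parts which must tile the whole
    sequence without gaps or overlaps.  Circular topology is accepted but
    processed as linear (logged as a warning): no origin-spanning THRs
    are generated.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    topology = record.annotations.get("topology", "linear")
    if topology == "circular":
        logger.warning(
            "%s declares circular topology; it is processed as a linear sequence", path
        )
    parts = _parse_parts(record, advanced=advanced)
    design = DesignRecord(
        identifier=record.id or record.name or Path(path).stem,
        sequence=seq,
        parts=parts,
        linear=(topology != "circular"),
    )
    design.validate()
    if advanced:
        _check_tiling(design)
    return design


def _parse_parts(record: SeqRecord, advanced: bool) -> list[Part]:
    parts: list[Part] = []
    for feature in record.features:
        if feature.type != "source":
            continue
        notes = feature.qualifiers.get("note", [])
        if not notes:
            continue
        if len(feature.location.parts) > 1:
            raise AnnotationError(
                f"part {notes[0]!r} has a discontinuous (join/order) location"
            )
        parts.append(
            Part(int(feature.location.start), int(feature.location.end), str(notes[0]))
        )
    parts.sort(key=lambda p: (p.start, p.end))
    if advanced and not parts:
        raise AnnotationError(
            "advanced mode requires `source` features with part annotations"
        )
    return parts


def _check_tiling(design: DesignRecord) -> None:
    pos = 0
    for part in design.parts:
        if part.start < pos:
            raise AnnotationError(f"part {part.label!r} overlaps the previous part")
        if part.start > pos:
            raise AnnotationError(
                f"gap of {part.start - pos} bp before part {part.label!r}"
            )
        pos = part.end
    if pos != design.length:
        raise AnnotationError(
            f"parts cover [0, {pos}) but the design is {design.length} bp"
        )


def extract_parts(record: DesignRecord) -> list[Part]:
    """Ordered part annotations of a parsed design (empty when none)."""
    return sorted(record.parts, key=lambda p: (p.start, p.end))


def write_design(record: DesignRecord, path: str | Path) -> Path:
    """Serialize a DesignRecord as a GenBank file (parts as `source`)."""
    path = Path(path)
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier[:16].replace(" ", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "linear" if record.linear else "circular",
        },
    )
    for part in record.parts:
        seqrec.features.append(
            SeqFeature(
                SimpleLocation(part.start, part.end),
                type="source",
                qualifiers={"mol_type": ["genomic DNA"], "note": [part.label]},
            )
        )
    with open(path, "w") as handle:
        SeqIO.write(seqrec, handle, "genbank")
    return path


def _write_fasta(units, design_seq: str, path: Path) -> int:
    records = [
        SeqRecord(Seq(u.full_sequence(design_seq)), id=u.key, description="")
        for u in units
    ]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=70)
        writer.write_file(records)
    return len(records)


def write_annotated_genbank(design: PartitionDesign, path: Path) -> int:
    """Annotate every assembly unit as a misc_feature on the input sequence."""
    record = SeqRecord(
        Seq(design.sequence),
        id=design.record.identifier,
        name=design.record.identifier[:16].replace(" ", "_"),
        description="partitioned design",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    count = 0
    for unit in design.iter_all_units():
        record.features.append(
            SeqFeature(
                SimpleLocation(unit.full_start, unit.core_end),
                type="misc_feature",
                qualifiers={"label": [unit.key], "tier": [unit.tier]},
            )
        )
        count += 1
    with open(path, "w") as handle:
        SeqIO.write(record, handle, "genbank")
    return count


def write_primer_table(pairs: list["PrimerPair"], path: Path) -> int:
    with open(path, "w") as handle:
        handle.write("\t".join(PRIMER_COLUMNS) + "\n")
        for p in pairs:
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        p.junction_id,
                        p.fw,
                        p.fw_start,
                        f"{p.tm_fw:.2f}",
                        p.rv,
                        p.rv_start,
                        f"{p.tm_rv:.2f}",
                        f"{p.dtm:.2f}",
                        p.amplicon_len,
                        p.iteration,
                    )
                )
                + "\n"
            )
    return len(pairs)


def _params_snapshot(design: PartitionDesign) -> dict:
    snap = dataclasses.asdict(design.params)
    snap["input"] = {
        "identifier": design.record.identifier,
        "length_bp": design.record.length,
        "parts": len(design.record.parts),
    }
    return snap


def write_outputs(
    design: PartitionDesign,
    out_dir: str | Path,
    primer_tables: dict[str, list["PrimerPair"]] | None = None,
    statistics_text: str | None = None,
    log_lines: list[str] | None = None,
) -> dict[str, int]:
    """Write the full output bundle; returns {filename: record count}."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OutputError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not design.segments:
        raise OutputError("design has no assembly units; build it first")

    manifest: dict[str, int] = {}
    seq = design.sequence
    for tier, fname in (
        ("segment", "segments.fasta"),
        ("block", "blocks.fasta"),
        ("subblock", "subblocks.fasta"),
    ):
        manifest[fname] = _write_fasta(design.units(tier), seq, out_dir / fname)
    manifest["partition_design.gb"] = write_annotated_genbank(
        design, out_dir / "partition_design.gb"
    )
    with open(out_dir / "parameters.yaml", "w") as handle:
        yaml.safe_dump(_params_snapshot(design), handle, sort_keys=False)
    manifest["parameters.yaml"] = 1
    if statistics_text is None:
        from .reports import render_statistics

        statistics_text = render_statistics(design, primer_tables)
    (out_dir / "statistics.txt").write_text(statistics_text)
    manifest["statistics.txt"] = 1
    (out_dir / "logfile.txt").write_text("\n".join(log_lines or []) + "\n")
    manifest["logfile.txt"] = 1
    if primer_tables is not None:
        for tier in ("segment", "block", "subblock"):
            fname = f"{tier}_primers.txt"
            manifest[fname] = write_primer_table(
                primer_tables.get(tier, []), out_dir / fname
            )
    return manifest
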