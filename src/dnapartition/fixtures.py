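"""Seeded synthetic DNA designs with implantable assembly constraints.

Every other module is testable without downloads: this module generates
random sequences at a controlled GC content, implants ground-truth
features (direct repeats, hairpins, shared motifs, homopolymers) at known
positions, and can serialize the result as an annotated GenBank file.

A single integer seed drives all randomness; two calls with identical
arguments produce byte-identical sequences and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constraint_scan import reverse_complement
from .errors import FixtureError
from .model import DesignRecord, Part

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Bounded retries for rejection sampling of forbidden sites.
MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class Implant:
    """One feature to write into a background sequence.

    kinds:
      - ``direct_repeat``: one motif of ``length`` bp copied to every
        position in ``positions`` (>= 2 of them);
      - ``hairpin``: motif at ``positions[0]``, its reverse complement
        ``loop`` nt further downstream;
      - ``shared_motif``: one motif copied to every position (used to make
        two different THRs share sequence);
      - ``homopolymer``: ``base * length`` at each position.
    """

    kind: str
    length: int
    positions: tuple[int, ...]
    loop: int = 4
    base: str = "A"
    motif: str | None = None  # fixed motif; None = drawn from the RNG

    def __post_init__(self) -> None:
        if self.kind not in ("direct_repeat", "hairpin", "shared_motif", "homopolymer"):
            raise FixtureError(f"unknown implant kind {self.kind!r}")
        if self.length < 1:
            raise FixtureError("implant length must be >= 1")
        if self.kind == "hairpin" and self.loop < 3:
            raise FixtureError("hairpin loop must be >= 3 nt")
        if self.kind in ("direct_repeat", "shared_motif") and len(self.positions) < 2:
            raise FixtureError(f"{self.kind} needs >= 2 positions")

    def intervals(self) -> list[tuple[int, int]]:
        if self.kind == "hairpin":
            start = self.positions[0]
            return [(start, start + 2 * self.length + self.loop)]
        return [(p, p + self.length) for p in self.positions]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic design."""

    length: int
    gc: float = 0.5
    seed: int = 0
    implants: tuple[Implant, ...] = ()
    parts: tuple[int, ...] = ()  # part sizes; must sum to length when given
    forbid_sites: tuple[str, ...] = ()
    identifier: str = "synthetic_design"


def random_sequence(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    forbid_sites: tuple[str, ...] = (),
) -> str:
    """Reproducible random A/C/G/T sequence with target GC content.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2, so the realized GC
    fraction is within ~0.01 of the target for sequences >= 10 kb.  When
    ``forbid_sites`` is given, windows containing a site (either strand)
    are resampled until clean, up to a bounded number of rounds.
    """
    if not 0.0 <= gc <= 1.0:
        raise FixtureError("gc must be within [0, 1]")
    if length < 1:
        raise FixtureError("length must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=probs)
    seq = arr.tobytes().decode()
    if not forbid_sites:
        return seq
    patterns = set()
    for site in forbid_sites:
        patterns.add(site)
        patterns.add(reverse_complement(site))
    for _ in range(MAX_RESAMPLE_ROUNDS):
        hits = []
        for pat in patterns:
            i = seq.find(pat)
            while i != -1:
                hits.append((i, i + len(pat)))
                i = seq.find(pat, i + 1)
        if not hits:
            return seq
        chars = list(seq)
        for lo, hi in hits:
            repl = rng.choice(_BASES, size=hi - lo, p=probs)
            chars[lo:hi] = repl.tobytes().decode()
        seq = "".join(chars)
    raise FixtureError("could not purge forbidden sites within the retry bound")


def _draw_motif(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode()


def implant_motif(seq: str, implant: Implant, rng: np.random.Generator | None = None) -> str:
    """Write one implant into ``seq``; the length is preserved.

    Raises :class:`FixtureError` if the implant's intervals fall outside
    the sequence.  Overlap between *different* implants is the caller's
    responsibility (see :func:`build_fixture`).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    for lo, hi in implant.intervals():
        if not (0 <= lo < hi <= len(seq)):
            raise FixtureError(f"implant interval [{lo}, {hi}) outside the sequence")
    motif = implant.motif or _draw_motif(rng, implant.length, 0.5)
    if len(motif) != implant.length and implant.kind != "homopolymer":
        raise FixtureError("motif length does not match the implant length")
    chars = list(seq)
    if implant.kind in ("direct_repeat", "shared_motif"):
        for p in implant.positions:
            chars[p : p + implant.length] = motif
    elif implant.kind == "hairpin":
        p = implant.positions[0]
        chars[p : p + implant.length] = motif
        q = p + implant.length + implant.loop
        chars[q : q + implant.length] = reverse_complement(motif)
    else:  # homopolymer
        for p in implant.positions:
            chars[p : p + implant.length] = implant.base * implant.length
    return "".join(chars)


def build_fixture(spec: FixtureSpec) -> DesignRecord:
    """Materialize a :class:`FixtureSpec` into a validated DesignRecord."""
    if spec.parts and sum(spec.parts) != spec.length:
        raise FixtureError("part sizes must sum to the design length")
    occupied: list[tuple[int, int]] = []
    for implant in spec.implants:
        for iv in implant.intervals():
            for other in occupied:
                if iv[0] < other[1] and other[0] < iv[1]:
                    raise FixtureError(f"implants overlap at [{iv[0]}, {iv[1]})")
            occupied.append(iv)
    seq = random_sequence(spec.length, spec.gc, spec.seed, spec.forbid_sites)
    rng = np.random.default_rng(spec.seed + 1)
    for implant in spec.implants:
        seq = implant_motif(seq, implant, rng)
    parts: list[Part] = []
    pos = 0
    for i, size in enumerate(spec.parts, start=1):
        parts.append(Part(pos, pos + size, f"synthetic part:{i}"))
        pos += size
    return DesignRecord(spec.identifier, seq, parts).validate()


def implant_block_junction_repeats(
    length: int = 40_000,
    gc: float = 0.5,
    seed: int = 4,
    repeat_len: int = 15,
    spacing: int = 30,
    params=None,
    identifier: str = "junction_repeat_fixture",
) -> DesignRecord:
    """Stress fixture: a distinct direct repeat centered on every planned
    block junction.

    For each equidistant block junction a fresh motif of ``repeat_len`` bp
    is written twice, copy starts ``spacing`` bp apart, with the two-copy
    construct centered on the junction position.  Junction shifts of a few
    tens of bp bring both copies inside one THR, so the optimizer must
    navigate around them.
    """
    from .partition import build_design  # planning defines junction positions

    if params is None:
        from .params import PartitionParams

        params = PartitionParams()
    seq = random_sequence(length, gc, seed)
    planned = build_design(DesignRecord(identifier, seq).validate(), params)
    rng = np.random.default_rng(seed + 1)
    span = repeat_len + spacing
    for state in planned.junctions["block"]:
        center = state.position
        first = center - span // 2
        motif = _draw_motif(rng, repeat_len, gc)
        seq = implant_motif(
            seq,
            Implant("direct_repeat", repeat_len, (first, first + spacing), motif=motif),
            rng,
        )
    return DesignRecord(identifier, seq).validate()


def implant_shared_block_motifs(
    length: int = 40_000,
    gc: float = 0.5,
    seed: int = 5,
    motif_len: int = 30,
    params=None,
    identifier: str = "shared_motif_fixture",
) -> DesignRecord:
    """Stress fixture: one identical motif inside two block THRs per segment.

    Each segment gets its own ``motif_len`` bp motif, written into the
    THRs of its first two planned block junctions; the two THRs then share
    the full motif and fail the non-unique-overlap rule until at least one
    junction is displaced.
    """
    from .partition import build_design

    if params is None:
        from .params import PartitionParams

        params = PartitionParams()
    seq = random_sequence(length, gc, seed)
    planned = build_design(DesignRecord(identifier, seq).validate(), params)
    rng = np.random.default_rng(seed + 1)
    for states in planned.junction_pools("block").values():
        if len(states) < 2:
            continue
        motif = _draw_motif(rng, motif_len, gc)
        overlap = states[0].overlap
        offset = motif_len + (overlap - motif_len) // 2  # motif centered in the THR
        positions = tuple(st.position - offset for st in states[:2])
        seq = implant_motif(
            seq, Implant("shared_motif", motif_len, positions, motif=motif), rng
        )
    return DesignRecord(identifier, seq).validate()


def make_annotated_design(spec: FixtureSpec, path: str | Path) -> Path:
    """Write the fixture as a GenBank file with `source` part features.

    Parts are annotated the way annotated designs in the field are: one
    ``source`` feature per part carrying a ``/note="synthetic part:N"``
    qualifier.  The file round-trips through
    :func:`dnapartition.sequence_io.read_design`.
    """
    from . import sequence_io  # local import: io depends on Biopython only

    record = build_fixture(spec)
    return sequence_io.write_design(record, path)
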