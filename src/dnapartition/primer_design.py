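"""Diagnostic PCR primer pairs spanning every assembly junction.

For each junction a forward and a reverse 20-mer are searched inside a
150 bp window on either side of the THR, under four rules:

1. pair melting temperatures within dTm <= 1.0 deg C;
2. the last 8 bases of each primer's 3' end are unique within its search
   window;
3. no cross-homology between the two primers (longest complementary run
   <= 7 bp, 3'-terminal complementarity <= 3 bp);
4. no internal repeat or hairpin feature longer than 4 bases within a
   primer.

The first pair passing all rules (forward position ascending, then
reverse position ascending) is emitted.  If no pair is found the window
grows by 50 bp and the dTm bound relaxes by 1 deg C, up to six
escalation iterations; junctions still unresolved are reported for
separate processing.

Melting temperatures come from nearest-neighbor thermodynamics with the
unified Allawi & SantaLucia (1997) parameter set at 50 mM monovalent salt
and 500 nM primer concentration (entropy salt correction
0.368 (N-1) ln[Na+]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constraint_scan import (
    count_occurrences,
    max_cross_shared_substring,
    max_direct_repeat,
    max_hairpin_stem,
    reverse_complement,
)
from .errors import ParameterError
from .model import PartitionDesign
from .params import PrimerParams

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor duplex parameters, Allawi & SantaLucia (1997):
# dH in kcal/mol, dS in cal/(mol K); keys are 5'->3' dinucleotide steps,
# a missing key is looked up via its reverse complement.
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_SYM = (0.0, -1.4)


def melting_temperature(
    seq: str, na_mM: float = 50.0, oligo_nM: float = 500.0, length: int = 20
) -> float:
    """Nearest-neighbor duplex Tm (deg C) of a primer ``seq``.

    Symmetric in the duplex: Tm(s) == Tm(reverse_complement(s)).
    """
    if len(seq) != length:
        raise ParameterError(f"primer must be {length} bp, got {len(seq)}")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        pair = _NN.get(step) or _NN[reverse_complement(step)]
        dh += pair[0]
        ds += pair[1]
    for terminal in (seq[0], seq[-1]):
        init = _INIT_AT if terminal in "AT" else _INIT_GC
        dh += init[0]
        ds += init[1]
    if seq == reverse_complement(seq):  # self-complementary duplex
        dh += _SYM[0]
        ds += _SYM[1]
    # primer in excess over template: CT term is the primer concentration
    k = oligo_nM * 1e-9
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return (1000.0 * dh) / (ds + R_GAS * math.log(k)) - 273.15


@dataclass(frozen=True)
class PrimerCandidate:
    seq: str  # 5'->3' on its own strand
    start: int  # leftmost design coordinate of the annealing site
    strand: str  # "+" forward, "-" reverse
    tm: float
    ok: bool
    fail_reason: str | None = None


@dataclass
class PrimerPair:
    """An accepted junction-verification pair."""

    junction_id: str
    tier: str
    fw: str
    rv: str
    fw_start: int
    rv_start: int
    tm_fw: float
    tm_rv: float
    amplicon_len: int
    iteration: int  # escalation round that produced the pair; 0 = none

    @property
    def dtm(self) -> float:
        return abs(self.tm_fw - self.tm_rv)


@dataclass
class PrimerDesignResult:
    tables: dict[str, list[PrimerPair]]
    unresolved: list[tuple[str, str]]  # (tier, junction_id)
    discarded: dict[str, int] = field(default_factory=dict)

    def all_pairs(self) -> list[PrimerPair]:
        return [p for tier in ("segment", "block", "subblock") for p in self.tables[tier]]


def _self_ok(primer: str, params: PrimerParams) -> str | None:
    if max_direct_repeat(primer) > params.max_self_feature:
        return "self_repeat"
    if max_hairpin_stem(primer, min_loop=3) > params.max_self_feature:
        return "self_hairpin"
    return None


def candidate_primers(
    design_seq: str,
    thr: tuple[int, int],
    window: int,
    side: str,
    params: PrimerParams | None = None,
) -> list[PrimerCandidate]:
    """All 20-mer candidates inside the window on one side of a THR.

    ``side`` is ``"upstream"`` (forward primers, plus strand, window ends
    at the THR start) or ``"downstream"`` (reverse primers, minus strand,
    window begins at the THR end).  Windows reaching past the design
    boundary are clipped.  Each candidate is annotated pass/fail for the
    single-primer rules (3'-end uniqueness within the window, internal
    repeat/hairpin limits).
    """
    params = params or PrimerParams()
    plen = params.primer_len
    u8 = params.three_prime_unique_len
    out: list[PrimerCandidate] = []
    if side == "upstream":
        w0, w1 = max(0, thr[0] - window), thr[0]
    elif side == "downstream":
        w0, w1 = thr[1], min(len(design_seq), thr[1] + window)
    else:
        raise ValueError(f"unknown side {side!r}")
    wseq = design_seq[w0:w1]
    if len(wseq) < plen:
        return out
    # the window sequence on the strand the primer anneals to
    strand_window = wseq if side == "upstream" else reverse_complement(wseq)
    for start in range(w0, w1 - plen + 1):  # leftmost coordinate, ascending
        if side == "upstream":
            primer = design_seq[start : start + plen]
        else:
            primer = reverse_complement(design_seq[start : start + plen])
        reason = None
        if count_occurrences(strand_window, primer[-u8:]) != 1:
            reason = "three_prime_not_unique"
        else:
            reason = _self_ok(primer, params)
        out.append(
            PrimerCandidate(
                seq=primer,
                start=start,
                strand="+" if side == "upstream" else "-",
                tm=melting_temperature(primer, params.na_mM, params.oligo_nM, plen),
                ok=reason is None,
                fail_reason=reason,
            )
        )
    return out


def _cross_run(p: str, q: str) -> int:
    """Longest complementary run between two primers (duplex-forming)."""
    return max_cross_shared_substring(p, reverse_complement(q), include_rc=False)


def _three_prime_complementarity(p: str, q: str) -> int:
    """Longest 3'-terminal suffix of ``p`` complementary to any part of ``q``."""
    rc_q = reverse_complement(q)
    for k in range(len(p), 0, -1):
        if p[-k:] in rc_q:
            return k
    return 0


def select_pair(
    fw_candidates: list[PrimerCandidate],
    rv_candidates: list[PrimerCandidate],
    dtm_max: float,
    params: PrimerParams | None = None,
    discarded: dict[str, int] | None = None,
) -> tuple[PrimerCandidate, PrimerCandidate] | None:
    """First pair passing the pair rules, in deterministic scan order.

    Forward candidates ascend by position, then reverse candidates ascend;
    a pair passes when dTm <= ``dtm_max`` and the two primers show no
    cross-homology.  ``discarded`` (if given) accumulates per-rule
    rejection counts for the log.
    """
    params = params or PrimerParams()

    def note(rule: str) -> None:
        if discarded is not None:
            discarded[rule] = discarded.get(rule, 0) + 1

    for fw in fw_candidates:
        if not fw.ok:
            continue
        for rv in rv_candidates:
            if not rv.ok:
                continue
            if abs(fw.tm - rv.tm) > dtm_max:
                note("dtm")
                continue
            if _cross_run(fw.seq, rv.seq) > params.max_cross_homology:
                note("cross_homology")
                continue
            if (
                _three_prime_complementarity(fw.seq, rv.seq)
                > params.max_three_prime_complementarity
                or _three_prime_complementarity(rv.seq, fw.seq)
                > params.max_three_prime_complementarity
            ):
                note("three_prime_complementarity")
                continue
            return fw, rv
    return None


def design_junction_pair(
    design_seq: str,
    thr: tuple[int, int],
    params: PrimerParams,
    discarded: dict[str, int] | None = None,
) -> tuple[PrimerCandidate, PrimerCandidate, int] | None:
    """Search one junction with window/dTm escalation; None if exhausted."""
    for iteration in range(params.max_iterations + 1):
        window = params.window + params.window_step * iteration
        dtm_max = params.dtm_max + params.dtm_step * iteration
        fw = candidate_primers(design_seq, thr, window, "upstream", params)
        rv = candidate_primers(design_seq, thr, window, "downstream", params)
        pair = select_pair(fw, rv, dtm_max, params, discarded)
        if pair is not None:
            return pair[0], pair[1], iteration
    return None


def design_all_junctions(
    design: PartitionDesign, params: PrimerParams | None = None
) -> PrimerDesignResult:
    """Primer tables for every junction at all three tiers."""
    params = params or design.params.primers
    seq = design.sequence
    result = PrimerDesignResult(
        tables={"segment": [], "block": [], "subblock": []}, unresolved=[]
    )
    for tier in ("segment", "block", "subblock"):
        for state in design.junctions[tier]:
            found = design_junction_pair(
                seq, state.thr_interval, params, result.discarded
            )
            if found is None:
                result.unresolved.append((tier, state.junction_id))
                continue
            fw, rv, iteration = found
            result.tables[tier].append(
                PrimerPair(
                    junction_id=state.junction_id,
                    tier=tier,
                    fw=fw.seq,
                    rv=rv.seq,
                    fw_start=fw.start,
                    rv_start=rv.start,
                    tm_fw=fw.tm,
                    tm_rv=rv.tm,
                    amplicon_len=(rv.start + params.primer_len) - fw.start,
                    iteration=iteration,
                )
            )
    return result
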