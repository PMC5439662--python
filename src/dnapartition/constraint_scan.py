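"""String kernels that detect assembly-impairing sequence features.

Three features inside a terminal homology region (THR) can derail
overlap-based DNA assembly:

* **direct repeats** -- a substring occurring at two or more start positions
  within the THR lets the overlap mis-align, producing short deletions or
  insertions;
* **hairpin stems** (inverted repeats) -- a substring whose reverse
  complement occurs downstream folds into a secondary structure that
  competes with annealing of the single-stranded overlap;
* **non-unique overlaps** -- a substring shared between two different THRs
  of co-assembled units lets a fragment anneal to the wrong junction.

Each kernel reports the *length in bp* of the longest such feature; the
caller compares it against a threshold (built-in 8 bp: features of 9 bp or
more are violations).  All kernels are exact string matching over the
{A,C,G,T} alphabet -- no thermodynamic folding model is applied.

The implementations binary-search the feature length and test each
candidate length with a hashed k-mer sweep (the existence of a feature of
length k implies one of length k-1, so the predicate is monotone).  They
are validated against quadratic brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConstraintThresholds:
    """Maximal tolerated feature lengths within a THR (bp).

    A feature is a violation iff its length is strictly greater than the
    threshold, i.e. >= 9 bp at the built-in 8 bp settings.
    """

    repeat_limit: int = 8
    hairpin_stem_limit: int = 8
    nonunique_limit: int = 8
    hairpin_min_loop: int = 3

    def __post_init__(self) -> None:
        if min(self.repeat_limit, self.hairpin_stem_limit, self.nonunique_limit) < 1:
            raise ValueError("constraint thresholds must be >= 1")
        if self.hairpin_min_loop < 0:
            raise ValueError("hairpin_min_loop must be >= 0")


@dataclass
class ThrReport:
    """Constraint scan result for one terminal homology region."""

    junction_id: str
    max_direct_repeat: int
    max_hairpin_stem: int
    max_cross_shared: int
    passes: bool

    @property
    def max_feature(self) -> int:
        return max(self.max_direct_repeat, self.max_hairpin_stem, self.max_cross_shared)

    def violation_count(self, thresholds: ConstraintThresholds) -> int:
        return (
            (self.max_direct_repeat > thresholds.repeat_limit)
            + (self.max_hairpin_stem > thresholds.hairpin_stem_limit)
            + (self.max_cross_shared > thresholds.nonunique_limit)
        )


def _has_repeat(seq: str, k: int) -> bool:
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        if sub in seen:
            return True
        seen.add(sub)
    return False


def max_direct_repeat(seq: str) -> int:
    """Length of the longest substring occurring at >= 2 distinct starts.

    Overlapping occurrences count, so e.g. ``"AAAAA"`` scores 4 ("AAAA" at
    starts 0 and 1).  Returns 0 for strings with no repeated substring.
    """
    n = len(seq)
    if n < 2:
        return 0
    lo, hi = 0, n - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _has_repeat(seq, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _has_stem(seq: str, k: int, min_loop: int) -> bool:
    # stem at [i, i+k), reverse complement at [j, j+k), j >= i + k + min_loop
    n = len(seq)
    first: dict[str, int] = {}
    for i in range(n - k + 1):
        sub = seq[i : i + k]
        if sub not in first:
            first[sub] = i
    for j in range(n - k + 1):
        i = first.get(reverse_complement(seq[j : j + k]))
        if i is not None and j >= i + k + min_loop:
            return True
    return False


def max_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest exact-match hairpin stem with a loop of >= ``min_loop`` nt.

    The stem and its reverse-complement partner must not overlap; the
    spacer between them is the loop.  Covers both "hairpin" and
    single-region "inverted repeat" features.
    """
    n = len(seq)
    hi = (n - min_loop) // 2
    if hi < 1:
        return 0
    lo = 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _has_stem(seq, mid, min_loop):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _has_common(a: str, b: str, k: int) -> bool:
    if k > len(a) or k > len(b):
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[j : j + k] in kmers for j in range(len(b) - k + 1))


def max_cross_shared_substring(a: str, b: str, include_rc: bool = True) -> int:
    """Longest common substring between ``a`` and ``b``.

    With ``include_rc`` the reverse complement of ``b`` is searched as
    well, because assembly overlaps anneal as duplexes and a shared
    sequence on either strand can seed mis-annealing.  The definition is
    symmetric in its arguments.
    """
    hi = min(len(a), len(b))
    if hi == 0:
        return 0

    def check(k: int) -> bool:
        if _has_common(a, b, k):
            return True
        return include_rc and _has_common(a, reverse_complement(b), k)

    lo = 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if check(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def gc_fraction(seq: str) -> float:
    """(G + C) / length for a non-empty A/C/G/T string."""
    if not seq:
        raise ValueError("gc_fraction is undefined for an empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_occurrences(haystack: str, needle: str) -> int:
    """Occurrences of ``needle`` in ``haystack``, overlaps allowed."""
    if not needle:
        return 0
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def scan_thr_set(
    thrs: Sequence[tuple[str, str]],
    thresholds: ConstraintThresholds | None = None,
) -> list[ThrReport]:
    """Scan a pool of THRs for all three constraint classes.

    ``thrs`` is a list of ``(junction_id, sequence)`` pairs belonging to
    one co-assembly pool.  The cross-shared value for each THR is the
    maximum over all *other* THRs in the pool, both orientations; a
    singleton pool scores 0.
    """
    thresholds = thresholds or ConstraintThresholds()
    reports: list[ThrReport] = []
    for idx, (jid, seq) in enumerate(thrs):
        if not seq:
            raise ValueError(f"empty THR for junction {jid!r}")
        cross = 0
        for other_idx, (_, other) in enumerate(thrs):
            if other_idx == idx:
                continue
            cross = max(cross, max_cross_shared_substring(seq, other, include_rc=True))
        dr = max_direct_repeat(seq)
        hp = max_hairpin_stem(seq, thresholds.hairpin_min_loop)
        reports.append(
            ThrReport(
                junction_id=jid,
                max_direct_repeat=dr,
                max_hairpin_stem=hp,
                max_cross_shared=cross,
                passes=(
                    dr <= thresholds.repeat_limit
                    and hp <= thresholds.hairpin_stem_limit
                    and cross <= thresholds.nonunique_limit
                ),
            )
        )
    return reports
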