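"""Independent brute-force oracles for the string kernels and primer rules.

These recompute feature lengths by exhaustive diagonal-run matching over
equality matrices (numpy), a completely different route from the
binary-search + k-mer-hash kernels in the package.  They are slow but
transparently correct, and are the ground truth for all kernel tests.
"""

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _runs(mask: np.ndarray):
    """(start, length) of every maximal run of True in a 1-D bool mask."""
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def _bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def oracle_direct_repeat(s: str) -> int:
    """Longest substring at >= 2 distinct starts: best True-run over all
    self-alignment offsets d >= 1."""
    n = len(s)
    x = _bytes(s)
    best = 0
    for d in range(1, n):
        eq = x[: n - d] == x[d:]
        for _, length in _runs(eq):
            best = max(best, length)
    return best


def oracle_hairpin(s: str, min_loop: int = 3) -> int:
    """Longest stem k with rc partner at j >= i + k + min_loop.

    Matches s against r = rc(s): a common substring s[i:i+k] == r[m:m+k]
    is a stem whose partner sits at j = n - m - k; within one maximal
    matching run both the run length and the loop budget shrink as the
    start advances, so the best stem of a run starts at its start.
    """
    n = len(s)
    x = _bytes(s)
    y = _bytes(rc(s))
    best = 0
    for off in range(-(n - 1), n):
        if off >= 0:
            xs, ys, i0, m0 = x[: n - off], y[off:], 0, off
        else:
            xs, ys, i0, m0 = x[-off:], y[: n + off], -off, 0
        for start, length in _runs(xs == ys):
            i, m = i0 + start, m0 + start
            k = min(length, (n - m - i - min_loop) // 2)
            best = max(best, k)
    return max(best, 0)


def oracle_lcs(a: str, b: str) -> int:
    """Longest common substring via all alignment offsets."""
    x, y = _bytes(a), _bytes(b)
    na, nb = len(x), len(y)
    best = 0
    for off in range(-(na - 1), nb):
        lo_a = max(0, -off)
        hi_a = min(na, nb - off)
        if hi_a <= lo_a:
            continue
        eq = x[lo_a:hi_a] == y[lo_a + off : hi_a + off]
        for _, length in _runs(eq):
            best = max(best, length)
    return best


def oracle_cross_shared(a: str, b: str, include_rc: bool = True) -> int:
    best = oracle_lcs(a, b)
    if include_rc:
        best = max(best, oracle_lcs(a, rc(b)))
    return best


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


# -- primer-rule validators (naive re-checks of emitted pairs) -------------

def primer_pair_valid(fw: str, rv: str, dtm: float, dtm_max: float,
                      max_cross: int = 7, max_three_prime: int = 3,
                      max_self: int = 4) -> bool:
    if len(fw) != 20 or len(rv) != 20:
        return False
    if dtm > dtm_max + 1e-9:
        return False
    if oracle_lcs(fw, rc(rv)) > max_cross:
        return False
    for p, q in ((fw, rv), (rv, fw)):
        rq = rc(q)
        k = 0
        for kk in range(1, len(p) + 1):
            if p[-kk:] in rq:
                k = kk
        if k > max_three_prime:
            return False
    for p in (fw, rv):
        if oracle_direct_repeat(p) > max_self or oracle_hairpin(p, 3) > max_self:
            return False
    return True
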