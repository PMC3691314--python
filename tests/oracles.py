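"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration or direct
scanning — and shares no code path with the implementations it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

_PAIRS = {"GC", "CG", "AT", "TA", "GT", "TG"}
_GU = {"GT", "TG"}
_AU = {"AT", "TA"}
_COMP = str.maketrans("ACGT", "TGCA")


def _stack(p1: str, p2: str) -> float:
    if p1 in _GU or p2 in _GU:
        return -1.0
    if p1 in _AU or p2 in _AU:
        return -2.0
    return -3.0


def enumerate_structures(seq: str):
    """Every non-crossing pair set with hairpin loops >= 3 nt."""

    def rec(i, j):
        if i > j:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + 4, j + 1):
            if seq[i] + seq[k] in _PAIRS:
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        yield inner | rest | {(i, k)}

    yield from rec(0, len(seq) - 1)


def structure_energy(seq: str, pairs) -> float:
    ps = set(pairs)
    return sum(
        _stack(seq[i] + seq[j], seq[i + 1] + seq[j - 1])
        for i, j in pairs
        if (i + 1, j - 1) in ps
    )


def mfe_by_enumeration(seq: str) -> float:
    return min(structure_energy(seq, p) for p in enumerate_structures(seq))


def duplex_mfe_by_enumeration(a: str, b: str) -> float:
    """Minimum over all monotone intermolecular matchings (a vs reversed b)."""
    c = b[::-1]
    n, m = len(a), len(c)
    best = [0.0]

    def rec(i, j, last, e):
        best[0] = min(best[0], e)
        for x in range(i, n):
            for y in range(j, m):
                if a[x] + c[y] in _PAIRS:
                    add = _stack(a[x - 1] + c[y - 1], a[x] + c[y]) \
                        if last == (x - 1, y - 1) else 0.0
                    rec(x + 1, y + 1, (x, y), e + add)

    rec(0, 0, None, 0.0)
    return best[0]


def best_local_alignment_score(a: str, b: str, seed_range=(1, 8)) -> float:
    """Exhaustive local alignment of a vs b under the target-score scheme."""
    MATCH, WOBBLE, MISMATCH = 5.0, 2.0, -3.0
    OPEN, EXT = -9.0, -4.0
    wob = {("G", "A"), ("T", "C")}

    def sub(i, j):
        s = MATCH if a[i] == b[j] else (WOBBLE if (a[i], b[j]) in wob else MISMATCH)
        return 2 * s if seed_range[0] <= i < seed_range[1] else s

    best = [0.0]

    def rec(i, j, score, gap):
        # gap: None / 'a' (gap in a) / 'b'
        best[0] = max(best[0], score)
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(i, j), None)
        if j < len(b):
            rec(i, j + 1, score + (EXT if gap == "a" else OPEN), "a")
        if i < len(a):
            rec(i + 1, j, score + (EXT if gap == "b" else OPEN), "b")

    for i in range(len(a)):
        for j in range(len(b)):
            rec(i, j, 0.0, None)
    return best[0]


def hypergeom_tail_exact(N: int, n: int, M: int, m: int):
    """P(X >= m) as an exact rational via integer binomials."""
    denom = math.comb(N, M)
    num = sum(
        math.comb(n, k) * math.comb(N - n, M - k)
        for k in range(m, min(n, M) + 1)
    )
    return num, denom


def hypergeom_tail_by_draws(N: int, n: int, M: int, m: int) -> float:
    """Literal enumeration of all C(N, M) draws (tiny N only)."""
    marked = set(range(n))
    hits = total = 0
    for draw in combinations(range(N), M):
        total += 1
        if len(marked.intersection(draw)) >= m:
            hits += 1
    return hits / total


def brute_force_map(tag: str, chromosomes: dict[str, str], max_mm: int = 1):
    """Scan every position on both strands with numpy; returns hit tuples."""
    hits = []
    rc = tag.translate(_COMP)[::-1]
    for chrom, seq in chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, query in (("+", tag), ("-", rc)):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            L = len(q)
            if L > len(arr):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm = (windows != q).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                hits.append((chrom, int(pos), strand, int(mm[pos])))
    return sorted(hits)
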