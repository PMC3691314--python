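"""RNA secondary-structure and duplex energies under a stacking model.

The folding engine is a Nussinov-style dynamic program scored with
base-pair *stacking* energies rather than pair counts: canonical pairs
(G:C, A:U, G:U wobble) are free to form, and every pair of adjacent
stacked pairs contributes

* -3.0 kcal/mol when both pairs are G:C,
* -2.0 kcal/mol when at least one pair is A:U (and none is G:U),
* -1.0 kcal/mol when at least one pair is G:U,

with unpaired bases and isolated pairs contributing nothing.  Hairpin
loops must enclose at least 3 unpaired nucleotides and pseudoknots are
excluded.  The model is deliberately simple — fully specified, exactly
optimizable, and testable against exhaustive enumeration — and all
energy thresholds used elsewhere in the package (hairpin acceptance at
-18 kcal/mol, duplex acceptance at -20 kcal/mol) are interpreted on this
model's scale.

`duplex_free_energy` applies the same stack table to intermolecular
hybridization of two strands (no intramolecular structure), which is
what seed-based target prediction needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from srnakit.util import check_alphabet, norm_seq

MIN_HAIRPIN_LOOP = 3

#: canonical pairs in DNA space (U already mapped to T)
_PAIRS = {"GC", "CG", "AT", "TA", "GT", "TG"}
_GU = {"GT", "TG"}
_AU = {"AT", "TA"}


def _pairable(x: str, y: str) -> bool:
    return x + y in _PAIRS

def _stack_energy(pair1: str, pair2: str) -> float:
    """Energy of two adjacent stacked pairs, classified by pair content."""
    if pair1 in _GU or pair2 in _GU:
        return -1.0
    if pair1 in _AU or pair2 in _AU:
        return -2.0
    return -3.0


@dataclass(frozen=True)
class FoldResult:
    """Minimum-energy structure of one sequence.

    Attributes
    ----------
    structure : dot-bracket string, same length as the input.
    energy : total stacking energy in kcal/mol (0 for the open chain).
    pairs : the base pairs (i, j), 0-based, i < j.
    """

    structure: str
    energy: float
    pairs: tuple[tuple[int, int], ...]

    def pair_table(self) -> list[int | None]:
        """partner index per position, None if unpaired."""
        table: list[int | None] = [None] * len(self.structure)
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table


def fold_rna(sequence: str, max_len: int = 200) -> FoldResult:
    """Fold one RNA/DNA sequence to its minimum stacking energy.

    Accepts either alphabet (U and T are equivalent).  Raises
    ``ValueError`` on characters outside {A,C,G,T,U} or on sequences
    longer than ``max_len`` (the cubic DP is meant for precursor-sized
    windows, not chromosomes).
    """
    seq = norm_seq(sequence)
    check_alphabet(seq)
    n = len(seq)
    if n > max_len:
        raise ValueError(f"sequence length {n} exceeds max_len={max_len}")
    if n == 0:
        return FoldResult("", 0.0, ())

    # pairability and stack-energy lookups
    P = np.zeros((n, n), dtype=bool)
    SE = np.full((n, n), np.inf)  # stack of (i,j) on (i+1,j-1)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if _pairable(seq[i], seq[j]):
                P[i, j] = True
    for i in range(n - 1):
        for j in range(i + MIN_HAIRPIN_LOOP + 3, n):
            if P[i, j] and P[i + 1, j - 1]:
                SE[i, j] = _stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1])

    # W[i][j]: MFE of subsequence i..j (inclusive); padded so W[k+1][j]
    # reads 0 for empty ranges.  V[i][j]: MFE given (i,j) paired.
    W = np.zeros((n + 1, n + 1))
    V = np.full((n, n), np.inf)

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if P[i, j]:
                v = W[i + 1, j - 1]
                if np.isfinite(SE[i, j]) and np.isfinite(V[i + 1, j - 1]):
                    v = min(v, V[i + 1, j - 1] + SE[i, j])
                V[i, j] = v
            best = W[i + 1, j]
            ks = np.nonzero(P[i, i + MIN_HAIRPIN_LOOP + 1 : j + 1])[0]
            if ks.size:
                ks = ks + i + MIN_HAIRPIN_LOOP + 1
                cand = V[i, ks] + W[ks + 1, j]
                best = min(best, cand.min())
            W[i, j] = best

    pairs: list[tuple[int, int]] = []
    _trace_w(0, n - 1, seq, W, V, SE, pairs)
    struct = ["."] * n
    for i, j in pairs:
        struct[i] = "("
        struct[j] = ")"
    return FoldResult("".join(struct), float(W[0, n - 1]), tuple(sorted(pairs)))


def _trace_w(i: int, j: int, seq, W, V, SE, pairs) -> None:
    # energies are exact multiples of 1.0, so == comparisons are safe
    while i < j:
        if W[i, j] == W[i + 1, j]:
            i += 1
            continue
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if np.isfinite(V[i, k]) and V[i, k] + W[k + 1, j] == W[i, j]:
                _trace_v(i, k, seq, W, V, SE, pairs)
                i = k + 1
                break
        else:  # pragma: no cover - trace must always resolve
            raise AssertionError("traceback failed")


def _trace_v(i: int, j: int, seq, W, V, SE, pairs) -> None:
    while True:
        pairs.append((i, j))
        inner_stacked = (
            np.isfinite(SE[i, j])
            and np.isfinite(V[i + 1, j - 1])
            and V[i, j] == V[i + 1, j - 1] + SE[i, j]
        )
        if inner_stacked:
            i, j = i + 1, j - 1
            continue
        _trace_w(i + 1, j - 1, seq, W, V, SE, pairs)
        return


def duplex_free_energy(seq_a: str, seq_b: str, max_len: int = 40) -> float:
    """Minimum hybridization energy of two strands under the stack model.

    Both sequences are read 5'->3'; pairing is between ``seq_a`` and the
    reverse of ``seq_b`` (antiparallel duplex), G:U allowed.  Only
    intermolecular pairs form, without crossings; adjacent pairs stack
    with the same energies as :func:`fold_rna`.  Returns 0.0 when no
    pair can form.  Symmetric in its arguments.
    """
    a = norm_seq(seq_a)
    b = norm_seq(seq_b)
    check_alphabet(a)
    check_alphabet(b)
    if len(a) > max_len or len(b) > max_len:
        raise ValueError(f"duplex sequences must be <= {max_len} nt")
    c = b[::-1]
    n, m = len(a), len(c)
    if n == 0 or m == 0:
        return 0.0

    INF = float("inf")
    # D[i][j]: best energy of a duplex whose 3'-most pair is (a_i, c_j);
    # Mn[i][j]: min of D over (<=i, <=j), for non-adjacent continuation.
    D = [[INF] * m for _ in range(n)]
    Mn = [[INF] * m for _ in range(n)]
    best = 0.0
    for i in range(n):
        for j in range(m):
            if _pairable(a[i], c[j]):
                d = 0.0
                if i > 0 and j > 0:
                    prev = Mn[i - 1][j - 1]
                    if prev < d:
                        d = prev
                    if D[i - 1][j - 1] < INF:
                        stacked = D[i - 1][j - 1] + _stack_energy(
                            a[i - 1] + c[j - 1], a[i] + c[j]
                        )
                        if stacked < d:
                            d = stacked
                D[i][j] = d
                if d < best:
                    best = d
            mn = D[i][j]
            if i > 0:
                mn = min(mn, Mn[i - 1][j])
            if j > 0:
                mn = min(mn, Mn[i][j - 1])
            Mn[i][j] = mn
    return best
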