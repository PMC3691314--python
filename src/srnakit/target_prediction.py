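"""Seed-based miRNA target prediction in 3'UTR sequences.

A candidate site must clear three filters, applied in order:

1. perfect Watson-Crick seed match — the reverse complement of miRNA
   positions 2-8 (1-based from the 5' end) occurs contiguously in the
   UTR, no G:U allowed in the seed;
2. miRNA/site duplex minimum free energy strictly below -20 kcal/mol
   (on the package's stacking-model scale, G:U allowed);
3. seed-weighted local complementarity score strictly above 140.

The score is a Smith-Waterman-style local alignment of the miRNA
against the reverse-complemented site: match +5, G:U wobble +2,
mismatch -3, gap open -9, gap extend -4, with miRNA positions 2-8
contributing double weight — calibrated so a perfect complement of a
22-nt miRNA scores 145 while seedless partial duplexes fall short.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from srnakit.fold import duplex_free_energy
from srnakit.util import check_alphabet, norm_seq, revcomp

SEED_START, SEED_END = 1, 8  # 0-based half-open: miRNA positions 2-8
MAX_DUPLEX_ENERGY = -20.0
MIN_SCORE = 140.0

MATCH, WOBBLE, MISMATCH = 5.0, 2.0, -3.0
GAP_OPEN, GAP_EXTEND = -9.0, -4.0

#: after reverse-complementing the site, a G:U duplex wobble appears as
#: (miRNA, site-complement) = (G, A) or (T, C)
_WOBBLE_PAIRS = {("G", "A"), ("T", "C")}


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the UTR
    end: int
    seed_match: bool
    duplex_energy: float
    score: float

    def passes(self, max_energy: float = MAX_DUPLEX_ENERGY,
               min_score: float = MIN_SCORE) -> bool:
        return self.seed_match and self.duplex_energy < max_energy \
            and self.score > min_score

    @property
    def passed(self) -> bool:
        return self.passes()


def find_seed_matches(mirna: str, utr: str) -> list[int]:
    """UTR offsets where the reverse complement of the seed occurs.

    The seed is miRNA positions 2-8 (7 nt); matches are exact
    Watson-Crick reverse complements, so G:U is implicitly excluded.
    """
    m = norm_seq(mirna)
    if len(m) < SEED_END:
        raise ValueError("miRNA must be at least 8 nt")
    u = norm_seq(utr)
    target = revcomp(m[SEED_START:SEED_END])
    positions = []
    p = u.find(target)
    while p != -1:
        positions.append(p)
        p = u.find(target, p + 1)
    return positions


def complementarity_score(mirna: str, site: str) -> float:
    """Best local alignment score of the miRNA against the site.

    The site is reverse complemented first, so complementary stretches
    align as identities.  Substitution scores at miRNA positions 2-8
    count double (seed emphasis); gaps are affine.  The score is never
    negative (empty alignment scores 0).
    """
    a = norm_seq(mirna)
    b = revcomp(site)
    check_alphabet(a)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0

    def sub(i: int, j: int) -> float:
        ai, bj = a[i], b[j]
        if ai == bj:
            s = MATCH
        elif (ai, bj) in _WOBBLE_PAIRS:
            s = WOBBLE
        else:
            s = MISMATCH
        return 2 * s if SEED_START <= i < SEED_END else s

    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]   # best ending at (i,j)
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in miRNA
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in site
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + sub(i - 1, j - 1),
                E[i][j],
                F[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


def _site_window(seed_pos: int, mirna_len: int, utr_len: int) -> tuple[int, int]:
    """UTR span a full miRNA duplex around a seed match could occupy.

    The seed occupies [p, p+7); miRNA position 1 pairs just 3' of it and
    the miRNA 3' end extends 5'-ward on the UTR, with 4 nt of slack for
    bulges.
    """
    end = min(utr_len, seed_pos + SEED_END)
    start = max(0, end - (mirna_len + 4))
    return start, end


def predict_targets(
    mirnas: list[tuple[str, str]],
    utrs: list[tuple[str, str]],
    max_energy: float = MAX_DUPLEX_ENERGY,
    min_score: float = MIN_SCORE,
) -> tuple[list[TargetSite], pd.DataFrame]:
    """All candidate sites plus the per-gene table of passing targets.

    UTR headers follow ``gene|transcript``; the gene table lists genes
    with at least one site passing all three rules.  Sites are emitted
    with their per-rule diagnostics whether or not they pass.
    """
    sites: list[TargetSite] = []
    for mid, mseq in mirnas:
        m = norm_seq(mseq)
        for header, useq in utrs:
            u = norm_seq(useq)
            for p in find_seed_matches(m, u):
                start, end = _site_window(p, len(m), len(u))
                site_seq = u[start:end]
                energy = duplex_free_energy(m, site_seq)
                score = complementarity_score(m, site_seq)
                sites.append(TargetSite(mid, header, start, end, True, energy, score))

    rows = []
    for site in sites:
        if not site.passes(max_energy, min_score):
            continue
        gene = site.transcript_id.split("|")[0]
        rows.append({"gene": gene, "mirna_id": site.mirna_id,
                     "transcript": site.transcript_id,
                     "score": site.score, "energy": site.duplex_energy})
    if rows:
        df = pd.DataFrame(rows)
        gene_table = (
            df.groupby("gene")
            .agg(n_sites=("mirna_id", "size"),
                 mirnas=("mirna_id", lambda s: ",".join(sorted(set(s)))),
                 best_score=("score", "max"),
                 best_energy=("energy", "min"))
            .reset_index()
            .sort_values("gene")
            .reset_index(drop=True)
        )
    else:
        gene_table = pd.DataFrame(
            columns=["gene", "n_sites", "mirnas", "best_score", "best_energy"]
        )
    return sites, gene_table
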