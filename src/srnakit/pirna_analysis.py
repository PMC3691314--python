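"""piRNA-class characterization: catalog matching, base biases,
ping-pong overlap signature, abundance concentration, target classes.

The ping-pong amplification cycle leaves two diagnostic marks in a
piRNA library: primary piRNAs begin with U (1U) while responder piRNAs
carry A at position 10 (10A), and sense/antisense read pairs overlap by
exactly 10 nt at their 5' ends.  The overlap histogram's 10-nt bin is
summarized as a z-score against the other bins; position-wise base
fractions are weighted by read counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from srnakit.annotate import align_within
from srnakit.preprocess import CleanTag
from srnakit.util import hamming, norm_seq, revcomp

PIRNA_LENGTH_WINDOW = (24, 32)

#: published top-10 piRNA table: (id, sequence, length, counts,
#: most-abundant-tag sequence, tag length, tag counts)
TOP10_PIRNA_TABLE = (
    ("DQ571592.1", "AUCGGAACCUGCAGACACUCGUGGAGGCGUC", 31, 106965,
     "UCGGAACCUGCAGACACUCGUGGAGGCGUC", 30, 77387),
    ("DQ601822.1", "UAGGUGUGGAGCUUCCCGACCGGCUG", 26, 87638,
     "UAGGUGUGGAGCUUCCCGACCGGCU", 25, 68013),
    ("DQ572237.1", "UAUGAGCUUUAGAAUCAGUCAAGAGG", 26, 84463,
     "UAUGAGCUUUAGAAUCAGUCAAGAGG", 26, 83929),
    ("DQ576939.1", "UCGGAACCUGCAGACACUUGUGGAGGA", 27, 22571,
     "UCGGAACCUGCAGACACUUGUGGAGGA", 27, 22190),
    ("DQ588372.1", "UGGGAACGAGAAGACACUCAUGGAGG", 26, 22435,
     "UGGGAACGAGAAGACACUCAUGG", 23, 8034),
    ("DQ588346.1", "UGGGAACCAGAAGACACUCCUGGAGGAGUC", 30, 21052,
     "UGGGAACCAGAAGACACUCCUGGAGGAGUC", 30, 20043),
    ("DQ601651.1", "UAGGGACAAGAAGACACUCCUGCAGGAGUCGU", 32, 18391,
     "UAGGGACAAGAAGACACUCCUGCAGGAGUC", 30, 17859),
    ("DQ569941.1", "AAAGAAUGAAGAAGAACUUACUUGGCCU", 28, 16135,
     "AAGAAUGAAGAAGAACUUACUUGGCCU", 27, 6886),
    ("DQ588403.1", "UGGGAACGAGAAGACACUCGUGGAGGC", 27, 11005,
     "UGGGAACGAGAAGACACUCGUGGAGGC", 27, 11004),
    ("DQ577923.1", "UCUGCCUGAACUACACUGAGAAUGCAU", 27, 10495,
     "UCUGCCUGAACUACACUGAGAAUGCAU", 27, 10436),
)


def tag_length(sequence: str) -> int:
    """Length of a tag in nucleotides (U/T agnostic)."""
    return len(norm_seq(sequence))


@dataclass
class PirnaHit:
    catalog_id: str
    catalog_sequence: str
    matched_tags: list[CleanTag]
    most_abundant_tag: CleanTag
    total_count: int


def match_pirna_catalog(
    tags: list[CleanTag],
    catalog: list[tuple[str, str]],
    max_mismatch: int = 1,
) -> list[PirnaHit]:
    """Match tags into catalog entries (same orientation, <=1 mismatch).

    A tag matching several catalog entries is credited to its best one
    (fewest mismatches, then catalog order), so read totals are
    conserved.  Hits are sorted by total count descending.
    """
    assigned: dict[str, list[CleanTag]] = defaultdict(list)
    order = {cid: i for i, (cid, _) in enumerate(catalog)}
    for tag in tags:
        best: tuple[int, int, str] | None = None
        for cid, ref in catalog:
            refn = norm_seq(ref)
            off = align_within(tag.sequence, refn, max_mismatch)
            if off is None:
                continue
            mm = hamming(norm_seq(tag.sequence), refn[off : off + len(tag.sequence)])
            key = (mm, order[cid], cid)
            if best is None or key < best:
                best = key
        if best is not None:
            assigned[best[2]].append(tag)
    hits = []
    for cid, ref in catalog:
        matched = assigned.get(cid)
        if not matched:
            continue
        top = max(matched, key=lambda t: (t.count, t.sequence))
        hits.append(PirnaHit(cid, ref, matched, top, sum(t.count for t in matched)))
    hits.sort(key=lambda h: (-h.total_count, h.catalog_id))
    return hits


def positional_base_bias(
    tags: list[CleanTag] | list[tuple[str, int]],
    position: int,
) -> dict[str, float]:
    """Count-weighted base fractions at a 1-based 5' position."""
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    counts: dict[str, float] = defaultdict(float)
    total = 0
    for tag in tags:
        seq, c = (tag.sequence, tag.count) if isinstance(tag, CleanTag) else tag
        seq = norm_seq(seq)
        if len(seq) >= position:
            counts[seq[position - 1]] += c
            total += c
    if total == 0:
        raise ValueError(f"no tags of length >= {position}")
    return {b: counts[b] / total for b in sorted(counts)}


@dataclass
class PingPongSignature:
    overlap_histogram: dict[int, int]  # 5' overlap length (1..30) -> pairs
    z10: float | None
    pos1_u_fraction: float | None = None
    pos10_a_fraction: float | None = None

    @property
    def mode(self) -> int | None:
        h = self.overlap_histogram
        if not any(h.values()):
            return None
        return max(h, key=lambda d: (h[d], -d))


def _z10(hist: dict[int, int]) -> float | None:
    if not any(hist.values()):
        return None
    others = np.array([hist[d] for d in hist if d != 10], dtype=float)
    sd = others.std(ddof=1)
    diff = hist[10] - others.mean()
    if sd == 0:
        return float("inf") if diff > 0 else 0.0
    return float(diff / sd)


def pingpong_overlap_signature(
    plus_reads: list[tuple[str, int, int]],
    minus_reads: list[tuple[str, int, int]],
    max_overlap: int = 30,
) -> PingPongSignature:
    """Histogram of 5'-end overlaps between opposite-strand read pairs.

    Reads are (chromosome, start, end) genomic intervals, 0-based
    half-open, with an optional fourth element weighting the read (e.g.
    a collapsed tag's count); a plus read's 5' end is its start, a
    minus read's is end - 1.  For every overlapping opposite-strand pair the overlap
    length (minus 5' - plus 5' + 1) is recorded when it falls in
    1..max_overlap.  z10 compares the 10-nt bin against the rest; it is
    None when there are no pairs at all.
    """
    hist = {d: 0 for d in range(1, max_overlap + 1)}
    by_chrom_p: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    by_chrom_m: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for rec in plus_reads:
        c, s, e, *w = rec
        by_chrom_p[c].append((s, e, w[0] if w else 1))
    for rec in minus_reads:
        c, s, e, *w = rec
        by_chrom_m[c].append((s, e, w[0] if w else 1))
    for chrom, plus in by_chrom_p.items():
        minus = by_chrom_m.get(chrom)
        if not minus:
            continue
        ps = np.array([p[0] for p in plus])
        pe = np.array([p[1] for p in plus])
        wp = np.array([p[2] for p in plus])
        ms = np.array([m[0] for m in minus])
        me = np.array([m[1] for m in minus])
        wm = np.array([m[2] for m in minus])
        d = (me[None, :] - 1) - ps[:, None] + 1
        mask = (
            (ms[None, :] < pe[:, None]) & (ps[:, None] < me[None, :])
            & (d >= 1) & (d <= max_overlap)
        )
        weights = (wp[:, None] * wm[None, :])[mask]
        for v, w in zip(d[mask], weights):
            hist[int(v)] += int(w)
    return PingPongSignature(hist, _z10(hist))


def top_share(expression: pd.DataFrame | list[int], n: int,
              count_col: str = "reads") -> float:
    """Fraction of total reads carried by the top-n entries."""
    if isinstance(expression, pd.DataFrame):
        counts = expression[count_col].to_numpy(dtype=float)
    else:
        counts = np.asarray(expression, dtype=float)
    if counts.size == 0:
        raise ValueError("empty expression table")
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = np.sort(counts)[::-1]
    return float(counts[:n].sum() / counts.sum())


def classify_pirna_targets(
    pirnas: list[tuple[str, str]],
    labeled_references: list[tuple[str, str, str]],
    min_identity: float = 0.9,
) -> tuple[dict[str, float], dict[str, str]]:
    """Assign each piRNA to the class of its best antisense alignment.

    ``labeled_references`` rows are (class label, reference id,
    sequence).  A piRNA targets a reference when its full-length reverse
    complement aligns within the reference at >= min_identity; the best
    alignment (fewest mismatches, then input order) decides the class.
    Returns (class -> fraction over assigned piRNAs, piRNA id -> class);
    unassigned piRNAs are excluded from the fractions.
    """
    per_pirna: dict[str, str] = {}
    for pid, seq in pirnas:
        query = revcomp(seq)
        max_mm = int(len(query) * (1 - min_identity))
        best: tuple[int, int] | None = None
        best_cls = None
        for i, (cls, _rid, ref) in enumerate(labeled_references):
            off = align_within(query, ref, max_mm)
            if off is None:
                continue
            mm = hamming(query, norm_seq(ref)[off : off + len(query)])
            if best is None or (mm, i) < best:
                best = (mm, i)
                best_cls = cls
        per_pirna[pid] = best_cls if best_cls is not None else "unassigned"
    assigned = [c for c in per_pirna.values() if c != "unassigned"]
    fractions = {
        cls: assigned.count(cls) / len(assigned)
        for cls in sorted(set(assigned))
    } if assigned else {}
    return fractions, per_pirna
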