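"""Genome mapping and the small-RNA annotation cascade.

Unique tags are mapped to both strands of the genome allowing at most
one substitution (no indels), then assigned to exactly one category by a
priority cascade over reference catalogs: miRNA first, then piRNA, then
the housekeeping non-coding classes in summary-table row order (rRNA,
scRNA, snRNA, snoRNA, srpRNA, tRNA), then repeats, then mRNA, and
finally "unannotated" for tags matching nothing.  A catalog match is an
alignment of the whole tag within a reference sequence with at most one
mismatch, in the same orientation, after U->T normalization.

Mapping uses a k-mer seed table with a pigeonhole guarantee: for tags at
least twice the seed length, the two end seeds cannot both contain the
single allowed mismatch; shorter tags fall back to exact half-searches
over the chromosome strings.  Both routes return exactly the hits a
brute-force scan would.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from srnakit.preprocess import CleanTag
from srnakit.synthdata import SyntheticGenome
from srnakit.util import hamming, norm_seq, revcomp

#: cascade priority; the non-coding block keeps summary-table row order
CASCADE = (
    ("miRNA", "mirna"),
    ("piRNA", "pirna"),
    ("rRNA", "rrna"),
    ("scRNA", "scrna"),
    ("snRNA", "snrna"),
    ("snoRNA", "snorna"),
    ("srpRNA", "srprna"),
    ("tRNA", "trna"),
    ("repeat", "repeat"),
    ("mRNA", "utr"),
)

CATEGORIES = tuple(c for c, _ in CASCADE) + ("unannotated",)


@dataclass(frozen=True)
class MappingHit:
    chromosome: str
    start: int  # 0-based on the forward strand
    strand: str
    mismatches: int


@dataclass
class AnnotationRecord:
    tag: CleanTag
    hits: list[MappingHit]
    category: str


class GenomeIndex:
    """k-mer seed table over the forward strand of every chromosome."""

    def __init__(self, chromosomes: dict[str, str], k: int = 12):
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.k = k
        self.chromosomes = {c: norm_seq(s) for c, s in chromosomes.items()}
        self._table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.chromosomes.items():
            for i in range(len(seq) - k + 1):
                self._table[seq[i : i + k]].append((chrom, i))

    @classmethod
    def from_genome(cls, genome: SyntheticGenome, k: int = 12) -> "GenomeIndex":
        return cls(genome.chromosomes, k)

    def seed_positions(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, [])


def _verify(index: GenomeIndex, query: str, chrom: str, start: int,
            max_mismatch: int) -> int | None:
    seq = index.chromosomes[chrom]
    if start < 0 or start + len(query) > len(seq):
        return None
    mm = 0
    for a, b in zip(query, seq[start : start + len(query)]):
        if a != b:
            mm += 1
            if mm > max_mismatch:
                return None
    return mm


def _candidates(index: GenomeIndex, query: str, max_mismatch: int):
    """Candidate start positions covering every <=max_mismatch alignment."""
    L, k = len(query), index.k
    cands: set[tuple[str, int]] = set()
    if max_mismatch == 0 or L >= 2 * k:
        # end seeds: a single mismatch cannot hit both disjoint seeds
        for off in (0, L - k):
            for chrom, pos in index.seed_positions(query[off : off + k]):
                cands.add((chrom, pos - off))
    else:
        # short tags: exact search for each half (one half is mismatch-free)
        half = L // 2
        for off, part in ((0, query[:half]), (half, query[half:])):
            for chrom, seq in index.chromosomes.items():
                p = seq.find(part)
                while p != -1:
                    cands.add((chrom, p - off))
                    p = seq.find(part, p + 1)
    return cands


def map_tag(
    tag: CleanTag | str,
    index: GenomeIndex,
    max_mismatch: int = 1,
) -> list[MappingHit]:
    """All genomic alignments of the tag with <= max_mismatch substitutions.

    Both strands are searched; minus-strand hits report the forward-strand
    start of the window whose reverse complement matches the tag.  Tags
    containing N yield no hits.
    """
    seq = norm_seq(tag.sequence if isinstance(tag, CleanTag) else tag)
    if "N" in seq or len(seq) < index.k // 2:
        return []
    hits: list[MappingHit] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for chrom, start in _candidates(index, query, max_mismatch):
            mm = _verify(index, query, chrom, start, max_mismatch)
            if mm is not None:
                hits.append(MappingHit(chrom, start, strand, mm))
    hits.sort(key=lambda h: (h.chromosome, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# catalog matching


def align_within(tag_seq: str, ref_seq: str, max_mismatch: int = 1) -> int | None:
    """Offset of the best alignment of the tag inside the reference.

    Same orientation only; the whole tag must fit.  Returns None when no
    offset has <= max_mismatch substitutions.  Uses exact half-searches
    (pigeonhole) so the scan stays fast on long references.
    """
    t = norm_seq(tag_seq)
    r = norm_seq(ref_seq)
    L = len(t)
    if L > len(r):
        return None
    if max_mismatch == 0:
        p = r.find(t)
        return p if p != -1 else None
    best: tuple[int, int] | None = None  # (mismatches, offset)
    half = L // 2
    seen: set[int] = set()
    for off, part in ((0, t[:half]), (half, t[half:])):
        p = r.find(part)
        while p != -1:
            start = p - off
            if 0 <= start <= len(r) - L and start not in seen:
                seen.add(start)
                mm = hamming(t, r[start : start + L])
                if mm <= max_mismatch and (best is None or (mm, start) < best):
                    best = (mm, start)
            p = r.find(part, p + 1)
    return best[1] if best else None


def classify_tag(
    tag: CleanTag | str,
    hits: list[MappingHit],
    references: dict[str, list[tuple[str, str]]],
    max_mismatch: int = 1,
) -> str:
    """First matching category in cascade order; 'unannotated' otherwise."""
    seq = tag.sequence if isinstance(tag, CleanTag) else tag
    for category, key in CASCADE:
        for _, ref in references.get(key, ()):
            if align_within(seq, ref, max_mismatch) is not None:
                return category
    return "unannotated"


def annotate_tags(
    tags: list[CleanTag],
    index: GenomeIndex,
    references: dict[str, list[tuple[str, str]]],
    max_mismatch: int = 1,
) -> list[AnnotationRecord]:
    """Map and classify every tag (pipeline convenience)."""
    out = []
    for t in tags:
        hits = map_tag(t, index, max_mismatch)
        out.append(AnnotationRecord(t, hits, classify_tag(t, hits, references, max_mismatch)))
    return out


# ---------------------------------------------------------------------------
# summaries


def summarize_categories(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Category table: unique tags, total reads, and their percentages."""
    rows = []
    n_tags = len(records)
    n_reads = sum(r.tag.count for r in records)
    for cat in CATEGORIES:
        recs = [r for r in records if r.category == cat]
        u = len(recs)
        reads = sum(r.tag.count for r in recs)
        rows.append({
            "Category": cat,
            "NO. of Unique tags": u,
            "Percent (tags)": 100.0 * u / n_tags if n_tags else 0.0,
            "Total reads": reads,
            "Percent (reads)": 100.0 * reads / n_reads if n_reads else 0.0,
        })
    rows.append({
        "Category": "Total",
        "NO. of Unique tags": n_tags,
        "Percent (tags)": 100.0 if n_tags else 0.0,
        "Total reads": n_reads,
        "Percent (reads)": 100.0 if n_reads else 0.0,
    })
    return pd.DataFrame(rows)


def chromosome_distribution(records: list[AnnotationRecord]) -> dict[str, float]:
    """Read counts per chromosome with fractional multi-hit assignment.

    A tag hitting h locations contributes count/h to each, so the total
    over chromosomes equals the total mapped read count exactly.
    """
    dist: dict[str, float] = defaultdict(float)
    for rec in records:
        if not rec.hits:
            continue
        share = rec.tag.count / len(rec.hits)
        for hit in rec.hits:
            dist[hit.chromosome] += share
    return dict(dist)


def quantify_known_mirnas(
    records: list[AnnotationRecord],
    mirna_catalog: list[tuple[str, str]],
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Read counts per detected catalog miRNA (absent = not detected)."""
    counts: dict[str, int] = defaultdict(int)
    for rec in records:
        if rec.category != "miRNA":
            continue
        best: tuple[int, str] | None = None
        for mid, ref in mirna_catalog:
            off = align_within(rec.tag.sequence, ref, max_mismatch)
            if off is not None:
                mm = hamming(
                    norm_seq(rec.tag.sequence),
                    norm_seq(ref)[off : off + len(rec.tag.sequence)],
                )
                if best is None or (mm, mid) < best:
                    best = (mm, mid)
        if best is not None:
            counts[best[1]] += rec.tag.count
    df = pd.DataFrame(
        [{"mirna_id": mid, "reads": c} for mid, c in counts.items()]
    )
    if df.empty:
        return pd.DataFrame(columns=["mirna_id", "reads"])
    return df.sort_values(
        ["reads", "mirna_id"], ascending=[False, True]
    ).reset_index(drop=True)


def top_n(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top n rows by reads, ties broken by name (deterministic)."""
    return table.head(n).copy()


def detect_editing(
    records: list[AnnotationRecord],
    mirna_catalog: list[tuple[str, str]],
    min_fraction: float = 0.10,
    end_exclusion: int = 2,
    max_mismatch: int = 1,
) -> list[tuple[str, int, float]]:
    """Candidate editing events: internal positions where single-mismatch
    reads exceed ``min_fraction`` of the reads covering that position.

    Pools exact and single-mismatch miRNA tags per catalog entry; the
    first and last ``end_exclusion`` reference positions are excluded
    because 5'/3' end heterogeneity confounds terminal mismatches.
    Positions are 0-based on the catalog sequence.
    """
    results: list[tuple[str, int, float]] = []
    for mid, ref in mirna_catalog:
        refn = norm_seq(ref)
        cover = defaultdict(int)
        mismatch = defaultdict(int)
        for rec in records:
            if rec.category != "miRNA":
                continue
            off = align_within(rec.tag.sequence, refn, max_mismatch)
            if off is None:
                continue
            t = norm_seq(rec.tag.sequence)
            for i, (a, b) in enumerate(zip(t, refn[off : off + len(t)])):
                pos = off + i
                cover[pos] += rec.tag.count
                if a != b:
                    mismatch[pos] += rec.tag.count
        for pos in sorted(mismatch):
            if pos < end_exclusion or pos >= len(refn) - end_exclusion:
                continue
            frac = mismatch[pos] / cover[pos]
            if frac > min_fraction:
                results.append((mid, pos, frac))
    return results
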