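"""Novel miRNA discovery from unannotated tags, hairpin-rule style.

Abundant unannotated tags are excised with genomic flanks, folded with
the package's stacking-energy engine, and kept only when the candidate
satisfies all five acceptance rules:

1. mature length >= 18 nt,
2. mature length <= 26 nt,
3. precursor fold energy <= -18 kcal/mol (on this model's scale),
4. spacing between mature and star arms <= 35 nt,
5. largest bulge in the mature/star duplex <= 4 nt,

plus the abundance cutoff (>= 45 reads by default).  The star arm is
the region pairing with at least 60% of mature bases; a candidate with
no such arm fails outright.  All thresholds are inclusive on the
passing side and exposed as parameters.  The 5'-terminal nucleotide of
each accepted mature is reported (U/A starts are common) but never used
as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from srnakit.annotate import GenomeIndex, MappingHit, map_tag
from srnakit.fold import FoldResult, fold_rna
from srnakit.preprocess import CleanTag
from srnakit.synthdata import SyntheticGenome
from srnakit.util import revcomp

MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 26
MAX_PRECURSOR_ENERGY = -18.0
MAX_STAR_SPACING = 35
MAX_DUPLEX_BULGE = 4
MIN_READ_COUNT = 45
MIN_STAR_PAIRING = 0.6

RULE_NAMES = ("mature_length", "energy", "spacing", "bulge", "count")


@dataclass
class HairpinCandidate:
    """One excised window evaluated against the hairpin rules."""

    chrom: str
    start: int
    end: int
    strand: str
    precursor: str
    fold: FoldResult
    mature: str
    count: int
    mature_offset: int
    star: str | None = None
    star_span: tuple[int, int] | None = None
    spacing: int = -1
    max_bulge: int = -1
    star_found: bool = False
    passed_rules: dict[str, bool] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.star_found and all(self.passed_rules.values())


def excise_precursor_windows(
    tag: CleanTag | str,
    hits: list[MappingHit],
    genome: SyntheticGenome,
    flank: int = 100,
) -> list[tuple[MappingHit, int, int, str]]:
    """Candidate precursor windows around each genomic hit.

    For a hit spanning [s, e) two windows are excised on the hit strand,
    [s - flank, e + 20) and [s - 20, e + flank), covering a mature arm on
    either side of the loop; both are clipped to chromosome bounds.
    Returns (hit, window_start, window_end, window_sequence) tuples with
    the sequence read 5'->3' on the hit strand.
    """
    seq = tag.sequence if isinstance(tag, CleanTag) else tag
    L = len(seq)
    out = []
    for hit in hits:
        chrom_seq = genome.chromosomes[hit.chromosome]
        s, e = hit.start, hit.start + L
        for ws, we in ((s - flank, e + 20), (s - 20, e + flank)):
            ws, we = max(0, ws), min(len(chrom_seq), we)
            window = chrom_seq[ws:we]
            if hit.strand == "-":
                window = revcomp(window)
            out.append((hit, ws, we, window))
    return out


def _longest_unpaired_run(pt, lo: int, hi: int) -> int:
    """Longest run of unpaired positions strictly inside [lo, hi]."""
    run = best = 0
    for i in range(lo, hi + 1):
        if pt[i] is None:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def evaluate_candidate(
    window: str,
    tag: CleanTag | str,
    fold: FoldResult | None = None,
    count: int | None = None,
    mature_offset: int | None = None,
    locus: tuple[str, int, int, str] = ("", 0, 0, "+"),
    min_count: int = MIN_READ_COUNT,
    max_energy: float = MAX_PRECURSOR_ENERGY,
) -> HairpinCandidate:
    """Score one window against the five hairpin rules."""
    seq = tag.sequence if isinstance(tag, CleanTag) else tag
    if count is None:
        count = tag.count if isinstance(tag, CleanTag) else 1
    if mature_offset is None:
        mature_offset = window.find(seq)
    if mature_offset < 0 or window[mature_offset : mature_offset + len(seq)] != seq:
        raise ValueError("mature tag not found in window")
    if fold is None:
        fold = fold_rna(window)
    cand = HairpinCandidate(
        chrom=locus[0], start=locus[1], end=locus[2], strand=locus[3],
        precursor=window, fold=fold, mature=seq, count=count,
        mature_offset=mature_offset,
    )
    L = len(seq)
    lo, hi = mature_offset, mature_offset + L - 1
    pt = fold.pair_table()
    partners = [
        pt[i] for i in range(lo, hi + 1)
        if pt[i] is not None and not lo <= pt[i] <= hi
    ]
    cand.star_found = len(partners) / L >= MIN_STAR_PAIRING
    if cand.star_found:
        smin, smax = min(partners), max(partners)
        cand.star = window[smin : smax + 1]
        cand.star_span = (smin, smax)
        cand.spacing = (smin - hi - 1) if smin > hi else (lo - smax - 1)
        paired_m = [i for i in range(lo, hi + 1) if pt[i] is not None]
        cand.max_bulge = max(
            _longest_unpaired_run(pt, min(paired_m), max(paired_m)),
            _longest_unpaired_run(pt, smin, smax),
        )
    cand.passed_rules = {
        "mature_length": MIN_MATURE_LEN <= L <= MAX_MATURE_LEN,
        "energy": fold.energy <= max_energy,
        "spacing": cand.star_found and 0 <= cand.spacing <= MAX_STAR_SPACING,
        "bulge": cand.star_found and cand.max_bulge <= MAX_DUPLEX_BULGE,
        "count": count >= min_count,
    }
    return cand


def predict_novel_mirnas(
    tags: list[CleanTag],
    index: GenomeIndex,
    genome: SyntheticGenome,
    min_count: int = MIN_READ_COUNT,
    flank: int = 100,
    max_energy: float = MAX_PRECURSOR_ENERGY,
    max_mismatch: int = 0,
) -> tuple[list[HairpinCandidate], pd.DataFrame]:
    """Run excision + folding + rule evaluation over abundant tags.

    Candidates sharing an overlapping precursor locus are deduplicated,
    keeping the highest mature count.  The companion table reports, per
    accepted candidate, read counts of 5'-shifted and 3'-shifted mature
    variants found among *all* supplied tags (end heterogeneity).
    """
    accepted: list[HairpinCandidate] = []
    for tag in tags:
        if tag.count < min_count:
            continue
        hits = map_tag(tag, index, max_mismatch)
        for hit, ws, we, window in excise_precursor_windows(tag, hits, genome, flank):
            try:
                cand = evaluate_candidate(
                    window, tag, count=tag.count,
                    locus=(hit.chromosome, ws, we, hit.strand),
                    min_count=min_count, max_energy=max_energy,
                )
            except ValueError:
                continue  # window excised around a mismatched hit
            if cand.accepted:
                accepted.append(cand)

    # deduplicate overlapping loci (strand-agnostic: a palindromic stem
    # is found from both arms), highest mature count wins
    accepted.sort(key=lambda c: (-c.count, c.chrom, c.start, c.strand))
    kept: list[HairpinCandidate] = []
    for cand in accepted:
        clash = any(
            k.chrom == cand.chrom and cand.start < k.end and k.start < cand.end
            for k in kept
        )
        if not clash:
            kept.append(cand)

    rows = []
    for i, cand in enumerate(kept):
        five = three = 0
        for tag in tags:
            if tag.sequence == cand.mature:
                continue
            off = cand.precursor.find(tag.sequence)
            if off < 0 or abs(off - cand.mature_offset) > 3:
                continue
            if off != cand.mature_offset:
                five += tag.count
            else:
                three += tag.count
        rows.append({
            "candidate": f"cand{i + 1:03d}",
            "chrom": cand.chrom, "start": cand.start, "end": cand.end,
            "strand": cand.strand, "mature": cand.mature,
            "first_nt": cand.mature[0].replace("T", "U"),
            "mature_reads": cand.count,
            "five_prime_variant_reads": five,
            "three_prime_variant_reads": three,
            "energy": cand.fold.energy,
            "spacing": cand.spacing, "max_bulge": cand.max_bulge,
        })
    het = pd.DataFrame(
        rows,
        columns=["candidate", "chrom", "start", "end", "strand", "mature",
                 "first_nt", "mature_reads", "five_prime_variant_reads",
                 "three_prime_variant_reads", "energy", "spacing", "max_bulge"],
    )
    return kept, het
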