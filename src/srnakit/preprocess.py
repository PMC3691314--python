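"""Raw-read cleaning and unique-tag collapsing.

Filters are applied in a fixed order — low quality, adapter stripping,
N rejection, length window — and every input read is accounted for
exactly once, either as a clean insert or under the first rejection
reason it triggered.  Quality scores decode as Q = ASCII - 64; a read is
low quality when the fraction of bases with Q below the threshold
(default 10) exceeds ``max_bad_fraction`` (default 0: a single bad base
rejects).  Clean inserts must fall in the 11-33 nt window; they are then
collapsed to unique tags carrying read counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from srnakit.synthdata import ADAPTER3, ADAPTER5, QUALITY_OFFSET, RawRead

LENGTH_WINDOW = (11, 33)

REJECT_LOW_QUALITY = "low_quality"
REJECT_ADAPTER_DIMER = "adapter_dimer"
REJECT_NO_3PRIME = "no_3prime_adapter"
REJECT_N = "contains_n"
REJECT_LENGTH = "length_window"


@dataclass(frozen=True)
class CleanTag:
    """A unique insert sequence with its collapsed read count."""

    sequence: str
    count: int


@dataclass
class CleaningSummary:
    total_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.total_reads != self.clean_reads + sum(self.rejected_by_reason.values()):
            raise AssertionError("read accounting does not balance")


class Rejection:
    """Sentinel return value from adapter stripping (a value, not an error)."""

    __slots__ = ("reason",)

    def __init__(self, reason: str):
        self.reason = reason

    def __repr__(self):
        return f"Rejection({self.reason!r})"

    def __eq__(self, other):
        return isinstance(other, Rejection) and other.reason == self.reason


def strip_adapters(
    read: RawRead | str,
    adapter5: str = ADAPTER5,
    adapter3: str = ADAPTER3,
    min_overlap: int = 6,
) -> str | Rejection:
    """Remove a leading 5'-adapter fragment and truncate at the 3' adapter.

    The longest suffix of ``adapter5`` (>= ``min_overlap``) matching a
    read prefix is removed; the read is then truncated at the leftmost
    position where a prefix of ``adapter3`` (>= ``min_overlap``, exact
    match) begins.  An empty remaining insert is an adapter dimer; a read
    with no detectable 3' adapter is rejected, since a short insert in a
    longer read must run into the adapter.
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    seq = read.sequence if isinstance(read, RawRead) else read
    for k in range(min(len(adapter5), len(seq)), min_overlap - 1, -1):
        if seq.startswith(adapter5[-k:]):
            seq = seq[k:]
            break
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        k = min(len(adapter3), n - p)
        if seq[p : p + k] == adapter3[:k]:
            if p == 0:
                return Rejection(REJECT_ADAPTER_DIMER)
            return seq[:p]
    return Rejection(REJECT_NO_3PRIME)


def is_low_quality(
    read: RawRead,
    q_threshold: int = 10,
    max_bad_fraction: float = 0.0,
) -> bool:
    """True iff the fraction of bases with Q < q_threshold exceeds the cap."""
    scores = read.scores()  # raises on length mismatch at construction
    if not scores:
        return False
    bad = sum(q < q_threshold for q in scores)
    return bad / len(scores) > max_bad_fraction


def clean_reads(
    reads: list[RawRead],
    adapter5: str = ADAPTER5,
    adapter3: str = ADAPTER3,
    length_window: tuple[int, int] = LENGTH_WINDOW,
    q_threshold: int = 10,
    max_bad_fraction: float = 0.0,
    min_overlap: int = 6,
) -> tuple[list[str], CleaningSummary]:
    """Run the full cleaning cascade; returns clean inserts + accounting."""
    lo, hi = length_window
    summary = CleaningSummary(total_reads=len(reads))
    rejected = Counter()
    inserts: list[str] = []
    for read in reads:
        if is_low_quality(read, q_threshold, max_bad_fraction):
            rejected[REJECT_LOW_QUALITY] += 1
            continue
        result = strip_adapters(read, adapter5, adapter3, min_overlap)
        if isinstance(result, Rejection):
            rejected[result.reason] += 1
            continue
        if "N" in result:
            rejected[REJECT_N] += 1
            continue
        if not lo <= len(result) <= hi:
            rejected[REJECT_LENGTH] += 1
            continue
        inserts.append(result)
    summary.clean_reads = len(inserts)
    summary.rejected_by_reason = dict(rejected)
    summary.check()
    return inserts, summary


def collapse_to_tags(inserts: list[str]) -> list[CleanTag]:
    """One tag per distinct insert, sorted by count desc then sequence."""
    counts = Counter(inserts)
    return [
        CleanTag(seq, c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
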