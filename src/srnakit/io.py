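"""FASTA/FASTQ reading and writing (Biopython-backed).

FASTQ uses the offset-64 encoding ("fastq-illumina" in Biopython),
matching the Q = ASCII - 64 quality convention of the cleaning stage.
Tag FASTA headers follow the ``tag<rank>_x<count>`` convention.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from srnakit.preprocess import CleanTag
from srnakit.synthdata import QUALITY_OFFSET, RawRead


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: list[RawRead], path: str | Path) -> None:
    def _records():
        for i, read in enumerate(reads):
            rec = SeqRecord(Seq(read.sequence), id=f"read{i + 1}", description="")
            rec.letter_annotations["phred_quality"] = read.scores()
            yield rec

    SeqIO.write(_records(), str(path), "fastq-illumina")


def read_fastq(path: str | Path) -> list[RawRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq-illumina"):
        qual = "".join(
            chr(q + QUALITY_OFFSET) for q in rec.letter_annotations["phred_quality"]
        )
        out.append(RawRead(str(rec.seq), qual))
    return out


def write_tags_fasta(tags: list[CleanTag], path: str | Path) -> None:
    write_fasta(
        [(f"tag{i + 1}_x{t.count}", t.sequence) for i, t in enumerate(tags)], path
    )


def read_tags_fasta(path: str | Path) -> list[CleanTag]:
    tags = []
    for name, seq in read_fasta(path):
        count = int(name.rsplit("_x", 1)[1]) if "_x" in name else 1
        tags.append(CleanTag(seq, count))
    return tags
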