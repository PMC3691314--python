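"""Seeded synthetic small RNA-seq fixtures.

Builds, from one integer seed, everything a testis-style small-RNA
profiling run needs: a multi-chromosome genome with planted features
(miRNA hairpins, piRNA loci including ping-pong pairs, housekeeping
ncRNAs, repeats/retrotransposons, mRNA 3'UTRs), reference FASTA catalogs
sliced from those features, gene->GO and gene->pathway maps with one
deliberately enriched term each, a truth table recording what was
planted, and an adapter-flanked offset-64 FASTQ read library.

Statistical structure the generator emulates (and downstream stages
assume):

* insert lengths with a 22-nt miRNA mode and a 26-27 nt piRNA mode;
* hairpin loci whose excised windows fold into strong stems under the
  package's stacking energy model, with 5'/3' end heterogeneity in the
  read stacks (3'-shifted variants more common than 5'-shifted);
* ping-pong piRNA pairs: sense reads starting with U, antisense reads
  with A at position 10, 5' ends overlapping by exactly 10 nt;
* a piRNA abundance profile whose top-10 entries carry 61% of piRNA
  reads, weighted like the published top-10 table;
* contamination as adapter-dimer reads and N-containing reads, plus a
  separate low-quality (Q < 10) read fraction;
* miRNA editing: a fixed internal position where a set fraction of a
  miRNA's reads carry a substitution.

Decoy hairpin loci (for discovery specificity checks) and the
loops/buffers around planted stems are drawn from an {A,C} alphabet, in
which no canonical base pair can form, so decoy windows fold to energy 0
and planted windows fold to exactly the designed stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from srnakit.util import norm_seq, revcomp

ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
QUALITY_OFFSET = 64

#: published top-10 piRNA read counts, used as relative weights for the
#: top of the synthetic piRNA abundance profile
TOP10_PIRNA_WEIGHTS = (
    106965, 87638, 84463, 22571, 22435, 21052, 18391, 16135, 11005, 10495,
)

FEATURE_CLASSES = (
    "mirna_hairpin", "pirna_locus", "rrna", "trna", "snrna", "snorna",
    "scrna", "srprna", "repeat", "retrotransposon:LINE1",
    "retrotransposon:LTR", "mrna_utr",
)


class CapacityError(ValueError):
    """Requested features do not fit in the configured chromosomes."""


@dataclass(frozen=True)
class RawRead:
    """One sequencer read: bases over {A,C,G,T,N} plus offset-64 qualities.

    The per-base score is Q = ord(char) - 64.
    """

    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence/quality length mismatch")

    def scores(self) -> list[int]:
        return [ord(c) - QUALITY_OFFSET for c in self.quality]


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    feature_class: str
    feature_id: str


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    feature_track: list[Feature]

    def feature_seq(self, feat: Feature) -> str:
        s = self.chromosomes[feat.chrom][feat.start : feat.end]
        return revcomp(s) if feat.strand == "-" else s


@dataclass(frozen=True)
class PlantedMirna:
    mirna_id: str
    mature: str
    star: str
    precursor: str
    locus: Feature
    expected_count: int
    is_known: bool


@dataclass(frozen=True)
class PlantedPirna:
    pirna_id: str
    sequence: str
    locus: Feature
    strand: str
    is_pingpong_responder: bool
    expected_count: int


@dataclass(frozen=True)
class PlantedOther:
    entry_id: str
    category: str  # cascade category the insert should receive
    insert: str
    expected_count: int


@dataclass(frozen=True)
class DecoyLocus:
    decoy_id: str
    sequence: str
    locus: Feature  # recorded for bookkeeping; not in the feature track
    expected_count: int


@dataclass
class TruthTable:
    planted_mirnas: list[PlantedMirna] = field(default_factory=list)
    planted_pirnas: list[PlantedPirna] = field(default_factory=list)
    planted_edits: list[tuple[str, int, float]] = field(default_factory=list)
    planted_other: list[PlantedOther] = field(default_factory=list)
    decoy_loci: list[DecoyLocus] = field(default_factory=list)
    #: piRNA id -> target class whose features carry its antisense copy
    pirna_target_classes: dict[str, str] = field(default_factory=dict)

    def entries(self) -> list[tuple[str, str, int]]:
        """(entry_id, insert sequence, expected count) over everything read-generating."""
        out = [(m.mirna_id, m.mature, m.expected_count) for m in self.planted_mirnas]
        out += [(p.pirna_id, p.sequence, p.expected_count) for p in self.planted_pirnas]
        out += [(o.entry_id, o.insert, o.expected_count) for o in self.planted_other]
        out += [(d.decoy_id, d.sequence, d.expected_count) for d in self.decoy_loci]
        return out


@dataclass
class SynthConfig:
    """Study conditions for the synthetic fixture (defaults documented
    in docs/methods.md)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 25_000 for i in range(1, 5)}
    )
    # hairpins
    n_known_mirnas: int = 10
    n_novel_mirnas: int = 5
    n_decoy_loci: int = 4
    mirna_length: int = 22
    hairpin_loop: int = 8
    hairpin_buffer: int = 40
    # piRNA
    n_pirna_loci: int = 30
    n_pingpong_loci: int = 2
    pingpong_locus_length: int = 600
    pirna_top10_share: float = 0.61
    pirna_1u_bias: float = 0.9
    total_pirna_reads: int = 3000
    # class mix of planted piRNA targets (antisense copies embedded in
    # the corresponding features); the remainder stays unassigned
    pirna_target_mix: dict[str, float] = field(
        default_factory=lambda: {
            "retrotransposon:LINE1": 0.69,
            "retrotransposon:LTR": 0.06,
            "repeat": 0.15,
            "mRNA": 0.10,
        }
    )
    # other classes: class -> (n features, feature length, total reads)
    other_classes: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {
            "rrna": (3, 120, 400),
            "trna": (4, 75, 150),
            "snrna": (3, 95, 120),
            "snorna": (3, 80, 80),
            "scrna": (2, 100, 40),
            "srprna": (2, 110, 20),
            "repeat": (4, 200, 250),
            "retrotransposon:LINE1": (4, 300, 0),
            "retrotransposon:LTR": (2, 250, 0),
        }
    )
    # UTRs / annotation maps
    n_utrs: int = 30
    utr_length: int = 400
    n_target_genes: int = 10
    n_go_terms: int = 12
    n_pathways: int = 8
    # expression
    known_mirna_counts: tuple[int, ...] = (
        1200, 900, 700, 550, 420, 320, 240, 180, 130, 90,
    )
    novel_mirna_counts: tuple[int, ...] = (350, 260, 200, 150, 100)
    decoy_counts: int = 120
    mrna_reads: int = 120
    # editing
    n_edits: int = 2
    edit_position: int = 10  # 0-based, interior
    edit_fraction: float = 0.15
    # library; long enough that a 33-nt insert still leaves a 6-nt
    # (minimum-overlap) 3'-adapter stub for the trimming stage
    read_length: int = 40
    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    contamination_fraction: float = 0.05
    low_quality_fraction: float = 0.03
    p_5prime_adapter: float = 0.10
    het_3p_fraction: float = 0.18
    het_5p_fraction: float = 0.07


# ---------------------------------------------------------------------------
# sequence helpers

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_AC = np.frombuffer(b"AC", dtype="S1")


def _rand_seq(rng: np.random.Generator, n: int, ac_only: bool = False) -> str:
    pool = _AC if ac_only else _BASES
    return rng.choice(pool, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, pos: int, avoid: str | None = None) -> str:
    avoid_set = {seq[pos]} | ({avoid} if avoid else set())
    choices = [b for b in "ACGT" if b not in avoid_set]
    new = choices[int(rng.integers(len(choices)))]
    return seq[:pos] + new + seq[pos + 1 :]


# ---------------------------------------------------------------------------
# reference generation


class _Plan:
    """One placeable chunk of chromosome content."""

    def __init__(self, content, feature_class, feature_id, strand, span):
        self.content = content
        self.feature_class = feature_class
        self.feature_id = feature_id
        self.strand = strand
        self.span = span  # (offset, length) of the feature within content


@dataclass
class ReferenceBundle:
    genome: SyntheticGenome
    references: dict[str, list[tuple[str, str]]]  # catalog -> [(id, seq)]
    go_map: dict[str, list[str]]
    pathway_map: dict[str, list[str]]
    truth: TruthTable
    config: SynthConfig
    #: (class label, id, sequence) for piRNA target classification
    labeled_repeats: list[tuple[str, str, str]] = field(default_factory=list)


def generate_references(seed: int, config: SynthConfig | None = None) -> ReferenceBundle:
    """Deterministically build genome, catalogs, annotation maps and truth."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    plans: list[_Plan] = []

    # --- miRNA hairpins: buffer + mature + AC-loop + revcomp(mature) + buffer
    n_hp = cfg.n_known_mirnas + cfg.n_novel_mirnas
    matures: list[str] = []
    seen: set[str] = set()
    while len(matures) < n_hp:
        m = _rand_seq(rng, cfg.mirna_length)
        if m not in seen and "AAAA" not in m:  # avoid homopolymer ends
            seen.add(m)
            matures.append(m)
    for i, mature in enumerate(matures):
        known = i < cfg.n_known_mirnas
        mid = f"{'mir' if known else 'nov'}{i + 1:03d}"
        star = revcomp(mature)
        loop = _rand_seq(rng, cfg.hairpin_loop, ac_only=True)
        precursor = mature + loop + star
        buf5 = _rand_seq(rng, cfg.hairpin_buffer, ac_only=True)
        buf3 = _rand_seq(rng, cfg.hairpin_buffer, ac_only=True)
        content = buf5 + precursor + buf3
        counts = cfg.known_mirna_counts if known else cfg.novel_mirna_counts
        idx = i if known else i - cfg.n_known_mirnas
        count = counts[idx % len(counts)]
        plans.append(
            _Plan(content, "mirna_hairpin", mid, "+",
                  (cfg.hairpin_buffer, len(precursor)))
        )
        truth.planted_mirnas.append(
            PlantedMirna(mid, mature, star, precursor, None, count, known)  # type: ignore[arg-type]
        )

    # --- decoy loci: {A,C} content cannot pair, windows fold to energy 0
    for i in range(cfg.n_decoy_loci):
        dseq = _rand_seq(rng, 26, ac_only=True)
        content = _rand_seq(rng, 120, ac_only=True) + dseq + _rand_seq(rng, 120, ac_only=True)
        plans.append(_Plan(content, None, f"dec{i + 1:03d}", "+", (120, 26)))
        truth.decoy_loci.append(DecoyLocus(f"dec{i + 1:03d}", dseq, None, cfg.decoy_counts))  # type: ignore[arg-type]

    # --- piRNA loci (simple) with lengths peaking at 26-27 nt
    pirna_lengths = rng.choice(
        [25, 26, 27, 28, 29, 30, 31],
        size=cfg.n_pirna_loci,
        p=[0.03, 0.35, 0.35, 0.10, 0.07, 0.05, 0.05],
    )
    n_top = min(10, cfg.n_pirna_loci)
    w = np.array(TOP10_PIRNA_WEIGHTS[:n_top], dtype=float)
    top_counts = np.round(
        w / w.sum() * cfg.pirna_top10_share * cfg.total_pirna_reads
    ).astype(int)
    n_rest = cfg.n_pirna_loci - n_top + 2 * cfg.n_pingpong_loci
    rest_each = max(
        1,
        int(round((1 - cfg.pirna_top10_share) * cfg.total_pirna_reads / max(n_rest, 1))),
    )
    for i in range(cfg.n_pirna_loci):
        L = int(pirna_lengths[i])
        seq = _rand_seq(rng, L)
        if rng.random() < cfg.pirna_1u_bias:
            seq = "T" + seq[1:]
        elif seq[0] == "T":
            seq = _mutate(rng, seq, 0)
        strand = "+" if rng.random() < 0.5 else "-"
        pid = f"pi{i + 1:04d}"
        count = int(top_counts[i]) if i < n_top else rest_each
        plans.append(_Plan(seq if strand == "+" else revcomp(seq),
                           "pirna_locus", pid, strand, (0, L)))
        truth.planted_pirnas.append(
            PlantedPirna(pid, seq, None, strand, False, count)  # type: ignore[arg-type]
        )

    # --- assign target classes to the simple piRNA loci; their antisense
    # copies are embedded into repeat/retrotransposon/UTR features below
    embed_queues: dict[str, list[str]] = {c: [] for c in cfg.pirna_target_mix}
    perm = rng.permutation(cfg.n_pirna_loci)
    cursor = 0
    for cls, frac in cfg.pirna_target_mix.items():
        take = int(round(frac * cfg.n_pirna_loci))
        for j in perm[cursor : cursor + take]:
            p = truth.planted_pirnas[int(j)]
            truth.pirna_target_classes[p.pirna_id] = cls
            embed_queues[cls].append(revcomp(p.sequence))
        cursor += take
    for p in truth.planted_pirnas:
        truth.pirna_target_classes.setdefault(p.pirna_id, "unassigned")

    # --- ping-pong loci: primary (+, 1U) and responder (-, 10A) pairs
    for i in range(cfg.n_pingpong_loci):
        L = cfg.pingpong_locus_length
        locus_seq = _rand_seq(rng, L)
        s = 20  # primary 5' end offset within the locus
        locus_seq = locus_seq[:s] + "T" + locus_seq[s + 1 :]
        primary = locus_seq[s : s + 26]
        responder = revcomp(locus_seq[s - 16 : s + 10])  # 5' end at s+9, pos10 pairs s
        pid = f"pp{i + 1:02d}"
        plans.append(_Plan(locus_seq, "pirna_locus", pid, "+", (0, L)))
        truth.planted_pirnas.append(
            PlantedPirna(pid + "p", primary, None, "+", False, rest_each)  # type: ignore[arg-type]
        )
        truth.planted_pirnas.append(
            PlantedPirna(pid + "r", responder, None, "-", True, rest_each)  # type: ignore[arg-type]
        )

    # --- housekeeping ncRNA / repeat features, with read-generating inserts
    for cls, (n_feat, length, total_reads) in cfg.other_classes.items():
        per = total_reads // max(n_feat, 1) if total_reads else 0
        queue = embed_queues.get(cls, [])
        for i in range(n_feat):
            fid = f"{cls.replace(':', '_')}{i + 1:02d}"
            seq = _rand_seq(rng, length)
            # spread this feature's share of antisense piRNA copies
            mine = queue[i::n_feat]
            if mine:
                seg = length // len(mine)
                for j, copy in enumerate(mine):
                    off = j * seg + int(rng.integers(0, max(1, seg - len(copy))))
                    seq = seq[:off] + copy + seq[off + len(copy):]
            strand = "+" if rng.random() < 0.7 else "-"
            plans.append(_Plan(seq if strand == "+" else revcomp(seq),
                               cls, fid, strand, (0, length)))
            if per:
                off = int(rng.integers(0, length - 24))
                insert = seq[off : off + int(rng.integers(20, 25))]
                category = {
                    "rrna": "rRNA", "trna": "tRNA", "snrna": "snRNA",
                    "snorna": "snoRNA", "scrna": "scRNA", "srprna": "srpRNA",
                    "repeat": "repeat",
                }.get(cls, "repeat")
                truth.planted_other.append(PlantedOther(fid + "_t", category, insert, per))

    # --- 3'UTRs; target sites for the first known miRNAs planted later
    utr_plans: list[_Plan] = []
    mrna_embeds = embed_queues.get("mRNA", [])
    for i in range(cfg.n_utrs):
        gid = f"g{i + 1:04d}"
        seq = _rand_seq(rng, cfg.utr_length)
        if i < cfg.n_target_genes:
            mature = truth.planted_mirnas[i % cfg.n_known_mirnas].mature
            site = revcomp(mature)
            pos = int(rng.integers(30, cfg.utr_length - len(site) - 30))
            seq = seq[:pos] + site + seq[pos + len(site) :]
        elif mrna_embeds and (i - cfg.n_target_genes) < len(mrna_embeds):
            copy = mrna_embeds[i - cfg.n_target_genes]
            off = int(rng.integers(0, cfg.utr_length - len(copy)))
            seq = seq[:off] + copy + seq[off + len(copy) :]
        utr_plans.append(_Plan(seq, "mrna_utr", gid, "+", (0, cfg.utr_length)))
    plans.extend(utr_plans)
    if cfg.mrna_reads and cfg.n_utrs:
        # mRNA-degradation inserts from the last (target-free) UTRs
        donors = utr_plans[cfg.n_target_genes :] or utr_plans
        per = max(1, cfg.mrna_reads // min(3, len(donors)))
        for j, plan in enumerate(donors[:3]):
            off = int(rng.integers(0, cfg.utr_length - 24))
            truth.planted_other.append(
                PlantedOther(plan.feature_id + "_t", "mRNA", plan.content[off : off + 22], per)
            )

    # --- assemble chromosomes: shuffle plans, pack with random gaps
    order = rng.permutation(len(plans))
    chrom_names = list(cfg.chrom_lengths)
    cursors = {c: 0 for c in chrom_names}
    parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    features: list[Feature] = []
    planted_loci: dict[str, Feature] = {}
    ci = 0
    for k in order:
        plan = plans[int(k)]
        gap = int(rng.integers(80, 200))
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            ci += 1
            need = gap + len(plan.content)
            if cursors[chrom] + need <= cfg.chrom_lengths[chrom]:
                parts[chrom].append(_rand_seq(rng, gap))
                start = cursors[chrom] + gap + plan.span[0]
                end = start + plan.span[1]
                parts[chrom].append(plan.content)
                cursors[chrom] += need
                feat = Feature(chrom, start, end, plan.strand,
                               plan.feature_class or "decoy", plan.feature_id)
                if plan.feature_class is not None:
                    features.append(feat)
                planted_loci[plan.feature_id] = feat
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"feature {plan.feature_id} ({len(plan.content)} nt) does not fit; "
                "increase chromosome lengths or reduce feature counts"
            )
    for chrom in chrom_names:
        pad = cfg.chrom_lengths[chrom] - cursors[chrom]
        if pad:
            parts[chrom].append(_rand_seq(rng, pad))
    genome = SyntheticGenome({c: "".join(parts[c]) for c in chrom_names}, features)

    # back-fill loci into truth records (frozen dataclasses -> rebuild)
    truth.planted_mirnas = [
        PlantedMirna(m.mirna_id, m.mature, m.star, m.precursor,
                     planted_loci[m.mirna_id], m.expected_count, m.is_known)
        for m in truth.planted_mirnas
    ]
    truth.planted_pirnas = [
        PlantedPirna(p.pirna_id, p.sequence,
                     planted_loci.get(p.pirna_id, planted_loci.get(p.pirna_id[:-1])),
                     p.strand, p.is_pingpong_responder, p.expected_count)
        for p in truth.planted_pirnas
    ]
    truth.decoy_loci = [
        DecoyLocus(d.decoy_id, d.sequence, planted_loci[d.decoy_id], d.expected_count)
        for d in truth.decoy_loci
    ]

    # --- editing events on known miRNAs
    for m in truth.planted_mirnas[: cfg.n_edits]:
        truth.planted_edits.append((m.mirna_id, cfg.edit_position, cfg.edit_fraction))

    # --- reference catalogs sliced from the genome at feature coordinates
    refs: dict[str, list[tuple[str, str]]] = {
        "mirna": [], "pirna": [], "rrna": [], "trna": [], "snrna": [],
        "snorna": [], "scrna": [], "srprna": [], "repeat": [], "utr": [],
    }
    for m in truth.planted_mirnas:
        if m.is_known:
            hp = genome.feature_seq(m.locus)
            refs["mirna"].append((m.mirna_id, hp[: cfg.mirna_length]))
    for p in truth.planted_pirnas:
        if p.locus.feature_class == "pirna_locus" and not p.pirna_id.startswith("pp"):
            refs["pirna"].append((p.pirna_id, genome.feature_seq(p.locus)))
        else:  # ping-pong primaries/responders enter the catalog directly
            refs["pirna"].append((p.pirna_id, p.sequence))
    class_to_cat = {
        "rrna": "rrna", "trna": "trna", "snrna": "snrna", "snorna": "snorna",
        "scrna": "scrna", "srprna": "srprna", "repeat": "repeat",
        "retrotransposon:LINE1": "repeat", "retrotransposon:LTR": "repeat",
    }
    for feat in features:
        cat = class_to_cat.get(feat.feature_class)
        if cat:
            refs[cat].append((feat.feature_id, genome.feature_seq(feat)))
        elif feat.feature_class == "mrna_utr":
            refs["utr"].append((f"{feat.feature_id}|t{feat.feature_id[1:]}",
                                genome.feature_seq(feat)))

    labeled = []
    label_of = {
        "repeat": "repeat",
        "retrotransposon:LINE1": "retrotransposon:LINE1",
        "retrotransposon:LTR": "retrotransposon:LTR",
        "mrna_utr": "mRNA",
    }
    for feat in features:
        lbl = label_of.get(feat.feature_class)
        if lbl:
            labeled.append((lbl, feat.feature_id, genome.feature_seq(feat)))

    go_map, pathway_map = _annotation_maps(rng, cfg)
    return ReferenceBundle(genome, refs, go_map, pathway_map, truth, cfg, labeled)


def _annotation_maps(rng, cfg):
    """Gene->GO and gene->pathway maps with one planted enriched term each.

    The planted term/pathway covers 6 of the target genes (those with
    planted sites) and 2 background genes, giving a clear >2-fold
    enrichment among predicted targets.
    """
    genes = [f"g{i + 1:04d}" for i in range(cfg.n_utrs)]
    go_terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    pathways = [f"path{i + 1:03d}" for i in range(cfg.n_pathways)]
    go_map: dict[str, list[str]] = {}
    pathway_map: dict[str, list[str]] = {}
    targets = genes[: cfg.n_target_genes]
    planted_go, planted_pw = go_terms[0], pathways[0]
    go_carriers = set(targets[:6]) | set(genes[cfg.n_target_genes :][:2])
    pw_carriers = set(targets[:6]) | set(genes[cfg.n_target_genes :][2:4])
    for g in genes:
        k = int(rng.integers(2, 5))
        terms = list(rng.choice(go_terms[1:], size=k, replace=False))
        if g in go_carriers:
            terms.append(planted_go)
        go_map[g] = sorted(set(terms))
        kp = int(rng.integers(1, 3))
        pws = list(rng.choice(pathways[1:], size=kp, replace=False))
        if g in pw_carriers:
            pws.append(planted_pw)
        pathway_map[g] = sorted(set(pws))
    return go_map, pathway_map


# ---------------------------------------------------------------------------
# read simulation


def _good_quality(rng, n: int) -> str:
    return "".join(chr(QUALITY_OFFSET + int(q)) for q in rng.integers(30, 41, size=n))


def _assemble_read(rng, insert: str, cfg: SynthConfig) -> str:
    parts = []
    # leftover 5'-adapter fragment, only when the insert plus a
    # recognizable 3'-adapter stub (>=6 nt) still fits in the read
    room = cfg.read_length - len(insert) - 6
    if room >= 6 and rng.random() < cfg.p_5prime_adapter:
        k = int(rng.integers(6, min(13, room + 1, len(cfg.adapter5) + 1)))
        parts.append(cfg.adapter5[-k:])
    parts.append(insert)
    parts.append(cfg.adapter3)
    read = "".join(parts)[: cfg.read_length]
    if len(read) < cfg.read_length:
        read += "A" * (cfg.read_length - len(read))
    return read


def simulate_library(
    truth: TruthTable,
    n_reads: int | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    config: SynthConfig | None = None,
) -> tuple[list[RawRead], dict[str, int]]:
    """Simulate an adapter-flanked read library from the truth table.

    Reads per truth entry are multinomial with probabilities proportional
    to expected counts, so realized counts match expectations up to
    sampling noise; the realized per-entry counts are returned alongside
    the reads.  ``error_rate`` is a per-base substitution probability
    (must be < 0.1).  Contamination (adapter dimers, N-containing reads)
    and low-quality reads are added on top per the config fractions.
    """
    cfg = config or SynthConfig()
    if not (0 <= error_rate < 0.1):
        raise ValueError("error_rate must be in [0, 0.1)")
    entries = truth.entries()
    if not entries:
        raise ValueError("truth table has no read-generating entries")
    expected = np.array([e[2] for e in entries], dtype=float)
    if n_reads is None:
        n_reads = int(expected.sum())
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    n_contam = int(round(cfg.contamination_fraction * n_reads))
    n_lowq = int(round(cfg.low_quality_fraction * n_reads))
    n_clean = n_reads - n_contam - n_lowq
    counts = rng.multinomial(n_clean, expected / expected.sum())
    edits = {mid: (pos, frac) for mid, pos, frac in truth.planted_edits}
    mirna_ids = {m.mirna_id for m in truth.planted_mirnas}

    reads: list[RawRead] = []
    realized: dict[str, int] = {}
    for (eid, insert, _), c in zip(entries, counts):
        realized[eid] = int(c)
        for _ in range(int(c)):
            ins = insert
            if eid in mirna_ids:
                u = rng.random()  # 5'/3' end heterogeneity (trimming variants)
                if u < cfg.het_3p_fraction:
                    ins = ins[:-1]
                elif u < cfg.het_3p_fraction + cfg.het_5p_fraction:
                    ins = ins[1:]
            if eid in edits:
                pos, frac = edits[eid]
                if rng.random() < frac and pos < len(ins):
                    ins = _mutate(rng, ins, pos)
            if error_rate > 0:
                errs = np.nonzero(rng.random(len(ins)) < error_rate)[0]
                for p in errs:
                    ins = _mutate(rng, ins, int(p))
            seq = _assemble_read(rng, ins, cfg)
            reads.append(RawRead(seq, _good_quality(rng, len(seq))))

    # contamination: half adapter dimers, half N-containing inserts
    for i in range(n_contam):
        if i % 2 == 0:
            seq = (cfg.adapter3 + _rand_seq(rng, cfg.read_length))[: cfg.read_length]
        else:
            eid, insert, _ = entries[int(rng.integers(len(entries)))]
            ins = list(insert)
            for p in rng.choice(len(ins), size=min(2, len(ins)), replace=False):
                ins[int(p)] = "N"
            seq = _assemble_read(rng, "".join(ins), cfg)
        reads.append(RawRead(seq, _good_quality(rng, len(seq))))
    # low-quality reads: plenty of bases below Q=10
    for _ in range(n_lowq):
        eid, insert, _ = entries[int(rng.integers(len(entries)))]
        seq = _assemble_read(rng, insert, cfg)
        qual = np.array(rng.integers(30, 41, size=len(seq)))
        bad = rng.choice(len(seq), size=max(1, len(seq) // 3), replace=False)
        qual[bad] = rng.integers(0, 10, size=bad.size)
        reads.append(RawRead(seq, "".join(chr(QUALITY_OFFSET + int(q)) for q in qual)))

    perm = rng.permutation(len(reads))
    return [reads[int(i)] for i in perm], realized


# ---------------------------------------------------------------------------
# ping-pong simulation


@dataclass(frozen=True)
class SimulatedPirnaRead:
    """A piRNA-sized read with its genomic placement on a locus."""

    read: RawRead
    start: int  # 0-based, on the locus forward strand
    end: int
    strand: str

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def simulate_pingpong_pairs(
    locus_sequence: str,
    n_pairs: int,
    seed: int = 0,
    bias_1u: float = 0.95,
    bias_10a: float = 0.95,
    read_length: int = 26,
    background_fraction: float = 0.05,
) -> list[SimulatedPirnaRead]:
    """Sense/antisense piRNA pairs with exact 10-nt 5' overlaps.

    Each pair has a sense read whose 5' end sits at position s and an
    antisense read whose 5' end sits at s+9 (overlap 10).  Sense reads
    start with U(T) with probability ``bias_1u``; antisense reads carry A
    at position 10 with probability ``bias_10a``.  A small fraction of
    unpaired background reads at uniform positions keeps the overlap
    histogram's off-signal bins populated, as degradation products do in
    real libraries.
    """
    locus = norm_seq(locus_sequence)
    L = len(locus)
    if L < 40:
        raise ValueError("ping-pong locus must be at least 40 nt")
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    rl = read_length
    out: list[SimulatedPirnaRead] = []
    lo, hi = rl - 10, L - rl  # keep both mates inside the locus
    for _ in range(n_pairs):
        s = int(rng.integers(lo, hi + 1))
        sense = locus[s : s + rl]
        if rng.random() < bias_1u:
            if sense[0] != "T":
                sense = "T" + sense[1:]
        elif sense[0] == "T":
            sense = _mutate(rng, sense, 0, avoid="T")
        anti_end = s + 10  # antisense 5' end at s+9
        anti = revcomp(locus[anti_end - rl : anti_end])
        if rng.random() < bias_10a:
            if anti[9] != "A":
                anti = anti[:9] + "A" + anti[10:]
        elif anti[9] == "A":
            anti = _mutate(rng, anti, 9, avoid="A")
        out.append(SimulatedPirnaRead(
            RawRead(sense, _good_quality(rng, rl)), s, s + rl, "+"))
        out.append(SimulatedPirnaRead(
            RawRead(anti, _good_quality(rng, rl)), anti_end - rl, anti_end, "-"))
    for _ in range(int(background_fraction * n_pairs)):
        s = int(rng.integers(0, L - rl + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = locus[s : s + rl] if strand == "+" else revcomp(locus[s : s + rl])
        out.append(SimulatedPirnaRead(
            RawRead(seq, _good_quality(rng, rl)), s, s + rl, strand))
    return out


def simulate_pingpong_reads(
    locus_sequence: str, n_pairs: int, seed: int = 0, **kwargs
) -> list[RawRead]:
    """Like :func:`simulate_pingpong_pairs` but returning bare reads."""
    return [r.read for r in simulate_pingpong_pairs(locus_sequence, n_pairs, seed, **kwargs)]
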