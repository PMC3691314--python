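"""End-to-end pipeline orchestration and reporting.

Runs synth -> clean -> annotate -> discover -> pirna -> targets ->
enrich with a single config whose defaults are the published thresholds
(Q < 10 low-quality, 11-33 nt window, <= 1 mismatch, >= 45 reads,
-18 / -20 kcal/mol energy cutoffs, score > 140, E-ratio > 2 for GO and
> 1.5 for pathways at p < 0.05).  Every stage writes a tab-separated
table into the run directory; the plain-text report aggregates the
headline numbers and the log records every threshold and the seed, so
each reported value can be traced back to a stage table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from srnakit import annotate as ann
from srnakit import enrichment as enr
from srnakit import io as sio
from srnakit import mirna_discovery as disc
from srnakit import pirna_analysis as pir
from srnakit import preprocess as pre
from srnakit import synthdata as syn
from srnakit import target_prediction as tgt

ALL_STAGES = ("synth", "clean", "annotate", "discover", "pirna", "targets", "enrich")

_TUPLE_FIELDS = {
    "stages", "length_window", "pirna_window",
    "known_mirna_counts", "novel_mirna_counts",
}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the published values."""

    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    # cleaning
    q_threshold: int = 10
    max_bad_fraction: float = 0.0
    length_window: tuple[int, int] = (11, 33)
    min_adapter_overlap: int = 6
    # mapping / annotation
    max_mismatch: int = 1
    kmer: int = 12
    # novel miRNA discovery
    min_read_count: int = 45
    max_precursor_energy: float = -18.0
    flank: int = 100
    # piRNA
    pirna_window: tuple[int, int] = (24, 32)
    # targets
    max_duplex_energy: float = -20.0
    min_target_score: float = 140.0
    n_top_mirnas: int = 10
    # enrichment
    go_e_ratio: float = 2.0
    pathway_e_ratio: float = 1.5
    p_threshold: float = 0.05
    # synthetic study conditions
    synth: syn.SynthConfig = field(default_factory=syn.SynthConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth_d = d.pop("synth", {})
        synth_fields = {f.name for f in dataclasses.fields(syn.SynthConfig)}
        synth = syn.SynthConfig(**{
            k: _coerce(k, v) for k, v in synth_d.items() if k in synth_fields
        })
        own = {f.name for f in dataclasses.fields(cls)} - {"synth"}
        return cls(synth=synth, **{
            k: _coerce(k, v) for k, v in d.items() if k in own
        })

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _coerce(key, value):
    if key in _TUPLE_FIELDS and isinstance(value, list):
        return tuple(value)
    return value


@dataclass
class RunReport:
    """In-memory results of one pipeline run (also written to disk)."""

    config: PipelineConfig
    bundle: syn.ReferenceBundle | None = None
    reads: list[syn.RawRead] | None = None
    index: "ann.GenomeIndex | None" = None
    realized_counts: dict[str, int] | None = None
    cleaning: pre.CleaningSummary | None = None
    tags: list[pre.CleanTag] | None = None
    records: list[ann.AnnotationRecord] | None = None
    category_table: pd.DataFrame | None = None
    chromosome_counts: dict[str, float] | None = None
    known_expression: pd.DataFrame | None = None
    editing: list[tuple[str, int, float]] | None = None
    novel_candidates: list[disc.HairpinCandidate] | None = None
    heterogeneity: pd.DataFrame | None = None
    pirna_expression: pd.DataFrame | None = None
    pirna_top10_share: float | None = None
    pingpong: pir.PingPongSignature | None = None
    pirna_target_fractions: dict[str, float] | None = None
    target_sites: list[tgt.TargetSite] | None = None
    target_genes: pd.DataFrame | None = None
    go_results: list[enr.EnrichmentResult] | None = None
    pathway_results: list[enr.EnrichmentResult] | None = None
    log: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute the configured stages, writing artifacts into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rpt = RunReport(config=config)
    stage = "setup"
    try:
        for stage in config.stages:
            _STAGE_FUNCS[stage](config, out, rpt)
            rpt.log.append(f"stage={stage} done")
    except Exception as exc:  # partial outputs stay on disk
        raise StageError(stage, exc) from exc
    _write_report(config, out, rpt)
    (out / "run.log").write_text("\n".join(rpt.log) + "\n")
    return rpt


# ---------------------------------------------------------------------------
# stages


def _stage_synth(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    bundle = syn.generate_references(cfg.seed, cfg.synth)
    reads, realized = syn.simulate_library(bundle.truth, seed=cfg.seed + 1,
                                           config=cfg.synth)
    rpt.bundle, rpt.realized_counts = bundle, realized
    rpt.reads = reads
    refdir = out / "refs"
    refdir.mkdir(exist_ok=True)
    sio.write_fasta(
        list(bundle.genome.chromosomes.items()), refdir / "genome.fa"
    )
    for cat, entries in bundle.references.items():
        sio.write_fasta(entries, refdir / f"{cat}.fa")
    with open(refdir / "go.tsv", "w") as fh:
        for g, terms in sorted(bundle.go_map.items()):
            for t in terms:
                fh.write(f"{g}\t{t}\n")
    with open(refdir / "pathway.tsv", "w") as fh:
        for g, pws in sorted(bundle.pathway_map.items()):
            for t in pws:
                fh.write(f"{g}\t{t}\n")
    sio.write_fastq(reads, out / "reads.fq")
    (refdir / "MANIFEST.txt").write_text(
        "Synthetic small RNA fixture.\n"
        "reads.fq quality encoding: offset 64 (Q = ASCII - 64).\n"
        f"seed: {cfg.seed}\n"
    )
    rpt.log.append(
        f"stage=synth reads={len(reads)} chromosomes={len(bundle.genome.chromosomes)} "
        f"features={len(bundle.genome.feature_track)} seed={cfg.seed}"
    )


def _stage_clean(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    inserts, summary = pre.clean_reads(
        rpt.reads,
        adapter5=cfg.synth.adapter5, adapter3=cfg.synth.adapter3,
        length_window=cfg.length_window, q_threshold=cfg.q_threshold,
        max_bad_fraction=cfg.max_bad_fraction,
        min_overlap=cfg.min_adapter_overlap,
    )
    tags = pre.collapse_to_tags(inserts)
    summary.unique_tags = len(tags)
    rpt.cleaning, rpt.tags = summary, tags
    sio.write_tags_fasta(tags, out / "tags.fa")
    rows = [{"metric": "total_reads", "value": summary.total_reads},
            {"metric": "clean_reads", "value": summary.clean_reads},
            {"metric": "unique_tags", "value": summary.unique_tags}]
    rows += [{"metric": f"rejected_{k}", "value": v}
             for k, v in sorted(summary.rejected_by_reason.items())]
    pd.DataFrame(rows).to_csv(out / "cleaning_summary.tsv", sep="\t", index=False)
    rpt.log.append(
        f"stage=clean total={summary.total_reads} clean={summary.clean_reads} "
        f"unique_tags={summary.unique_tags} q_threshold={cfg.q_threshold} "
        f"window={cfg.length_window}"
    )


def _stage_annotate(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    index = ann.GenomeIndex.from_genome(rpt.bundle.genome, cfg.kmer)
    rpt.index = index
    records = ann.annotate_tags(rpt.tags, index, rpt.bundle.references,
                                cfg.max_mismatch)
    rpt.records = records
    table = ann.summarize_categories(records)
    table.columns = ["Category", "NO. of Unique tags", "Percent",
                     "Total reads", "Percent "]
    table.to_csv(out / "category_summary.tsv", sep="\t", index=False,
                 float_format="%.2f")
    rpt.category_table = ann.summarize_categories(records)
    rpt.chromosome_counts = ann.chromosome_distribution(records)
    pd.DataFrame(
        sorted(rpt.chromosome_counts.items()),
        columns=["chromosome", "reads"],
    ).to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False,
             float_format="%.2f")
    rpt.known_expression = ann.quantify_known_mirnas(
        records, rpt.bundle.references["mirna"], cfg.max_mismatch
    )
    rpt.known_expression.to_csv(out / "known_mirna_expression.tsv",
                                sep="\t", index=False)
    rpt.editing = ann.detect_editing(records, rpt.bundle.references["mirna"])
    pd.DataFrame(rpt.editing, columns=["mirna_id", "position", "fraction"]) \
        .to_csv(out / "editing.tsv", sep="\t", index=False, float_format="%.4f")
    rpt.log.append(
        f"stage=annotate tags={len(records)} max_mismatch={cfg.max_mismatch} "
        f"k={cfg.kmer} detected_mirnas={len(rpt.known_expression)}"
    )


def _stage_discover(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    unann = [r.tag for r in rpt.records if r.category == "unannotated"]
    cands, het = disc.predict_novel_mirnas(
        unann, rpt.index, rpt.bundle.genome,
        min_count=cfg.min_read_count, flank=cfg.flank,
        max_energy=cfg.max_precursor_energy,
    )
    rpt.novel_candidates, rpt.heterogeneity = cands, het
    het.to_csv(out / "novel_mirnas.tsv", sep="\t", index=False,
               float_format="%.1f")
    sio.write_fasta(
        [(f"cand{i + 1:03d}", c.precursor) for i, c in enumerate(cands)],
        out / "novel_precursors.fa",
    )
    rpt.log.append(
        f"stage=discover candidates={len(cands)} min_count={cfg.min_read_count} "
        f"max_energy={cfg.max_precursor_energy}"
    )


def _stage_pirna(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    lo, hi = cfg.pirna_window
    pir_tags = [
        r.tag for r in rpt.records
        if r.category == "piRNA" and lo <= len(r.tag.sequence) <= hi
    ]
    hits = pir.match_pirna_catalog(pir_tags, rpt.bundle.references["pirna"],
                                   cfg.max_mismatch)
    expr = pd.DataFrame([
        {"pirna_id": h.catalog_id,
         "sequence": h.catalog_sequence.replace("T", "U"),
         "length": pir.tag_length(h.catalog_sequence),
         "reads": h.total_count,
         "most_abundant_tag": h.most_abundant_tag.sequence.replace("T", "U"),
         "tag_length": len(h.most_abundant_tag.sequence),
         "tag_reads": h.most_abundant_tag.count}
        for h in hits
    ])
    rpt.pirna_expression = expr
    expr.head(10).to_csv(out / "pirna_top10.tsv", sep="\t", index=False)
    expr.to_csv(out / "pirna_expression.tsv", sep="\t", index=False)
    rpt.pirna_top10_share = pir.top_share(expr, 10) if len(expr) else None

    plus, minus = [], []
    for r in rpt.records:
        if r.category != "piRNA":
            continue
        for h in r.hits:
            iv = (h.chromosome, h.start, h.start + len(r.tag.sequence),
                  r.tag.count)
            (plus if h.strand == "+" else minus).append((iv, r.tag))
    sig = pir.pingpong_overlap_signature([v for v, _ in plus],
                                         [v for v, _ in minus])
    # 1U on the sense partners / 10A on the antisense partners of
    # 10-nt-overlap pairs
    p_partners, m_partners = _overlap10_partners(plus, minus)
    sig.pos1_u_fraction = (
        pir.positional_base_bias(p_partners, 1).get("T", 0.0)
        if p_partners else None
    )
    sig.pos10_a_fraction = (
        pir.positional_base_bias(m_partners, 10).get("A", 0.0)
        if m_partners else None
    )
    rpt.pingpong = sig
    pd.DataFrame(
        sorted(sig.overlap_histogram.items()),
        columns=["overlap_nt", "pairs"],
    ).to_csv(out / "pingpong_histogram.tsv", sep="\t", index=False)

    fractions, _ = pir.classify_pirna_targets(
        [(h.catalog_id, h.catalog_sequence) for h in hits],
        rpt.bundle.labeled_repeats,
    )
    rpt.pirna_target_fractions = fractions
    pd.DataFrame(sorted(fractions.items()), columns=["target_class", "fraction"]) \
        .to_csv(out / "pirna_target_classes.tsv", sep="\t", index=False,
                float_format="%.4f")
    rpt.log.append(
        f"stage=pirna tags={len(pir_tags)} catalog_hits={len(hits)} "
        f"window={cfg.pirna_window}"
    )


def _overlap10_partners(plus, minus):
    p_part, m_part = [], []
    for (pc, ps, pe, pw), ptag in plus:
        for (mc, ms, me, mw), mtag in minus:
            if pc == mc and ms < pe and ps < me and (me - 1) - ps + 1 == 10:
                p_part.append(ptag)
                m_part.append(mtag)
    return list(dict.fromkeys(p_part)), list(dict.fromkeys(m_part))


def _stage_targets(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    catalog = dict(rpt.bundle.references["mirna"])
    top = ann.top_n(rpt.known_expression, cfg.n_top_mirnas)
    mirnas = [(mid, catalog[mid]) for mid in top["mirna_id"]]
    for i, cand in enumerate(rpt.novel_candidates or []):
        mirnas.append((f"cand{i + 1:03d}", cand.mature))
    sites, gene_table = tgt.predict_targets(
        mirnas, rpt.bundle.references["utr"],
        max_energy=cfg.max_duplex_energy, min_score=cfg.min_target_score,
    )
    rpt.target_sites, rpt.target_genes = sites, gene_table
    pd.DataFrame([
        {"mirna_id": s.mirna_id, "transcript": s.transcript_id,
         "start": s.start, "end": s.end, "seed_match": s.seed_match,
         "energy": s.duplex_energy, "score": s.score,
         "passed": s.passes(cfg.max_duplex_energy, cfg.min_target_score)}
        for s in sites
    ]).to_csv(out / "target_sites.tsv", sep="\t", index=False,
              float_format="%.1f")
    gene_table.to_csv(out / "target_genes.tsv", sep="\t", index=False,
                      float_format="%.1f")
    rpt.log.append(
        f"stage=targets mirnas={len(mirnas)} sites={len(sites)} "
        f"genes={len(gene_table)} max_energy={cfg.max_duplex_energy} "
        f"min_score={cfg.min_target_score}"
    )


def _stage_enrich(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    targets = set(rpt.target_genes["gene"]) if rpt.target_genes is not None else set()
    universe = set(rpt.bundle.go_map)
    rpt.go_results = enr.enrich(
        rpt.bundle.go_map, targets, universe,
        e_ratio_threshold=cfg.go_e_ratio, p_threshold=cfg.p_threshold,
    )
    rpt.pathway_results = enr.enrich(
        rpt.bundle.pathway_map, targets, set(rpt.bundle.pathway_map),
        e_ratio_threshold=cfg.pathway_e_ratio, p_threshold=cfg.p_threshold,
    )
    for name, results in (("go", rpt.go_results), ("pathway", rpt.pathway_results)):
        pd.DataFrame([
            {"term": r.term, "m": r.m, "M": r.M, "n": r.n, "N": r.N,
             "target_pct": 100 * r.m / r.M, "genome_pct": 100 * r.n / r.N,
             "e_ratio": r.e_ratio, "p_value": r.p_value,
             "significant": r.significant}
            for r in results
        ]).to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False,
                  float_format="%.4g")
    rpt.log.append(
        f"stage=enrich go_significant={sum(r.significant for r in rpt.go_results)} "
        f"pathway_significant={sum(r.significant for r in rpt.pathway_results)} "
        f"thresholds=({cfg.go_e_ratio},{cfg.pathway_e_ratio},{cfg.p_threshold})"
    )


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "clean": _stage_clean,
    "annotate": _stage_annotate,
    "discover": _stage_discover,
    "pirna": _stage_pirna,
    "targets": _stage_targets,
    "enrich": _stage_enrich,
}


def _write_report(cfg: PipelineConfig, out: Path, rpt: RunReport) -> None:
    lines = ["small RNA profiling run report", "=" * 32, f"seed: {cfg.seed}", ""]
    if rpt.cleaning:
        s = rpt.cleaning
        lines += [
            "[cleaning]",
            f"total reads: {s.total_reads}",
            f"clean reads: {s.clean_reads}",
            f"unique tags: {s.unique_tags}",
            "rejected: " + ", ".join(
                f"{k}={v}" for k, v in sorted(s.rejected_by_reason.items())
            ),
            "",
        ]
    if rpt.category_table is not None:
        lines += ["[categories]"]
        for _, row in rpt.category_table.iterrows():
            lines.append(
                f"{row['Category']:>12}: {row['NO. of Unique tags']:>6} tags "
                f"({row['Percent (tags)']:6.2f}%)  {row['Total reads']:>8} reads "
                f"({row['Percent (reads)']:6.2f}%)"
            )
        lines.append("")
    if rpt.chromosome_counts is not None:
        lines += ["[chromosome distribution]"]
        lines += [f"{c}: {v:.1f}" for c, v in sorted(rpt.chromosome_counts.items())]
        lines.append("")
    if rpt.known_expression is not None:
        lines += ["[top known miRNAs]"]
        for _, row in ann.top_n(rpt.known_expression, cfg.n_top_mirnas).iterrows():
            lines.append(f"{row['mirna_id']}: {row['reads']}")
        lines.append("")
    if rpt.novel_candidates is not None:
        lines += [f"[novel miRNA candidates] accepted: {len(rpt.novel_candidates)}"]
        het = rpt.heterogeneity if rpt.heterogeneity is not None else pd.DataFrame()
        for _, row in het.iterrows():
            lines.append(
                f"{row['candidate']} {row['chrom']}:{row['start']}-{row['end']}"
                f"({row['strand']}) reads={row['mature_reads']} 5'={row['first_nt']} "
                f"energy={row['energy']:.1f}"
            )
        lines.append("")
    if rpt.pingpong is not None:
        sig = rpt.pingpong
        z = "n/a" if sig.z10 is None else f"{sig.z10:.2f}"
        lines += [
            "[piRNA]",
            f"top-10 share: "
            + ("n/a" if rpt.pirna_top10_share is None
               else f"{100 * rpt.pirna_top10_share:.1f}%"),
            f"ping-pong overlap mode: {sig.mode}  z10: {z}",
            f"sense 1U fraction: "
            + ("n/a" if sig.pos1_u_fraction is None else f"{sig.pos1_u_fraction:.3f}"),
            f"antisense 10A fraction: "
            + ("n/a" if sig.pos10_a_fraction is None else f"{sig.pos10_a_fraction:.3f}"),
        ]
        if rpt.pirna_target_fractions:
            lines += ["target classes: " + ", ".join(
                f"{k}={100 * v:.1f}%"
                for k, v in sorted(rpt.pirna_target_fractions.items())
            )]
        lines.append("")
    if rpt.target_genes is not None:
        lines += [
            f"[targets] passing sites: "
            f"{sum(s.passes(cfg.max_duplex_energy, cfg.min_target_score) for s in rpt.target_sites)}"
            f"  target genes: {len(rpt.target_genes)}",
            "",
        ]
    if rpt.go_results is not None:
        lines += ["[enrichment]"]
        for label, results in (("GO", rpt.go_results),
                               ("pathway", rpt.pathway_results)):
            sig = [r for r in results if r.significant]
            lines.append(f"{label}: {len(sig)} significant")
            for r in sig[:10]:
                lines.append(
                    f"  {r.term}  m/M={r.m}/{r.M} n/N={r.n}/{r.N} "
                    f"E-ratio={r.e_ratio:.2f} p={r.p_value:.3g}"
                )
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
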