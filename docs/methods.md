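# Methods

This note documents the models and procedures `srnakit` implements, the
parameters that matter, what the synthetic data does and does not
emulate, and the design choices made where the design was genuinely open.

## Read cleaning

Qualities decode as Q = ASCII − 64 (the Solexa-era offset; FASTQ I/O uses
Biopython's `fastq-illumina` codec). A read is *low quality* when the
fraction of bases with Q < `q_threshold` (default 10) exceeds
`max_bad_fraction` (default 0, i.e. a single bad base rejects — the
strictest reading of the Q < 10 rule; the fraction is exposed for looser
policies). Filters apply in a fixed order — quality, adapters, N,
length — and the summary charges each rejected read to the *first* rule
it failed, so accounting balances exactly: total = clean + Σ rejected.

Adapter handling is exact-match with a 6-nt minimum overlap: the longest
suffix of the 5′ adapter found as a read prefix is removed, and the read
is truncated at the leftmost occurrence of a ≥ 6-nt prefix of the 3′
adapter. An empty remaining insert is an adapter dimer. Reads with no
detectable 3′ adapter are rejected rather than kept whole: a small-RNA
insert in a longer read must run into the adapter, so its absence means
the insert boundary is unknown. Clean inserts must fall in the 11–33 nt
window; collapsing produces unique tags sorted by count (ties
lexicographic).

## Mapping and the annotation cascade

The genome index is a k-mer table (k = 12 by default) over the forward
strand. A tag is aligned on both strands with at most one substitution,
no indels. Completeness: for tags ≥ 2k the two end seeds are disjoint, so
a single mismatch leaves at least one seed exact (pigeonhole); shorter
tags use exact half-string searches over the chromosome strings, which
carries the same guarantee. Both routes are tested against a brute-force
scan of every position.

Category assignment matches the whole tag *within* a reference sequence
(same orientation, ≤ 1 mismatch, U and T equivalent) in priority order:
miRNA, piRNA, then the housekeeping classes in summary-row order (rRNA,
scRNA, snRNA, snoRNA, srpRNA, tRNA), then repeat, then mRNA, else
unannotated. Each tag gets exactly one category, so category totals
conserve reads. Per-chromosome read counts split a multi-mapping tag's
count evenly across its hits, keeping the chromosome total equal to the
mapped read total exactly.

Editing detection pools exact and single-mismatch tags per catalog miRNA
and reports reference positions where mismatch reads exceed 10% of
coverage. The first and last 2 positions are excluded because 5′/3′ end
heterogeneity produces terminal mismatches that are not editing.

## The energy model

Folding is a Nussinov-style dynamic program scored by *stacks*, not
pairs: G:C, A:U and G:U may pair; two adjacent stacked pairs contribute
−3.0 kcal/mol (both G:C), −2.0 (at least one A:U, no G:U), or −1.0 (any
G:U); isolated pairs and unpaired bases contribute nothing; hairpin
loops enclose ≥ 3 nt; no pseudoknots. This model is deliberately simpler
than full nearest-neighbour thermodynamics: it is exactly optimizable,
its optimum is verifiable by exhaustive structure enumeration (which the
test suite does), and all thresholds stated against it (−18 for
precursors, −20 for target duplexes) are interpreted on its scale. The
synthetic generator plants hairpins and target sites calibrated to the
same scale, so threshold semantics are exercised exactly. Energies are
integer multiples of 1 kcal/mol, which makes the DP's tie behaviour and
the tests' equality assertions exact.

`duplex_free_energy` applies the same stack table to purely
intermolecular hybridization of two strands (monotone non-crossing pair
sets), again verified against enumeration at small lengths.

## Novel miRNA discovery

For each unannotated tag with ≥ 45 reads, every genomic hit is excised
into two windows, [start − flank, end + 20) and [start − 20, end + flank)
with flank = 100 nt — one for a mature arm 5′ of the loop, one for 3′ —
clipped to chromosome bounds. The window is folded; the star arm is the
region pairing with ≥ 60% of mature bases (no qualifying arm fails the
candidate outright); spacing is the unpaired gap between the arms; the
bulge is the longest unpaired run inside either arm of the duplex. The
five rules (mature 18–26 nt, energy ≤ −18, spacing ≤ 35, bulge ≤ 4,
count ≥ 45) are all inclusive on the passing side. The count cutoff is
"at least 45", the stricter-to-smaller of the two plausible readings,
and is config-exposed. Candidates at overlapping loci are merged
keeping the highest mature count; merging ignores strand because a
planted stem (mature + reverse complement) is discovered from both arms.
The 5′-terminal nucleotide of each accepted mature is reported but never
filtered on — U/A starts are an observed tendency, not a rule.

## piRNA analysis

Tags in the 24–32 nt window (an inclusive superset of the usual
24–31 nt definitions) are matched into the catalog by the same
≤ 1-mismatch within-sequence alignment; a tag matching several entries
is credited to its best one so read totals conserve. Positional base
biases are count-weighted over tags long enough to have the position.

The ping-pong signature takes genomic intervals per strand (optionally
weighted by tag counts), counts every overlapping opposite-strand pair
whose 5′-end distance d = minus5′ − plus5′ + 1 lies in 1..30, and
summarizes the 10-nt bin as z10 = (h[10] − mean(h≠10)) / sd(h≠10)
(sample sd). With no pairs, z10 is undefined (None); with an empty
off-signal histogram it is reported as +inf. Calibration on the
simulator: 300 pairs on a 600-nt locus give mode 10 and z10 ≈ 17–32
across seeds, while position-shuffled nulls give z10 < 2 in ≥ 95% of
trials. The locus must be long enough that read 5′ positions are
sparse; on a very short locus the all-vs-all combinatorial background
swamps the 10-nt excess, which is a property of the statistic, not the
simulation.

piRNA target classes are assigned by the best antisense alignment of
the full piRNA (≥ 90% identity) against labeled repeat/retrotransposon/
mRNA references; unassigned piRNAs are excluded from the reported
fractions. The identity cutoff is a declared stand-in for the original
BLAST-based search, whose parameters are not specified anywhere.

## Target prediction

Rule 1 is a perfect Watson–Crick match of the reverse-complemented seed
(miRNA positions 2–8) in the UTR — G:U is excluded in the seed by
construction. Around each seed match a site window of up to miRNA
length + 4 nt is excised (site lengths stay within [L − 4, L + 8]).
Rule 2 is the duplex energy of miRNA vs site, strictly below
−20 kcal/mol. Rule 3 is a Smith–Waterman local alignment of the miRNA
against the reverse-complemented site — match +5, G:U wobble +2,
mismatch −3, gap open −9, gap extend −4, substitution scores doubled at
miRNA positions 2–8 — strictly above 140. The parameterization is a
declared stand-in for the original tool's unpublished matrix, calibrated
so a perfect complement of a ≥ 22-nt miRNA scores 145 while seedless
partial duplexes fall short; all five parameters are module constants.
Scores are per-site; a gene qualifies with ≥ 1 passing site, and the
gene table deduplicates.

## Enrichment

With N annotated genes in the universe, n carrying the term, M annotated
targets and m targets carrying the term, E = (m/M)/(n/N) and
p = P(X ≥ m) under the hypergeometric distribution (scipy's survival
function, computed stably in log space; the one-sided Fisher test is the
same tail and is implemented as such). The E-ratio formula is the fold
enrichment consistent with the paired "targets % / genome %" presentation
of such tables. Thresholds are strict as printed: GO E > 2, pathway
E > 1.5, p < 0.05. No multiple-testing correction is applied by default,
matching the original analysis style; Benjamini–Hochberg q-values are
available behind a flag. Ties in the E-ratio ordering break by ascending
p, then term id.

## Synthetic study conditions

Defaults (all in `SynthConfig`): four 25-kb chromosomes; 10 known and 5
novel miRNA hairpins with geometric-ish abundances (known 1200…90,
novel 350…100 expected reads) — five novels mirror the headline result
of the study design this emulates; 30 catalog piRNAs whose top-10
expected counts are proportional to the published top-10 table and sum
to 61% of piRNA reads; two 600-nt ping-pong loci with 1U/10A biases of
0.95 (0.9 is the guaranteed floor after background dilution); piRNA
lengths peaking at 26–27 nt; piRNA target classes 69% LINE-1, 6% LTR,
15% other repeat, 10% mRNA (≈ 75% retrotransposon); housekeeping
ncRNA/repeat features with modest read counts; 30 UTR genes of 400 nt,
the first 10 carrying perfect complements of known miRNAs; a GO term
and a pathway planted on 6 target + 2 background genes; two editing
events at position 10 with fraction 0.15; reads of 40 nt (long enough
that a 33-nt insert still leaves the 6-nt minimum 3′-adapter overlap)
with 5% contamination (half adapter dimers, half N-containing) and 3%
low-quality reads. Hairpin loops, stem buffers and decoy loci are drawn
from an {A,C} alphabet, in which no canonical pair exists, so decoy
windows fold to 0 kcal/mol and planted windows fold to exactly the
designed stem.

What the generator does *not* emulate: realistic sequencing error
profiles and quality decay, ligation bias, isomiR distributions beyond
±1-nt trimming, piRNA clusters, genome repetitiveness (multi-mapping is
rare by construction), and real database redundancy. Passing tests
therefore demonstrate correctness of the *rules and statistics* under
controlled conditions, not performance on real libraries.

Problem sizes throughout (100-kb genome, ~10k reads, 30-gene universe)
are chosen so the full pipeline runs in seconds and exhaustive oracles
(structure enumeration ≤ 14 nt, full position scans, the complete
N ≤ 60 hypergeometric grid) remain feasible; they are scaled-down study
conditions, and quantities that depend on absolute catalog sizes
(e.g. "770 miRNAs") are out of scope by design.

## Numerical and degenerate-case choices

- All stack energies are integers, so float equality in DP tracebacks
  and tests is exact.
- `map_tag` returns nothing for N-containing tags; `fold_rna` rejects
  non-nucleotide characters and sequences over 200 nt (it is cubic).
- Empty inputs return empty results (cleaning, collapsing, discovery,
  enrichment of an empty annotated set); an empty universe or an empty
  eligible tag set for a base-bias position is an error.
- The cleaning summary records only the first rejection reason per read.
- Deduplication, sorting and report formatting are all deterministic;
  rerunning any stage with the same seed is byte-identical.

## Known limitations

- The energy model's kcal/mol scale is not comparable to
  nearest-neighbour folders; thresholds transfer only in spirit.
- One-mismatch catalog matching cannot distinguish editing from SNPs or
  sequencing error; the >10% fraction rule is the only guard.
- The ping-pong z-score needs sparse 5′ positions (locus length ≫
  pair count / positions); dense stacks require read-level pair matching
  instead.
- Target prediction considers 3′UTRs only, without conservation or
  3′-supplementary pairing bonuses.
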