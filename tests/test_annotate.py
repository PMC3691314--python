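"""Mapping (vs brute force), cascade priority, summaries, editing."""

import numpy as np
import pytest

from srnakit.annotate import (
    AnnotationRecord,
    GenomeIndex,
    MappingHit,
    align_within,
    annotate_tags,
    chromosome_distribution,
    classify_tag,
    detect_editing,
    map_tag,
    quantify_known_mirnas,
    summarize_categories,
    top_n,
)
from srnakit.preprocess import CleanTag
from srnakit.util import revcomp

from oracles import brute_force_map


@pytest.fixture(scope="module")
def toy_index():
    rng = np.random.default_rng(0)
    chroms = {
        "c1": "".join(rng.choice(list("ACGT"), 3000)),
        "c2": "".join(rng.choice(list("ACGT"), 2000)),
    }
    return GenomeIndex(chroms, k=12)


class TestMapTag:
    def test_exact_substring_hit(self, toy_index):
        tag = toy_index.chromosomes["c1"][500:522]
        hits = map_tag(tag, toy_index)
        assert MappingHit("c1", 500, "+", 0) in hits

    def test_one_vs_two_mismatches(self, toy_index):
        tag = list(toy_index.chromosomes["c2"][100:122])
        tag[5] = "A" if tag[5] != "A" else "C"
        one = map_tag("".join(tag), toy_index)
        assert any(h.start == 100 and h.mismatches == 1 for h in one)
        tag[15] = "A" if tag[15] != "A" else "C"
        two = map_tag("".join(tag), toy_index)
        assert not any(h.chromosome == "c2" and h.start == 100 for h in two)

    def test_minus_strand_hit(self, toy_index):
        tag = revcomp(toy_index.chromosomes["c1"][800:826])
        hits = map_tag(tag, toy_index)
        assert MappingHit("c1", 800, "-", 0) in hits

    def test_n_containing_tag_has_no_hits(self, toy_index):
        assert map_tag("ACGTNACGTACGTACGTACGT", toy_index) == []

    @pytest.mark.parametrize("length", [13, 16, 22, 26, 31])
    def test_equals_brute_force(self, toy_index, length):
        """Seeded lookup returns exactly the brute-force hit set for
        planted, mutated and random tags of every length class."""
        rng = np.random.default_rng(length)
        for trial in range(8):
            if trial % 2 == 0:  # planted (possibly mutated) tag
                pos = int(rng.integers(0, 1500))
                tag = list(toy_index.chromosomes["c1"][pos : pos + length])
                if trial % 4 == 2:
                    i = int(rng.integers(length))
                    tag[i] = "ACGT"[int(rng.integers(4))]
                tag = "".join(tag)
            else:
                tag = "".join(rng.choice(list("ACGT"), length))
            got = sorted(
                (h.chromosome, h.start, h.strand, h.mismatches)
                for h in map_tag(tag, toy_index)
            )
            assert got == brute_force_map(tag, toy_index.chromosomes)


class TestCascade:
    REFS = {
        "mirna": [("m1", "TGAGGTAGTAGGTTGTATAGTT")],
        "pirna": [("p1", "TCGGAACCTGCAGACACTCGTGGAGGCGTC")],
        "repeat": [("r1", "TGAGGTAGTAGGTTGTATAGTT" + "ACGT" * 20)],
    }

    def test_mirna_beats_repeat(self):
        # the tag occurs in both the miRNA and repeat sets
        cat = classify_tag("TGAGGTAGTAGGTTGTATAGTT", [], self.REFS)
        assert cat == "miRNA"

    def test_pirna_only(self):
        assert classify_tag("TCGGAACCTGCAGACACTCGTGGAGGCGTC", [], self.REFS) == "piRNA"

    def test_unannotated(self):
        assert classify_tag("CCCCCCCCCCCCCCCCCCCCCC", [], self.REFS) == "unannotated"

    def test_one_mismatch_still_matches(self):
        tag = "TGAGGTAGTAGGTTGTATAGTA"  # last base differs
        assert classify_tag(tag, [], self.REFS) == "miRNA"

    def test_load_order_is_irrelevant(self, tags, bundle, genome_index):
        shuffled = {k: list(reversed(v)) for k, v in bundle.references.items()}
        sample = tags[::5]
        for tag in sample:
            assert classify_tag(tag, [], bundle.references) == \
                classify_tag(tag, [], shuffled)


class TestAlignWithin:
    def test_suffix_match(self):
        ref = "TCGGAACCTGCAGACACTCGTGGAGGCGTC"
        assert align_within(ref[1:], ref) == 1

    def test_u_t_normalization(self):
        assert align_within("UGAGGUAG", "ATGAGGTAGC") == 1

    def test_too_long_tag(self):
        assert align_within("ACGTACGT", "ACGT") is None


class TestSummaries:
    def test_same_category_totals(self):
        recs = [
            AnnotationRecord(CleanTag("AAACCC", 3), [], "miRNA"),
            AnnotationRecord(CleanTag("GGGTTT", 7), [], "miRNA"),
        ]
        df = summarize_categories(recs)
        row = df[df["Category"] == "miRNA"].iloc[0]
        assert row["NO. of Unique tags"] == 2
        assert row["Total reads"] == 10
        assert row["Percent (reads)"] == 100.0

    def test_percentages_sum_to_100(self, records):
        df = summarize_categories(records)
        body = df[df["Category"] != "Total"]
        assert abs(body["Percent (tags)"].sum() - 100) < 0.01
        assert abs(body["Percent (reads)"].sum() - 100) < 0.01
        total = df[df["Category"] == "Total"].iloc[0]
        assert total["NO. of Unique tags"] == body["NO. of Unique tags"].sum()
        assert total["Total reads"] == body["Total reads"].sum()

    def test_planted_mirna_share_exceeds_pirna(self, bundle, records):
        """The generator plants ~3x more miRNA than piRNA reads."""
        df = summarize_categories(records).set_index("Category")
        assert df.loc["miRNA", "Total reads"] > df.loc["piRNA", "Total reads"]

    def test_truth_category_recovery_noise_free(self, noise_free):
        """>= 95% of planted reference-derived tags get their true category."""
        cfg, bun, reads, _ = noise_free
        from srnakit.preprocess import clean_reads, collapse_to_tags
        tags = collapse_to_tags(clean_reads(reads)[0])
        index = GenomeIndex.from_genome(bun.genome)
        recs = annotate_tags(tags, index, bun.references)
        truth = {}
        for m in bun.truth.planted_mirnas:
            truth[m.mature] = "miRNA" if m.is_known else "unannotated"
        for p in bun.truth.planted_pirnas:
            truth[p.sequence] = "piRNA"
        for o in bun.truth.planted_other:
            truth[o.insert] = o.category
        checked = [(r.category, truth[r.tag.sequence])
                   for r in recs if r.tag.sequence in truth]
        assert checked
        correct = sum(got == want for got, want in checked)
        assert correct / len(checked) >= 0.95


class TestChromosomeDistribution:
    def test_single_hit(self):
        rec = AnnotationRecord(CleanTag("ACGTACGTACGT", 5),
                               [MappingHit("chr1", 0, "+", 0)], "miRNA")
        assert chromosome_distribution([rec]) == {"chr1": 5.0}

    def test_fractional_multihit(self):
        rec = AnnotationRecord(
            CleanTag("ACGTACGTACGT", 4),
            [MappingHit("chr1", 0, "+", 0), MappingHit("chr2", 9, "-", 0)],
            "repeat",
        )
        assert chromosome_distribution([rec]) == {"chr1": 2.0, "chr2": 2.0}

    def test_conserves_mapped_reads(self, records):
        dist = chromosome_distribution(records)
        mapped = sum(r.tag.count for r in records if r.hits)
        assert abs(sum(dist.values()) - mapped) < 1e-6


class TestExpression:
    CATALOG = [("mA", "ACCGTTGGCAACCGTTGGCAAT"),
               ("mB", "TGCATGCATGCATGCATGCAAG"),
               ("mC", "GATCGATCGATCGATCGATCGA")]

    def _recs(self, counts):
        return [
            AnnotationRecord(CleanTag(seq, c), [], "miRNA")
            for (_, seq), c in zip(self.CATALOG, counts)
        ]

    def test_rank_order_recovered(self):
        df = quantify_known_mirnas(self._recs([1000, 100, 10]), self.CATALOG)
        assert list(df["mirna_id"]) == ["mA", "mB", "mC"]
        assert list(df["reads"]) == [1000, 100, 10]

    def test_undetected_absent(self):
        df = quantify_known_mirnas(self._recs([5, 7, 0])[:2], self.CATALOG)
        assert "mC" not in set(df["mirna_id"])

    def test_top_n_bounded(self):
        df = quantify_known_mirnas(self._recs([3, 2, 1]), self.CATALOG)
        assert len(top_n(df, 10)) <= 10
        assert len(top_n(df, 2)) == 2


class TestEditing:
    CATALOG = [("m1", "ACCGTTGGCAACCGTTGGCAAT")]

    def test_reported_above_threshold(self):
        ref = self.CATALOG[0][1]
        edited = ref[:10] + "G" + ref[11:]
        recs = [
            AnnotationRecord(CleanTag(ref, 85), [], "miRNA"),
            AnnotationRecord(CleanTag(edited, 15), [], "miRNA"),
        ]
        assert detect_editing(recs, self.CATALOG) == [("m1", 10, 0.15)]

    def test_not_reported_below_threshold(self):
        ref = self.CATALOG[0][1]
        edited = ref[:10] + "G" + ref[11:]
        recs = [
            AnnotationRecord(CleanTag(ref, 95), [], "miRNA"),
            AnnotationRecord(CleanTag(edited, 5), [], "miRNA"),
        ]
        assert detect_editing(recs, self.CATALOG) == []

    def test_no_mismatches_empty(self):
        recs = [AnnotationRecord(CleanTag(self.CATALOG[0][1], 50), [], "miRNA")]
        assert detect_editing(recs, self.CATALOG) == []

    def test_terminal_mismatches_excluded(self):
        ref = self.CATALOG[0][1]
        edited = "G" + ref[1:]  # first base differs
        recs = [
            AnnotationRecord(CleanTag(ref, 50), [], "miRNA"),
            AnnotationRecord(CleanTag(edited, 50), [], "miRNA"),
        ]
        assert detect_editing(recs, self.CATALOG) == []

    def test_planted_edits_recovered(self, bundle, records):
        found = detect_editing(records, bundle.references["mirna"])
        planted = {(mid, pos) for mid, pos, _ in bundle.truth.planted_edits}
        got = {(mid, pos) for mid, pos, _ in found}
        assert planted <= got
        for mid, pos, frac in found:
            if (mid, pos) in planted:
                assert abs(frac - 0.15) < 0.06
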