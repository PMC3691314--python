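"""piRNA analysis: catalog matching, base biases, ping-pong signature,
abundance concentration, target-class recovery."""

import numpy as np
import pytest

from srnakit.pirna_analysis import (
    TOP10_PIRNA_TABLE,
    classify_pirna_targets,
    match_pirna_catalog,
    pingpong_overlap_signature,
    positional_base_bias,
    tag_length,
    top_share,
)
from srnakit.preprocess import CleanTag
from srnakit.synthdata import simulate_pingpong_pairs
from srnakit.util import revcomp


class TestCatalogMatching:
    CATALOG = [("DQ571592.1", "AUCGGAACCUGCAGACACUCGUGGAGGCGUC"),
               ("DQ572237.1", "UAUGAGCUUUAGAAUCAGUCAAGAGG")]

    def test_exact_match_is_own_most_abundant(self):
        tag = CleanTag("ATCGGAACCTGCAGACACTCGTGGAGGCGTC", 10)
        hits = match_pirna_catalog([tag], self.CATALOG)
        assert len(hits) == 1
        assert hits[0].most_abundant_tag is tag
        assert hits[0].total_count == 10

    def test_suffix_tag_matches_published_pattern(self):
        """The published top piRNA's most abundant tag is its 30-nt
        suffix (first base missing); substring matching must catch it."""
        full = "ATCGGAACCTGCAGACACTCGTGGAGGCGTC"
        suffix = CleanTag(full[1:], 77387)
        hits = match_pirna_catalog([suffix], self.CATALOG)
        assert hits and hits[0].catalog_id == "DQ571592.1"
        assert len(hits[0].most_abundant_tag.sequence) == 30

    def test_non_matching_absent(self):
        hits = match_pirna_catalog([CleanTag("C" * 28, 5)], self.CATALOG)
        assert hits == []

    def test_most_abundant_bounded_by_total(self, records, bundle):
        pir_tags = [r.tag for r in records if r.category == "piRNA"]
        for hit in match_pirna_catalog(pir_tags, bundle.references["pirna"]):
            assert hit.most_abundant_tag.count <= hit.total_count
            assert hit.total_count == sum(t.count for t in hit.matched_tags)


class TestTagLength:
    @pytest.mark.parametrize("row", TOP10_PIRNA_TABLE,
                             ids=[r[0] for r in TOP10_PIRNA_TABLE])
    def test_published_lengths(self, row):
        pid, seq, length, _, tag_seq, tag_len, _ = row
        assert tag_length(seq) == length
        assert tag_length(tag_seq) == tag_len


class TestBaseBias:
    def test_all_t_position_one(self):
        tags = [CleanTag("TACGTACGTA", 3), CleanTag("TGCAGGCATG", 7)]
        assert positional_base_bias(tags, 1) == {"T": 1.0}

    def test_fractions_sum_to_one_weighted(self):
        rng = np.random.default_rng(0)
        tags = [CleanTag("".join(rng.choice(list("ACGT"), 27)),
                         int(rng.integers(1, 50))) for _ in range(300)]
        for pos in (1, 10, 27):
            bias = positional_base_bias(tags, pos)
            assert abs(sum(bias.values()) - 1) < 1e-12

    def test_uniform_tags_near_quarter(self):
        rng = np.random.default_rng(1)
        tags = [CleanTag("".join(rng.choice(list("ACGT"), 26)), 1)
                for _ in range(2000)]
        bias = positional_base_bias(tags, 1)
        for b in "ACGT":
            assert abs(bias[b] - 0.25) < 0.05

    def test_empty_eligible_set_errors(self):
        with pytest.raises(ValueError):
            positional_base_bias([CleanTag("ACGT", 1)], 10)


class TestPingPong:
    def test_constructed_pair_counts_once(self):
        # plus 5' at 100; minus 5' at 109 -> overlap 10
        sig = pingpong_overlap_signature(
            [("c", 100, 126)], [("c", 84, 110)]
        )
        hist = {d: n for d, n in sig.overlap_histogram.items() if n}
        assert hist == {10: 1}

    def test_no_pairs_is_missing(self):
        sig = pingpong_overlap_signature([("c", 0, 26)], [("c", 500, 526)])
        assert not any(sig.overlap_histogram.values())
        assert sig.z10 is None
        assert sig.mode is None

    def test_weighted_pairs(self):
        sig = pingpong_overlap_signature(
            [("c", 100, 126, 5)], [("c", 84, 110, 7)]
        )
        assert sig.overlap_histogram[10] == 35

    def test_simulated_library_signature(self):
        rng = np.random.default_rng(11)
        locus = "".join(rng.choice(list("ACGT"), 600))
        pp = simulate_pingpong_pairs(locus, 300, seed=4)
        plus = [("L", r.start, r.end) for r in pp if r.strand == "+"]
        minus = [("L", r.start, r.end) for r in pp if r.strand == "-"]
        sig = pingpong_overlap_signature(plus, minus)
        assert sig.mode == 10
        assert sig.z10 > 3

    def test_histogram_conserves_pairs(self):
        rng = np.random.default_rng(2)
        plus = [("c", int(s), int(s) + 26) for s in rng.integers(0, 300, 40)]
        minus = [("c", int(s), int(s) + 26) for s in rng.integers(0, 300, 40)]
        sig = pingpong_overlap_signature(plus, minus)
        expected = sum(
            1
            for _, ps, pe in plus
            for _, ms, me in minus
            if ms < pe and ps < me and 1 <= (me - 1) - ps + 1 <= 30
        )
        assert sum(sig.overlap_histogram.values()) == expected


class TestTopShare:
    def test_single_entry(self):
        assert top_share([42], 1) == 1.0

    def test_arithmetic(self):
        assert top_share([50, 30, 20], 2) == pytest.approx(0.8)

    def test_planted_61_percent(self, records, bundle):
        import pandas as pd
        pir_tags = [r.tag for r in records if r.category == "piRNA"
                    and 24 <= len(r.tag.sequence) <= 32]
        hits = match_pirna_catalog(pir_tags, bundle.references["pirna"])
        expr = pd.DataFrame({"reads": [h.total_count for h in hits]})
        assert top_share(expr, 10) == pytest.approx(0.61, abs=0.02)

    def test_errors(self):
        with pytest.raises(ValueError):
            top_share([], 1)
        with pytest.raises(ValueError):
            top_share([1, 2], 0)


class TestTargetClasses:
    def test_antisense_line1_assignment(self):
        pirna = "TGGGAACGAGAAGACACTCATGGAGG"
        ref = "AAAA" + revcomp(pirna) + "CCCC"
        fractions, per = classify_pirna_targets(
            [("p1", pirna)], [("retrotransposon:LINE1", "L1a", ref)]
        )
        assert per["p1"] == "retrotransposon:LINE1"
        assert fractions == {"retrotransposon:LINE1": 1.0}

    def test_unmatched_is_unassigned(self):
        fractions, per = classify_pirna_targets(
            [("p1", "ACGT" * 7)], [("repeat", "r1", "TTTT" * 20)]
        )
        assert per["p1"] == "unassigned"
        assert fractions == {}

    def test_planted_class_mix_recovered(self, bundle):
        """~75% of planted piRNAs target retrotransposons, as configured."""
        pirnas = [(p.pirna_id, p.sequence) for p in bundle.truth.planted_pirnas
                  if not p.pirna_id.startswith("pp")]
        fractions, per = classify_pirna_targets(pirnas, bundle.labeled_repeats)
        planted = bundle.truth.pirna_target_classes
        correct = sum(per[pid] == planted[pid] for pid, _ in pirnas
                      if planted[pid] != "unassigned")
        n_assigned = sum(1 for pid, _ in pirnas if planted[pid] != "unassigned")
        assert correct / n_assigned >= 0.95
        retro = sum(v for k, v in fractions.items()
                    if k.startswith("retrotransposon"))
        assert retro == pytest.approx(0.75, abs=0.05)
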