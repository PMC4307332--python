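"""Junction screening filters: counts, repeats, novelty, EST support."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from splicevar.annotation_io import AnnotationSet, GenomicInterval, TranscriptModel
from splicevar.junction_screen import (
    JunctionEvidence,
    ScreenConfig,
    filter_by_counts,
    filter_by_novelty,
    filter_by_repeats,
    filter_by_support,
    read_junctions,
    screen,
    write_junctions,
)


def jev(start=1000, end=1200, counts=(5, 3), contig="c", strand="+"):
    return JunctionEvidence(
        GenomicInterval(contig, start, end, strand),
        tuple(counts),
        tuple(f"s{i}" for i in range(len(counts))),
    )


def toy_annotation():
    t = TranscriptModel(
        "t1", "g1",
        exons=[
            GenomicInterval("c", 800, 1000),
            GenomicInterval("c", 1200, 1400),
            GenomicInterval("c", 1600, 1800),
        ],
    )
    return AnnotationSet([t])


class TestCountFilter:
    @pytest.mark.parametrize(
        "counts,min_reads,expected",
        [
            ((2, 0), 2, True),   # two reads in at least one dataset
            ((1, 1), 2, False),  # fewer than two reads per sample everywhere
            ((0, 0), 0, True),   # threshold zero passes everything
        ],
    )
    def test_threshold_semantics(self, counts, min_reads, expected):
        cfg = ScreenConfig(min_reads_per_sample=min_reads)
        assert filter_by_counts(jev(counts=counts), cfg) is expected


class TestRepeatFilter:
    def test_donor_site_inside_repeat_fails_either_site(self):
        cfg = ScreenConfig(repeat_policy="either_site")
        repeats = [GenomicInterval("c", 995, 1005)]
        assert not filter_by_repeats(jev(), repeats, cfg)

    def test_repeat_deep_inside_intron_passes_either_site(self):
        cfg = ScreenConfig(repeat_policy="either_site")
        repeats = [GenomicInterval("c", 1100, 1110)]  # 100 nt from both sites
        assert filter_by_repeats(jev(), repeats, cfg)

    def test_same_repeat_fails_any_overlap(self):
        cfg = ScreenConfig(repeat_policy="any_overlap")
        repeats = [GenomicInterval("c", 1100, 1110)]
        assert not filter_by_repeats(jev(), repeats, cfg)

    def test_matches_brute_force_intersection(self):
        """Interval logic agrees with base-by-base membership on random cases."""
        rng = random.Random(11)
        for _ in range(200):
            a = rng.randrange(0, 500)
            b = a + rng.randrange(4, 100)
            r0 = rng.randrange(0, 600)
            repeats = [GenomicInterval("c", r0, r0 + rng.randrange(1, 50))]
            j = jev(a, b)
            rep_bases = set(range(repeats[0].start, repeats[0].end))
            site_bases = {a, a + 1, b - 2, b - 1}
            expected_site = not (site_bases & rep_bases)
            expected_any = not (set(range(a, b)) & rep_bases)
            assert filter_by_repeats(
                j, repeats, ScreenConfig(repeat_policy="either_site")
            ) is expected_site
            assert filter_by_repeats(
                j, repeats, ScreenConfig(repeat_policy="any_overlap")
            ) is expected_any


class TestNoveltyFilter:
    def test_exact_annotated_intron_is_not_novel(self):
        ann = toy_annotation()
        assert not filter_by_novelty(jev(1000, 1200), ann)

    def test_shared_donor_only_is_novel(self):
        ann = toy_annotation()
        assert filter_by_novelty(jev(1000, 1600), ann)

    def test_every_annotated_intron_fails(self):
        ann = toy_annotation()
        for intron in ann.introns():
            j = jev(intron.start, intron.end)
            assert not filter_by_novelty(j, ann)


class TestSupportFilter:
    def test_exact_match_passes(self):
        cfg = ScreenConfig()
        support = [GenomicInterval("c", 1000, 1200), GenomicInterval("c", 1000, 1200)]
        assert filter_by_support(jev(), support, cfg)

    def test_missing_support_fails_unless_disabled(self):
        assert not filter_by_support(jev(), [], ScreenConfig())
        assert filter_by_support(jev(), [], ScreenConfig(support_required=False))


class TestScreen:
    def test_first_failed_filter_is_recorded(self):
        ann = toy_annotation()
        low = jev(1000, 1600, counts=(1, 1))
        rep = screen([low], ann, repeats=[GenomicInterval("c", 998, 1002)],
                     support=[])
        # the count filter fires before the repeat filter
        assert rep.rejections[low] == "LOW_COUNT"

    def test_empty_input_empty_report(self):
        rep = screen([], toy_annotation())
        assert rep.candidates == [] and rep.rejections == {}

    def test_partition_and_order_independence(self):
        ann = toy_annotation()
        js_ = [
            jev(1000, 1600),
            jev(1000, 1200),
            jev(1000, 1600, counts=(1, 0)),
        ]
        sup = [GenomicInterval("c", 1000, 1600)]
        r1 = screen(js_, ann, support=sup)
        r2 = screen(list(reversed(js_)), ann, support=sup)
        assert len(r1.candidates) + len(r1.rejections) == len(js_)
        assert set(r1.candidates) == set(r2.candidates)
        assert r1.rejections == r2.rejections

    @settings(derandomize=True, max_examples=60)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 6)), min_size=1, max_size=20
        ),
        threshold=st.integers(0, 5),
    )
    def test_candidate_count_monotone_in_threshold(self, counts, threshold):
        ann = toy_annotation()
        js_ = [jev(1000 + 10 * i, 1600, counts=c) for i, c in enumerate(counts)]
        sup = [j.intron for j in js_]
        lo = screen(js_, ann, [], sup, ScreenConfig(min_reads_per_sample=threshold))
        hi = screen(js_, ann, [], sup, ScreenConfig(min_reads_per_sample=threshold * 2))
        assert len(hi.candidates) <= len(lo.candidates)


class TestJunctionTable:
    def test_round_trip(self, tmp_path):
        js_ = [jev(counts=(2, 0)), jev(2000, 2400, counts=(7, 1))]
        p = tmp_path / "j.tsv"
        write_junctions(js_, p)
        assert read_junctions(p) == js_

    def test_missing_header_is_an_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("c\t10\t200\t+\t5,3\n")
        with pytest.raises(ValueError, match="samples"):
            read_junctions(p)
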