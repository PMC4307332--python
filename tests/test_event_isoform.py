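"""Event classification geometry and isoform reconstruction."""

import pytest

from splicevar import (
    classify,
    classify_all,
    evaluate_bundle,
    generate_custom_genome,
    read_bed,
    read_genome,
    read_gtf,
    read_junctions,
    reconstruct,
    screen,
)
from splicevar.annotation_io import (
    AnnotationSet,
    GenomeRef,
    GenomicInterval,
    TranscriptModel,
    spliced_sequence,
)
from splicevar.event_isoform import (
    UnclassifiableError,
    check_splice_sites,
    intron_dinucleotides,
)
from splicevar.junction_screen import JunctionEvidence


def jev(start, end, contig="c", strand="+"):
    return JunctionEvidence(
        GenomicInterval(contig, start, end, strand), (5,), ("s1",)
    )


@pytest.fixture
def five_exon_ann():
    exons = [
        GenomicInterval("c", 100, 200),
        GenomicInterval("c", 300, 400),
        GenomicInterval("c", 500, 600),
        GenomicInterval("c", 700, 800),
        GenomicInterval("c", 900, 1000),
    ]
    return AnnotationSet([TranscriptModel("t1", "g1", exons=exons)])


class TestClassify:
    def test_cassette_skip(self, five_exon_ann):
        ev = classify(jev(200, 500), five_exon_ann)
        assert ev.category == "CASSETTE_SKIP"
        assert ev.skipped_exon_indices == [2]

    def test_multi_exon_skip(self, five_exon_ann):
        ev = classify(jev(200, 700), five_exon_ann)
        assert ev.category == "MULTI_EXON_SKIP"
        assert ev.skipped_exon_indices == [2, 3]

    def test_alt_donor_inside_exon(self, five_exon_ann):
        ev = classify(jev(150, 300), five_exon_ann)
        assert ev.category == "ALT_DONOR"
        assert ev.novel_donor == 150

    def test_alt_donor_plus_skip(self, five_exon_ann):
        ev = classify(jev(150, 500), five_exon_ann)
        assert ev.category == "ALT_DONOR_PLUS_SKIP"
        assert ev.skipped_exon_indices == [2]

    def test_intron_internal_acceptor_unpaired(self, five_exon_ann):
        ev = classify(jev(200, 250), five_exon_ann)
        assert ev.category == "ALT_ACCEPTOR"

    def test_annotated_intron_is_unclassifiable(self, five_exon_ann):
        with pytest.raises(UnclassifiableError):
            classify(jev(200, 300), five_exon_ann)

    def test_no_template_is_unclassifiable(self, five_exon_ann):
        with pytest.raises(UnclassifiableError, match="template"):
            classify(jev(200, 500, contig="other"), five_exon_ann)

    def test_exon_gain_needs_a_pair(self, five_exon_ann):
        pair = [jev(200, 240), jev(260, 300)]
        events, failures = classify_all(pair, five_exon_ann)
        assert [e.category for e in events] == ["EXON_GAIN"]
        assert [(g.start, g.end) for g in events[0].gained_exons] == [(240, 260)]
        assert not failures

    def test_cryptic_acceptor_inside_gained_exon(self, five_exon_ann):
        triple = [jev(200, 240), jev(200, 250), jev(260, 300)]
        events, _ = classify_all(triple, five_exon_ann)
        cats = sorted(e.category for e in events)
        assert cats == ["EXON_GAIN", "EXON_GAIN_CRYPTIC_ACCEPTOR"]
        cryptic = next(
            e for e in events if e.category == "EXON_GAIN_CRYPTIC_ACCEPTOR"
        )
        assert [(g.start, g.end) for g in cryptic.gained_exons] == [(250, 260)]


class TestReconstruct:
    def test_skip_length_conservation(self, five_exon_ann):
        genome = GenomeRef({"c": "A" * 1100})
        ev = classify(jev(200, 500), five_exon_ann)
        iso = reconstruct(ev, genome)
        template_len = five_exon_ann.transcripts["t1"].length
        assert len(iso.sequence) == template_len - 100

    def test_gain_adds_exactly_the_gained_exon(self, five_exon_ann):
        genome = GenomeRef({"c": "A" * 1100})
        events, _ = classify_all([jev(200, 240), jev(260, 300)], five_exon_ann)
        iso = reconstruct(events[0], genome)
        template_len = five_exon_ann.transcripts["t1"].length
        assert len(iso.sequence) == template_len + 20

    def test_idempotent(self, five_exon_ann):
        genome = GenomeRef({"c": "A" * 1100})
        ev = classify(jev(200, 500), five_exon_ann)
        a = reconstruct(ev, genome, isoform_id="x")
        b = reconstruct(ev, genome, isoform_id="x")
        assert a.exons == b.exons and a.sequence == b.sequence


class TestSpliceSites:
    def test_canonical_plus(self):
        genome = GenomeRef({"c": "AAAAAGTAAGTTTTTTTTAGAAAAA"})
        intron = GenomicInterval("c", 5, 20, "+")
        assert intron_dinucleotides(intron, genome) == ("GT", "AG")

    def test_canonical_after_minus_strand_projection(self):
        # reverse complement of GT..AG is CT..AC read forward
        genome = GenomeRef({"c": "AAAAACTAAGTTTTTTTACAAAAA"})
        intron = GenomicInterval("c", 5, 19, "-")
        assert intron_dinucleotides(intron, genome) == ("GT", "AG")

    def test_minor_class_names(self, five_exon_ann):
        genome = GenomeRef({"c": "A" * 200 + "GC" + "A" * 296 + "AG" + "A" * 600})
        ev = classify(jev(200, 500), five_exon_ann)
        sites = check_splice_sites(ev, genome)
        assert sites[0]["class"] == "GC-AG"

    def test_all_annotated_introns_canonical_on_generated_fixture(self, tmp_path):
        bundle = generate_custom_genome(20, (3, 6), seed=1, out_dir=tmp_path)
        genome = read_genome(bundle.genome_path)
        ann = read_gtf(bundle.annotation_path)
        for intron in ann.introns():
            assert intron_dinucleotides(intron, genome) == ("GT", "AG")


class TestStrandInvariance:
    @pytest.mark.parametrize(
        "name", ["satb1_skip_start_exon", "znf266_upstream_aug", "elf2_exon_gain"]
    )
    def test_mirrored_fixture_gives_identical_isoform_sequence(
        self, bundle_factory, name
    ):
        seqs = {}
        for strand in "+-":
            b = bundle_factory(name, seed=2, strand=strand)
            genome = read_genome(b.genome_path)
            ann = read_gtf(b.annotation_path)
            juncs = read_junctions(b.junctions_path)
            rep = screen(juncs, ann, read_bed(b.repeats_path),
                         read_bed(b.est_support_path))
            events, _ = classify_all(rep.candidates, ann)
            focus = [e for e in events if e.category == b.truth["category"]]
            iso = reconstruct(focus[0], genome)
            seqs[strand] = (focus[0].category, iso.sequence)
        assert seqs["+"] == seqs["-"]


class TestInjectedCategoryRecovery:
    def test_pipeline_recovers_every_injected_category(self, tmp_path):
        bundle = generate_custom_genome(20, (3, 6), seed=1, out_dir=tmp_path)
        ann = read_gtf(bundle.annotation_path)
        juncs = read_junctions(bundle.junctions_path)
        rep = screen(juncs, ann, [], read_bed(bundle.est_support_path))
        assert not rep.rejections
        events, failures = classify_all(rep.candidates, ann)
        assert not failures
        got = {}
        for e in events:
            got.setdefault(e.template.gene_id, e.category)
        assert got == bundle.truth
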