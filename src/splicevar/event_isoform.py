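"""Alternative-splicing event classification and novel-isoform reconstruction.

A candidate junction is interpreted against a template transcript chosen from
the annotation. The realised geometries are: skipping of one (cassette) or
several whole exons; an alternative donor inside an exon, optionally bypassing
downstream exons; an alternative acceptor; and gain of an unannotated exon
inside an annotated intron, evidenced by a junction *pair* bracketing the
gained interval (with an optional cryptic acceptor inside the gained exon).

Reconstruction is template editing: the novel isoform's exon chain is the
template chain with skipped exons removed, exon bounds trimmed, or gained
exons inserted, and its spliced sequence recomputed from the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation_io import (
    AnnotationSet,
    GenomeRef,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    spliced_sequence,
)
from .junction_screen import JunctionEvidence

__all__ = [
    "SpliceEvent",
    "NovelIsoform",
    "UnclassifiableError",
    "choose_template",
    "classify",
    "classify_all",
    "reconstruct",
    "check_splice_sites",
]

CASSETTE_SKIP = "CASSETTE_SKIP"
MULTI_EXON_SKIP = "MULTI_EXON_SKIP"
ALT_DONOR = "ALT_DONOR"
ALT_ACCEPTOR = "ALT_ACCEPTOR"
ALT_DONOR_PLUS_SKIP = "ALT_DONOR_PLUS_SKIP"
EXON_GAIN = "EXON_GAIN"
EXON_GAIN_CRYPTIC_ACCEPTOR = "EXON_GAIN_CRYPTIC_ACCEPTOR"

CATEGORIES = (
    CASSETTE_SKIP,
    MULTI_EXON_SKIP,
    ALT_DONOR,
    ALT_ACCEPTOR,
    ALT_DONOR_PLUS_SKIP,
    EXON_GAIN,
    EXON_GAIN_CRYPTIC_ACCEPTOR,
)

MINOR_SITE_CLASSES = {("GC", "AG"): "GC-AG", ("AT", "AC"): "AT-AC"}


class UnclassifiableError(ValueError):
    """Junction geometry matches no supported event category."""


@dataclass
class SpliceEvent:
    """A classified alternative-splicing event on a template transcript.

    ``skipped_exon_indices`` are 1-based in transcript order; ``gained_exons``
    lie wholly within one template intron.
    """

    junctions: tuple[JunctionEvidence, ...]
    template: TranscriptModel
    category: str
    skipped_exon_indices: list[int] = field(default_factory=list)
    gained_exons: list[GenomicInterval] = field(default_factory=list)
    # genomic positions of non-boundary splice-site cuts, if any
    novel_donor: int | None = None
    novel_acceptor: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class NovelIsoform:
    isoform_id: str
    event: SpliceEvent
    exons: list[GenomicInterval]
    sequence: str
    splice_sites_canonical: list[bool]

    def __post_init__(self) -> None:
        if len(self.sequence) != sum(len(e) for e in self.exons):
            raise ValueError("sequence length must equal the exon-chain length")

    def as_transcript_model(self) -> TranscriptModel:
        t = self.event.template
        return TranscriptModel(
            transcript_id=self.isoform_id,
            gene_id=t.gene_id,
            gene_symbol=t.gene_symbol,
            exons=list(self.exons),
        )


# ---------------------------------------------------------------------------
# template choice
# ---------------------------------------------------------------------------


def _shared_sites(t: TranscriptModel, j: JunctionEvidence) -> int:
    bounds = set()
    for e in t.exons:
        bounds.update((e.start, e.end))
    return int(j.intron.start in bounds) + int(j.intron.end in bounds)


def choose_template(
    j: JunctionEvidence, ann: AnnotationSet
) -> TranscriptModel | None:
    """Pick the template: most shared splice sites, then longest CDS, then id."""
    contenders = [
        t
        for t in ann
        if t.contig == j.intron.contig
        and t.strand == j.intron.strand
        and t.exons[0].start <= j.intron.start
        and j.intron.end <= t.exons[-1].end
    ]
    if not contenders:
        return None
    return max(
        contenders,
        key=lambda t: (_shared_sites(t, j), t.cds_length(), t.transcript_id),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _tx_index(t: TranscriptModel, genomic_index: int) -> int:
    """Genomic exon index (0-based) -> 1-based transcript-order exon number."""
    n = len(t.exons)
    return genomic_index + 1 if t.strand == "+" else n - genomic_index


def _locate(t: TranscriptModel, pos: int, side: str) -> tuple[str, int]:
    """Relate a junction end to the template exon chain.

    ``side`` is "left" (pos compared against exon ends) or "right" (against
    exon starts). Returns (relation, genomic exon index) where relation is
    "boundary", "inside" or "intron"; for "intron" the index is that of the
    genomically preceding exon.
    """
    for i, e in enumerate(t.exons):
        if side == "left" and e.end == pos:
            return "boundary", i
        if side == "right" and e.start == pos:
            return "boundary", i
        if e.start < pos < e.end:
            return "inside", i
    for i, (a, b) in enumerate(zip(t.exons, t.exons[1:])):
        if a.end <= pos <= b.start:
            return "intron", i
    raise UnclassifiableError(f"position {pos} outside the template exon span")


def classify(
    j: JunctionEvidence,
    ann: AnnotationSet,
    template: TranscriptModel | None = None,
) -> SpliceEvent:
    """Classify a single candidate junction (exon-gain pairs: see classify_all)."""
    t = template or choose_template(j, ann)
    if t is None:
        raise UnclassifiableError(
            f"no overlapping template transcript for {j.intron}"
        )
    a, b = j.intron.start, j.intron.end
    rel_a, i = _locate(t, a, "left")
    rel_b, k = _locate(t, b, "right")
    plus = t.strand == "+"

    if rel_a == "boundary" and rel_b == "boundary":
        if k == i + 1:
            raise UnclassifiableError("junction matches an annotated intron")
        skipped = [_tx_index(t, g) for g in range(i + 1, k)]
        cat = CASSETTE_SKIP if len(skipped) == 1 else MULTI_EXON_SKIP
        return SpliceEvent((j,), t, cat, skipped_exon_indices=sorted(skipped))

    if rel_a == "inside" and rel_b == "boundary":
        skipped = [_tx_index(t, g) for g in range(i + 1, k)]
        if plus:  # donor cut inside exon i
            cat = ALT_DONOR_PLUS_SKIP if skipped else ALT_DONOR
            return SpliceEvent(
                (j,), t, cat, skipped_exon_indices=sorted(skipped), novel_donor=a
            )
        # minus strand: the intra-exon cut is on the acceptor side
        return SpliceEvent(
            (j,), t, ALT_ACCEPTOR, skipped_exon_indices=sorted(skipped),
            novel_acceptor=a,
        )

    if rel_a == "boundary" and rel_b == "inside":
        skipped = [_tx_index(t, g) for g in range(i + 1, k)]
        if plus:
            return SpliceEvent(
                (j,), t, ALT_ACCEPTOR, skipped_exon_indices=sorted(skipped),
                novel_acceptor=b,
            )
        cat = ALT_DONOR_PLUS_SKIP if skipped else ALT_DONOR
        return SpliceEvent(
            (j,), t, cat, skipped_exon_indices=sorted(skipped), novel_donor=b
        )

    if rel_a == "boundary" and rel_b == "intron" and k == i:
        # junction ends inside the intron following exon i (unpaired)
        cat = ALT_ACCEPTOR if plus else ALT_DONOR
        ev = SpliceEvent((j,), t, cat)
        if plus:
            ev.novel_acceptor = b
        else:
            ev.novel_donor = b
        return ev
    if rel_a == "intron" and rel_b == "boundary" and i == k - 1:
        cat = ALT_DONOR if plus else ALT_ACCEPTOR
        ev = SpliceEvent((j,), t, cat)
        if plus:
            ev.novel_donor = a
        else:
            ev.novel_acceptor = a
        return ev

    raise UnclassifiableError(
        f"unsupported junction geometry [{a}, {b}) on {t.transcript_id}"
    )


def _gain_part(
    j: JunctionEvidence, t: TranscriptModel
) -> tuple[str, int] | None:
    """Is ``j`` one half of an exon-gain pair inside a template intron?

    Returns ("left"|"right", intron index) or None. A "left" part runs from an
    annotated exon end to a point strictly inside the intron; a "right" part
    from inside the intron to the next annotated exon start.
    """
    a, b = j.intron.start, j.intron.end
    for idx, (e1, e2) in enumerate(zip(t.exons, t.exons[1:])):
        if a == e1.end and e1.end < b < e2.start:
            return "left", idx
        if b == e2.start and e1.end < a < e2.start:
            return "right", idx
    return None


def classify_all(
    junctions: Sequence[JunctionEvidence],
    ann: AnnotationSet,
) -> tuple[list[SpliceEvent], dict[JunctionEvidence, str]]:
    """Classify a set of candidate junctions, pairing exon-gain halves.

    Junction pairs whose ends bracket an unannotated interval inside one
    template intron become EXON_GAIN events; additional acceptors inside the
    gained exon become EXON_GAIN_CRYPTIC_ACCEPTOR. Everything else is
    classified singly. Returns (events, unclassifiable reasons).
    """
    events: list[SpliceEvent] = []
    failures: dict[JunctionEvidence, str] = {}
    groups: dict[tuple[str, int], list[tuple[str, JunctionEvidence]]] = {}
    singles: list[tuple[JunctionEvidence, TranscriptModel | None]] = []

    for j in junctions:
        t = choose_template(j, ann)
        part = _gain_part(j, t) if t is not None else None
        if part is not None:
            groups.setdefault((t.transcript_id, part[1]), []).append((part[0], j))
        else:
            singles.append((j, t))

    for (tid, intron_idx), members in sorted(groups.items()):
        t = ann.transcripts[tid]
        lefts = sorted(
            (j for side, j in members if side == "left"),
            key=lambda j: j.intron.end,
        )
        rights = sorted(
            (j for side, j in members if side == "right"),
            key=lambda j: j.intron.start,
        )
        if not lefts or not rights:
            # unpaired halves fall back to single-junction classification
            for _, j in members:
                singles.append((j, t))
            continue
        plus = t.strand == "+"
        # acceptor-side halves carry the cryptic-acceptor alternatives
        if plus:
            acceptors, donors = lefts, rights
        else:
            acceptors, donors = rights, lefts
        # the acceptor nearest the annotated donor defines the full gained exon
        acceptors = acceptors if plus else list(reversed(acceptors))
        for d in donors:
            for rank, acc in enumerate(acceptors):
                if plus:
                    x, y = acc.intron.end, d.intron.start
                else:
                    x, y = d.intron.end, acc.intron.start
                if x >= y:
                    failures[acc] = "exon-gain pair brackets an empty interval"
                    continue
                gained = GenomicInterval(t.contig, x, y, t.strand)
                cat = EXON_GAIN if rank == 0 else EXON_GAIN_CRYPTIC_ACCEPTOR
                pair = (acc, d) if plus else (d, acc)
                events.append(
                    SpliceEvent(pair, t, cat, gained_exons=[gained])
                )

    for j, t in singles:
        try:
            events.append(classify(j, ann, template=t))
        except UnclassifiableError as exc:
            failures[j] = str(exc)
    return events, failures


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def reconstruct(
    e: SpliceEvent, genome: GenomeRef, isoform_id: str | None = None
) -> NovelIsoform:
    """Edit the template exon chain per the event and resplice the sequence."""
    t = e.template
    n = len(t.exons)
    skipped_genomic = {
        (idx - 1) if t.strand == "+" else (n - idx)
        for idx in e.skipped_exon_indices
    }
    chain: list[list[int]] = [
        [ex.start, ex.end]
        for g, ex in enumerate(t.exons)
        if g not in skipped_genomic
    ]

    for j in e.junctions:
        a, b = j.intron.start, j.intron.end
        for bounds in chain:
            if bounds[0] < a < bounds[1]:  # cut removes the exon tail
                bounds[1] = a
            if bounds[0] < b < bounds[1]:  # cut removes the exon head
                bounds[0] = b

    for g in e.gained_exons:
        chain.append([g.start, g.end])
    chain.sort()

    exons = []
    for s, t_end in chain:
        if s >= t_end:
            raise ValueError("event edits produce a zero-length exon")
        exons.append(GenomicInterval(t.contig, s, t_end, t.strand))
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValueError("event edits produce overlapping exons")

    iso_id = isoform_id or f"{t.transcript_id}.novel.{e.category}"
    model = TranscriptModel(
        transcript_id=iso_id,
        gene_id=t.gene_id,
        gene_symbol=t.gene_symbol,
        exons=exons,
    )
    seq = spliced_sequence(model, genome)
    sites = check_splice_sites(e, genome)
    return NovelIsoform(
        isoform_id=iso_id,
        event=e,
        exons=exons,
        sequence=seq,
        splice_sites_canonical=[s["class"] == "canonical" for s in sites],
    )


def intron_dinucleotides(
    intron: GenomicInterval, genome: GenomeRef
) -> tuple[str, str]:
    """(donor, acceptor) dinucleotides of an intron on its own strand."""
    left = genome.fetch(
        GenomicInterval(intron.contig, intron.start, intron.start + 2)
    )
    right = genome.fetch(
        GenomicInterval(intron.contig, intron.end - 2, intron.end)
    )
    if intron.strand == "+":
        return left, right
    return reverse_complement(right), reverse_complement(left)


def check_splice_sites(e: SpliceEvent, genome: GenomeRef) -> list[dict]:
    """Per-junction splice-site class: canonical GT..AG, minor GC-AG / AT-AC,
    or noncanonical."""
    out = []
    for j in e.junctions:
        donor, acceptor = intron_dinucleotides(j.intron, genome)
        if (donor, acceptor) == ("GT", "AG"):
            cls = "canonical"
        else:
            cls = MINOR_SITE_CLASSES.get((donor, acceptor), "noncanonical")
        out.append({"donor": donor, "acceptor": acceptor, "class": cls})
    return out
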