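"""Deterministic synthetic fixtures for the splice-variant pipeline.

Each preset scenario engineers a toy gene whose structure reproduces one of
the validated variant geometries: skipping of the start-codon exon with a
downstream in-frame AUG, gain of an unannotated exon (with or without a
cryptic acceptor inside it), in-frame modular-exon skipping, multi-exon
skipping with frameshift and PTC, and an event creating an upstream in-frame
AUG. A bundle is a directory of standard-format files (FASTA genome, GTF
annotation, BED repeats and EST-support introns, a junction table, primer and
domain TSVs) plus a flat key-value truth file recording every expected
downstream result, so the whole pipeline can be scored against it.

Construction guarantees, by design rather than by chance:

* every annotated and every engineered novel intron is GT..AG on the gene
  strand;
* the spliced transcript contains no AUG other than the engineered ones
  (random stretches are drawn so that "ATG" cannot occur, and coding codons
  come from a codon set that can form neither ATG nor a stop across codon
  boundaries);
* decoy ORFs (e.g. the canonical AUG after an exon gain breaks its frame)
  terminate within fewer than 30 codons, below the default ORF-reporting
  threshold;
* read counts are fixed integers taken from the scenario parameters, so
  filter outcomes are deterministic;
* the three negative controls differ from the start-exon-skip scenario only
  in the single violated screening property.

The same gene can be emitted on either strand: the generator builds the plus
orientation and mirrors the whole contig, which leaves all transcript-level
truth identical.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_io import (
    GenomeRef,
    GenomicInterval,
    TranscriptModel,
    write_bed,
    write_genome,
    write_gtf,
)
from .junction_screen import JunctionEvidence, write_junctions
from .orf_consequence import DomainAnnotation, write_domains
from .validation_toolkit import PrimerPair, write_primers

__all__ = [
    "ScenarioSpec",
    "FixtureBundle",
    "PRESET_NAMES",
    "POSITIVE_PRESETS",
    "NEGATIVE_PRESETS",
    "generate_scenario",
    "generate_custom_genome",
    "load_truth",
]

STOPS = ("TAA", "TAG", "TGA")

# Codons that can never create an ATG or an in-frame stop, even across codon
# boundaries: no stop codons, not ATG itself, and no codon starting with "G"
# or "TG" (which could complete ATG after a codon ending in "AT" or "A").
SAFE_CODONS = tuple(
    a + b + c
    for a in "ACT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
    and a + b + c != "ATG"
    and not (a == "G")
    and not (a + b == "TG")
)

POSITIVE_PRESETS = (
    "satb1_skip_start_exon",
    "elf2_exon_gain",
    "elf2_cryptic_acceptor",
    "sp140l_inframe_skip",
    "arid5b_inframe_skip",
    "ncoa2_frameshift_skip",
    "irf1_multiskip_inframe",
    "irf1_multiskip_ptc",
    "znf266_upstream_aug",
)
NEGATIVE_PRESETS = (
    "lowcount_junction",
    "repeat_overlap_junction",
    "unsupported_junction",
)
PRESET_NAMES = POSITIVE_PRESETS + NEGATIVE_PRESETS


class ScenarioError(ValueError):
    """Invalid scenario parameters; the message names the offending field."""


@dataclass
class ScenarioSpec:
    """Identifies one synthetic scenario: preset name, seed, strand, params."""

    name: str
    seed: int = 0
    n_samples: int = 2
    strand: str = "+"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in PRESET_NAMES and self.name != "custom":
            raise ScenarioError(f"name: unknown scenario {self.name!r}")
        if self.n_samples < 1:
            raise ScenarioError("n_samples: must be >= 1")
        if self.strand not in ("+", "-"):
            raise ScenarioError("strand: must be '+' or '-'")
        counts = self.params.get("counts")
        if counts is not None:
            if len(counts) != self.n_samples:
                raise ScenarioError("counts: length must equal n_samples")
            if any(int(c) < 0 for c in counts):
                raise ScenarioError("counts: must be non-negative")
        ac = self.params.get("annotated_codons")
        if ac is not None and int(ac) < 150:
            raise ScenarioError("annotated_codons: must be >= 150")


@dataclass
class FixtureBundle:
    out_dir: Path
    genome_path: Path
    annotation_path: Path
    repeats_path: Path
    est_support_path: Path
    junctions_path: Path
    primers_path: Path
    domains_path: Path
    truth_path: Path
    truth: dict[str, str]


def load_truth(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            k, _, v = line.rstrip("\n").partition("\t")
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# sequence assembly primitives
# ---------------------------------------------------------------------------


class _Asm:
    """Assembles a transcript-level sequence while guaranteeing that no
    unintended ATG can form, including across piece boundaries."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.parts: list[str] = []
        self.tail = ""

    def random(self, n: int) -> str:
        out = []
        t = self.tail
        for _ in range(n):
            while True:
                b = self.rng.choice("ACGT")
                if t[-2:] == "AT" and b == "G":
                    continue
                break
            out.append(b)
            t = (t + b)[-2:]
        s = "".join(out)
        self.tail = t
        self.parts.append(s)
        return s

    def emit(self, s: str, allow_atg: bool = False) -> str:
        joint = self.tail + s[:2]
        if "ATG" in joint and not (allow_atg and s.startswith("ATG")):
            raise ScenarioError("construction: ATG formed at a piece boundary")
        if not allow_atg and "ATG" in s:
            raise ScenarioError("construction: unintended ATG in emitted piece")
        self.tail = ((self.tail + s)[-2:]) if s else self.tail
        self.parts.append(s)
        return s

    @property
    def seq(self) -> str:
        return "".join(self.parts)


def _codons(rng: random.Random, n: int, patches: dict[int, str] | None = None,
             terminal_stop: bool = True) -> str:
    """``n`` coding codons from the safe set, with engineered overrides."""
    patches = patches or {}
    out = []
    for i in range(n):
        out.append(patches.get(i) or rng.choice(SAFE_CODONS))
    if terminal_stop:
        out.append("TAA")
    return "".join(out)


def _plain_random(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _intron(rng: random.Random, n: int = 100) -> str:
    if n < 4:
        raise ScenarioError("intron_len: must be >= 4")
    return "GT" + _plain_random(rng, n - 4) + "AG"


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------


@dataclass
class _Build:
    contig_id: str
    contig_seq: str
    transcript: TranscriptModel
    tx_seq: str
    junctions: list[JunctionEvidence] = field(default_factory=list)
    repeats: list[GenomicInterval] = field(default_factory=list)
    support: list[GenomicInterval] = field(default_factory=list)
    primers: list[PrimerPair] = field(default_factory=list)
    domains: list[DomainAnnotation] = field(default_factory=list)
    truth: dict[str, str] = field(default_factory=dict)


def _layout(
    rng: random.Random,
    contig_id: str,
    gene: str,
    tx: str,
    cuts: list[int],
    cds_tx: tuple[int, int] | None,
    custom_introns: dict[int, str] | None = None,
    pad: int = 80,
) -> tuple[str, list[GenomicInterval], TranscriptModel]:
    """Place transcript pieces on a plus-strand contig with GT..AG introns.

    ``cuts`` are internal transcript offsets splitting ``tx`` into exons;
    ``cds_tx`` the transcript-offset CDS bounds (stop codon included).
    """
    bounds = [0, *cuts, len(tx)]
    exon_seqs = [tx[a:b] for a, b in zip(bounds, bounds[1:])]
    custom_introns = custom_introns or {}
    parts = [_plain_random(rng, pad)]
    pos = pad
    exon_ivs: list[GenomicInterval] = []
    tx2g: list[tuple[int, int]] = []  # (tx offset of exon start, genomic start)
    tx_off = 0
    for i, es in enumerate(exon_seqs):
        exon_ivs.append(GenomicInterval(contig_id, pos, pos + len(es)))
        tx2g.append((tx_off, pos))
        parts.append(es)
        pos += len(es)
        tx_off += len(es)
        if i < len(exon_seqs) - 1:
            iseq = custom_introns.get(i) or _intron(rng)
            parts.append(iseq)
            pos += len(iseq)
    parts.append(_plain_random(rng, pad))
    contig = "".join(parts)

    def to_genomic(off: int) -> int:
        for (ts, gs), e in zip(tx2g, exon_ivs):
            if ts <= off < ts + len(e):
                return gs + (off - ts)
        raise ScenarioError(f"construction: offset {off} not exonic")

    cds_g = None
    if cds_tx is not None:
        cds_g = (to_genomic(cds_tx[0]), to_genomic(cds_tx[1] - 1) + 1)
    model = TranscriptModel(
        transcript_id=f"{gene}_tx1",
        gene_id=gene,
        gene_symbol=gene,
        exons=exon_ivs,
        cds_start=None if cds_g is None else cds_g[0],
        cds_end=None if cds_g is None else cds_g[1],
    )
    return contig, exon_ivs, model


def _mirror(b: _Build) -> _Build:
    """Reverse-complement the contig and flip every interval; the
    transcript-level truth is unchanged."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    L = len(b.contig_seq)
    b.contig_seq = "".join(comp[c] for c in reversed(b.contig_seq))

    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.contig, L - iv.end, L - iv.start, "-")

    t = b.transcript
    b.transcript = TranscriptModel(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        gene_symbol=t.gene_symbol,
        exons=[flip(e) for e in t.exons],
        cds_start=None if t.cds_start is None else L - t.cds_end,
        cds_end=None if t.cds_end is None else L - t.cds_start,
    )
    b.junctions = [
        JunctionEvidence(flip(j.intron), j.counts, j.sample_ids)
        for j in b.junctions
    ]
    b.repeats = [flip(r) for r in b.repeats]
    b.support = [flip(s) for s in b.support]
    return b


def _counts(spec: ScenarioSpec, default_first: int = 5) -> tuple[int, ...]:
    if "counts" in spec.params:
        return tuple(int(c) for c in spec.params["counts"])
    return tuple(default_first if i == 0 else 3 for i in range(spec.n_samples))


def _samples(spec: ScenarioSpec) -> tuple[str, ...]:
    return tuple(f"s{i + 1}" for i in range(spec.n_samples))


def _jev(spec: ScenarioSpec, contig: str, a: int, b: int) -> JunctionEvidence:
    return JunctionEvidence(
        GenomicInterval(contig, a, b, "+"), _counts(spec), _samples(spec)
    )


# ---------------------------------------------------------------------------
# preset builders (all construct the plus-strand orientation)
# ---------------------------------------------------------------------------


def _build_satb1(rng: random.Random, spec: ScenarioSpec) -> _Build:
    """Start-exon skip: the cassette holds the canonical AUG; the next
    in-frame AUG sits 216 nt downstream, so 763 aa shrink to 691 aa."""
    gene, n_aa = "SATB1", 763
    asm = _Asm(rng)
    asm.random(198)
    asm.emit("CC")  # exon-1 tail; keeps the novel e1|e3 junction ATG-free
    asm.random(111)
    asm.emit("CACC")  # strong Kozak context for the canonical AUG
    cds = _codons(rng, n_aa, {0: "ATG", 1: "GAA", 71: "ACC", 72: "ATG", 73: "GAA"})
    asm.emit(cds, allow_atg=True)
    asm.random(60)
    tx = asm.seq
    if tx.count("ATG") != 2:
        raise ScenarioError("construction: unexpected AUG count")
    cuts = [200, 435, 835, 1615]  # e2 = 235 nt and carries CDS[0:120)
    contig, exons, model = _layout(rng, "chrS", gene, tx, cuts, (315, 315 + len(cds)))
    b = _Build("chrS", contig, model, tx)
    b.junctions = [_jev(spec, "chrS", exons[0].end, exons[2].start)]
    b.repeats = [GenomicInterval("chrS", 10, 30)]
    b.support = [b.junctions[0].intron, model.introns()[2]]
    b.primers = [
        PrimerPair(f"{gene}_p1", tx[170:190], _rc(tx[630:650]), gene)
    ]
    b.domains = [DomainAnnotation(f"{gene}_prot", "NLS", 20, 40)]
    b.truth = {
        "junction_status": "PASS",
        "category": "CASSETTE_SKIP",
        "skipped_exons": "2",
        "consequence_class": "N_TERMINAL_TRUNCATION",
        "four_way_class": "1",
        "annotated_protein_aa": str(n_aa),
        "protein_length_aa": "691",
        "n_term_delta_aa": "72",
        "internal_deleted_aa": "0",
        "c_term_lost_aa": "0",
        "ptc": "false",
        "nmd_candidate": "false",
        "lost_domains": "NLS",
        "isoform_length_nt": str(len(tx) - 235),
        "amplicon_annotated_nt": "480",
        "amplicon_novel_nt": "245",
    }
    return b


def _build_satb1_negative(rng: random.Random, spec: ScenarioSpec, kind: str) -> _Build:
    """Negative controls: identical to the start-exon-skip gene except for
    exactly one violated screening property."""
    b = _build_satb1(rng, spec)
    j = b.junctions[0]
    if kind == "lowcount":
        counts = spec.params.get("counts") or [1] * spec.n_samples
        b.junctions = [
            JunctionEvidence(j.intron, tuple(int(c) for c in counts), j.sample_ids)
        ]
        reason = "LOW_COUNT"
    elif kind == "repeat":
        b.repeats.append(
            GenomicInterval("chrS", j.intron.start - 5, j.intron.start + 3)
        )
        reason = "REPEAT_OVERLAP"
    elif kind == "unsupported":
        b.support = [b.transcript.introns()[2]]
        reason = "UNSUPPORTED"
    else:  # pragma: no cover
        raise ScenarioError(f"kind: unknown negative control {kind!r}")
    b.truth = {"junction_status": reason}
    return b


def _build_elf2(rng: random.Random, spec: ScenarioSpec, cryptic: bool) -> _Build:
    """Exon gain in intron 3 (159 nt), optionally with a cryptic acceptor
    retaining only the 3'-terminal 103 nt; either way the broken canonical
    frame forces a downstream AUG and a protein 104 aa shorter."""
    gene = "ELF2"
    n_aa = int(spec.params.get("annotated_codons", 581))
    asm = _Asm(rng)
    asm.random(96)
    asm.emit("CACC")
    cds = _codons(rng, n_aa, {0: "ATG", 1: "GAA", 103: "ACC", 104: "ATG", 105: "GAA"})
    asm.emit(cds, allow_atg=True)
    asm.random(60)
    tx = asm.seq
    if tx.count("ATG") != 2:
        raise ScenarioError("construction: unexpected AUG count")

    # gained exon: early stops kill the canonical ORF in both framings;
    # G[54:56] = AG provides the cryptic acceptor's splice site
    g_asm = _Asm(rng)
    g_asm.emit("C")
    g_asm.random(23)
    g_asm.emit("TAA")
    g_asm.random(27)
    g_asm.emit("AG")
    g_asm.emit("C")
    g_asm.random(2)
    g_asm.emit("TAA")
    g_asm.random(97)
    gained = g_asm.seq
    assert len(gained) == 159 and "ATG" not in gained

    intron3 = "GT" + _plain_random(rng, 47) + "AG" + gained + "GT" + _plain_random(rng, 47) + "AG"
    cuts = [70, 130, 160, 500]
    contig, exons, model = _layout(
        rng, "chrE", gene, tx, cuts, (100, 100 + len(cds)),
        custom_introns={2: intron3},
    )
    g_start = exons[2].end + 51
    g_end = g_start + 159
    b = _Build("chrE", contig, model, tx)
    j_left_full = _jev(spec, "chrE", exons[2].end, g_start)
    j_right = _jev(spec, "chrE", g_end, exons[3].start)
    if cryptic:
        j_left_cryptic = _jev(spec, "chrE", exons[2].end, g_start + 56)
        b.junctions = [j_left_full, j_left_cryptic, j_right]
    else:
        b.junctions = [j_left_full, j_right]
    b.repeats = [GenomicInterval("chrE", 10, 30)]
    b.support = [j.intron for j in b.junctions] + [model.introns()[0]]
    b.primers = [PrimerPair(f"{gene}_p1", tx[140:160], _rc(tx[166:186]), gene)]
    b.domains = [DomainAnnotation(f"{gene}_prot", "Transactivation", 30, 100)]
    gained_len = 103 if cryptic else 159
    b.truth = {
        "junction_status": "PASS",
        "category": "EXON_GAIN_CRYPTIC_ACCEPTOR" if cryptic else "EXON_GAIN",
        "skipped_exons": "",
        "gained_exon_len": str(gained_len),
        "consequence_class": "N_TERMINAL_TRUNCATION",
        "four_way_class": "2",
        "annotated_protein_aa": str(n_aa),
        "protein_length_aa": str(n_aa - 104),
        "n_term_delta_aa": "104",
        "internal_deleted_aa": "0",
        "c_term_lost_aa": "0",
        "ptc": "false",
        "nmd_candidate": "false",
        "lost_domains": "Transactivation",
        "isoform_length_nt": str(len(tx) + gained_len),
        "amplicon_annotated_nt": "46",
        "amplicon_novel_nt": str(46 + gained_len),
    }
    return b


@dataclass
class _SkipDesign:
    gene: str
    contig: str
    n_aa: int
    utr5: int
    cds_cuts: list[int]  # exon boundaries as CDS offsets
    skip_first: int      # 1-based exon numbers to remove (inclusive range)
    skip_last: int
    fw_tx: int           # forward-primer 5' transcript offset
    product_annotated: int
    patches: dict[int, str] = field(default_factory=dict)
    domains: list[tuple[str, int, int]] = field(default_factory=list)


_SKIP_DESIGNS = {
    "sp140l_inframe_skip": _SkipDesign(
        "SP140L", "chrP", 580, 120, [33, 108, 400], 2, 2, 113, 154,
        domains=[("SP100", 1, 120)],
    ),
    "arid5b_inframe_skip": _SkipDesign(
        "ARID5B", "chrA", 1188, 100, [200, 350, 501, 732, 2000], 4, 4, 531, 367,
        domains=[("ARID", 300, 400)],
    ),
    "ncoa2_frameshift_skip": _SkipDesign(
        "NCOA2", "chrN", 1464, 100,
        [220, 437, 654, 871, 1088, 1305, 1522, 1739, 1956, 2173, 2394, 2594,
         2812, 3100, 3400],
        12, 13, 2354, 687,
        patches={967: "CTA", 968: "ACC"},  # shifted-frame TAA at CDS 2902
        domains=[("bHLH_PAS", 30, 80), ("NR_box_LXXLL", 900, 910),
                 ("PolyQ", 1200, 1230)],
    ),
    "irf1_multiskip_inframe": _SkipDesign(
        "IRF1", "chrI", 325, 100,
        [150, 250, 330, 390, 420, 450, 541, 661, 750], 7, 9, 522, 380,
        patches={230: "CTA", 231: "ACC"},  # shifted-frame TAA at CDS 691
        domains=[("DBD", 10, 110), ("IAD", 200, 300)],
    ),
    "irf1_multiskip_ptc": _SkipDesign(
        "IRF1", "chrI", 325, 100,
        [150, 250, 330, 390, 420, 450, 541, 661, 750], 7, 8, 522, 380,
        patches={230: "CTA", 231: "ACC"},
        domains=[("DBD", 10, 110), ("IAD", 200, 300)],
    ),
}


def _build_skip(rng: random.Random, spec: ScenarioSpec, d: _SkipDesign) -> _Build:
    """Whole-exon skip presets: in-frame modular-exon loss when the removed
    coding length is a multiple of 3, frameshift + PTC otherwise."""
    asm = _Asm(rng)
    asm.random(d.utr5 - 4)
    asm.emit("CACC")
    patches = {0: "ATG", 1: "GAA", **d.patches}
    cds = _codons(rng, d.n_aa, patches)
    asm.emit(cds, allow_atg=True)
    asm.random(60)
    tx = asm.seq
    if tx.count("ATG") != 1:
        raise ScenarioError("construction: unexpected AUG count")
    cuts = [d.utr5 + c for c in d.cds_cuts]
    contig, exons, model = _layout(
        rng, d.contig, d.gene, tx, cuts, (d.utr5, d.utr5 + len(cds))
    )
    b = _Build(d.contig, contig, model, tx)
    b.junctions = [
        _jev(spec, d.contig, exons[d.skip_first - 2].end, exons[d.skip_last].start)
    ]
    b.repeats = [GenomicInterval(d.contig, 10, 30)]
    b.support = [b.junctions[0].intron, model.introns()[0]]
    rv_end = d.fw_tx + d.product_annotated
    b.primers = [
        PrimerPair(f"{d.gene}_p1", tx[d.fw_tx : d.fw_tx + 20],
                   _rc(tx[rv_end - 20 : rv_end]), d.gene)
    ]
    b.domains = [
        DomainAnnotation(f"{d.gene}_prot", n, s, e) for n, s, e in d.domains
    ]

    cds_bounds = [0, *d.cds_cuts, len(cds)]
    removed = cds_bounds[d.skip_last] - cds_bounds[d.skip_first - 1]
    skip_start_cds = cds_bounds[d.skip_first - 1]
    n_skipped = d.skip_last - d.skip_first + 1
    skipped = ",".join(str(i) for i in range(d.skip_first, d.skip_last + 1))
    truth: dict[str, str] = {
        "junction_status": "PASS",
        "category": "CASSETTE_SKIP" if n_skipped == 1 else "MULTI_EXON_SKIP",
        "skipped_exons": skipped,
        "annotated_protein_aa": str(d.n_aa),
        "amplicon_annotated_nt": str(d.product_annotated),
        "amplicon_novel_nt": str(d.product_annotated - removed),
        "isoform_length_nt": str(len(tx) - removed),
    }
    if removed % 3 == 0:
        first_res = skip_start_cds // 3 + 1
        truth.update(
            consequence_class="IN_FRAME_INTERNAL_DELETION",
            four_way_class="3",
            protein_length_aa=str(d.n_aa - removed // 3),
            n_term_delta_aa="0",
            internal_deleted_aa=str(removed // 3),
            deleted_residue_start=str(first_res),
            deleted_residue_end=str(first_res + removed // 3 - 1),
            c_term_lost_aa="0",
            ptc="false",
            nmd_candidate="false",
        )
        lost_rng = (first_res, first_res + removed // 3 - 1)
    else:
        # walk the novel coding stream to the first (engineered or chance)
        # stop in the shifted frame — this is the generator's own oracle
        stream = cds[:skip_start_cds] + cds[cds_bounds[d.skip_last] :]
        n_codons = None
        for i in range(0, len(stream) - 2, 3):
            if stream[i : i + 3] in STOPS:
                n_codons = i // 3
                break
        if n_codons is None:
            raise ScenarioError("construction: frameshifted ORF never stops")
        shared = skip_start_cds // 3
        truth.update(
            consequence_class="FRAMESHIFT_PTC",
            four_way_class="4",
            protein_length_aa=str(n_codons),
            n_term_delta_aa="0",
            internal_deleted_aa="0",
            c_term_lost_aa=str(d.n_aa - shared),
            ptc="true",
            nmd_candidate="true",
        )
        lost_rng = (shared + 1, d.n_aa)
    lost = sorted(
        n for n, s, e in d.domains
        if min(e, lost_rng[1]) - max(s, lost_rng[0]) >= 0
    )
    truth["lost_domains"] = ",".join(lost)
    b.truth = truth
    return b


def _build_znf266(rng: random.Random, spec: ScenarioSpec) -> _Build:
    """Alternative donor inside exon 6 plus skipping of exon 7 rewires the
    5' UTR so that an AUG 201 nt upstream of the canonical one becomes
    in-frame and stop-free: 549 aa grow to 616 aa (67 new N-terminal
    residues). In the annotated transcript the same upstream AUG runs into a
    stop after 20 codons and is never reported."""
    gene, n_aa = "ZNF266", 549
    # 201-nt extension insert: AUG + 66 safe codons, split 30/27/144 nt over
    # exon 5 tail, exon 6 head and exon 8 head
    ins = "ATG" + _codons(rng, 66, {0: "GAA", 17: "CCT", 65: "ACC"},
                          terminal_stop=False)
    assert len(ins) == 201

    asm = _Asm(rng)
    for _ in range(4):  # exons 1-4: plain UTR
        asm.random(90)
    asm.random(66)
    asm.emit("CACC")
    asm.emit(ins[:30], allow_atg=True)  # exon 5 tail (new AUG, strong Kozak)
    asm.emit(ins[30:57])                # exon 6 head kept by the novel donor
    asm.emit("GTCTAA")                  # novel donor GT + early in-frame stop
    asm.random(87)
    asm.random(90)                      # exon 7 (skipped entirely)
    asm.emit(ins[57:201])               # exon 8 head up to the canonical AUG
    cds = _codons(rng, n_aa, {0: "ATG", 1: "GAA"})
    asm.emit(cds, allow_atg=True)
    asm.random(60)
    tx = asm.seq
    if tx.count("ATG") != 2:
        raise ScenarioError("construction: unexpected AUG count")
    cuts = [90, 180, 270, 360, 460, 580, 670, 1320, 1920]
    contig, exons, model = _layout(rng, "chrZ", gene, tx, cuts, (814, 814 + len(cds)))
    b = _Build("chrZ", contig, model, tx)
    b.junctions = [_jev(spec, "chrZ", exons[5].start + 27, exons[7].start)]
    b.repeats = [GenomicInterval("chrZ", 10, 30)]
    b.support = [b.junctions[0].intron, model.introns()[0]]
    b.primers = [PrimerPair(f"{gene}_p1", tx[330:350], _rc(tx[690:710]), gene)]
    b.domains = [DomainAnnotation(f"{gene}_prot", "KRAB", 1, 42)]
    b.truth = {
        "junction_status": "PASS",
        "category": "ALT_DONOR_PLUS_SKIP",
        "skipped_exons": "7",
        "consequence_class": "N_TERMINAL_EXTENSION",
        "four_way_class": "1",
        "annotated_protein_aa": str(n_aa),
        "protein_length_aa": "616",
        "n_term_delta_aa": "67",
        "internal_deleted_aa": "0",
        "c_term_lost_aa": "0",
        "ptc": "false",
        "nmd_candidate": "false",
        "lost_domains": "",
        "isoform_length_nt": str(len(tx) - 183),
        "amplicon_annotated_nt": "380",
        "amplicon_novel_nt": "197",
    }
    return b


def _rc(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(s))


_BUILDERS = {
    "satb1_skip_start_exon": _build_satb1,
    "elf2_exon_gain": lambda rng, spec: _build_elf2(rng, spec, cryptic=False),
    "elf2_cryptic_acceptor": lambda rng, spec: _build_elf2(rng, spec, cryptic=True),
    "znf266_upstream_aug": _build_znf266,
    "lowcount_junction": lambda rng, spec: _build_satb1_negative(rng, spec, "lowcount"),
    "repeat_overlap_junction": lambda rng, spec: _build_satb1_negative(rng, spec, "repeat"),
    "unsupported_junction": lambda rng, spec: _build_satb1_negative(rng, spec, "unsupported"),
    **{name: (lambda rng, spec, d=d: _build_skip(rng, spec, d))
       for name, d in _SKIP_DESIGNS.items()},
}


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def _write_bundle(b: _Build, spec: ScenarioSpec, out_dir: str | Path) -> FixtureBundle:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome_path = out / "genome.fa"
    write_genome(GenomeRef({b.contig_id: b.contig_seq}), genome_path)
    annotation_path = out / "annotation.gtf"
    write_gtf([b.transcript], annotation_path, source="synthetic")
    repeats_path = out / "repeats.bed"
    write_bed(b.repeats, repeats_path, [f"rep{i}" for i in range(len(b.repeats))])
    support_path = out / "est_support.bed"
    write_bed(b.support, support_path, [f"est{i}" for i in range(len(b.support))])
    junctions_path = out / "junctions.tsv"
    write_junctions(b.junctions, junctions_path)
    primers_path = out / "primers.tsv"
    write_primers(b.primers, primers_path)
    domains_path = out / "domains.tsv"
    write_domains(b.domains, domains_path)
    truth = {"scenario": spec.name, "strand": spec.strand, **b.truth}
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        for k, v in truth.items():
            fh.write(f"{k}\t{v}\n")
    return FixtureBundle(
        out_dir=out,
        genome_path=genome_path,
        annotation_path=annotation_path,
        repeats_path=repeats_path,
        est_support_path=support_path,
        junctions_path=junctions_path,
        primers_path=primers_path,
        domains_path=domains_path,
        truth_path=truth_path,
        truth=truth,
    )


def generate_scenario(spec: ScenarioSpec, out_dir: str | Path) -> FixtureBundle:
    """Generate one preset scenario bundle into ``out_dir``.

    Output is byte-identical for identical (name, seed, strand, params).
    """
    if spec.name == "custom":
        raise ScenarioError("name: use generate_custom_genome for custom fixtures")
    # negative controls reuse the start-exon-skip gene byte for byte, so each
    # differs from the positive scenario only in its violated property
    stream_name = (
        "satb1_skip_start_exon" if spec.name in NEGATIVE_PRESETS else spec.name
    )
    rng = random.Random((spec.seed & 0x7FFFFFFF) ^ zlib.crc32(stream_name.encode()))
    b = _BUILDERS[spec.name](rng, spec)
    if spec.strand == "-":
        b = _mirror(b)
    return _write_bundle(b, spec, out_dir)


def generate_custom_genome(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (3, 6),
    seed: int = 0,
    out_dir: str | Path = "custom_fixture",
    n_samples: int = 2,
) -> FixtureBundle:
    """Random multi-gene fixture with injected novel junctions of known
    category (property-test fuel). One gene per contig, strands alternating;
    all annotated introns are GT..AG; the truth file maps each gene to its
    injected event category."""
    if n_genes < 1:
        raise ScenarioError("n_genes: must be >= 1")
    lo, hi = exons_per_gene
    if lo < 2 or hi < lo:
        raise ScenarioError("exons_per_gene: need 2 <= lo <= hi")
    rng = random.Random((seed & 0x7FFFFFFF) ^ 0x5EED)
    contigs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    junctions: list[JunctionEvidence] = []
    support: list[GenomicInterval] = []
    truth: dict[str, str] = {}
    sample_ids = tuple(f"s{i + 1}" for i in range(n_samples))
    counts = tuple(5 if i == 0 else 3 for i in range(n_samples))

    for gi in range(n_genes):
        cid = f"g{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        n_ex = rng.randint(lo, hi)
        choices = ["gain"]
        if n_ex >= 3:
            choices.append("skip")
        if n_ex >= 4:
            choices.append("multiskip")
        kind = rng.choice(choices)
        exon_seqs = [_plain_random(rng, rng.randint(60, 240)) for _ in range(n_ex)]
        gain_intron = rng.randrange(n_ex - 1)
        gained_len = rng.randint(21, 60)
        intron_seqs = []
        gain_offset = None
        for ii in range(n_ex - 1):
            if kind == "gain" and ii == gain_intron:
                l1 = rng.randint(10, 40)
                l2 = rng.randint(10, 40)
                intron_seqs.append(
                    "GT" + _plain_random(rng, l1) + "AG"
                    + _plain_random(rng, gained_len)
                    + "GT" + _plain_random(rng, l2) + "AG"
                )
                gain_offset = 2 + l1 + 2
            else:
                intron_seqs.append(_intron(rng, rng.randint(80, 160)))

        pad = 60
        parts = [_plain_random(rng, pad)]
        pos = pad
        exon_ivs = []
        for ii, es in enumerate(exon_seqs):
            exon_ivs.append(GenomicInterval(cid, pos, pos + len(es)))
            pos += len(es)
            parts.append(es)
            if ii < n_ex - 1:
                parts.append(intron_seqs[ii])
                pos += len(intron_seqs[ii])
        parts.append(_plain_random(rng, pad))
        seq = "".join(parts)
        model = TranscriptModel(
            transcript_id=f"{cid}_tx1", gene_id=cid, gene_symbol=cid,
            exons=exon_ivs,
        )

        if kind == "gain":
            i_start = exon_ivs[gain_intron].end
            g_start = i_start + gain_offset
            g_end = g_start + gained_len
            new_j = [
                (i_start, g_start),
                (g_end, exon_ivs[gain_intron + 1].start),
            ]
            truth[cid] = "EXON_GAIN"
        else:
            width = 1 if kind == "skip" else 2
            first = rng.randint(1, n_ex - 1 - width)  # genomic index of exon before
            new_j = [(exon_ivs[first - 1].end, exon_ivs[first + width].start)]
            truth[cid] = "CASSETTE_SKIP" if width == 1 else "MULTI_EXON_SKIP"

        if strand == "-":
            L = len(seq)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            seq = "".join(comp[c] for c in reversed(seq))
            exon_ivs = [
                GenomicInterval(cid, L - e.end, L - e.start, "-")
                for e in exon_ivs
            ]
            model = TranscriptModel(
                transcript_id=model.transcript_id, gene_id=cid,
                gene_symbol=cid, exons=exon_ivs,
            )
            new_j = [(L - b_, L - a_) for a_, b_ in new_j]

        contigs[cid] = seq
        transcripts.append(model)
        for a_, b_ in new_j:
            iv = GenomicInterval(cid, a_, b_, strand)
            junctions.append(JunctionEvidence(iv, counts, sample_ids))
            support.append(iv)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome_path = out / "genome.fa"
    write_genome(GenomeRef(contigs), genome_path)
    annotation_path = out / "annotation.gtf"
    write_gtf(transcripts, annotation_path, source="synthetic")
    repeats_path = out / "repeats.bed"
    write_bed([], repeats_path)
    support_path = out / "est_support.bed"
    write_bed(support, support_path, [f"est{i}" for i in range(len(support))])
    junctions_path = out / "junctions.tsv"
    write_junctions(junctions, junctions_path)
    primers_path = out / "primers.tsv"
    primers_path.write_text("#name\ttarget\tforward_seq\treverse_seq\n")
    domains_path = out / "domains.tsv"
    domains_path.write_text("#protein_id\tdomain_name\tstart_aa\tend_aa\n")
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        for k, v in truth.items():
            fh.write(f"{k}\t{v}\n")
    return FixtureBundle(
        out_dir=out, genome_path=genome_path, annotation_path=annotation_path,
        repeats_path=repeats_path, est_support_path=support_path,
        junctions_path=junctions_path, primers_path=primers_path,
        domains_path=domains_path, truth_path=truth_path, truth=truth,
    )
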