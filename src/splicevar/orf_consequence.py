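"""ORF selection and protein-level consequence prediction for novel isoforms.

The stage scans a novel isoform for AUG-initiated ORFs, grades each start by
its Kozak context (positions -3 and +4), selects a start, and then aligns the
resulting ORF to the template's annotated ORF *by shared genomic codon
positions* to decide the protein-level consequence: N-terminal extension or
truncation, in-frame internal deletion (modular-exon loss), or frameshift
with premature termination codon (PTC) — in which case NMD candidacy is
evaluated with the classic 50-nt rule. A PROSITE-style C2H2 zinc-finger
scanner supports the motif-level reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .annotation_io import (
    GenomeRef,
    TranscriptModel,
    transcript_to_genomic,
)
from .event_isoform import (
    EXON_GAIN,
    EXON_GAIN_CRYPTIC_ACCEPTOR,
    NovelIsoform,
)

__all__ = [
    "OrfCall",
    "OrfConsequence",
    "MotifHit",
    "DomainAnnotation",
    "DomainLoss",
    "scan_orfs",
    "kozak_class",
    "select_start",
    "classify_consequence",
    "nmd_candidate",
    "scan_c2h2",
    "translate",
    "read_domains",
]

STOPS = ("TAA", "TAG", "TGA")

N_TERMINAL_EXTENSION = "N_TERMINAL_EXTENSION"
N_TERMINAL_TRUNCATION = "N_TERMINAL_TRUNCATION"
IN_FRAME_INTERNAL_DELETION = "IN_FRAME_INTERNAL_DELETION"
FRAMESHIFT_PTC = "FRAMESHIFT_PTC"
UNCHANGED = "UNCHANGED"
NONCODING = "NONCODING"

# PROSITE PS00028: C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H
C2H2_PATTERN = re.compile(r"C.{2,4}?C.{3}[LIVMFYWC].{8}H.{3,5}?H")


def translate(cds: str) -> str:
    """Translate a stop-terminated CDS; the terminal stop is dropped."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


@dataclass(frozen=True)
class OrfCall:
    """One AUG-to-stop ORF on a spliced transcript sequence."""

    start_offset: int
    stop_offset: int  # offset just past the stop codon
    kozak_class: str
    protein_length_aa: int
    in_frame_with_canonical: bool | None = None

    def __post_init__(self) -> None:
        if (self.stop_offset - self.start_offset) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        expected = (self.stop_offset - self.start_offset) // 3 - 1
        if self.protein_length_aa != expected:
            raise ValueError("protein_length_aa inconsistent with ORF bounds")


@dataclass(frozen=True)
class MotifHit:
    start_aa: int  # 1-based inclusive
    end_aa: int
    pattern_name: str = "C2H2_PS00028"


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    name: str
    start_aa: int  # 1-based inclusive
    end_aa: int


@dataclass(frozen=True)
class DomainLoss:
    name: str
    overlap_fraction: float


@dataclass
class OrfConsequence:
    isoform_id: str
    selected_orf: OrfCall | None
    consequence_class: str
    four_way_class: int | None = None
    n_term_delta_aa: int = 0
    internal_deleted_aa: int = 0
    c_term_lost_aa: int = 0
    deleted_residue_range: tuple[int, int] | None = None
    ptc: bool = False
    nmd_candidate: bool = False
    lost_domains: list[DomainLoss] = field(default_factory=list)
    protein_sequence: str = ""

    def __post_init__(self) -> None:
        if self.nmd_candidate and not self.ptc:
            raise ValueError("NMD candidacy requires a PTC")


def kozak_class(seq: str, aug_offset: int) -> str:
    """Kozak strength of an AUG: purine at -3 and G at +4 -> strong; exactly
    one of the two -> adequate; neither -> weak. Out-of-range positions do
    not match."""
    if seq[aug_offset : aug_offset + 3] != "ATG":
        raise ValueError(f"no ATG at offset {aug_offset}")
    minus3 = seq[aug_offset - 3] if aug_offset >= 3 else ""
    plus4 = seq[aug_offset + 3] if aug_offset + 3 < len(seq) else ""
    good = int(minus3 in ("A", "G")) + int(plus4 == "G")
    return {2: "strong", 1: "adequate", 0: "weak"}[good]


def scan_orfs(
    seq: str,
    canonical_start: int | None = None,
    min_protein_aa: int = 30,
) -> list[OrfCall]:
    """All AUG-initiated ORFs ending at the first in-frame stop, 5' to 3'.

    ORFs without an in-frame stop are not reported. ``canonical_start`` (a
    transcript offset, when the canonical AUG survives in this sequence)
    annotates each call with its frame relation to the canonical start.
    """
    calls: list[OrfCall] = []
    pos = seq.find("ATG")
    while pos != -1:
        stop_end = None
        for i in range(pos + 3, len(seq) - 2, 3):
            if seq[i : i + 3] in STOPS:
                stop_end = i + 3
                break
        if stop_end is not None:
            n_aa = (stop_end - pos) // 3 - 1
            if n_aa >= min_protein_aa:
                in_frame = (
                    None
                    if canonical_start is None
                    else (pos - canonical_start) % 3 == 0
                )
                calls.append(
                    OrfCall(
                        start_offset=pos,
                        stop_offset=stop_end,
                        kozak_class=kozak_class(seq, pos),
                        protein_length_aa=n_aa,
                        in_frame_with_canonical=in_frame,
                    )
                )
        pos = seq.find("ATG", pos + 1)
    return calls


def select_start(
    orfs: Sequence[OrfCall], policy: str = "five_prime_first"
) -> OrfCall:
    """Pick the translated ORF.

    ``five_prime_first``: the 5'-most AUG in at least adequate Kozak context,
    falling back to the 5'-most AUG outright. ``longest_orf``: the longest
    protein, ties to the 5'-most start.
    """
    if not orfs:
        raise ValueError("no ORFs to select from (noncoding isoform)")
    ordered = sorted(orfs, key=lambda o: o.start_offset)
    if policy == "five_prime_first":
        for o in ordered:
            if o.kozak_class in ("strong", "adequate"):
                return o
        return ordered[0]
    if policy == "longest_orf":
        return max(ordered, key=lambda o: (o.protein_length_aa, -o.start_offset))
    raise ValueError(f"unknown start policy {policy!r}")


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------


def _codon_positions(
    model: TranscriptModel, tx_start: int, tx_stop: int
) -> list[tuple[int, int, int]]:
    """Genomic position triple of every *coding* codon (stop excluded)."""
    out = []
    for off in range(tx_start, tx_stop - 3, 3):
        out.append(
            (
                transcript_to_genomic(model, off),
                transcript_to_genomic(model, off + 1),
                transcript_to_genomic(model, off + 2),
            )
        )
    return out


def _canonical_codons(template: TranscriptModel) -> list[tuple[int, int, int]]:
    if not template.is_coding:
        raise ValueError(f"{template.transcript_id} has no annotated CDS")
    bound = (
        template.cds_start if template.strand == "+" else template.cds_end - 1
    )
    from .annotation_io import genomic_to_transcript

    start = genomic_to_transcript(template, bound)
    return _codon_positions(template, start, start + template.cds_length())


def _common_prefix(a: Sequence, b: Sequence) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_consequence(
    iso: NovelIsoform,
    template: TranscriptModel,
    genome: GenomeRef,
    orf: OrfCall | None,
    domains: Iterable[DomainAnnotation] = (),
    nmd_rule_nt: int = 50,
) -> OrfConsequence:
    """Align the novel ORF to the canonical one by genomic codon positions.

    The canonical and novel coding codons are expressed as genomic position
    triples; suffix/prefix structure of the two codon lists decides the class,
    and a novel stop that is not the canonical stop marks a PTC.
    """
    if iso.event.template.transcript_id != template.transcript_id:
        raise ValueError("isoform was not derived from this template")
    if orf is None:
        return OrfConsequence(iso.isoform_id, None, NONCODING)

    model = iso.as_transcript_model()
    c_cod = _canonical_codons(template)
    n_cod = _codon_positions(model, orf.start_offset, orf.stop_offset)
    C, N = len(c_cod), len(n_cod)
    protein = translate(iso.sequence[orf.start_offset : orf.stop_offset])

    res = OrfConsequence(
        iso.isoform_id, orf, UNCHANGED, protein_sequence=protein
    )
    lost_lo = lost_hi = 0  # 1-based inclusive range of lost canonical residues
    if n_cod == c_cod:
        res.consequence_class = UNCHANGED
    elif N > C and n_cod[N - C :] == c_cod:
        res.consequence_class = N_TERMINAL_EXTENSION
        res.n_term_delta_aa = N - C
    elif N < C and n_cod == c_cod[C - N :]:
        res.consequence_class = N_TERMINAL_TRUNCATION
        res.n_term_delta_aa = C - N
        lost_lo, lost_hi = 1, C - N
    else:
        p = _common_prefix(n_cod, c_cod)
        s = _common_prefix(n_cod[::-1], c_cod[::-1])
        if N < C and n_cod[0] == c_cod[0] and n_cod[-1] == c_cod[-1] and p + s >= N:
            # identical termini, internal codons missing, in frame
            res.consequence_class = IN_FRAME_INTERNAL_DELETION
            res.internal_deleted_aa = C - N
            p = min(p, N - s)
            res.deleted_residue_range = (p + 1, p + C - N)
            lost_lo, lost_hi = p + 1, p + C - N
        else:
            res.consequence_class = FRAMESHIFT_PTC
            res.ptc = True
            res.c_term_lost_aa = C - p
            lost_lo, lost_hi = p + 1, C
            res.nmd_candidate = nmd_candidate(iso, orf, rule_nt=nmd_rule_nt)

    if lost_hi >= lost_lo and lost_hi > 0:
        for d in domains:
            ov = min(d.end_aa, lost_hi) - max(d.start_aa, lost_lo) + 1
            if ov > 0:
                frac = ov / (d.end_aa - d.start_aa + 1)
                res.lost_domains.append(DomainLoss(d.name, round(frac, 4)))

    res.four_way_class = _four_way_class(iso, res)
    return res


def _four_way_class(iso: NovelIsoform, res: OrfConsequence) -> int | None:
    """Map to the published four-way event taxonomy: (1) exon skipping with
    alternative AUG usage, (2) exon gain with alternative AUG usage, (3)
    modular-exon loss with ORF maintenance, (4) skipping with frameshift and
    PTC formation."""
    if res.consequence_class == FRAMESHIFT_PTC:
        return 4
    if res.consequence_class == IN_FRAME_INTERNAL_DELETION:
        return 3
    if res.consequence_class in (N_TERMINAL_EXTENSION, N_TERMINAL_TRUNCATION):
        if iso.event.category in (EXON_GAIN, EXON_GAIN_CRYPTIC_ACCEPTOR):
            return 2
        return 1
    return None


def nmd_candidate(
    iso: NovelIsoform | TranscriptModel,
    orf: OrfCall,
    rule_nt: int = 50,
) -> bool:
    """50-nt rule: NMD candidate iff the stop codon ends more than ``rule_nt``
    nt upstream of the isoform's last exon-exon junction (strict inequality).
    Single-exon isoforms are never candidates."""
    exons = iso.exons if isinstance(iso, NovelIsoform) else iso.exons
    if len(exons) < 2:
        return False
    strand = exons[0].strand
    tx_order = exons if strand == "+" else list(reversed(exons))
    last_junction = sum(len(e) for e in tx_order[:-1])
    return last_junction - orf.stop_offset > rule_nt


# ---------------------------------------------------------------------------
# C2H2 zinc-finger motif scan
# ---------------------------------------------------------------------------


def scan_c2h2(protein: str, overlapping: bool = False) -> list[MotifHit]:
    """PROSITE PS00028 C2H2 zinc-finger hits, leftmost with the shortest
    admissible spacers; non-overlapping by default."""
    hits: list[MotifHit] = []
    if overlapping:
        for i in range(len(protein)):
            m = C2H2_PATTERN.match(protein, i)
            if m:
                hits.append(MotifHit(m.start() + 1, m.end()))
        return hits
    pos = 0
    while True:
        m = C2H2_PATTERN.search(protein, pos)
        if not m:
            return hits
        hits.append(MotifHit(m.start() + 1, m.end()))
        pos = m.end()


# ---------------------------------------------------------------------------
# domain table I/O (protein_id, domain_name, start_aa, end_aa; 1-based incl.)
# ---------------------------------------------------------------------------


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            pid, name, s, e = line.rstrip("\n").split("\t")
            out.append(DomainAnnotation(pid, name, int(s), int(e)))
    return out


def write_domains(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tdomain_name\tstart_aa\tend_aa\n")
        for d in domains:
            fh.write(f"{d.protein_id}\t{d.name}\t{d.start_aa}\t{d.end_aa}\n")
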