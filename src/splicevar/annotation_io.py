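"""Genome/annotation data model and format I/O.

All coordinates are internally 0-based half-open (BED convention); GTF's
1-based inclusive coordinates are converted at the read/write boundary.
Transcript-level sequences and offsets are always on the sense (transcript)
strand; genomic intervals never flip.

One deliberate deviation from the Ensembl GTF dialect: the CDS bounds of a
:class:`TranscriptModel` *include* the terminal stop codon, so a transcript
encoding ``n`` amino acids has a spliced CDS of ``3 * (n + 1)`` nt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRef",
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "AnnotationWarning",
    "GtfParseError",
    "NotExonicError",
    "read_genome",
    "write_genome",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "spliced_sequence",
    "genomic_to_transcript",
    "transcript_to_genomic",
    "reverse_complement",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""


class NotExonicError(KeyError):
    """A genomic position does not fall inside any exon of the transcript."""


class AnnotationWarning(UserWarning):
    """Non-fatal annotation inconsistency (e.g. a CDS that does not validate)."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Exact-coordinate lookup key (contig, start, end, strand)."""
        return (self.contig, self.start, self.end, self.strand)


class GenomeRef:
    """In-memory reference genome: contig id -> uppercase sequence."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        self.contigs = {cid: seq.upper() for cid, seq in contigs.items()}
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} has empty sequence")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, iv: GenomicInterval) -> str:
        """Sequence of ``iv`` on the *forward* genomic strand."""
        seq = self.contigs[iv.contig]
        if iv.end > len(seq):
            raise IndexError(
                f"interval [{iv.start}, {iv.end}) outside contig "
                f"{iv.contig} (length {len(seq)})"
            )
        return seq[iv.start : iv.end]

    def fetch_stranded(self, iv: GenomicInterval) -> str:
        """Sequence of ``iv`` on its own strand (5'->3')."""
        s = self.fetch(iv)
        return reverse_complement(s) if iv.strand == "-" else s


@dataclass
class TranscriptModel:
    """Exon chain (and optional CDS) of one annotated transcript.

    ``exons`` are kept in genomic order regardless of strand; transcript
    order is derived. ``cds_start``/``cds_end`` are genomic 0-based
    half-open bounds of the ORF *including* the stop codon.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str = ""
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        contig = exons[0].contig
        strand = exons[0].strand
        for a, b in zip(exons, exons[1:]):
            if b.contig != contig or b.strand != strand:
                raise ValueError(
                    f"{self.transcript_id}: exons span contigs/strands"
                )
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(
                f"{self.transcript_id}: cds_start and cds_end must be set together"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exons_in_transcript_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            GenomicInterval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def cds_segments(self) -> list[GenomicInterval]:
        """Exon pieces inside the CDS bounds, genomic order."""
        if not self.is_coding:
            return []
        segs = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s < t:
                segs.append(GenomicInterval(self.contig, s, t, self.strand))
        return segs

    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments())

    def structural_check(self) -> list[str]:
        """Structural CDS problems (coordinate-level; no genome needed)."""
        problems = []
        if self.is_coding:
            exonic = [
                p
                for p in (self.cds_start, self.cds_end - 1)
                if not any(e.contains(p) for e in self.exons)
            ]
            if exonic:
                problems.append("cds_bounds_outside_exons")
            if self.cds_length() % 3 != 0:
                problems.append("cds_length_not_multiple_of_3")
        return problems


def _tx_cum_offsets(t: TranscriptModel) -> list[tuple[GenomicInterval, int]]:
    out, off = [], 0
    for e in t.exons_in_transcript_order():
        out.append((e, off))
        off += len(e)
    return out


def genomic_to_transcript(t: TranscriptModel, pos: int) -> int:
    """Map an exonic genomic position to its transcript offset (strand-aware)."""
    for e, off in _tx_cum_offsets(t):
        if e.contains(pos):
            if t.strand == "+":
                return off + (pos - e.start)
            return off + (e.end - 1 - pos)
    raise NotExonicError(f"position {pos} not exonic in {t.transcript_id}")


def transcript_to_genomic(t: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_transcript`."""
    if offset < 0 or offset >= t.length:
        raise NotExonicError(f"offset {offset} outside transcript {t.transcript_id}")
    for e, off in _tx_cum_offsets(t):
        if off <= offset < off + len(e):
            d = offset - off
            return e.start + d if t.strand == "+" else e.end - 1 - d
    raise AssertionError("unreachable")


def spliced_sequence(t: TranscriptModel, genome: GenomeRef) -> str:
    """Spliced transcript sequence, 5'->3' on the transcript strand."""
    s = "".join(genome.fetch(e) for e in t.exons)
    return reverse_complement(s) if t.strand == "-" else s


def spliced_cds(t: TranscriptModel, genome: GenomeRef) -> str:
    segs = t.cds_segments()
    s = "".join(genome.fetch(seg) for seg in segs)
    return reverse_complement(s) if t.strand == "-" else s


class AnnotationSet:
    """Collection of transcripts plus the derived intron index."""

    def __init__(self, transcripts: Iterable[TranscriptModel], source: str = ""):
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
        self.source = source

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for t in self:
            out.extend(t.introns())
        return out

    def intron_keys(self) -> set[tuple[str, int, int, str]]:
        return {iv.key for iv in self.introns()}

    def exon_boundaries(self, contig: str, strand: str) -> set[int]:
        b: set[int] = set()
        for t in self:
            if t.contig == contig and t.strand == strand:
                for e in t.exons:
                    b.update((e.start, e.end))
        return b

    def validate_cds(self, genome: GenomeRef) -> None:
        """Sequence-level CDS check: starts ATG / ends stop. Warn, don't fail."""
        for t in self:
            if not t.is_coding:
                continue
            problems = t.structural_check()
            if not problems:
                cds = spliced_cds(t, genome)
                if not cds.startswith("ATG"):
                    problems.append("cds_no_start_codon")
                if cds[-3:] not in STOP_CODONS:
                    problems.append("cds_no_stop_codon")
            for p in problems:
                if p not in t.flags:
                    t.flags.append(p)
                warnings.warn(
                    f"{t.transcript_id}: {p}", AnnotationWarning, stacklevel=2
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genome(path: str | Path) -> GenomeRef:
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GenomeRef(contigs)


def write_genome(genome: GenomeRef, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.contigs.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def _prescan_gtf(path: str | Path) -> None:
    # gffutils does not report line numbers; do a cheap structural pass first.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}, line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if "gene_id" not in fields[8] or "transcript_id" not in fields[8]:
                raise GtfParseError(
                    f"{path}, line {lineno}: missing gene_id/transcript_id attribute"
                )


def read_gtf(path: str | Path, source: str = "") -> AnnotationSet:
    """Read exon + CDS features from a GTF file.

    Unknown feature types and attributes are ignored. CDS features are merged
    into genomic bounds; structural inconsistencies flag the transcript
    (warn-not-fail) rather than rejecting it.
    """
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    cds_bounds: dict[str, list[int]] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        sym = feat.attributes.get("gene_name", [""])[0]
        meta.setdefault(tid, (gid, sym))
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            lo, hi = cds_bounds.get(tid, (iv.start, iv.end))
            cds_bounds[tid] = [min(lo, iv.start), max(hi, iv.end)]
    transcripts = []
    for tid, exon_list in exons.items():
        gid, sym = meta[tid]
        cs, ce = (cds_bounds.get(tid) or (None, None))
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            gene_symbol=sym,
            exons=exon_list,
            cds_start=cs,
            cds_end=ce,
        )
        for p in t.structural_check():
            t.flags.append(p)
            warnings.warn(f"{tid}: {p}", AnnotationWarning, stacklevel=2)
        transcripts.append(t)
    return AnnotationSet(transcripts, source=source)


def write_gtf(
    ann: AnnotationSet | Iterable[TranscriptModel],
    path: str | Path,
    source: str = "splicevar",
) -> None:
    transcripts = list(ann)
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            )
            if t.gene_symbol:
                attrs += f' gene_name "{t.gene_symbol}";'
            for e in t.exons:
                fh.write(
                    f"{t.contig}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                for seg in t.cds_segments():
                    fh.write(
                        f"{t.contig}\t{source}\tCDS\t{seg.start + 1}\t{seg.end}"
                        f"\t.\t{t.strand}\t.\t{attrs}\n"
                    )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED6 (or BED3, strand defaulting to '+') intervals, 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: fewer than 3 BED fields")
            strand = fields[5] if len(fields) >= 6 else "+"
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )
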