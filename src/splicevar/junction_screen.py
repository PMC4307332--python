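"""Candidate-junction screening.

De novo splice junctions (each represented by its intron interval plus
per-sample read counts) are screened by four filters applied in a fixed
order — read-count threshold, repeat exclusion, novelty against the
annotation, and EST/prediction support — so that every rejected junction
carries a single, deterministic rejection reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .annotation_io import AnnotationSet, GenomicInterval

__all__ = [
    "JunctionEvidence",
    "ScreenConfig",
    "ScreenReport",
    "RejectionReason",
    "filter_by_counts",
    "filter_by_repeats",
    "filter_by_novelty",
    "filter_by_support",
    "screen",
    "read_junctions",
    "write_junctions",
]

# rejection reasons, in filter order
LOW_COUNT = "LOW_COUNT"
REPEAT_OVERLAP = "REPEAT_OVERLAP"
ANNOTATED = "ANNOTATED"
UNSUPPORTED = "UNSUPPORTED"

RejectionReason = str


@dataclass(frozen=True)
class JunctionEvidence:
    """One de novo splice junction: the excised intron plus read support.

    ``intron`` spans the first to last intronic base, half-open; counts are
    reads spanning the junction, one integer per sample.
    """

    intron: GenomicInterval
    counts: tuple[int, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.sample_ids):
            raise ValueError("counts and sample_ids must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("read counts must be non-negative")
        if len(self.intron) < 4:
            raise ValueError("intron shorter than 4 nt cannot hold GT..AG")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and policies for junction screening.

    The read-count rule keeps a junction with at least ``min_reads_per_sample``
    reads in at least ``min_samples_passing`` samples (defaults: >=2 reads in
    >=1 sample). ``repeat_policy`` decides whether a repeat must touch a splice
    site (``either_site``) or merely the intron (``any_overlap``) to disqualify.
    """

    min_reads_per_sample: int = 2
    min_samples_passing: int = 1
    repeat_policy: str = "either_site"
    support_required: bool = True

    def __post_init__(self) -> None:
        if self.min_reads_per_sample < 0 or self.min_samples_passing < 0:
            raise ValueError("thresholds must be >= 0")
        if self.repeat_policy not in ("either_site", "any_overlap"):
            raise ValueError(f"unknown repeat_policy {self.repeat_policy!r}")


@dataclass
class ScreenReport:
    candidates: list[JunctionEvidence] = field(default_factory=list)
    rejections: dict[JunctionEvidence, RejectionReason] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.candidates) + len(self.rejections)


def filter_by_counts(j: JunctionEvidence, cfg: ScreenConfig) -> bool:
    n_pass = sum(c >= cfg.min_reads_per_sample for c in j.counts)
    return n_pass >= cfg.min_samples_passing


def _repeat_tree(repeats: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end)
    return trees


def filter_by_repeats(
    j: JunctionEvidence,
    repeats: Iterable[GenomicInterval] | dict[str, IntervalTree],
    cfg: ScreenConfig,
) -> bool:
    trees = repeats if isinstance(repeats, dict) else _repeat_tree(repeats)
    tree = trees.get(j.intron.contig)
    if tree is None:
        return True
    a, b = j.intron.start, j.intron.end
    if cfg.repeat_policy == "any_overlap":
        return not tree.overlap(a, b)
    # either_site: test the two terminal (splice-site) dinucleotides only
    return not (tree.overlap(a, a + 2) or tree.overlap(b - 2, b))


def filter_by_novelty(j: JunctionEvidence, ann: AnnotationSet) -> bool:
    """Novel iff the intron does not exactly match any annotated intron."""
    return j.intron.key not in ann.intron_keys()


def filter_by_support(
    j: JunctionEvidence,
    support: Iterable[GenomicInterval],
    cfg: ScreenConfig,
) -> bool:
    if not cfg.support_required:
        return True
    keys = (
        support
        if isinstance(support, set)
        else {iv.key for iv in support}
    )
    return j.intron.key in keys


def screen(
    junctions: Sequence[JunctionEvidence],
    ann: AnnotationSet,
    repeats: Iterable[GenomicInterval] = (),
    support: Iterable[GenomicInterval] = (),
    cfg: ScreenConfig | None = None,
) -> ScreenReport:
    """Apply all four filters in fixed order count -> repeat -> novelty -> support.

    Every input junction lands exactly once in ``candidates`` or
    ``rejections``; the recorded reason is the first filter failed.
    """
    cfg = cfg or ScreenConfig()
    trees = _repeat_tree(repeats)
    support_keys = {iv.key for iv in support}
    known = ann.intron_keys()
    report = ScreenReport()
    for j in junctions:
        if not filter_by_counts(j, cfg):
            report.rejections[j] = LOW_COUNT
        elif not filter_by_repeats(j, trees, cfg):
            report.rejections[j] = REPEAT_OVERLAP
        elif j.intron.key in known:
            report.rejections[j] = ANNOTATED
        elif cfg.support_required and j.intron.key not in support_keys:
            report.rejections[j] = UNSUPPORTED
        else:
            report.candidates.append(j)
    return report


# ---------------------------------------------------------------------------
# junction table I/O
# ---------------------------------------------------------------------------
# Format: header line "#samples=<id1,id2,...>" then tab-separated rows
# "contig  intron_start  intron_end  strand  counts" with counts a
# comma-separated per-sample list.


def read_junctions(path: str | Path) -> list[JunctionEvidence]:
    sample_ids: tuple[str, ...] | None = None
    out: list[JunctionEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#samples="):
                sample_ids = tuple(line[len("#samples=") :].split(","))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}, line {lineno}: expected 5 fields, got {len(fields)}"
                )
            if sample_ids is None:
                raise ValueError(f"{path}: missing '#samples=' header")
            counts = tuple(int(c) for c in fields[4].split(","))
            out.append(
                JunctionEvidence(
                    intron=GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2]), fields[3]
                    ),
                    counts=counts,
                    sample_ids=sample_ids,
                )
            )
    return out


def write_junctions(junctions: Sequence[JunctionEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        if junctions:
            fh.write(f"#samples={','.join(junctions[0].sample_ids)}\n")
        for j in junctions:
            counts = ",".join(str(c) for c in j.counts)
            fh.write(
                f"{j.intron.contig}\t{j.intron.start}\t{j.intron.end}\t"
                f"{j.intron.strand}\t{counts}\n"
            )
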