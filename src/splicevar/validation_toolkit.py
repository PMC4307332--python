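"""In-silico support for RT-PCR validation and conservation profiling.

``predict_amplicon`` reproduces the product-size arithmetic of isoform
RT-PCR: the forward primer is matched exactly on the spliced sense sequence,
the reverse primer as its reverse complement downstream, and the product is
the inclusive span from the forward primer's 5' end to the projection of the
reverse primer's 5' end. ``diversity_profile`` computes per-column diversity
of a protein multiple alignment (normalized Shannon entropy by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .annotation_io import reverse_complement

__all__ = [
    "PrimerPair",
    "AmpliconPrediction",
    "DiversityProfile",
    "predict_amplicon",
    "diversity_profile",
    "read_primers",
    "write_primers",
    "read_msa",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward_seq: str
    reverse_seq: str
    target_gene: str = ""

    def __post_init__(self) -> None:
        for label, s in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if len(s) < 10:
                raise ValueError(f"{self.name}: {label} primer shorter than 10 nt")


@dataclass
class AmpliconPrediction:
    isoform_id: str
    primer_name: str
    product_length_nt: int | None  # None = no product
    forward_start: int | None = None
    reverse_end: int | None = None
    ambiguous: bool = False  # multiple primer sites on the target
    all_products: list[int] = field(default_factory=list)


def _find_all(seq: str, sub: str) -> list[int]:
    out, pos = [], seq.find(sub)
    while pos != -1:
        out.append(pos)
        pos = seq.find(sub, pos + 1)
    return out


def predict_amplicon(
    p: PrimerPair, isoform_seq: str, isoform_id: str = ""
) -> AmpliconPrediction:
    """Exact-match amplicon prediction on one spliced isoform sequence.

    Multiple primer-site combinations are all reported and the prediction is
    flagged ambiguous; the reported product is then the shortest (the dominant
    band under standard PCR kinetics).
    """
    fw_sites = _find_all(isoform_seq, p.forward_seq.upper())
    rv_sites = _find_all(isoform_seq, reverse_complement(p.reverse_seq.upper()))
    products: list[tuple[int, int, int]] = []
    for f in fw_sites:
        for r in rv_sites:
            r_end = r + len(p.reverse_seq)
            length = r_end - f
            if r >= f + len(p.forward_seq):
                products.append((length, f, r_end))
    if not products:
        return AmpliconPrediction(isoform_id, p.name, None)
    products.sort()
    length, f, r_end = products[0]
    return AmpliconPrediction(
        isoform_id,
        p.name,
        product_length_nt=length,
        forward_start=f,
        reverse_end=r_end,
        ambiguous=len(products) > 1,
        all_products=[x[0] for x in products],
    )


@dataclass
class DiversityProfile:
    values: list[float]
    metric: str
    all_gap_columns: list[int] = field(default_factory=list)  # 0-based

    def __post_init__(self) -> None:
        if any(v < 0 or v > 1 + 1e-12 for v in self.values):
            raise ValueError("diversity values must lie in [0, 1]")


def diversity_profile(
    msa: Sequence[str], metric: str = "shannon_normalized"
) -> DiversityProfile:
    """Per-column diversity of an aligned set of protein sequences.

    ``shannon_normalized``: Shannon entropy of residue frequencies divided by
    ln(20), so identical columns score 0 and maximal 20-way diversity scores 1.
    ``one_minus_consensus``: 1 minus the frequency of the most common residue.
    Gap characters ('-', '.') are excluded from the frequencies; an all-gap
    column scores 0 and is flagged.
    """
    if len(msa) < 2:
        raise ValueError("an alignment needs at least 2 rows")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment: rows differ in length")
    if metric not in ("shannon_normalized", "one_minus_consensus"):
        raise ValueError(f"unknown metric {metric!r}")

    values: list[float] = []
    all_gap: list[int] = []
    for col in range(width):
        residues = [row[col].upper() for row in msa]
        residues = [r for r in residues if r not in ("-", ".")]
        if not residues:
            values.append(0.0)
            all_gap.append(col)
            continue
        _, counts = np.unique(residues, return_counts=True)
        freqs = counts / counts.sum()
        if metric == "shannon_normalized":
            h = float(-(freqs * np.log(freqs)).sum())
            values.append(min(h / np.log(len(AA_ALPHABET)), 1.0))
        else:
            values.append(float(1.0 - freqs.max()))
    return DiversityProfile(values, metric, all_gap)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_primers(path: str | Path) -> list[PrimerPair]:
    """Primers TSV: name, transcript/gene id, forward_seq, reverse_seq."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, target, fwd, rev = line.rstrip("\n").split("\t")
            out.append(PrimerPair(name, fwd, rev, target))
    return out


def write_primers(primers: Sequence[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\ttarget\tforward_seq\treverse_seq\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.target_gene}\t{p.forward_seq}\t{p.reverse_seq}\n")


def read_msa(path: str | Path) -> list[str]:
    """Aligned FASTA -> list of equal-length row strings."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
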