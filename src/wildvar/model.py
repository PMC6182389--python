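"""Core data model for the variant-analysis pipeline.

All genomic coordinates held in memory are 1-based inclusive (the VCF/GFF
convention). Conversion to 0-based half-open happens only at the BED/bedGraph
I/O boundary. InDel positions anchor at the VCF record position as given;
no left-normalisation is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class VariantClass(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class Zygosity(str, Enum):
    HET = "heterozygous"
    HOM = "homozygous-alt"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Classify a ref/alt allele pair as SNP, insertion or deletion."""
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            raise ValueError(f"ref and alt are identical: {ref!r}")
        return VariantClass.SNP
    if len(alt) > len(ref):
        return VariantClass.INS
    if len(ref) > len(alt):
        return VariantClass.DEL
    raise ValueError(
        f"unsupported allele pair (multi-nucleotide substitution?): {ref!r}>{alt!r}"
    )


@dataclass(frozen=True, order=True)
class Variant:
    """One called variant site for one sample.

    ``pos`` is the 1-based reference position of the first affected base
    (the VCF anchor base for InDels).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Zygosity = Zygosity.HOM
    depth: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        classify_alleles(self.ref, self.alt)  # validates allele shapes

    @property
    def vclass(self) -> VariantClass:
        return classify_alleles(self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return self.vclass is VariantClass.SNP

    @property
    def is_indel(self) -> bool:
        return self.vclass is not VariantClass.SNP

    @property
    def signed_length(self) -> int:
        """len(alt) - len(ref): positive for insertions, negative for deletions."""
        return len(self.alt) - len(self.ref)

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference span (1-based inclusive): pos .. pos+len(ref)-1."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class DomainInterval:
    """A protein-domain interval in 1-based amino-acid coordinates."""

    family: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValueError(
                f"invalid domain interval {self.family}: {self.aa_start}..{self.aa_end}"
            )

    def contains(self, aa_pos: int) -> bool:
        return self.aa_start <= aa_pos <= self.aa_end


@dataclass
class GeneModel:
    """A gene with its representative transcript's CDS segments.

    ``cds_segments`` is stored in ascending genomic order; use
    :meth:`cds_in_translation_order` for the order in which segments are
    spliced and translated (descending coordinates on the minus strand).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    domains: list[DomainInterval] = field(default_factory=list)
    is_nbs_lrr: bool = False
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.cds_segments = sorted(self.cds_segments)
        prev_end = None
        for s, e in self.cds_segments:
            if s > e or s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: CDS segment ({s},{e}) outside gene span "
                    f"[{self.start},{self.end}]"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    def cds_in_translation_order(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return list(self.cds_segments)
        return list(reversed(self.cds_segments))

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic position ``pos`` within the spliced CDS,

        counted in translation order, or None if ``pos`` is not in the CDS.
        """
        off = 0
        for s, e in self.cds_in_translation_order():
            if s <= pos <= e:
                if self.strand == "+":
                    return off + (pos - s)
                return off + (e - pos)
            off += e - s + 1
        return None

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive CDS segments, ascending genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.cds_segments, self.cds_segments[1:]):
            out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class DepthTrack:
    """Per-base read depth as sorted, non-overlapping 0-based half-open runs.

    Positions not covered by any run have implicit depth 0.
    """

    chrom: str
    runs: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.runs = sorted(self.runs)
        prev_end = None
        for s, e, d in self.runs:
            if s >= e or d < 0:
                raise ValueError(f"invalid depth run ({s},{e},{d}) on {self.chrom}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping depth runs on {self.chrom} at {s}")
            prev_end = e

    def bases_at_least(self, start: int, end: int, min_depth: int) -> int:
        """Count bases in 1-based inclusive [start, end] with depth >= min_depth.

        With ``min_depth == 0`` every base qualifies.
        """
        if min_depth <= 0:
            return end - start + 1
        lo, hi = start - 1, end  # half-open
        total = 0
        for s, e, d in self.runs:
            if e <= lo:
                continue
            if s >= hi:
                break
            if d >= min_depth:
                total += min(e, hi) - max(s, lo)
        return total


def sort_variants(variants: Iterable[Variant]) -> list[Variant]:
    return sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def check_sorted(variants: Sequence[Variant]) -> None:
    for a, b in zip(variants, variants[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError(
                f"variants not sorted: {a.chrom}:{a.pos} before {b.chrom}:{b.pos}"
            )
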