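"""Summary statistics over filtered variant sets.

Covers transition/transversion counting, zygosity proportions, InDel
length spectra (including the coding-region triple-nucleotide excess),
and assignment of variants to genomic regions (genic, 2-kb upstream /
downstream flanks, intergenic).

Ratios and percentages are computed in exact integer arithmetic and
rounded half-up at the reporting boundary, so printed values match what
recomputation from the underlying counts gives.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from fractions import Fraction
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .model import GeneModel, Variant, VariantClass, Zygosity

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_TI_PAIRS = {frozenset("AG"), frozenset("CT")}


class Substitution(str, Enum):
    TI = "Ti"
    TV = "Tv"


class Region(str, Enum):
    GENIC = "GENIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"


def round_half_up(value: Fraction | float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(value))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def classify_substitution(ref: str, alt: str) -> Substitution:
    """Transition (A<->G, C<->T) vs transversion for a single-base change."""
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"alleles must be single A/C/G/T bases: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"identical alleles: {ref!r}")
    return Substitution.TI if frozenset((ref, alt)) in _TI_PAIRS else Substitution.TV


def titv_ratio(n_ti: int, n_tv: int) -> float | None:
    """Ti/Tv to two decimals; None when there are no transversions."""
    if n_tv == 0:
        return None
    return round_half_up(Fraction(n_ti, n_tv))


def het_percentage(n_het: int, n_hom: int) -> float | None:
    if n_het + n_hom == 0:
        return None
    return round_half_up(Fraction(100 * n_het, n_het + n_hom))


@dataclass
class SnpSummary:
    n_snps: int
    n_ti: int
    n_tv: int
    n_het: int
    n_hom: int
    per_chromosome: dict[str, "SnpSummary"] = field(default_factory=dict)

    @property
    def titv(self) -> float | None:
        return titv_ratio(self.n_ti, self.n_tv)

    @property
    def het_pct(self) -> float | None:
        return het_percentage(self.n_het, self.n_hom)


@dataclass
class IndelSummary:
    n_ins: int
    n_del: int
    n_cds_ins: int
    n_cds_del: int
    length_histogram: dict[int, int] = field(default_factory=dict)
    cds_length_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_ins + self.n_del

    @property
    def n_cds(self) -> int:
        return self.n_cds_ins + self.n_cds_del

    def _pct(self, num: int, den: int) -> float | None:
        if den == 0:
            return None
        return round_half_up(Fraction(100 * num, den))

    @property
    def pct_cds(self) -> float | None:
        return self._pct(self.n_cds, self.n_total)

    @property
    def pct_single_nt(self) -> float | None:
        n1 = sum(c for l, c in self.length_histogram.items() if abs(l) == 1)
        return self._pct(n1, self.n_total)

    @property
    def pct_1_9bp(self) -> float | None:
        n = sum(c for l, c in self.length_histogram.items() if 1 <= abs(l) <= 9)
        return self._pct(n, self.n_total)

    @property
    def pct_triple_nt_genome(self) -> float | None:
        n3 = sum(c for l, c in self.length_histogram.items() if abs(l) == 3)
        return self._pct(n3, self.n_total)

    @property
    def pct_triple_nt_cds(self) -> float | None:
        n3 = sum(c for l, c in self.cds_length_histogram.items() if abs(l) == 3)
        return self._pct(n3, self.n_cds)


def snp_summary(snps: Sequence[Variant]) -> SnpSummary:
    """Table of SNP substitution-type and zygosity counts, whole genome and

    per chromosome."""
    def _tally(vs: Sequence[Variant]) -> SnpSummary:
        n_ti = n_tv = n_het = n_hom = 0
        for v in vs:
            if not v.is_snp:
                raise ValueError(f"non-SNP in snp_summary: {v.chrom}:{v.pos}")
            if classify_substitution(v.ref, v.alt) is Substitution.TI:
                n_ti += 1
            else:
                n_tv += 1
            if v.zygosity is Zygosity.HET:
                n_het += 1
            else:
                n_hom += 1
        return SnpSummary(len(vs), n_ti, n_tv, n_het, n_hom)

    total = _tally(snps)
    by_chrom: dict[str, list[Variant]] = {}
    for v in snps:
        by_chrom.setdefault(v.chrom, []).append(v)
    total.per_chromosome = {c: _tally(vs) for c, vs in sorted(by_chrom.items())}
    return total


def _cds_tree(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        t = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.cds_segments:
            t.addi(s, e + 1)  # tree is half-open
    return trees


def in_cds(variant: Variant, cds_trees: Mapping[str, IntervalTree]) -> bool:
    """True when the variant's affected reference span intersects any CDS."""
    t = cds_trees.get(variant.chrom)
    if t is None:
        return False
    s, e = variant.span
    return bool(t.overlap(s, e + 1))


def indel_summary(
    indels: Sequence[Variant], genes: Sequence[GeneModel]
) -> IndelSummary:
    """Insertion/deletion counts and signed-length spectra, genome-wide and

    restricted to coding sequence. An InDel is coding when its affected
    span (anchor..anchor+len(ref)-1) intersects any CDS segment."""
    trees = _cds_tree(genes)
    hist: Counter[int] = Counter()
    cds_hist: Counter[int] = Counter()
    n_ins = n_del = n_cds_ins = n_cds_del = 0
    for v in indels:
        if v.is_snp:
            raise ValueError(f"SNP in indel_summary: {v.chrom}:{v.pos}")
        L = v.signed_length
        hist[L] += 1
        cds = in_cds(v, trees)
        if cds:
            cds_hist[L] += 1
        if v.vclass is VariantClass.INS:
            n_ins += 1
            n_cds_ins += cds
        else:
            n_del += 1
            n_cds_del += cds
    return IndelSummary(
        n_ins=n_ins,
        n_del=n_del,
        n_cds_ins=n_cds_ins,
        n_cds_del=n_cds_del,
        length_histogram=dict(hist),
        cds_length_histogram=dict(cds_hist),
    )


class GeneIndex:
    """Interval index over gene spans and their strand-aware 2-kb flanks."""

    def __init__(self, genes: Sequence[GeneModel], flank_bp: int = 2000):
        self.flank_bp = flank_bp
        self.genic: dict[str, IntervalTree] = {}
        self.upstream: dict[str, IntervalTree] = {}
        self.downstream: dict[str, IntervalTree] = {}
        for g in genes:
            self.genic.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1)
            if g.strand == "+":
                up = (g.start - flank_bp, g.start - 1)
                dn = (g.end + 1, g.end + flank_bp)
            else:
                up = (g.end + 1, g.end + flank_bp)
                dn = (g.start - flank_bp, g.start - 1)
            for tree, (s, e) in ((self.upstream, up), (self.downstream, dn)):
                s = max(s, 1)
                if s <= e:
                    tree.setdefault(g.chrom, IntervalTree()).addi(s, e + 1)

    def _hit(self, trees: Mapping[str, IntervalTree], chrom: str, pos: int) -> bool:
        t = trees.get(chrom)
        return bool(t is not None and t.overlap(pos, pos + 1))


def assign_region(
    variant: Variant, index: GeneIndex
) -> Region:
    """GENIC > UPSTREAM > DOWNSTREAM > INTERGENIC precedence on overlap."""
    c, p = variant.chrom, variant.pos
    if index._hit(index.genic, c, p):
        return Region.GENIC
    if index._hit(index.upstream, c, p):
        return Region.UPSTREAM
    if index._hit(index.downstream, c, p):
        return Region.DOWNSTREAM
    return Region.INTERGENIC


def region_counts(
    variants: Sequence[Variant], genes: Sequence[GeneModel], flank_bp: int = 2000
) -> dict[Region, int]:
    index = GeneIndex(genes, flank_bp)
    counts = {r: 0 for r in Region}
    for v in variants:
        counts[assign_region(v, index)] += 1
    return counts
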