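"""Codon- and splice-aware effect classification of variants on gene models.

A CDS SNP is classified by mutating its codon and translating with the
standard nuclear code (reverse-complement aware on the minus strand):
stop gained/lost, start lost, synonymous or non-synonymous. CDS InDels are
frameshift when their length change is not a multiple of 3, otherwise
in-frame codon InDels. Splice classes follow the usual annotator geometry:
the first/last two intronic bases are donor/acceptor sites, and a wider
splice region covers exonic bases 1-3 and intronic bases 3-8 from each
internal junction.

Variants in the eight disruptive categories — start/stop codon changes,
the three splice classes, and frameshifts — are flagged "large-effect",
the predicate used to pull out genes with potentially broken products.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Mapping, Protocol, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .model import GeneModel, Variant, VariantClass
from .stats import GeneIndex, Region, assign_region, round_half_up


class EffectCategory(str, Enum):
    SYNONYMOUS = "SYNONYMOUS"
    NON_SYNONYMOUS = "NON_SYNONYMOUS"
    START_LOST = "START_LOST"
    NON_SYNONYMOUS_START = "NON_SYNONYMOUS_START"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    FRAME_SHIFT = "FRAME_SHIFT"
    CODON_INDEL = "CODON_INDEL"
    SPLICE_SITE_DONOR = "SPLICE_SITE_DONOR"
    SPLICE_SITE_ACCEPTOR = "SPLICE_SITE_ACCEPTOR"
    SPLICE_SITE_REGION = "SPLICE_SITE_REGION"
    INTRON = "INTRON"
    UTR = "UTR"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"


LARGE_EFFECT_CATEGORIES = frozenset(
    {
        EffectCategory.START_LOST,
        EffectCategory.NON_SYNONYMOUS_START,
        EffectCategory.STOP_GAINED,
        EffectCategory.STOP_LOST,
        EffectCategory.SPLICE_SITE_REGION,
        EffectCategory.SPLICE_SITE_ACCEPTOR,
        EffectCategory.SPLICE_SITE_DONOR,
        EffectCategory.FRAME_SHIFT,
    }
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

START_CODON = "ATG"
# alternative starts recognised when a codon-1 change still yields a start
ALT_START_CODONS = frozenset({"CTG", "TTG"})


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


class GenomeSource(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Reference bases for 1-based inclusive [start, end], uppercase."""


class DictGenome:
    """In-memory genome: a mapping of chromosome name to sequence string."""

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = {c: s.upper() for c, s in seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start - 1 : end]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


class FastaGenome:
    """pyfaidx-backed genome access."""

    def __init__(self, path: str):
        import pyfaidx

        self.fa = pyfaidx.Fasta(path)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self.fa[chrom][start - 1 : end]).upper()

    def lengths(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self.fa.items()}


@dataclass(frozen=True)
class SpliceConfig:
    donor_bp: int = 2
    acceptor_bp: int = 2
    region_exonic_bp: int = 3
    region_intronic_min: int = 3
    region_intronic_max: int = 8


@dataclass(frozen=True)
class EffectCall:
    variant: Variant
    gene_id: str | None
    category: EffectCategory
    protein_pos: int | None = None  # 1-based aa position, CDS SNPs only
    aa_change: str | None = None    # e.g. "W12*"

    @property
    def is_large_effect(self) -> bool:
        return self.category in LARGE_EFFECT_CATEGORIES


# window categories in decreasing severity for point/interval splice lookup
_SPLICE_PRIORITY = {
    EffectCategory.SPLICE_SITE_DONOR: 2,
    EffectCategory.SPLICE_SITE_ACCEPTOR: 2,
    EffectCategory.SPLICE_SITE_REGION: 1,
}


class EffectClassifier:
    """Classifies variants against gene models, caching per-gene geometry."""

    def __init__(
        self,
        genome: GenomeSource,
        splice: SpliceConfig | None = None,
        flank_bp: int = 2000,
    ):
        self.genome = genome
        self.splice = splice or SpliceConfig()
        self.flank_bp = flank_bp
        self._cds_cache: dict[str, str] = {}
        self._window_cache: dict[str, list[tuple[int, int, EffectCategory, bool]]] = {}

    # -- gene geometry -----------------------------------------------------

    def spliced_cds(self, gene: GeneModel) -> str:
        seq = self._cds_cache.get(gene.gene_id)
        if seq is None:
            parts = [
                self.genome.fetch(gene.chrom, s, e) for s, e in gene.cds_segments
            ]
            seq = "".join(parts)
            if gene.strand == "-":
                seq = revcomp(seq)
            self._cds_cache[gene.gene_id] = seq
        return seq

    def splice_windows(
        self, gene: GeneModel
    ) -> list[tuple[int, int, EffectCategory, bool]]:
        """Genomic (start, end, category, exonic) splice windows of a gene."""
        cached = self._window_cache.get(gene.gene_id)
        if cached is not None:
            return cached
        sp = self.splice
        win: list[tuple[int, int, EffectCategory, bool]] = []
        for intron_s, intron_e in gene.introns():
            if intron_s > intron_e:
                continue
            # transcript-orientation: donor side is the intron edge adjacent
            # to the earlier exon in translation order
            if gene.strand == "+":
                donor_lo, acceptor_hi = intron_s, intron_e
                win.append((intron_s, min(intron_s + sp.donor_bp - 1, intron_e),
                            EffectCategory.SPLICE_SITE_DONOR, False))
                win.append((max(intron_e - sp.acceptor_bp + 1, intron_s), intron_e,
                            EffectCategory.SPLICE_SITE_ACCEPTOR, False))
                region = [
                    (intron_s + sp.region_intronic_min - 1,
                     intron_s + sp.region_intronic_max - 1),
                    (intron_e - sp.region_intronic_max + 1,
                     intron_e - sp.region_intronic_min + 1),
                ]
            else:
                win.append((max(intron_e - sp.donor_bp + 1, intron_s), intron_e,
                            EffectCategory.SPLICE_SITE_DONOR, False))
                win.append((intron_s, min(intron_s + sp.acceptor_bp - 1, intron_e),
                            EffectCategory.SPLICE_SITE_ACCEPTOR, False))
                region = [
                    (intron_e - sp.region_intronic_max + 1,
                     intron_e - sp.region_intronic_min + 1),
                    (intron_s + sp.region_intronic_min - 1,
                     intron_s + sp.region_intronic_max - 1),
                ]
            for s, e in region:
                s, e = max(s, intron_s), min(e, intron_e)
                if s <= e:
                    win.append((s, e, EffectCategory.SPLICE_SITE_REGION, False))
            # exonic splice-region bases flanking the junction
            win.append((intron_s - sp.region_exonic_bp, intron_s - 1,
                        EffectCategory.SPLICE_SITE_REGION, True))
            win.append((intron_e + 1, intron_e + sp.region_exonic_bp,
                        EffectCategory.SPLICE_SITE_REGION, True))
        self._window_cache[gene.gene_id] = win
        return win

    def _splice_lookup(
        self, gene: GeneModel, start: int, end: int
    ) -> EffectCategory | None:
        """Highest-severity splice window overlapping [start, end], if any."""
        best: EffectCategory | None = None
        for s, e, cat, _exonic in self.splice_windows(gene):
            if s <= end and start <= e:
                if best is None or _SPLICE_PRIORITY[cat] > _SPLICE_PRIORITY[best]:
                    best = cat
        return best

    # -- classification ----------------------------------------------------

    def classify(self, variant: Variant, gene: GeneModel) -> EffectCall:
        v, g = variant, gene
        if v.chrom != g.chrom or not g.contains(v.pos):
            return EffectCall(v, None, self._flank_category(v, g))
        if v.is_snp:
            return self._classify_snp(v, g)
        return self._classify_indel(v, g)

    def _flank_category(self, v: Variant, g: GeneModel) -> EffectCategory:
        if v.chrom == g.chrom:
            if g.strand == "+":
                up = g.start - self.flank_bp <= v.pos < g.start
                dn = g.end < v.pos <= g.end + self.flank_bp
            else:
                up = g.end < v.pos <= g.end + self.flank_bp
                dn = g.start - self.flank_bp <= v.pos < g.start
            if up:
                return EffectCategory.UPSTREAM
            if dn:
                return EffectCategory.DOWNSTREAM
        return EffectCategory.INTERGENIC

    def _classify_snp(self, v: Variant, g: GeneModel) -> EffectCall:
        off = g.cds_offset(v.pos)
        splice = self._splice_lookup(g, v.pos, v.pos)
        if off is None:
            if splice is not None:
                return EffectCall(v, g.gene_id, splice)
            if any(s <= v.pos <= e for s, e in g.introns()):
                return EffectCall(v, g.gene_id, EffectCategory.INTRON)
            return EffectCall(v, g.gene_id, EffectCategory.UTR)
        if splice is not None:
            # exonic splice-region bases outrank coding classification
            return EffectCall(v, g.gene_id, splice,
                              protein_pos=off // 3 + 1)
        ref_base = self.genome.fetch(v.chrom, v.pos, v.pos)
        if ref_base != v.ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: VCF ref {v.ref!r} "
                f"vs genome {ref_base!r}"
            )
        cds = self.spliced_cds(g)
        ci, within = divmod(off, 3)
        codon_ref = cds[ci * 3 : ci * 3 + 3]
        alt = v.alt if g.strand == "+" else v.alt.translate(_COMPLEMENT)
        codon_alt = codon_ref[:within] + alt + codon_ref[within + 1 :]
        return self._categorize_codon_change(v, g, ci, codon_ref, codon_alt, len(cds))

    def _categorize_codon_change(
        self, v: Variant, g: GeneModel, ci: int,
        codon_ref: str, codon_alt: str, cds_len: int,
    ) -> EffectCall:
        aa_ref = translate_codon(codon_ref)
        aa_alt = translate_codon(codon_alt)
        ppos = ci + 1
        change = f"{aa_ref}{ppos}{aa_alt}"
        last = ci == cds_len // 3 - 1
        if ci == 0 and codon_ref == START_CODON:
            if codon_alt in ALT_START_CODONS:
                cat = EffectCategory.NON_SYNONYMOUS_START
            else:
                cat = EffectCategory.START_LOST
        elif last and aa_ref == "*":
            cat = (EffectCategory.SYNONYMOUS if aa_alt == "*"
                   else EffectCategory.STOP_LOST)
        elif aa_alt == "*":
            cat = EffectCategory.STOP_GAINED
        elif aa_alt == aa_ref:
            cat = EffectCategory.SYNONYMOUS
        else:
            cat = EffectCategory.NON_SYNONYMOUS
        return EffectCall(v, g.gene_id, cat, protein_pos=ppos, aa_change=change)

    def _classify_indel(self, v: Variant, g: GeneModel) -> EffectCall:
        s, e = v.span
        splice = self._splice_lookup(g, s, e)
        in_cds = any(cs <= e and s <= ce for cs, ce in g.cds_segments)
        if splice is not None:
            return EffectCall(v, g.gene_id, splice)
        if in_cds:
            if abs(v.signed_length) % 3 != 0:
                return EffectCall(v, g.gene_id, EffectCategory.FRAME_SHIFT)
            return EffectCall(v, g.gene_id, EffectCategory.CODON_INDEL)
        if any(i_s <= e and s <= i_e for i_s, i_e in g.introns()):
            return EffectCall(v, g.gene_id, EffectCategory.INTRON)
        return EffectCall(v, g.gene_id, EffectCategory.UTR)


def classify_effect(
    variant: Variant,
    gene: GeneModel,
    genome: GenomeSource,
    splice: SpliceConfig | None = None,
) -> EffectCall:
    """One-shot classification of a single variant against a single gene."""
    return EffectClassifier(genome, splice).classify(variant, gene)


def annotate_variants(
    variants: Sequence[Variant],
    genes: Sequence[GeneModel],
    genome: GenomeSource,
    splice: SpliceConfig | None = None,
    flank_bp: int = 2000,
) -> list[EffectCall]:
    """Classify every variant against every gene whose span contains it.

    Variants hitting no gene get a single call with the flank/intergenic
    category from strand-aware region assignment.
    """
    clf = EffectClassifier(genome, splice, flank_bp)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    index = GeneIndex(genes, flank_bp)
    region_to_cat = {
        Region.UPSTREAM: EffectCategory.UPSTREAM,
        Region.DOWNSTREAM: EffectCategory.DOWNSTREAM,
        Region.INTERGENIC: EffectCategory.INTERGENIC,
    }
    calls: list[EffectCall] = []
    for v in variants:
        tree = trees.get(v.chrom)
        hits = sorted(tree.overlap(v.pos, v.pos + 1),
                      key=lambda iv: iv.data.gene_id) if tree else []
        if hits:
            calls.extend(clf.classify(v, iv.data) for iv in hits)
        else:
            region = assign_region(v, index)
            calls.append(EffectCall(v, None, region_to_cat.get(
                region, EffectCategory.INTERGENIC)))
    return calls


def large_effect_genes(
    effects: Sequence[EffectCall],
) -> tuple[set[str], dict[str, dict[str, int]]]:
    """Genes carrying >= 1 large-effect call, with per-gene SNP/InDel counts."""
    counts: dict[str, dict[str, int]] = {}
    for c in effects:
        if not c.is_large_effect or c.gene_id is None:
            continue
        d = counts.setdefault(c.gene_id, {"snp": 0, "indel": 0})
        d["snp" if c.variant.is_snp else "indel"] += 1
    return set(counts), counts


@dataclass(frozen=True)
class DomainNsSy:
    family: str
    n_nonsynonymous: int
    n_synonymous: int

    @property
    def ratio(self) -> float | None:
        if self.n_synonymous == 0:
            return None
        return round_half_up(Fraction(self.n_nonsynonymous, self.n_synonymous))


def ns_sy_by_domain(
    effects: Sequence[EffectCall], genes: Sequence[GeneModel]
) -> list[DomainNsSy]:
    """Non-synonymous / synonymous SNP counts per protein-domain family.

    A coding SNP contributes to a family when its amino-acid position
    (ceil of CDS offset / 3) falls in one of that family's intervals on the
    hit gene.
    """
    by_id = {g.gene_id: g for g in genes}
    ns: dict[str, int] = {}
    sy: dict[str, int] = {}
    for c in effects:
        if c.gene_id is None or c.protein_pos is None:
            continue
        if c.category not in (EffectCategory.NON_SYNONYMOUS, EffectCategory.SYNONYMOUS):
            continue
        gene = by_id.get(c.gene_id)
        if gene is None:
            continue
        for d in gene.domains:
            if d.contains(c.protein_pos):
                target = ns if c.category is EffectCategory.NON_SYNONYMOUS else sy
                target[d.family] = target.get(d.family, 0) + 1
    families = sorted(set(ns) | set(sy))
    return [DomainNsSy(f, ns.get(f, 0), sy.get(f, 0)) for f in families]


def overlap_genes(
    intervals: Sequence[tuple[str, int, int]], genes: Sequence[GeneModel]
) -> dict[tuple[str, int, int], list[str]]:
    """Gene ids whose span intersects each 1-based inclusive interval."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    out: dict[tuple[str, int, int], list[str]] = {}
    for chrom, start, end in intervals:
        tree = trees.get(chrom)
        hits = sorted(iv.data for iv in tree.overlap(start, end + 1)) if tree else []
        out[(chrom, start, end)] = hits
    return out
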