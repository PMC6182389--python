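"""Effect classification: codon changes, frameshifts, splice geometry,
the large-effect predicate, and domain-level Ns/Sy ratios."""
import random

import pytest
from Bio.Seq import Seq

from wildvar.effects import (
    DictGenome,
    EffectCategory,
    EffectClassifier,
    LARGE_EFFECT_CATEGORIES,
    annotate_variants,
    classify_effect,
    large_effect_genes,
    ns_sy_by_domain,
    overlap_genes,
    revcomp,
)
from wildvar.model import DomainInterval, GeneModel, Variant
from wildvar import synth

CAT = EffectCategory


# codon layout of toy_gene_plus: ATG(101) TGG(104) GAA(107) TAA(110)
class TestCodonChanges:
    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (106, "G", "A", CAT.STOP_GAINED),          # TGG -> TGA
        (109, "A", "G", CAT.SYNONYMOUS),           # GAA -> GAG (both Glu)
        (107, "G", "C", CAT.NON_SYNONYMOUS),       # GAA -> CAA (Glu->Gln)
        (110, "T", "C", CAT.STOP_LOST),            # TAA -> CAA
        (101, "A", "G", CAT.START_LOST),           # ATG -> GTG
        (101, "A", "C", CAT.NON_SYNONYMOUS_START), # ATG -> CTG (alt start)
        (112, "A", "G", CAT.SYNONYMOUS),           # TAA -> TAG (stop kept)
    ])
    def test_snp_categories(self, toy_gene_plus, toy_genome_plus,
                            pos, ref, alt, expected):
        call = classify_effect(Variant("Chr1", pos, ref, alt),
                               toy_gene_plus, toy_genome_plus)
        assert call.category is expected
        assert call.is_large_effect == (expected in LARGE_EFFECT_CATEGORIES)

    def test_reference_mismatch_names_position(self, toy_gene_plus,
                                               toy_genome_plus):
        with pytest.raises(ValueError, match="Chr1:106"):
            classify_effect(Variant("Chr1", 106, "C", "A"),
                            toy_gene_plus, toy_genome_plus)


class TestIndelFrames:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("ATT", "A", CAT.FRAME_SHIFT),   # -2
        ("ATTT", "A", CAT.CODON_INDEL),  # -3
        ("A", "AC", CAT.FRAME_SHIFT),    # +1
        ("A", "ACCCGGG", CAT.CODON_INDEL),  # +6
    ])
    def test_mod3_rule_inside_cds(self, ref, alt, expected):
        seq = ["A"] * 400
        cds = "ATG" + "GGC" * 60 + "TAA"
        seq[100:100 + len(cds)] = list(cds)
        genome = DictGenome({"Chr1": "".join(seq)})
        gene = GeneModel(gene_id="g", chrom="Chr1", strand="+", start=51,
                         end=350, cds_segments=[(101, 100 + len(cds))])
        v = Variant("Chr1", 150, ref, alt)
        call = classify_effect(v, gene, genome)
        assert call.category is expected
        assert call.is_large_effect == (expected is CAT.FRAME_SHIFT)


def two_exon_gene(strand):
    """CDS 101..160 and 301..360 with a 140-bp intron; valid 40-codon ORF."""
    cds = "ATG" + "GCT" * 38 + "TGA"  # 120 nt
    seq = ["A"] * 500
    genomic = cds if strand == "+" else revcomp(cds)
    seq[100:160] = list(genomic[:60])
    seq[300:360] = list(genomic[60:])
    genome = DictGenome({"Chr1": "".join(seq)})
    gene = GeneModel(gene_id="g2x", chrom="Chr1", strand=strand, start=51,
                     end=420, cds_segments=[(101, 160), (301, 360)])
    return gene, genome


class TestSpliceGeometry:
    @pytest.mark.parametrize("pos,expected", [
        (161, CAT.SPLICE_SITE_DONOR),     # intron base 1 after exon
        (162, CAT.SPLICE_SITE_DONOR),
        (163, CAT.SPLICE_SITE_REGION),    # intron bases 3..8
        (168, CAT.SPLICE_SITE_REGION),
        (169, CAT.INTRON),
        (292, CAT.INTRON),
        (293, CAT.SPLICE_SITE_REGION),    # intron bases 3..8 before exon
        (298, CAT.SPLICE_SITE_REGION),
        (299, CAT.SPLICE_SITE_ACCEPTOR),  # last 2 intronic bases
        (300, CAT.SPLICE_SITE_ACCEPTOR),
        (160, CAT.SPLICE_SITE_REGION),    # exonic bases 1..3 of junction
        (158, CAT.SPLICE_SITE_REGION),
        (70, CAT.UTR),
        (380, CAT.UTR),
    ])
    def test_plus_strand_offsets(self, pos, expected):
        gene, genome = two_exon_gene("+")
        base = genome.fetch("Chr1", pos, pos)
        alt = "C" if base != "C" else "G"
        call = classify_effect(Variant("Chr1", pos, base, alt), gene, genome)
        assert call.category is expected

    def test_minus_strand_swaps_donor_acceptor(self):
        gene, genome = two_exon_gene("-")
        # on -, translation runs right to left: donor side is intron end
        for pos, expected in [(299, CAT.SPLICE_SITE_DONOR),
                              (300, CAT.SPLICE_SITE_DONOR),
                              (161, CAT.SPLICE_SITE_ACCEPTOR),
                              (162, CAT.SPLICE_SITE_ACCEPTOR)]:
            base = genome.fetch("Chr1", pos, pos)
            alt = "C" if base != "C" else "G"
            call = classify_effect(Variant("Chr1", pos, base, alt), gene, genome)
            assert call.category is expected, pos

    def test_indel_spanning_junction_takes_splice_class(self):
        gene, genome = two_exon_gene("+")
        ref = genome.fetch("Chr1", 159, 163)  # crosses exon end into donor
        v = Variant("Chr1", 159, ref, ref[0])
        call = classify_effect(v, gene, genome)
        assert call.category is CAT.SPLICE_SITE_DONOR
        assert call.is_large_effect


class TestStrandSymmetry:
    def test_mirrored_gene_gives_identical_categories(self):
        """Reverse-complementing genome, gene and variant preserves calls."""
        gene, genome = two_exon_gene("+")
        L = len(genome.seqs["Chr1"])
        flipped = DictGenome({"Chr1": revcomp(genome.seqs["Chr1"])})
        mirror = GeneModel(
            gene_id="g2x", chrom="Chr1", strand="-",
            start=L - gene.end + 1, end=L - gene.start + 1,
            cds_segments=[(L - e + 1, L - s + 1) for s, e in gene.cds_segments],
        )
        comp = dict(zip("ACGT", "TGCA"))
        rng = random.Random(9)
        for _ in range(60):
            pos = rng.randint(gene.start, gene.end)
            ref = genome.fetch("Chr1", pos, pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = classify_effect(Variant("Chr1", pos, ref, alt), gene, genome)
            rev = classify_effect(
                Variant("Chr1", L - pos + 1, comp[ref], comp[alt]),
                mirror, flipped)
            assert fwd.category is rev.category, (pos, ref, alt)


class TestRandomOracle:
    def test_cds_snps_match_full_retranslation(self):
        """500 random coding SNPs vs an independent whole-protein oracle."""
        lengths = {"Chr01": 400_000}
        genome = synth.make_genome(lengths, seed=7)
        genes, _ = synth.make_genes(genome, n_genes=12, seed=7)
        clf = EffectClassifier(genome)
        rng = random.Random(7)
        checked = 0
        while checked < 500:
            gene = rng.choice(genes)
            # keep clear of junctions so splice classes cannot trigger
            seg = rng.choice(gene.cds_segments)
            if seg[1] - seg[0] < 10:
                continue
            pos = rng.randint(seg[0] + 4, seg[1] - 4)
            ref = genome.fetch(gene.chrom, pos, pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            got = clf.classify(Variant(gene.chrom, pos, ref, alt), gene)
            assert got.category is self.retranslation_oracle(
                genome, gene, pos, alt), (gene.gene_id, pos, ref, alt)
            checked += 1

    @staticmethod
    def retranslation_oracle(genome, gene, pos, alt):
        """Mutate the chromosome, re-extract the CDS, translate end to end."""
        chrom_seq = genome.seqs[gene.chrom]
        mutated = chrom_seq[: pos - 1] + alt + chrom_seq[pos:]

        def protein(seq):
            cds = "".join(seq[s - 1:e] for s, e in gene.cds_segments)
            if gene.strand == "-":
                cds = revcomp(cds)
            return str(Seq(cds).translate())

        p_ref, p_alt = protein(chrom_seq), protein(mutated)
        off = gene.cds_offset(pos)
        ci = off // 3
        if ci == 0:
            alt_start = ("".join(mutated[s - 1:e] for s, e in gene.cds_segments))
            if gene.strand == "-":
                alt_start = revcomp(alt_start)
            first = alt_start[:3]
            if first == "ATG":
                return CAT.SYNONYMOUS if p_alt == p_ref else CAT.NON_SYNONYMOUS
            return (CAT.NON_SYNONYMOUS_START if first in {"CTG", "TTG"}
                    else CAT.START_LOST)
        if p_alt == p_ref:
            return CAT.SYNONYMOUS
        if p_ref[ci] == "*" and p_alt[ci] != "*":
            return CAT.STOP_LOST
        if p_alt[ci] == "*" and p_ref[ci] != "*":
            return CAT.STOP_GAINED
        return CAT.NON_SYNONYMOUS

    def test_cds_indels_match_mod3_oracle(self):
        lengths = {"Chr01": 400_000}
        genome = synth.make_genome(lengths, seed=8)
        genes, _ = synth.make_genes(genome, n_genes=12, seed=8)
        clf = EffectClassifier(genome)
        rng = random.Random(8)
        checked = 0
        while checked < 500:
            gene = rng.choice(genes)
            seg = rng.choice(gene.cds_segments)
            if seg[1] - seg[0] < 40:
                continue
            n = rng.randint(1, 9)
            pos = rng.randint(seg[0] + 9, seg[1] - 9 - n)
            if rng.random() < 0.5:
                ref = genome.fetch(gene.chrom, pos, pos + n)
                v = Variant(gene.chrom, pos, ref, ref[0])
            else:
                ref = genome.fetch(gene.chrom, pos, pos)
                v = Variant(gene.chrom, pos, ref,
                            ref + "".join(rng.choice("ACGT") for _ in range(n)))
            got = clf.classify(v, gene)
            expected = (CAT.FRAME_SHIFT if abs(v.signed_length) % 3
                        else CAT.CODON_INDEL)
            assert got.category is expected
            checked += 1


class TestLargeEffectPredicate:
    def test_eight_category_set(self):
        assert LARGE_EFFECT_CATEGORIES == {
            CAT.START_LOST, CAT.NON_SYNONYMOUS_START, CAT.STOP_GAINED,
            CAT.STOP_LOST, CAT.SPLICE_SITE_REGION, CAT.SPLICE_SITE_ACCEPTOR,
            CAT.SPLICE_SITE_DONOR, CAT.FRAME_SHIFT}

    def test_large_effect_genes_groupby(self, toy_gene_plus, toy_genome_plus):
        calls = [
            classify_effect(Variant("Chr1", 106, "G", "A"),  # stop gained
                            toy_gene_plus, toy_genome_plus),
            classify_effect(Variant("Chr1", 109, "A", "G"),  # synonymous
                            toy_gene_plus, toy_genome_plus),
        ]
        genes, counts = large_effect_genes(calls)
        assert genes == {"gA"}
        assert counts["gA"] == {"snp": 1, "indel": 0}

    def test_empty_input(self):
        assert large_effect_genes([]) == (set(), {})


class TestNsSyByDomain:
    def test_planted_counts_recovered(self, toy_genome_plus):
        gene = GeneModel(
            gene_id="gA", chrom="Chr1", strand="+", start=51, end=162,
            cds_segments=[(101, 112)],
            domains=[DomainInterval("NB-ARC", 2, 3)])
        calls = [
            classify_effect(Variant("Chr1", 107, "G", "C"), gene,
                            toy_genome_plus),  # non-syn at aa 3
            classify_effect(Variant("Chr1", 108, "A", "T"), gene,
                            toy_genome_plus),  # non-syn at aa 3
            classify_effect(Variant("Chr1", 109, "A", "G"), gene,
                            toy_genome_plus),  # synonymous at aa 3
            classify_effect(Variant("Chr1", 104, "T", "A"), gene,
                            toy_genome_plus),  # aa 2 in domain: non-syn
        ]
        (d,) = ns_sy_by_domain(calls, [gene])
        assert (d.family, d.n_nonsynonymous, d.n_synonymous) == ("NB-ARC", 3, 1)
        assert d.ratio == 3.00

    def test_zero_synonymous_undefined_ratio(self, toy_genome_plus):
        gene = GeneModel(
            gene_id="gA", chrom="Chr1", strand="+", start=51, end=162,
            cds_segments=[(101, 112)],
            domains=[DomainInterval("LRR_1", 2, 3)])
        calls = [classify_effect(Variant("Chr1", 107, "G", "C"), gene,
                                 toy_genome_plus)]
        (d,) = ns_sy_by_domain(calls, [gene])
        assert d.n_synonymous == 0 and d.ratio is None


class TestOverlapGenes:
    def test_full_and_no_overlap(self, toy_gene_plus):
        res = overlap_genes([("Chr1", 1, 200), ("Chr1", 250, 260)],
                            [toy_gene_plus])
        assert res[("Chr1", 1, 200)] == ["gA"]
        assert res[("Chr1", 250, 260)] == []

    def test_matches_quadratic_oracle(self):
        rng = random.Random(4)
        genes = [GeneModel(gene_id=f"g{i}", chrom="Chr1", strand="+",
                           start=s, end=s + rng.randint(100, 2000),
                           cds_segments=[])
                 for i, s in enumerate(sorted(rng.sample(range(1, 90_000), 20)))]
        intervals = []
        for _ in range(100):
            s = rng.randint(1, 95_000)
            intervals.append(("Chr1", s, s + rng.randint(1, 3000)))
        res = overlap_genes(intervals, genes)
        for iv in intervals:
            expected = sorted(g.gene_id for g in genes
                              if g.start <= iv[2] and iv[1] <= g.end)
            assert res[iv] == expected


class TestAnnotateVariants:
    def test_every_variant_gets_at_least_one_call(self, toy_gene_plus,
                                                  toy_genome_plus):
        vs = [Variant("Chr1", 106, "G", "A"), Variant("Chr1", 250, "A", "C")]
        calls = annotate_variants(vs, [toy_gene_plus], toy_genome_plus)
        assert len(calls) == 2
        assert calls[0].gene_id == "gA"
        assert calls[1].gene_id is None
        assert calls[1].category is CAT.DOWNSTREAM  # 250 within 2 kb of 3' end
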