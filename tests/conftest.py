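import textwrap

import pytest

from wildvar.model import DomainInterval, GeneModel, Variant, Zygosity


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write a minimal VCF from body lines (CHROM..sample columns)."""

    def _write(body_lines, sample="S1", contigs=(("Chr1", 1_000_000),)):
        header = ["##fileformat=VCFv4.2"]
        header += [f"##contig=<ID={c},length={l}>" for c, l in contigs]
        header += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
        ]
        path = tmp_path / "test.vcf"
        path.write_text("\n".join(header + list(body_lines)) + "\n")
        return path

    return _write


@pytest.fixture
def toy_gene_plus():
    """Single-exon + strand gene: ATG TGG GAA TAA at 101..112."""
    return GeneModel(
        gene_id="gA", chrom="Chr1", strand="+", start=51, end=162,
        cds_segments=[(101, 112)],
    )


@pytest.fixture
def toy_genome_plus(toy_gene_plus):
    from wildvar.effects import DictGenome

    seq = ["A"] * 300
    seq[100:112] = list("ATGTGGGAATAA")
    return DictGenome({"Chr1": "".join(seq)})


def snp(chrom, pos, ref="A", alt="G", zyg=Zygosity.HOM, depth=50):
    return Variant(chrom, pos, ref, alt, zyg, depth)


def deletion(chrom, pos, n=1, zyg=Zygosity.HOM, depth=50):
    return Variant(chrom, pos, "A" + "T" * n, "A", zyg, depth)


def insertion(chrom, pos, n=1, zyg=Zygosity.HOM, depth=50):
    return Variant(chrom, pos, "A", "A" + "T" * n, zyg, depth)


@pytest.fixture
def mk():
    """Namespace of little variant factories for terse test bodies."""

    class M:
        pass

    M.snp = staticmethod(snp)
    M.deletion = staticmethod(deletion)
    M.insertion = staticmethod(insertion)
    return M
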