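"""Readers and writers for the formats the pipeline touches.

VCF goes through pysam, GFF3 through gffutils, FASTA through pyfaidx /
Biopython. BED4, bedGraph, the chromosome-length table and the domain
sidecar are small whitespace-delimited text formats handled directly.

Coordinate conventions: VCF/GFF and the in-memory model are 1-based
inclusive; BED and bedGraph are 0-based half-open. Conversion happens only
in this module.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import gffutils

from .model import (
    DepthTrack,
    DomainInterval,
    GeneModel,
    Variant,
    VariantClass,
    Zygosity,
    sort_variants,
)

log = logging.getLogger(__name__)

DEFAULT_NBS_FAMILIES = frozenset({"NB-ARC"})


class VCFError(ValueError):
    pass


class GFFError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample: str | None = None) -> list[Variant]:
    """Read one sample's variants from a VCF 4.x file.

    Multi-allelic records are split into one :class:`Variant` per alternate
    allele. Zygosity: a genotype carrying two copies of that allele is
    homozygous-alt; any other called genotype (one reference allele, or two
    distinct alternates) is heterozygous. Depth comes from the per-sample DP
    field, falling back to INFO/DP, then 0. Records whose genotype is
    entirely uncalled (./.) are skipped.
    """
    path = str(path)
    variants: list[Variant] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise VCFError(
                    f"{path}: sample name required (file has {len(samples)} samples)"
                )
            sample = samples[0]
        if sample not in samples:
            raise VCFError(f"{path}: sample {sample!r} not in VCF header")
        for i, rec in enumerate(vf, start=1):
            try:
                variants.extend(_split_record(rec, sample))
            except VCFError:
                raise
            except Exception as exc:  # malformed record content
                raise VCFError(f"{path}: malformed record #{i} at "
                               f"{rec.chrom}:{rec.pos}: {exc}") from exc
    return sort_variants(variants)


def _split_record(rec: pysam.VariantRecord, sample: str) -> list[Variant]:
    call = rec.samples[sample]
    if "GT" not in call:
        raise VCFError(f"record {rec.chrom}:{rec.pos} has no GT for sample {sample!r}")
    gt = call["GT"]
    if gt is None or all(a is None for a in gt):
        return []  # uncalled genotype
    depth = call.get("DP")
    if depth is None:
        depth = rec.info.get("DP", 0)
    depth = int(depth) if depth is not None else 0

    out = []
    alts = rec.alts or ()
    for ai, alt in enumerate(alts, start=1):
        if alt is None or alt == "*" or alt.startswith("<"):
            continue
        hom = tuple(a for a in gt if a is not None) == (ai, ai)
        out.append(
            Variant(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                zygosity=Zygosity.HOM if hom else Zygosity.HET,
                depth=depth,
            )
        )
    return out


def write_vcf(
    variants: Sequence[Variant],
    path: str | Path,
    sample: str,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write variants as a single-sample uncompressed VCF with GT:DP."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sort_variants(variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.samples[sample]["GT"] = (1, 1) if v.zygosity is Zygosity.HOM else (0, 1)
            rec.samples[sample].phased = False
            rec.samples[sample]["DP"] = v.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# GFF3 + domain sidecar
# ---------------------------------------------------------------------------

def read_domains(path: str | Path) -> dict[str, list[DomainInterval]]:
    """Read the domain sidecar TSV: gene_id, family, aa_start, aa_end."""
    out: dict[str, list[DomainInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gene_id, family, aa_start, aa_end = line.split("\t")[:4]
            out.setdefault(gene_id, []).append(
                DomainInterval(family, int(aa_start), int(aa_end))
            )
    return out


def write_domains(domains: Mapping[str, Sequence[DomainInterval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily\taa_start\taa_end\n")
        for gene_id in sorted(domains):
            for d in domains[gene_id]:
                fh.write(f"{gene_id}\t{d.family}\t{d.aa_start}\t{d.aa_end}\n")


def read_gff(
    path: str | Path,
    domains_path: str | Path | None = None,
    nbs_families: frozenset[str] = DEFAULT_NBS_FAMILIES,
) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/CDS hierarchy).

    One representative transcript per gene: the mRNA with the longest total
    CDS. Genes whose representative CDS length is not a multiple of 3 are
    flagged ``incomplete`` with a warning. Domain intervals come from the
    optional sidecar TSV; a gene is flagged NBS-LRR when any of its domain
    families is in ``nbs_families``.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # CDS features must hang off an mRNA (or gene) parent
    for cds in db.features_of_type("CDS"):
        if not list(db.parents(cds)):
            raise GFFError(f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no parent")

    domain_map = read_domains(domains_path) if domains_path else {}

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            best, best_len = None, -1
            for m in mrnas:
                clen = sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
                if clen > best_len:
                    best, best_len = m, clen
            cds = list(db.children(best, featuretype="CDS"))
        else:
            cds = list(db.children(gene, featuretype="CDS"))
        segments = sorted((c.start, c.end) for c in cds)
        incomplete = False
        total = sum(e - s + 1 for s, e in segments)
        if segments and total % 3 != 0:
            warnings.warn(
                f"gene {gene.id}: CDS length {total} not a multiple of 3; "
                "model flagged incomplete"
            )
            incomplete = True
        dom = domain_map.get(gene.id, [])
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                cds_segments=segments,
                domains=list(dom),
                is_nbs_lrr=any(d.family in nbs_families for d in dom),
                incomplete=incomplete,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\twildvar\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\twildvar\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            # phase in translation order
            phase, rows = 0, []
            for s, e in g.cds_in_translation_order():
                rows.append((s, e, phase))
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for s, e, ph in sorted(rows):
                fh.write(
                    f"{g.chrom}\twildvar\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"ID=cds-{mrna};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# FASTA & chromosome lengths
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_lengths(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length = line.split()[:2]
            out[chrom] = int(length)
    return out


# ---------------------------------------------------------------------------
# BED4 (labeled regions) & bedGraph
# ---------------------------------------------------------------------------

def write_region_bed(
    regions: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write labeled 1-based inclusive intervals as sorted BED4.

    Input tuples are (chrom, start, end, label); output is 0-based half-open.
    """
    rows = sorted(regions)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlabel\n")
        for chrom, start, end, label in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{label}\n")


def read_region_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED4 back into 1-based inclusive labeled intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            chrom, start, end, label = line.split("\t")[:4]
            out.append((chrom, int(start) + 1, int(end), label))
    return out


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Alias used for pan-genome unique-gene interval lists (BED4)."""
    return read_region_bed(path)


def write_bedgraph(tracks: Mapping[str, DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            for s, e, d in tracks[chrom].runs:
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def read_bedgraph(path: str | Path) -> dict[str, DepthTrack]:
    """Read a bedGraph file into per-chromosome depth tracks."""
    runs: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, depth = line.split()[:4]
            runs.setdefault(chrom, []).append((int(start), int(end), int(float(depth))))
    return {c: DepthTrack(chrom=c, runs=r) for c, r in runs.items()}
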