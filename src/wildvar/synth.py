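"""Synthetic genomes, gene models, variant sets and depth tracks with
recorded truth.

The generator emulates the statistical structure of a deep-coverage rice
re-sequencing experiment: a random reference genome at rice-like GC
content, non-overlapping protein-coding gene models (ATG start, stop
codon, no internal stops, optional NB-ARC/LRR_1 domain annotations and
planted clusters), per-sample variant sets with controllable Ti/Tv ratio,
heterozygous fraction, InDel length spectrum (with the coding-region
triple-nucleotide spike), planted variation-rich/-poor 100-kb tiles, and
per-sample depth tracks with planted absent genes. Everything planted is
recorded in a :class:`SyntheticTruth` so recovery tests read expectations
from the truth object, never from hard-coded numbers.

Each output draws from its own RNG stream derived from the master seed by
a fixed label, so generating one artifact never perturbs another.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .effects import DictGenome, revcomp
from .model import DepthTrack, DomainInterval, GeneModel, Variant, Zygosity

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = ("TAA", "TAG", "TGA")
_TI_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream for one artifact, derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    seed: int
    titv: float | None = None
    het_fraction: float | None = None
    indel_geom_p: float | None = None
    cds_triple_fraction: float | None = None
    cds_indel_fraction: float | None = None
    del_fraction: float | None = None
    n_snps: int = 0
    n_indels: int = 0
    window_bp: int = 100_000
    rich_tiles: list[tuple[str, int, int]] = field(default_factory=list)
    poor_tiles: list[tuple[str, int, int]] = field(default_factory=list)
    rich_multiplier: float = 10.0
    poor_multiplier: float = 0.05
    planted_clusters: list[list[str]] = field(default_factory=list)
    absent_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["rich_tiles"] = [tuple(t) for t in d.get("rich_tiles", [])]
        d["poor_tiles"] = [tuple(t) for t in d.get("poor_tiles", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(
    chromosome_lengths: Mapping[str, int], gc: float = 0.435, seed: int = 0
) -> DictGenome:
    """Random reference genome at the given GC content (rice-like default)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    for chrom in sorted(chromosome_lengths):
        rng = stream(seed, f"genome/{chrom}")
        arr = rng.choice(BASES, size=chromosome_lengths[chrom], p=p)
        seqs[chrom] = arr.tobytes().decode()
    return DictGenome(seqs)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """A planted gene cluster: n_genes NBS-LRR genes inside span_bp."""

    chrom: str
    start: int
    n_genes: int
    span_bp: int


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence: ATG, non-stop codons, one stop. Length 3*(n+2)."""
    codons = ["ATG"]
    while len(codons) < n_codons + 1:
        c = "".join(rng.choice(BASES, size=3).astype(str))
        if c not in STOP_CODONS:  # internal Met is fine; internal stops are not
            codons.append(c)
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def _split_exons(
    rng: np.random.Generator, cds_len: int, n_exons: int, intron_len: tuple[int, int]
) -> tuple[list[int], list[int]]:
    """Exon lengths summing to cds_len, and intron lengths between them."""
    if n_exons == 1:
        return [cds_len], []
    cuts = sorted(
        rng.choice(np.arange(30, cds_len - 30), size=n_exons - 1, replace=False)
    )
    exon_lens = np.diff([0, *cuts, cds_len]).tolist()
    intron_lens = rng.integers(intron_len[0], intron_len[1] + 1,
                               size=n_exons - 1).tolist()
    return exon_lens, intron_lens


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start_hint: int,
    n_codons: int,
    n_exons: int,
    utr: int = 200,
    intron_len: tuple[int, int] = (60, 400),
) -> tuple[GeneModel, str, list[tuple[int, int]]]:
    """Gene model anchored near start_hint plus its CDS sequence and segments."""
    cds_seq = _random_cds(rng, n_codons)
    exon_lens, intron_lens = _split_exons(rng, len(cds_seq), n_exons, intron_len)
    strand = "+" if rng.random() < 0.5 else "-"
    cds_start = start_hint + utr
    segments = []
    pos = cds_start
    for i, el in enumerate(exon_lens):
        segments.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start_hint,
        end=segments[-1][1] + utr,
        cds_segments=segments,
    )
    return gene, cds_seq, segments


def _patch_cds(
    seqs: dict[str, bytearray], gene: GeneModel, cds_seq: str
) -> None:
    """Write the coding sequence into the genome under the gene's segments."""
    genomic = cds_seq if gene.strand == "+" else revcomp(cds_seq)
    buf = seqs[gene.chrom]
    off = 0
    for s, e in gene.cds_segments:
        n = e - s + 1
        buf[s - 1 : e] = genomic[off : off + n].encode()
        off += n


def make_genes(
    genome: DictGenome,
    n_genes: int,
    n_nbs: int = 0,
    seed: int = 0,
    clusters: Sequence[ClusterSpec] = (),
    codon_range: tuple[int, int] = (100, 300),
    gap_range: tuple[int, int] = (6_000, 20_000),
) -> tuple[list[GeneModel], dict[str, list[DomainInterval]]]:
    """Place non-overlapping gene models and patch their CDS into the genome.

    ``n_genes`` background genes are laid out left to right with random
    intergenic gaps across the chromosomes; planted clusters add
    ``n_genes`` NBS-LRR genes each inside the requested span. The first
    ``n_nbs`` background genes also carry NB-ARC/LRR_1 domains. Returns the
    models plus the domain sidecar mapping. Raises when genes cannot be
    packed into the genome.
    """
    rng = stream(seed, "genes")
    lengths = genome.lengths()
    seqs = {c: bytearray(s, "ascii") for c, s in genome.seqs.items()}
    genes: list[GeneModel] = []
    domains: dict[str, list[DomainInterval]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}

    def add_domains(gene: GeneModel) -> None:
        plen = gene.protein_length
        nb_end = min(plen - 1, 180)
        domains[gene.gene_id] = [
            DomainInterval("NB-ARC", 20, max(nb_end, 21)),
            DomainInterval("LRR_1", min(plen - 1, nb_end + 10), plen - 1),
        ]
        gene.domains = list(domains[gene.gene_id])
        gene.is_nbs_lrr = True

    # planted clusters first, so background placement can avoid them
    for ci, spec in enumerate(clusters):
        if spec.chrom not in lengths:
            raise ValueError(f"cluster on unknown chromosome {spec.chrom!r}")
        slot = spec.span_bp // spec.n_genes
        cluster_ids = []
        for k in range(spec.n_genes):
            gid = f"nbsC{ci}_{k}"
            hint = spec.start + k * slot
            n_codons = int(rng.integers(*codon_range))
            gene, cds_seq, _ = _build_gene(
                rng, gid, spec.chrom, hint, n_codons, n_exons=1, utr=100
            )
            if gene.end >= spec.start + spec.span_bp or gene.end > lengths[spec.chrom]:
                raise ValueError(
                    f"cluster {ci}: gene {gid} does not fit in span "
                    f"{spec.span_bp} bp (needs {gene.end - spec.start + 1})"
                )
            _patch_cds(seqs, gene, cds_seq)
            add_domains(gene)
            genes.append(gene)
            cluster_ids.append(gid)
        occupied[spec.chrom].append((spec.start, spec.start + spec.span_bp))

    # background genes
    chroms = sorted(lengths)
    cursor = {c: int(rng.integers(*gap_range)) for c in chroms}
    placed = 0
    ci = 0
    attempts = 0
    while placed < n_genes:
        attempts += 1
        if attempts > 20 * n_genes + 100:
            raise ValueError("cannot pack requested genes into the genome")
        chrom = chroms[ci % len(chroms)]
        ci += 1
        hint = cursor[chrom]
        n_codons = int(rng.integers(*codon_range))
        n_exons = int(rng.integers(1, 4))
        gid = f"g{placed:04d}"
        gene, cds_seq, _ = _build_gene(rng, gid, chrom, hint, n_codons, n_exons)
        if gene.end > lengths[chrom] - 1000:
            cursor[chrom] = lengths[chrom] + 1  # chromosome full
            if all(cursor[c] > lengths[c] for c in chroms):
                raise ValueError("cannot pack requested genes into the genome")
            continue
        clash = any(s <= gene.end and gene.start <= e
                    for s, e in occupied[chrom])
        if clash:
            cursor[chrom] = max(e for s, e in occupied[chrom]
                                if s <= gene.end and gene.start <= e) + int(
                                    rng.integers(*gap_range))
            continue
        _patch_cds(seqs, gene, cds_seq)
        if placed < n_nbs:
            add_domains(gene)
        genes.append(gene)
        occupied[chrom].append((gene.start, gene.end))
        cursor[chrom] = gene.end + int(rng.integers(*gap_range))
        placed += 1

    genome.seqs = {c: b.decode() for c, b in seqs.items()}
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes, domains


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _tile_grid(
    lengths: Mapping[str, int], window_bp: int
) -> list[tuple[str, int, int]]:
    tiles = []
    for chrom in sorted(lengths):
        L = lengths[chrom]
        for s in range(1, L + 1, window_bp):
            tiles.append((chrom, s, min(s + window_bp - 1, L)))
    return tiles


def _indel_length(
    rng: np.random.Generator, p: float, in_cds: bool, triple_frac: float
) -> int:
    """Geometric(ish) InDel length on 1..30; coding InDels spike at 3."""
    if in_cds and rng.random() < triple_frac:
        return 3
    while True:
        L = int(rng.geometric(p))
        if L > 30:
            continue
        if in_cds and L == 3:
            continue  # the spike owns all coding triples
        return L


def make_variants(
    genome: DictGenome,
    genes: Sequence[GeneModel],
    n_snps: int,
    n_indels: int,
    titv: float = 2.53,
    het_frac: float = 0.1135,
    indel_geom_p: float = 0.235,
    cds_triple_frac: float = 0.4274,
    cds_indel_frac: float = 0.058,
    del_frac: float = 0.519,
    rich_tiles: Sequence[tuple[str, int, int]] = (),
    poor_tiles: Sequence[tuple[str, int, int]] = (),
    rich_multiplier: float = 10.0,
    poor_multiplier: float = 0.05,
    window_bp: int = 100_000,
    depth_mean: float = 45.0,
    depth_shape: float = 4.0,
    seed: int = 0,
    label: str = "variants",
) -> tuple[list[Variant], SyntheticTruth]:
    """Draw a per-sample variant set with recorded truth.

    SNP substitutions are transitions with probability titv/(1+titv), so
    the expected Ti/Tv ratio equals ``titv``. Zygosity is Bernoulli
    (``het_frac``). SNP (and background InDel) positions are uniform within
    tiles whose sampling weight is 1 except for planted rich/poor tiles at
    the stated multipliers. A fraction ``cds_indel_frac`` of InDels is
    placed inside coding segments, with length 3 at probability
    ``cds_triple_frac`` (the remainder geometric, conditioned away from 3,
    so the coding triple fraction is the dial itself); background InDels
    are geometric on 1..30 and avoid CDS. Read depths are gamma-Poisson
    (negative-binomial-like) with the given mean and shape, overdispersed
    as real re-sequencing coverage is, so the 11-100x depth filter has
    realistic tails to act on.
    """
    rng = stream(seed, label)
    lengths = genome.lengths()
    tiles = _tile_grid(lengths, window_bp)
    tile_index = {(c, s): i for i, (c, s, _e) in enumerate(tiles)}
    mult = np.ones(len(tiles))
    for tset, m in ((rich_tiles, rich_multiplier), (poor_tiles, poor_multiplier)):
        for chrom, s, e in tset:
            key = (chrom, s)
            if key not in tile_index or tiles[tile_index[key]][2] != e:
                raise ValueError(f"planted tile {chrom}:{s}-{e} not on the tile grid")
            mult[tile_index[key]] = m
    sizes = np.array([e - s + 1 for _c, s, e in tiles], dtype=float)
    weights = sizes / window_bp * mult
    weights /= weights.sum()

    used: dict[str, set[int]] = {c: set() for c in lengths}

    def sample_positions(n: int) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        per_tile = rng.multinomial(n, weights)
        for (chrom, s, e), cnt in zip(tiles, per_tile):
            if cnt == 0:
                continue
            taken = used[chrom]
            size = e - s + 1
            picks = rng.choice(size, size=min(cnt * 2 + 8, size), replace=False)
            got = 0
            for off in picks:
                pos = s + int(off)
                if pos in taken:
                    continue
                taken.add(pos)
                out.append((chrom, pos))
                got += 1
                if got == cnt:
                    break
            if got < cnt:
                raise ValueError(f"tile {chrom}:{s} too dense to place variants")
        return out

    # CDS interval lists for background rejection / coding placement
    cds_ivals: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    seg_pool: list[tuple[str, int, int]] = []
    for g in genes:
        for s, e in g.cds_segments:
            cds_ivals[g.chrom].append((s, e))
            seg_pool.append((g.chrom, s, e))
    for c in cds_ivals:
        cds_ivals[c].sort()

    def span_in_cds(chrom: str, lo: int, hi: int) -> bool:
        import bisect
        ivals = cds_ivals[chrom]
        i = bisect.bisect_right(ivals, (hi, float("inf")))
        for s, e in ivals[max(0, i - 8) : i + 1]:
            if s <= hi and lo <= e:
                return True
        return False

    variants: list[Variant] = []

    def depth() -> int:
        return int(rng.poisson(rng.gamma(depth_shape, depth_mean / depth_shape)))

    def zyg() -> Zygosity:
        return Zygosity.HET if rng.random() < het_frac else Zygosity.HOM

    # SNPs
    p_ti = titv / (1.0 + titv)
    for chrom, pos in sample_positions(n_snps):
        ref = genome.fetch(chrom, pos, pos)
        if rng.random() < p_ti:
            alt = _TI_PARTNER[ref]
        else:
            alt = _TV_PARTNERS[ref][rng.integers(2)]
        variants.append(Variant(chrom, pos, ref, alt, zyg(), depth()))

    # InDels
    n_cds_indels = int(round(cds_indel_frac * n_indels))
    n_bg_indels = n_indels - n_cds_indels
    if n_cds_indels and not seg_pool:
        raise ValueError("coding InDels requested but no genes supplied")
    seg_weights = None
    if seg_pool:
        seg_lens = np.array([e - s + 1 for _c, s, e in seg_pool], dtype=float)
        seg_weights = seg_lens / seg_lens.sum()

    def make_indel(chrom: str, pos: int, in_cds: bool) -> Variant | None:
        L = _indel_length(rng, indel_geom_p, in_cds, cds_triple_frac)
        if rng.random() < del_frac:  # deletion
            if pos + L > lengths[chrom]:
                return None
            ref = genome.fetch(chrom, pos, pos + L)
            alt = ref[0]
        else:
            ref = genome.fetch(chrom, pos, pos)
            ins = "".join(rng.choice(BASES, size=L).astype(str))
            alt = ref + ins
        return Variant(chrom, pos, ref, alt, zyg(), depth())

    # background InDels: uniform via tile weights, rejected out of CDS
    placed = 0
    guard = 0
    while placed < n_bg_indels:
        guard += 1
        if guard > 200 * n_bg_indels + 1000:
            raise ValueError("cannot place background InDels away from CDS")
        for chrom, pos in sample_positions(min(n_bg_indels - placed, 4096)):
            v = make_indel(chrom, pos, in_cds=False)
            if v is None or span_in_cds(chrom, *v.span):
                used[chrom].discard(pos)
                continue
            variants.append(v)
            placed += 1
            if placed == n_bg_indels:
                break

    # coding InDels: anchored so the affected span stays inside one segment
    placed = 0
    guard = 0
    while placed < n_cds_indels:
        guard += 1
        if guard > 200 * n_cds_indels + 1000:
            raise ValueError("cannot place coding InDels")
        si = int(rng.choice(len(seg_pool), p=seg_weights))
        chrom, s, e = seg_pool[si]
        if e - s + 1 < 35:
            continue
        pos = int(rng.integers(s, e - 31))
        if pos in used[chrom]:
            continue
        v = make_indel(chrom, pos, in_cds=True)
        if v is None or v.span[1] > e:
            continue
        used[chrom].add(pos)
        variants.append(v)
        placed += 1

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    truth = SyntheticTruth(
        seed=seed,
        titv=titv,
        het_fraction=het_frac,
        indel_geom_p=indel_geom_p,
        cds_triple_fraction=cds_triple_frac,
        cds_indel_fraction=cds_indel_frac,
        del_fraction=del_frac,
        n_snps=n_snps,
        n_indels=n_indels,
        window_bp=window_bp,
        rich_tiles=[tuple(t) for t in rich_tiles],
        poor_tiles=[tuple(t) for t in poor_tiles],
        rich_multiplier=rich_multiplier,
        poor_multiplier=poor_multiplier,
    )
    return variants, truth


# ---------------------------------------------------------------------------
# Depth tracks / PAV
# ---------------------------------------------------------------------------

DEFAULT_SIM_CONFIG: dict = {
    # A scaled-down three-accession study: two 2-Mb chromosomes instead of
    # twelve ~30-Mb ones, with per-sample Ti/Tv and heterozygosity set to
    # the three accessions' reported values.
    "seed": 1,
    "chromosomes": {"Chr01": 2_000_000, "Chr02": 2_000_000},
    "gc": 0.435,
    "genes": {
        "n": 60,
        "n_nbs": 6,
        "clusters": [
            {"chrom": "Chr02", "start": 1_600_001, "n_genes": 5, "span_bp": 150_000}
        ],
    },
    "samples": [
        {"name": "S24", "n_snps": 20_000, "n_indels": 4_000,
         "titv": 2.40, "het_frac": 0.5471,
         "rich_tiles": [["Chr01", 1_200_001, 1_300_000]],
         "poor_tiles": [["Chr02", 300_001, 400_000]]},
        {"name": "Huaye3", "n_snps": 15_000, "n_indels": 3_000,
         "titv": 2.51, "het_frac": 0.1164,
         "rich_tiles": [["Chr01", 1_200_001, 1_300_000]],
         "poor_tiles": []},
        {"name": "Huaye4", "n_snps": 18_000, "n_indels": 3_500,
         "titv": 2.53, "het_frac": 0.1135,
         "rich_tiles": [["Chr01", 1_200_001, 1_300_000],
                        ["Chr02", 700_001, 800_000]],
         "poor_tiles": []},
    ],
    "pav": {"n_unique": 30, "absent_per_sample": 4, "shared_absent": 2,
            "base_depth": 30},
}


def simulate(config: Mapping | None = None, outdir: str | Path = "sim") -> dict:
    """Generate a full study bundle on disk and return the truth dict.

    Writes ref.fa, lengths.tsv, genes.gff3, domains.tsv, one VCF and one
    bedGraph per sample, unique_genes.bed, and truth.json under ``outdir``.
    """
    from . import io_formats

    cfg = {**DEFAULT_SIM_CONFIG, **(dict(config) if config else {})}
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lengths = dict(cfg["chromosomes"])
    genome = make_genome(lengths, gc=cfg["gc"], seed=seed)
    clusters = [ClusterSpec(**c) for c in cfg["genes"].get("clusters", [])]
    genes, domains = make_genes(
        genome, cfg["genes"]["n"], cfg["genes"].get("n_nbs", 0),
        seed=seed, clusters=clusters,
    )
    io_formats.write_fasta(genome.seqs, outdir / "ref.fa")
    io_formats.write_lengths(lengths, outdir / "lengths.tsv")
    io_formats.write_gff(genes, outdir / "genes.gff3")
    io_formats.write_domains(domains, outdir / "domains.tsv")

    truth: dict = {
        "seed": seed,
        "chromosomes": lengths,
        "planted_clusters": [
            [g.gene_id for g in genes
             if g.gene_id.startswith(f"nbsC{i}_")]
            for i in range(len(clusters))
        ],
        "samples": {},
    }

    for sample in cfg["samples"]:
        s = dict(sample)
        name = s.pop("name")
        s["rich_tiles"] = [tuple(t) for t in s.pop("rich_tiles", [])]
        s["poor_tiles"] = [tuple(t) for t in s.pop("poor_tiles", [])]
        variants, vtruth = make_variants(
            genome, genes, seed=seed, label=f"variants/{name}", **s
        )
        io_formats.write_vcf(variants, outdir / f"{name}.vcf", name, lengths)
        truth["samples"][name] = asdict(vtruth)

    # PAV: unique genes and planted absences
    pav = cfg.get("pav") or {}
    if pav:
        rng = stream(seed, "pav")
        pool = [g for g in genes if not g.is_nbs_lrr]
        n_unique = min(int(pav["n_unique"]), len(pool))
        unique = sorted(
            (pool[i] for i in rng.choice(len(pool), n_unique, replace=False)),
            key=lambda g: (g.chrom, g.start),
        )
        io_formats.write_region_bed(
            [(g.chrom, g.start, g.end, g.gene_id) for g in unique],
            outdir / "unique_genes.bed",
        )
        ids = [g.gene_id for g in unique]
        shared = [str(x) for x in rng.choice(ids, int(pav.get("shared_absent", 0)),
                                             replace=False)]
        absent: dict[str, set[str]] = {}
        for sample in cfg["samples"]:
            name = sample["name"]
            rest = [g for g in ids if g not in shared]
            extra = [str(x) for x in rng.choice(
                rest, int(pav.get("absent_per_sample", 0)), replace=False)]
            absent[name] = set(shared) | set(extra)
        tracks, absent_truth = make_depth(
            lengths, unique, absent,
            base_depth=int(pav.get("base_depth", 30)), seed=seed,
        )
        for name, per_chrom in tracks.items():
            io_formats.write_bedgraph(per_chrom, outdir / f"{name}.bedgraph")
        truth["unique_genes"] = ids
        truth["absent_genes"] = {k: sorted(v) for k, v in absent.items()}
        truth["shared_absent"] = sorted(shared)

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=list)
    return truth


def make_depth(
    chromosome_lengths: Mapping[str, int],
    unique_genes: Sequence[GeneModel],
    absent: Mapping[str, set[str] | Sequence[str]],
    base_depth: int = 30,
    seed: int = 0,
) -> tuple[dict[str, dict[str, DepthTrack]], dict[str, list[str]]]:
    """Per-sample depth tracks: uniform coverage with planted absent genes.

    Each sample's track holds ``base_depth`` everywhere except over that
    sample's absent genes, which drop to depth 0 across their whole span.
    Returns tracks keyed by sample then chromosome, plus the absent-gene
    truth mapping.
    """
    by_id = {g.gene_id: g for g in unique_genes}
    tracks: dict[str, dict[str, DepthTrack]] = {}
    truth: dict[str, list[str]] = {}
    for sample in sorted(absent):
        gone = sorted(set(absent[sample]))
        missing = [g for g in gone if g not in by_id]
        if missing:
            raise ValueError(f"absent genes not in unique-gene set: {missing}")
        truth[sample] = gone
        zero: dict[str, list[tuple[int, int]]] = {}
        for gid in gone:
            g = by_id[gid]
            zero.setdefault(g.chrom, []).append((g.start - 1, g.end))  # half-open
        sample_tracks: dict[str, DepthTrack] = {}
        for chrom in sorted(chromosome_lengths):
            L = chromosome_lengths[chrom]
            holes = sorted(zero.get(chrom, []))
            runs: list[tuple[int, int, int]] = []
            cur = 0
            for hs, he in holes:
                if hs > cur:
                    runs.append((cur, hs, base_depth))
                runs.append((hs, he, 0))
                cur = he
            if cur < L:
                runs.append((cur, L, base_depth))
            sample_tracks[chrom] = DepthTrack(chrom=chrom, runs=runs)
        tracks[sample] = sample_tracks
    return tracks, truth
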