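"""End-to-end orchestration: filter -> stats -> density -> effects ->
clusters/PAV over one or more samples, with a consolidated JSON manifest.

Every artifact is a plain-text table (TSV/BED/VCF) plus one machine-
readable manifest of the headline numbers; re-running with the same
inputs and config reproduces the manifest byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cluster_pav, density, effects as fx, filtering, io_formats, stats
from .effects import FastaGenome
from .model import GeneModel, Variant

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample: str | None, cause: Exception):
        super().__init__(f"stage {stage!r}"
                         + (f" (sample {sample})" if sample else "")
                         + f" failed: {cause}")
        self.stage = stage
        self.sample = sample


@dataclass
class SampleInputs:
    name: str
    vcf: str
    bedgraph: str | None = None


@dataclass
class RunConfig:
    samples: list[SampleInputs]
    gff: str
    fasta: str
    outdir: str
    domains: str | None = None
    lengths: str | None = None
    unique_genes: str | None = None  # BED4 of pan-genome unique-gene intervals
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    depth_first: bool = False
    window_bp: int = 100_000
    flank_bp: int = 2000
    fence_multiplier: float = 1.5
    cluster_max_span_bp: int = 200_000
    cluster_min_genes: int = 4
    pav_threshold: float = 1.0
    pav_min_depth: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["samples"] = [SampleInputs(**s) for s in raw["samples"]]
        if "filter" in raw:
            raw["filter"] = filtering.FilterConfig(**raw["filter"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            **{k: v for k, v in self.__dict__.items()
               if k not in ("samples", "filter")},
            "samples": [s.__dict__ for s in self.samples],
            "filter": self.filter.__dict__,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _snp_block(s: stats.SnpSummary) -> dict:
    return {
        "n_snps": s.n_snps, "n_ti": s.n_ti, "n_tv": s.n_tv,
        "titv": s.titv, "n_het": s.n_het, "n_hom": s.n_hom,
        "het_pct": s.het_pct,
    }


def _indel_block(s: stats.IndelSummary) -> dict:
    return {
        "n_ins": s.n_ins, "n_del": s.n_del, "n_total": s.n_total,
        "n_cds": s.n_cds, "pct_cds": s.pct_cds,
        "pct_single_nt": s.pct_single_nt, "pct_1_9bp": s.pct_1_9bp,
        "pct_triple_nt_cds": s.pct_triple_nt_cds,
        "pct_triple_nt_genome": s.pct_triple_nt_genome,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.echo.yaml")

    genome = FastaGenome(cfg.fasta)
    lengths = (io_formats.read_lengths(cfg.lengths) if cfg.lengths
               else genome.lengths())
    genes = io_formats.read_gff(cfg.gff, cfg.domains)
    unique_intervals = (io_formats.read_bed_intervals(cfg.unique_genes)
                        if cfg.unique_genes else [])

    manifest: dict = {"samples": {}, "shared": {}}
    region_calls: dict[str, dict[str, list[density.RegionCall]]] = {"SNP": {}, "InDel": {}}
    site_sets: dict[str, set] = {}
    presence: dict[str, list[cluster_pav.PresenceCall]] = {}

    for si in cfg.samples:
        name = si.name
        sm: dict = {}
        try:
            variants = io_formats.read_vcf(si.vcf, name)
        except Exception as exc:
            raise PipelineError("read_vcf", name, exc) from exc

        try:
            report = filtering.apply_all_filters(variants, cfg.filter,
                                                 depth_first=cfg.depth_first)
            kept = report.kept
            io_formats.write_vcf(kept, out / f"{name}.kept.vcf", name, lengths)
            pd.DataFrame(report.to_rows()).to_csv(
                out / f"{name}.filter_report.tsv", sep="\t", index=False)
            sm["filter"] = {"n_input": report.n_input,
                            "removed": dict(report.removed_by_stage),
                            "kept_by_class": dict(report.kept_by_class)}
        except Exception as exc:
            raise PipelineError("filter", name, exc) from exc

        snps = [v for v in kept if v.is_snp]
        indels = [v for v in kept if v.is_indel]
        site_sets[name] = {(v.chrom, v.pos, v.ref, v.alt) for v in kept}

        try:
            ssum = stats.snp_summary(snps)
            isum = stats.indel_summary(indels, genes)
            regions = stats.region_counts(kept, genes, cfg.flank_bp)
            sm["snp_summary"] = _snp_block(ssum)
            sm["snp_summary"]["per_chromosome"] = {
                c: _snp_block(x) for c, x in ssum.per_chromosome.items()}
            sm["indel_summary"] = _indel_block(isum)
            sm["region_counts"] = {r.value: n for r, n in regions.items()}
            blocks = [
                pd.DataFrame([{"chrom": "ALL", **_snp_block(ssum)}]
                             + [{"chrom": c, **_snp_block(x)}
                                for c, x in ssum.per_chromosome.items()]),
            ]
            blocks[0].to_csv(out / f"{name}.snp_summary.tsv", sep="\t", index=False)
            pd.DataFrame([_indel_block(isum)]).to_csv(
                out / f"{name}.indel_summary.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError("stats", name, exc) from exc

        try:
            for label, vs in (("SNP", snps), ("InDel", indels)):
                track = density.window_counts(vs, lengths, cfg.window_bp)
                calls = density.call_regions(track, cfg.fence_multiplier)
                region_calls[label][name] = calls
                io_formats.write_region_bed(
                    [(c.chrom, c.start, c.end, c.label) for c in calls],
                    out / f"{name}.{label.lower()}_regions.bed")
                sm.setdefault("density", {})[label] = {
                    "rich": sum(c.label == "rich" for c in calls),
                    "poor": sum(c.label == "poor" for c in calls)}
        except Exception as exc:
            raise PipelineError("density", name, exc) from exc

        try:
            calls = fx.annotate_variants(kept, genes, genome,
                                         flank_bp=cfg.flank_bp)
            rows = [{
                "chrom": c.variant.chrom, "pos": c.variant.pos,
                "ref": c.variant.ref, "alt": c.variant.alt,
                "gene_id": c.gene_id or ".", "category": c.category.value,
                "large_effect": int(c.is_large_effect),
                "protein_pos": c.protein_pos or ".",
                "aa_change": c.aa_change or "."} for c in calls]
            pd.DataFrame(rows).to_csv(out / f"{name}.effects.tsv",
                                      sep="\t", index=False)
            le_genes, le_counts = fx.large_effect_genes(calls)
            pd.DataFrame(
                [{"gene_id": g, **le_counts[g]} for g in sorted(le_genes)]
            ).to_csv(out / f"{name}.large_effect_genes.tsv", sep="\t", index=False)
            nssy = fx.ns_sy_by_domain(calls, genes)
            pd.DataFrame([{
                "family": d.family, "n_ns": d.n_nonsynonymous,
                "n_sy": d.n_synonymous,
                "ratio": d.ratio if d.ratio is not None else "NA"}
                for d in nssy]).to_csv(
                out / f"{name}.domain_ns_sy.tsv", sep="\t", index=False)
            sm["effects"] = {
                "n_large_effect_snps": sum(
                    1 for c in calls if c.is_large_effect and c.variant.is_snp),
                "n_large_effect_indels": sum(
                    1 for c in calls if c.is_large_effect and c.variant.is_indel),
                "n_large_effect_genes": len(le_genes),
            }
            nbs_candidates = [g for g in genes
                              if g.is_nbs_lrr and g.gene_id in le_genes]
            clusters = cluster_pav.detect_clusters(
                nbs_candidates, cfg.cluster_max_span_bp, cfg.cluster_min_genes)
            pd.DataFrame([{
                "chrom": cl.chrom, "start": cl.start, "end": cl.end,
                "n_genes": cl.size, "genes": ",".join(cl.gene_ids)}
                for cl in clusters]).to_csv(
                out / f"{name}.nbs_clusters.tsv", sep="\t", index=False)
            sm["nbs"] = {"n_variant_nbs_genes": len(nbs_candidates),
                         "n_clusters": len(clusters),
                         "n_clustered_genes": sum(cl.size for cl in clusters)}
        except Exception as exc:
            raise PipelineError("effects", name, exc) from exc

        if si.bedgraph and unique_intervals:
            try:
                tracks = io_formats.read_bedgraph(si.bedgraph)
                covs = {}
                for chrom, s, e, gid in unique_intervals:
                    gm = GeneModel(gene_id=gid, chrom=chrom, strand="+",
                                   start=s, end=e)
                    covs[gid] = cluster_pav.gene_coverage(
                        tracks, gm, cfg.pav_min_depth)
                calls = cluster_pav.call_presence(covs, cfg.pav_threshold)
                presence[name] = calls
                pd.DataFrame([{
                    "gene_id": c.gene_id, "covered_fraction": c.covered_fraction,
                    "present": int(c.present)} for c in calls]).to_csv(
                    out / f"{name}.pav.tsv", sep="\t", index=False)
                sm["pav"] = {"n_present": sum(c.present for c in calls),
                             "n_absent": sum(not c.present for c in calls)}
            except Exception as exc:
                raise PipelineError("pav", name, exc) from exc

        manifest["samples"][name] = sm
        log.info("sample %s done", name)

    # cross-sample intersections
    if len(site_sets) >= 2:
        manifest["shared"]["sites"] = compare_samples(site_sets)
    for label in ("SNP", "InDel"):
        if len(region_calls[label]) >= 2:
            for kind in ("rich", "poor"):
                shared = density.shared_regions(region_calls[label], kind)
                manifest["shared"][f"{label.lower()}_{kind}_regions"] = len(shared)
                io_formats.write_region_bed(
                    [(c, s, e, kind) for c, s, e in shared],
                    out / f"shared.{label.lower()}_{kind}.bed")
    if len(presence) >= 2:
        counts, shared_genes = cluster_pav.presence_matrix(presence)
        manifest["shared"]["present_genes"] = {
            "per_sample": counts, "all_samples": len(shared_genes)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def compare_samples(
    site_sets: Mapping[str, set[tuple[str, int, str, str]]],
) -> dict:
    """Pairwise and all-way intersection counts of variant-site keys.

    Sites are identified exactly by (chrom, pos, ref, alt).
    """
    names = sorted(site_sets)
    out: dict = {"per_sample": {n: len(site_sets[n]) for n in names}}
    pairs = {}
    for a, b in combinations(names, 2):
        pairs[f"{a}&{b}"] = len(site_sets[a] & site_sets[b])
    out["pairwise"] = pairs
    if names:
        out["all_samples"] = len(set.intersection(*(site_sets[n] for n in names)))
    return out
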