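"""Positional and depth filters applied to raw per-sample variant calls.

Three positional filters remove suspect call clusters — two or more SNPs
within a 5-bp window, SNPs within 5 bp of an InDel, and two or more InDels
within a 10-bp window — and a depth filter retains calls covered between
11x and 100x. Cluster removal is symmetric: every member of a violating
pair is discarded. A k-bp window holds positions p..p+k-1, so two SNPs
conflict iff their positions differ by at most k-1.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

from .model import Variant, VariantClass, check_sorted


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the variant filters.

    ``snp_window_bp``: window size within which >= 2 SNPs are all removed.
    ``snp_indel_dist_bp``: SNPs at most this far from an InDel's affected
    reference span are removed. ``indel_window_bp``: like ``snp_window_bp``
    for InDel anchors. Depth bounds are inclusive; ``sv_min_depth`` is the
    lower bound used when filtering structural-variant calls instead.
    """

    snp_window_bp: int = 5
    snp_indel_dist_bp: int = 5
    indel_window_bp: int = 10
    min_depth: int = 11
    max_depth: int = 100
    sv_min_depth: int = 21

    def __post_init__(self) -> None:
        for name in ("snp_window_bp", "snp_indel_dist_bp", "indel_window_bp",
                     "min_depth", "max_depth", "sv_min_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")


@dataclass
class FilterReport:
    """Survivors plus per-stage removal counts."""

    kept: list[Variant]
    removed_by_stage: dict[str, int] = field(default_factory=dict)
    kept_by_class: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + sum(self.removed_by_stage.values())

    def to_rows(self) -> list[dict]:
        rows = [
            {"stage": stage, "removed": n} for stage, n in self.removed_by_stage.items()
        ]
        rows.append({"stage": "kept_total", "removed": len(self.kept)})
        return rows


def filter_depth(
    variants: Sequence[Variant], cfg: FilterConfig, min_depth: int | None = None
) -> tuple[list[Variant], list[Variant]]:
    """Partition variants into (kept, removed) by inclusive depth bounds."""
    lo = cfg.min_depth if min_depth is None else min_depth
    kept, removed = [], []
    for v in variants:
        (kept if lo <= v.depth <= cfg.max_depth else removed).append(v)
    return kept, removed


def filter_snp_clusters(
    snps: Sequence[Variant], cfg: FilterConfig
) -> tuple[list[Variant], list[Variant]]:
    """Remove every SNP with another SNP within a snp_window_bp-bp span."""
    for v in snps:
        if not v.is_snp:
            raise ValueError(f"non-SNP in SNP cluster filter: {v.chrom}:{v.pos}")
    check_sorted(snps)
    max_gap = cfg.snp_window_bp - 1
    bad = [False] * len(snps)
    for i in range(len(snps) - 1):
        a, b = snps[i], snps[i + 1]
        if a.chrom == b.chrom and b.pos - a.pos <= max_gap:
            bad[i] = bad[i + 1] = True
    kept = [v for v, b in zip(snps, bad) if not b]
    removed = [v for v, b in zip(snps, bad) if b]
    return kept, removed


def filter_snps_near_indels(
    snps: Sequence[Variant],
    indels: Sequence[Variant],
    cfg: FilterConfig,
) -> tuple[list[Variant], list[Variant]]:
    """Remove SNPs within snp_indel_dist_bp of any InDel's affected span.

    The affected span of an InDel is anchor..anchor+len(ref)-1; a SNP inside
    the span is at distance 0. InDels are never removed by this filter.
    """
    check_sorted(snps)
    check_sorted(indels)
    d = cfg.snp_indel_dist_bp
    spans: dict[str, tuple[list[int], list[tuple[int, int]]]] = {}
    for v in indels:
        s, e = v.span
        spans.setdefault(v.chrom, ([], []))
        spans[v.chrom][0].append(s)
        spans[v.chrom][1].append((s, e))
    max_ref = max((len(v.ref) for v in indels), default=1)

    kept, removed = [], []
    for snp in snps:
        hit = False
        if snp.chrom in spans:
            starts, ivals = spans[snp.chrom]
            lo = bisect.bisect_left(starts, snp.pos - d - max_ref)
            hi = bisect.bisect_right(starts, snp.pos + d)
            for s, e in ivals[lo:hi]:
                dist = max(s - snp.pos, snp.pos - e, 0)
                if dist <= d:
                    hit = True
                    break
        (removed if hit else kept).append(snp)
    return kept, removed


def filter_indel_clusters(
    indels: Sequence[Variant], cfg: FilterConfig
) -> tuple[list[Variant], list[Variant]]:
    """Remove every InDel whose anchor shares an indel_window_bp-bp span

    with another InDel's anchor."""
    for v in indels:
        if v.is_snp:
            raise ValueError(f"SNP in InDel cluster filter: {v.chrom}:{v.pos}")
    check_sorted(indels)
    max_gap = cfg.indel_window_bp - 1
    bad = [False] * len(indels)
    for i in range(len(indels) - 1):
        a, b = indels[i], indels[i + 1]
        if a.chrom == b.chrom and b.pos - a.pos <= max_gap:
            bad[i] = bad[i + 1] = True
    kept = [v for v, b in zip(indels, bad) if not b]
    removed = [v for v, b in zip(indels, bad) if b]
    return kept, removed


def apply_all_filters(
    variants: Sequence[Variant],
    cfg: FilterConfig | None = None,
    depth_first: bool = False,
) -> FilterReport:
    """Run the full filter pipeline on a mixed, sorted variant list.

    Default order: the three positional cluster filters act on the raw call
    set (so a depth-failing variant still disqualifies its neighbours),
    then the depth filter on the survivors. ``depth_first=True`` swaps the
    order.
    """
    cfg = cfg or FilterConfig()
    check_sorted(variants)
    pool = list(variants)
    report = FilterReport(kept=[])

    def positional(pool: list[Variant]) -> list[Variant]:
        snps = [v for v in pool if v.is_snp]
        indels = [v for v in pool if v.is_indel]
        snps, rm1 = filter_snp_clusters(snps, cfg)
        report.removed_by_stage["snp_cluster"] = len(rm1)
        snps, rm2 = filter_snps_near_indels(snps, indels, cfg)
        report.removed_by_stage["snp_near_indel"] = len(rm2)
        indels, rm3 = filter_indel_clusters(indels, cfg)
        report.removed_by_stage["indel_cluster"] = len(rm3)
        merged = sorted(snps + indels, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        return merged

    def depth(pool: list[Variant]) -> list[Variant]:
        kept, rm = filter_depth(pool, cfg)
        report.removed_by_stage["depth"] = len(rm)
        return kept

    pool = depth(positional(pool)) if not depth_first else positional(depth(pool))
    report.kept = pool
    report.kept_by_class = {
        c.value: sum(1 for v in pool if v.vclass is c) for c in VariantClass
    }
    return report
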