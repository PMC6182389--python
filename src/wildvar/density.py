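"""Windowed variant density and boxplot-outlier region calling.

The genome is tiled into consecutive 100-kb windows; the variant count per
window is the local density. A five-number summary (min, Q1, median, Q3,
max) is taken over all complete tiles pooled genome-wide, and tiles beyond
the Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR) are called variation-poor /
variation-rich. Trailing partial tiles contribute neither to the summary
nor to calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import Variant


@dataclass(frozen=True)
class Tile:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    count: int
    partial: bool = False

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class WindowDensityTrack:
    window_bp: int
    windows: list[Tile]
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def complete_counts(self) -> np.ndarray:
        return np.array([t.count for t in self.windows if not t.partial], dtype=int)


@dataclass(frozen=True)
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def upper_fence(self) -> float:
        return self.q3 + 1.5 * self.iqr

    @property
    def lower_fence(self) -> float:
        return self.q1 - 1.5 * self.iqr


@dataclass(frozen=True)
class RegionCall:
    chrom: str
    start: int
    end: int
    label: str  # "rich" | "poor"
    count: int

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def name(self) -> str:
        """Render as e.g. Chr01:12.5-12.6 (Mb, one decimal)."""
        return f"{self.chrom}:{(self.start - 1) / 1e6:.1f}-{self.end / 1e6:.1f}"


def window_counts(
    variants: Sequence[Variant],
    chromosome_lengths: Mapping[str, int],
    window_bp: int = 100_000,
) -> WindowDensityTrack:
    """Count variants in consecutive ``window_bp`` tiles per chromosome.

    Tile k spans [(k-1)*W+1 .. k*W]; a variant belongs to the tile holding
    its anchor position. A trailing shorter tile is kept but flagged partial.
    """
    counts: dict[tuple[str, int], int] = {}
    for v in variants:
        if v.chrom not in chromosome_lengths:
            raise ValueError(f"variant on unknown chromosome {v.chrom!r}")
        if v.pos > chromosome_lengths[v.chrom]:
            raise ValueError(
                f"variant at {v.chrom}:{v.pos} beyond chromosome end"
            )
        counts[(v.chrom, (v.pos - 1) // window_bp)] = (
            counts.get((v.chrom, (v.pos - 1) // window_bp), 0) + 1
        )
    tiles: list[Tile] = []
    for chrom in sorted(chromosome_lengths):
        L = chromosome_lengths[chrom]
        n_full, rem = divmod(L, window_bp)
        for k in range(n_full):
            tiles.append(
                Tile(chrom, k * window_bp + 1, (k + 1) * window_bp,
                     counts.get((chrom, k), 0))
            )
        if rem:
            tiles.append(
                Tile(chrom, n_full * window_bp + 1, L,
                     counts.get((chrom, n_full), 0), partial=True)
            )
    return WindowDensityTrack(window_bp, tiles, dict(chromosome_lengths))


def five_number(track: WindowDensityTrack) -> FiveNumberSummary:
    """Five-number summary of complete-tile counts.

    Quartiles use linear interpolation between order statistics, pinned so
    independent implementations agree.
    """
    counts = track.complete_counts()
    if counts.size == 0:
        raise ValueError("no complete tiles: five-number summary undefined")
    qs = np.quantile(counts, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FiveNumberSummary(*map(float, qs))


def call_regions(
    track: WindowDensityTrack,
    fence_multiplier: float = 1.5,
    per_chromosome: bool = False,
) -> list[RegionCall]:
    """Call variation-rich / variation-poor tiles by Tukey fences.

    rich: count > Q3 + m*IQR; poor: count < Q1 - m*IQR, with quartiles
    pooled over all complete tiles genome-wide (or within each chromosome
    when ``per_chromosome`` is set). Partial tiles are never called.
    """
    if per_chromosome:
        calls: list[RegionCall] = []
        for chrom in sorted({t.chrom for t in track.windows}):
            sub = WindowDensityTrack(
                track.window_bp,
                [t for t in track.windows if t.chrom == chrom],
                track.chromosome_lengths,
            )
            calls.extend(call_regions(sub, fence_multiplier))
        return calls
    summary = five_number(track)
    hi = summary.q3 + fence_multiplier * summary.iqr
    lo = summary.q1 - fence_multiplier * summary.iqr
    calls: list[RegionCall] = []
    for t in track.windows:
        if t.partial:
            continue
        if t.count > hi:
            calls.append(RegionCall(t.chrom, t.start, t.end, "rich", t.count))
        elif t.count < lo:
            calls.append(RegionCall(t.chrom, t.start, t.end, "poor", t.count))
    return calls


def shared_regions(
    calls_per_sample: Mapping[str, Sequence[RegionCall]], label: str
) -> list[tuple[str, int, int]]:
    """Tiles carrying ``label`` in every sample (all scanned on one grid)."""
    if not calls_per_sample:
        return []
    seen: dict[tuple[str, int], int] = {}
    sets = []
    for sample, calls in calls_per_sample.items():
        for c in calls:
            key = (c.chrom, c.start)
            if key in seen and seen[key] != c.end:
                raise ValueError(
                    f"mismatched window grids: tile {c.chrom}:{c.start} has "
                    f"ends {seen[key]} and {c.end}"
                )
            seen[key] = c.end
        sets.append({c.interval for c in calls if c.label == label})
    shared = set.intersection(*sets)
    return sorted(shared)
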