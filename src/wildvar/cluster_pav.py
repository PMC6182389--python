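"""Resistance-gene cluster detection and coverage-based presence/absence calls.

A gene cluster is more than three candidate genes (>= 4) spanning less
than 200 kb on one chromosome, found greedily left-to-right over the
candidate list so reported clusters are maximal and disjoint. Presence/
absence variation (PAV) of pan-genome "unique" genes is called from a
per-base depth track: a gene is present when the required fraction of its
bases (default: all of them) is covered by reads.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .model import DepthTrack, GeneModel


@dataclass(frozen=True)
class GeneCluster:
    chrom: str
    gene_ids: tuple[str, ...]
    start: int  # first gene start
    end: int    # last gene end

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class PresenceCall:
    gene_id: str
    covered_fraction: float
    present: bool


def detect_clusters(
    candidate_genes: Sequence[GeneModel],
    max_span_bp: int = 200_000,
    min_genes: int = 4,
) -> list[GeneCluster]:
    """Greedy leftmost-maximal runs of consecutive candidates under the span cap.

    Consecutiveness is within the provided candidate list (sorted by
    chromosome and start); unlisted genes lying between candidates do not
    break a run.
    """
    genes = sorted(candidate_genes, key=lambda g: (g.chrom, g.start))
    clusters: list[GeneCluster] = []
    i = 0
    while i < len(genes):
        j = i
        end = genes[i].end
        while (
            j + 1 < len(genes)
            and genes[j + 1].chrom == genes[i].chrom
            and max(end, genes[j + 1].end) - genes[i].start + 1 < max_span_bp
        ):
            j += 1
            end = max(end, genes[j].end)
        if j - i + 1 >= min_genes:
            run = genes[i : j + 1]
            clusters.append(
                GeneCluster(
                    chrom=genes[i].chrom,
                    gene_ids=tuple(g.gene_id for g in run),
                    start=genes[i].start,
                    end=max(g.end for g in run),
                )
            )
            i = j + 1
        else:
            i += 1
    return clusters


def gene_coverage(
    track: Mapping[str, DepthTrack] | DepthTrack,
    gene: GeneModel,
    min_depth: int = 1,
) -> float:
    """Fraction of gene bases (span, inclusive) with depth >= min_depth.

    Computed exactly as a rational and rounded to 4 decimals.
    """
    if isinstance(track, DepthTrack):
        if track.chrom != gene.chrom:
            raise ValueError(
                f"depth track is for {track.chrom}, gene {gene.gene_id} on {gene.chrom}"
            )
        t = track
    else:
        t = track.get(gene.chrom)
        if t is None:
            raise ValueError(f"no depth track for chromosome {gene.chrom!r}")
    covered = t.bases_at_least(gene.start, gene.end, min_depth)
    frac = Fraction(covered, gene.end - gene.start + 1)
    return round(float(frac), 4)


def call_presence(
    coverages: Mapping[str, float], threshold: float = 1.0
) -> list[PresenceCall]:
    """Presence calls for one sample: present iff covered_fraction >= threshold."""
    return [
        PresenceCall(gene_id, frac, frac >= threshold)
        for gene_id, frac in sorted(coverages.items())
    ]


def presence_matrix(
    calls_per_sample: Mapping[str, Sequence[PresenceCall]],
) -> tuple[dict[str, int], set[str]]:
    """Per-sample present-gene counts and the genes present in every sample."""
    counts = {
        s: sum(c.present for c in calls) for s, calls in calls_per_sample.items()
    }
    gene_sets = [
        {c.gene_id for c in calls if c.present}
        for calls in calls_per_sample.values()
    ]
    shared = set.intersection(*gene_sets) if gene_sets else set()
    return counts, shared
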