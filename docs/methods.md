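# Methods

This note records the models, conventions and deliberate choices behind
`wildvar`, at the level of detail a maintainer or reviewer needs to judge
what a passing test does and does not establish.

## Coordinates and the data model

All in-memory coordinates are 1-based inclusive (the VCF/GFF convention);
BED and bedGraph conversion (0-based half-open) happens only at the I/O
boundary, and the two conversions compose to identity. An InDel keeps the
anchor position of its VCF record; no left-normalisation is attempted, so
two representations of the same InDel are distinct sites. A variant's
*affected reference span* is `pos .. pos + len(ref) − 1`: the single base
for SNPs and insertions (insertions disturb only their anchor base on the
reference), the anchor plus deleted bases for deletions. Multi-allelic
records are split into one variant per alternate allele; a genotype with
two copies of that allele is homozygous-alt, any other called genotype is
heterozygous, and fully uncalled genotypes are skipped. One representative
transcript per gene (longest total CDS) carries the coding annotation.

## Filters

The three positional filters and the depth filter:

| filter | rule | default |
|---|---|---|
| SNP cluster | ≥ 2 SNPs inside a w-bp span, i.e. Δpos ≤ w−1 | w = 5 |
| SNP near InDel | distance from SNP to an InDel's affected span ≤ d | d = 5 |
| InDel cluster | ≥ 2 InDel anchors inside a w-bp span | w = 10 |
| depth | keep min ≤ DP ≤ max (inclusive) | 11–100× |

A *w-bp window* holds positions `p..p+w−1`, so the strictest reading is
`|Δpos| ≤ w−1`; the thresholds are configurable. Cluster removal is
symmetric — every member of a violating pair goes, since the source
protocol states no survivor rule. Distance to an InDel is measured to its
whole affected span, not just its anchor, because the entire disturbed
region is suspect; this too is configurable. Positional filters run before
the depth filter by default so that a depth-failing variant still
disqualifies its neighbours (`depth_first=True` swaps the order). Each
filter is idempotent and partitions its input exactly; equivalence with
quadratic all-pairs oracles is asserted on random instances in the tests.

## Summary statistics

Transitions are the purine↔purine and pyrimidine↔pyrimidine pairs
({A,G}, {C,T}); the other eight ordered pairs are transversions. Zygosity
statistics are computed over SNPs (SNP zygosity standing in for genome
zygosity). All ratios and percentages are exact rationals rounded half-up
at two decimals only at the reporting boundary, so recomputing a printed
ratio from its printed counts reproduces it bit for bit. When the
published table's own ratio disagrees with the ratio of its printed counts
(one accession's Ti/Tv is printed 2.49 where the counts give 2.40), this
implementation reports from counts and leaves the discrepancy documented
rather than resolved. Region assignment uses strand-aware 2-kb flanks with
precedence GENIC > UPSTREAM > DOWNSTREAM > INTERGENIC; genic hits win over
flanks, and upstream wins when a position is simultaneously in one gene's
upstream and another's downstream flank (common annotator precedence; both
the flank size and the precedence are configurable).

## Density scan and region calling

Tile k of width W spans `[(k−1)W+1 .. kW]`; the default W = 100,000.
Trailing partial tiles are recorded but excluded from the summary and
never called, so short chromosome tails cannot masquerade as variant-poor
regions. Quartiles use linear interpolation between order statistics —
pinned explicitly so an independent implementation (e.g. R's default
`quantile` type 7) agrees. Outliers use Tukey fences at 1.5 × IQR; the
multiplier is a config knob. Fences are computed genome-wide over all
complete tiles pooled across chromosomes, because the emulated study
reports genome-level rich/poor totals per accession; a per-chromosome mode
would simply re-run the caller per chromosome track. Note the fence is an
empirical-quartile rule: on a homogeneous Poisson background a tile beyond
the fence occurs by chance at roughly the percent level per tile, so
isolated background calls are expected behaviour, not bugs; the recovery
tests therefore plant signals (10× / 0.05× background) far outside the
fences, where sensitivity and specificity are exactly 1.

## Effect classification

Coding SNPs: the affected codon is rebuilt from the spliced CDS
(segments concatenated in translation order, reverse-complemented on the
minus strand), mutated, and translated with the standard nuclear code.
Categories: new stop → STOP_GAINED; lost terminal stop → STOP_LOST
(a stop retained by a third-position change is SYNONYMOUS); first-codon
changes lose the ATG start → START_LOST, unless the mutated codon is an
alternative start (CTG/TTG) → NON_SYNONYMOUS_START — the semantics of
that category drifted between annotator versions, and this reading is a
declared choice, not an assertion about any particular tool; otherwise
SYNONYMOUS / NON_SYNONYMOUS by amino-acid identity.

Coding InDels: FRAME_SHIFT iff `|len(alt) − len(ref)| mod 3 ≠ 0`, else
CODON_INDEL (in-frame, not large-effect).

Splice geometry (configurable): donor = first 2 intronic bases after an
exon in transcript orientation, acceptor = last 2 before the next exon,
splice region = exonic bases 1–3 and intronic bases 3–8 from an internal
junction. Severity is splice > frameshift > codon classes: an exonic SNP
within 3 bp of a junction is reported as SPLICE_SITE_REGION rather than
its codon effect, and an InDel overlapping a donor window takes the donor
class regardless of frame. Introns here are the gaps between CDS segments;
genic positions outside the CDS envelope are UTR. Non-genic positions fall
through to the flank/intergenic assignment.

The large-effect predicate is exactly the eight disruptive categories
(start/stop changes, the three splice classes, frameshift). Domain-level
Ns/Sy ratios count NON_SYNONYMOUS and SYNONYMOUS coding SNPs whose
amino-acid position `⌈cds_offset/3⌉` lies in a domain interval of that
family; a family with zero synonymous hits reports an undefined ratio
rather than raising.

## Clusters and presence/absence

A gene cluster is a maximal run of ≥ 4 consecutive candidate genes (the
literal reading of "more than three") whose first-start→last-end span is
strictly under 200 kb. Runs are found greedily left to right, so reported
clusters are disjoint and each gene belongs to at most one;
consecutiveness is within the supplied candidate list (typically the
NBS-LRR genes carrying large-effect variants), so unlisted genes between
candidates do not break a run. Presence/absence of a pan-genome unique
gene is the fraction of its bases at depth ≥ 1 (exact rational, 4
decimals); *present* means 100 % by default — "fully covered" read
literally — with the threshold exposed because strict 100 % is brittle
against sequencing noise on real data.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested.

- **Genome**: i.i.d. bases at 43.5 % GC (rice-like), per-chromosome RNG
  streams. Defaults elsewhere assume a scaled-down genome (two 2-Mb
  chromosomes standing in for twelve ~30-Mb ones; 5-Mb chromosomes for the
  density and parameter-recovery runs) — sizes chosen so every planted
  structure has room while full runs stay in seconds.
- **Genes**: non-overlapping models with 1–3 exons, 100–300 codons, an ATG
  start, a stop, and no internal stops, patched into the genome so
  sequence-level classification is self-consistent; NBS-LRR genes carry
  NB-ARC and LRR_1 domain intervals; clusters are planted as n genes
  inside a stated span.
- **SNPs**: transitions with probability titv/(1+titv) so the expected
  Ti/Tv equals the dial (default 2.53); zygosity Bernoulli(het fraction,
  default 0.1135) — both defaults are one accession's reported values.
- **InDel lengths**: geometric on 1..30 with p = 0.235, chosen so
  P(length ≤ 9) ≈ 0.91, matching the reported 90–91 % of InDels at 1–9 bp.
  A geometric law cannot simultaneously reproduce the reported ~46 %
  single-nucleotide fraction (that would need p ≈ 0.46, pushing
  P(≤9) ≈ 0.996); the 1–9 bp and coding-triple marginals are the two this
  generator reproduces, and the single-nucleotide fraction is
  correspondingly low (~23 %). Deletions slightly outnumber insertions
  (51.9 %).
- **Coding InDels**: a configured fraction of InDels (default 5.8 %) is
  placed inside CDS segments with length 3 at exactly the configured
  probability (default 0.4274; the non-spike draw is conditioned away from
  3). Background InDels are rejection-sampled away from CDS, so the coding
  InDel fraction and the coding triple fraction are direct dials rather
  than mixtures — the price is that the generator has no "incidental"
  coding InDels.
- **Placement**: positions are uniform within 100-kb tiles whose sampling
  weight is 1 except planted rich/poor tiles (defaults 10× / 0.05×);
  duplicate positions are rejected. Filter-triggering clusters arise only
  by chance (or are planted explicitly by tests), not by design.
- **Depth**: gamma-Poisson with mean 45× and shape 4 — overdispersed like
  real coverage, so the 11–100× filter has tails to act on.
- **Depth tracks / PAV**: uniform base depth with planted absent genes
  zeroed across their whole span.
- **Determinism**: every artifact draws from its own stream derived from
  the master seed and a fixed label (CRC-32 of the label into a seed
  sequence), so adding an output never perturbs existing ones; identical
  seeds give byte-identical files.

What passing recovery tests show: the pipeline's arithmetic, geometry and
set logic are correct under these idealised conditions. What they do not
show: robustness to alignment artefacts, reference errors, repeat-mediated
mis-mapping, InDel representation drift between callers, incomplete gene
models, or coverage biases — none of which the generator emulates.

## Numerical and degenerate-input conventions

Division guards return an undefined marker (None) rather than raising:
Ti/Tv with zero transversions, het % with zero SNPs, Ns/Sy with zero
synonymous hits. Quantiles over an empty complete-tile set raise, since a
five-number summary of nothing is meaningless. Constant tile counts give
IQR 0 and hence no region calls. Empty inputs flow through every stage to
all-zero reports. Reference-mismatch between a VCF allele and the FASTA
raises naming the offending position.

## Problem sizes used in checks

The self-check script (`scripts/acceptance.py`) uses 20 random
1,000-variant instances for the filter oracles, a 2 × 5 Mb genome with
50,000 SNPs for region recovery, 500 random coding variants for the
effect oracle, and 100,000 variants (80,000 SNPs + 20,000 InDels over 60
genes) for parameter recovery — sizes at which binomial sampling error
puts the recovered Ti/Tv, het fraction and coding-triple fraction within
three standard errors of their dials, while a full run completes in
seconds.
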