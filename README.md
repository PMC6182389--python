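# wildvar

Downstream variant analysis for deep re-sequencing of wild rice (*Oryza
rufipogon*) accessions against the Nipponbare reference — the post-calling
half of a resequencing study, reimplemented as a tested, reusable Python
library. Upstream read alignment and raw variant calling (BWA/GATK) are out
of scope; `wildvar` starts from per-sample VCFs, gene models and depth
tracks and produces the population-genetic summaries, hotspot regions,
effect annotations and resistance-gene analyses such a study reports.

## What it computes

- **Filtering** — the positional cluster rules (two or more SNPs in a 5-bp
  window; SNPs within 5 bp of an InDel; two or more InDels in a 10-bp
  window; every member of a violating pair is removed) followed by an
  11–100× read-depth window.
- **Summary statistics** — transition/transversion ratio
  Ti/Tv = n(A↔G, C↔T) / n(other pairs), heterozygosity percentage
  100·Het/(Het+Hom), insertion/deletion counts genome-wide and in coding
  sequence, signed InDel length spectra (single-nucleotide, 1–9 bp and
  triple-nucleotide fractions), and assignment of each variant to
  GENIC / UPSTREAM (2 kb, strand-aware) / DOWNSTREAM (2 kb) / INTERGENIC.
- **Density scan** — variant counts in consecutive 100-kb tiles; a
  five-number summary (min, Q1, median, Q3, max) over all complete tiles;
  tiles with count > Q3 + 1.5·IQR are variation-rich, count < Q1 − 1.5·IQR
  variation-poor; shared regions are the tile-wise intersection across
  accessions.
- **Effect annotation** — strand-aware codon mutation and translation for
  coding SNPs (synonymous / non-synonymous / stop gained / stop lost /
  start lost), mod-3 frameshift logic for coding InDels, annotator-style
  splice-site geometry (donor/acceptor = first/last 2 intronic bases;
  splice region = exonic 1–3 and intronic 3–8 bp from a junction). The
  eight disruptive categories form the **large-effect** predicate, and
  non-synonymous/synonymous (Ns/Sy) ratios are tallied per Pfam-style
  protein domain (NB-ARC, LRR_1, …).
- **NBS-LRR clusters and PAV** — gene clusters (> 3 candidate genes in
  < 200 kb, greedy leftmost-maximal), and presence/absence variation of
  pan-genome unique genes called from per-base coverage (present ⇔ 100 %
  of bases covered by default).
- **Synthetic data** — a generator that emulates all of the above inputs
  with recorded truth (configured Ti/Tv, het fraction, InDel length law,
  planted rich/poor tiles, planted clusters, planted absent genes), so the
  whole pipeline is testable without any downloads.

## Worked example

```bash
cd some/work/dir
python /path/to/examples/01_simulate_study.py   # writes sim_out/
python /path/to/examples/02_filter_variants.py
python /path/to/examples/03_summary_statistics.py
```

prints (three simulated accessions; Huaye4 is configured at Ti/Tv 2.53,
het 11.35 %, 5.8 % of InDels coding):

```
input variants : 21500
removed by snp_cluster   : 1682
removed by snp_near_indel: 439
removed by indel_cluster : 140
removed by depth         : 961
kept           : 18278  {'SNP': 15066, 'INS': 1543, 'DEL': 1669}

SNPs 18000: Ti 12937 / Tv 5063 -> Ti/Tv 2.56
zygosity: 2010 het / 15990 hom -> het 11.17%
InDels 3500 (1673 ins / 1827 del), 203 in CDS (5.8%)
1-9 bp: 90.77%   triple-nt in CDS: 42.36% vs genome-wide 15.97%
```

The observed Ti/Tv (2.56) and heterozygosity (11.17 %) sit within sampling
error of the configured values; the coding InDels show the planted
triple-nucleotide excess over the genome-wide background. The remaining
examples (`04`–`06`) call the planted variation-rich region in every
accession, annotate large-effect variants with per-domain Ns/Sy ratios,
and recover the planted NBS-LRR cluster and absent-gene sets exactly.

The same operations are available from a thin CLI
(`wildvar simulate|filter|stats|density|effects|clusters|pav|run|compare`),
with `wildvar run --config pipeline.yaml` orchestrating everything into
per-sample TSV/BED/VCF artifacts plus a JSON manifest.

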