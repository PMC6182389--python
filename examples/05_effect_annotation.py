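"""Classify variant effects on gene models and pull out large-effect genes.

A coding SNP's codon is mutated and translated (strand-aware); InDels are
frameshift when their length change is not a multiple of 3. Start/stop
codon changes, splice-site hits and frameshifts are "large-effect" —
variants likely to break the encoded product. For NBS-LRR genes the
non-synonymous/synonymous ratio is also reported per protein domain.
"""
from collections import Counter

from wildvar import (
    FastaGenome,
    annotate_variants,
    apply_all_filters,
    large_effect_genes,
    ns_sy_by_domain,
)
from wildvar.io_formats import read_gff, read_vcf

variants = apply_all_filters(read_vcf("sim_out/Huaye4.vcf", "Huaye4")).kept
genes = read_gff("sim_out/genes.gff3", "sim_out/domains.tsv")
genome = FastaGenome("sim_out/ref.fa")

calls = annotate_variants(variants, genes, genome)
by_cat = Counter(c.category.value for c in calls)
print("top categories:", by_cat.most_common(6))

le_set, le_counts = large_effect_genes(calls)
n_le = sum(c.is_large_effect for c in calls)
print(f"{n_le} large-effect calls across {len(le_set)} genes")
for gid in sorted(le_set)[:5]:
    print(f"  {gid}: {le_counts[gid]}")

for d in ns_sy_by_domain(calls, genes):
    print(f"domain {d.family}: Ns {d.n_nonsynonymous} / Sy {d.n_synonymous}"
          f" -> ratio {d.ratio}")
# Ratios above 1 mean the domain accumulates more amino-acid-changing
# substitutions than silent ones.
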