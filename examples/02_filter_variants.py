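"""Apply the positional and depth filters to one accession's raw calls.

Removes SNP pairs sharing a 5-bp window, SNPs within 5 bp of an InDel,
InDel pairs sharing a 10-bp window, and calls covered below 11x or above
100x. Run examples/01_simulate_study.py first.
"""
from wildvar import FilterConfig, apply_all_filters
from wildvar.io_formats import read_vcf

variants = read_vcf("sim_out/Huaye4.vcf", "Huaye4")
report = apply_all_filters(variants, FilterConfig())

print(f"input variants : {report.n_input}")
for stage, n in report.removed_by_stage.items():
    print(f"removed by {stage:<14}: {n}")
print(f"kept           : {len(report.kept)}  {report.kept_by_class}")
# The cluster filters fire only on variants that landed close together by
# chance; the depth filter removes the Poisson tails outside 11-100x.
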