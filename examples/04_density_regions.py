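"""Scan 100-kb windows and call variation-rich/-poor regions per accession.

Window counts are summarised by a five-number boxplot over complete tiles;
tiles beyond the 1.5*IQR Tukey fences are the rich/poor calls. The planted
rich tile (Chr01, 1.2-1.3 Mb in the default simulation) should be called
in every sample and therefore appear in the shared intersection.
"""
from wildvar import call_regions, five_number, shared_regions, window_counts
from wildvar.io_formats import read_lengths, read_vcf

lengths = read_lengths("sim_out/lengths.tsv")
calls = {}
for name in ("S24", "Huaye3", "Huaye4"):
    snps = [v for v in read_vcf(f"sim_out/{name}.vcf", name) if v.is_snp]
    track = window_counts(snps, lengths, window_bp=100_000)
    s = five_number(track)
    calls[name] = call_regions(track)
    rich = [c for c in calls[name] if c.label == "rich"]
    print(f"{name}: median {s.median:.0f} SNPs/100kb, "
          f"fences [{s.lower_fence:.1f}, {s.upper_fence:.1f}], "
          f"rich: {[c.name for c in rich]}")

shared = shared_regions(calls, "rich")
print("rich regions shared by all samples:",
      [f"{c}:{(s - 1) / 1e6:.1f}-{e / 1e6:.1f}" for c, s, e in shared])
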