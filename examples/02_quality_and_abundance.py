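"""Tier MAG quality and compute relative abundance from read counts.

Uses three worked completeness/contamination pairs and a small count table;
prints the tier per bin and the fraction of sample reads per genome.
"""

from syntroscreen import CountRecord, quality_tier, relative_abundance
from syntroscreen.metrics import unbinned_fraction

bins = [("R1.8-like", 94.06, 0.96),
        ("R1.25-like", 97.2, 0.5),
        ("low-methanogen", 22.43, 5.0),
        ("gap-case", 80.0, 5.0)]
print("bin\tcompleteness\tcontamination\ttier")
for name, completeness, contamination in bins:
    print(f"{name}\t{completeness}\t{contamination}\t"
          f"{quality_tier(completeness, contamination)}")

total = 1_000_000
counts = [CountRecord("g1", "S1", 227_000, total),
          CountRecord("g2", "S1", 58_000, total),
          CountRecord("g3", "S1", 7_500, total)]
abundances = relative_abundance(counts)
print("\ngenome\tfraction\tpercent")
for gid, rec in sorted(abundances.items()):
    print(f"{gid}\t{rec.fraction:.4f}\t{rec.percent:.2f}")
print(f"unbinned remainder: {unbinned_fraction(abundances, 'S1'):.4f}")
print("\nTier 'high' needs completeness >= 90% and contamination <= 10%;")
print("abundance is mapped reads over the sample's total reads.")
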