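"""SV density in 500 kb bins and kernel-density hotspot calling.

An artificial cluster of 60 extra deletions in one 100 kb window is implanted
on top of a uniform background; the Gaussian-KDE scan (bandwidth 200 kb)
compares the observed density against 200 uniform re-placements and reports
intervals exceeding the family-wise null threshold.
"""

import numpy as np

from svpopscan import HotspotParams, SVRecord, SVType, binned_density, kde_hotspots

rng = np.random.default_rng(3)
sizes = {"chr1": 10_000_000}

svs = [
    SVRecord(f"bg{i}", "chr1", int(s), int(s) + 120, SVType.DEL, 120)
    for i, s in enumerate(rng.integers(0, 9_990_000, size=400))
]
svs += [
    SVRecord(f"hot{i}", "chr1", int(s), int(s) + 120, SVType.DEL, 120)
    for i, s in enumerate(rng.integers(6_200_000, 6_300_000, size=60))
]

density = binned_density(svs, sizes)
top_bins = density.nlargest(3, "DEL")[["chrom", "bin_start", "DEL"]]
print("densest 500 kb bins (deletions):")
print(top_bins.to_string(index=False))

calls = kde_hotspots(svs, sizes, HotspotParams(num_trial=200), seed=1)
print(f"\nhotspots called: {len(calls)}")
for c in calls:
    print(f"  {c.chrom}:{c.start:,}-{c.end:,}  peak={c.peak_density:.3g}/bp  "
          f"p={c.empirical_p:.4f}")
# The implanted 6.2-6.3 Mb window is the only region exceeding the null's
# maximum-density threshold; empirical p is bounded below by 1/(trials+1).
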