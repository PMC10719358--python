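# svpopscan

Population-scale structural-variant (SV) analysis for two-population cohorts:
multi-caller consensus calling, nonredundant cross-sample merging, cohort
statistics, a Weir–Cockerham F_ST selection scan with population-specificity
filters, kernel-density SV hotspot detection, LD-based SV-to-phenotype
bridging, and regulatory-element overlap.

The package targets studies that genotype SVs (deletions, insertions,
duplications, inversions ≥ 50 bp) from long-read sequencing in two related
populations and ask which SVs are candidates for differential selection —
for example, comparing a high-altitude population against a lowland one.
Because real cohorts of this kind are usually access-restricted, the package
ships a first-class synthetic cohort generator (Balding–Nichols
differentiation, per-caller noise models, LD-tagged SNPs, annotation tracks)
with a machine-readable truth table, so every stage of the pipeline is
verifiable end to end.

## Methods at a glance

* **Raw-call filter** — keep calls with read-support AF > 0.3, depth < 2× the
  sample mean, and 50 bp ≤ length ≤ 50 kb.
* **Matching rule** — two SVs match when breakpoints differ by < 1 kb; spanned
  types additionally need ≥ 40% reciprocal overlap, insertions a length
  difference < 2× the shorter insert. Within-sample consensus keeps calls
  supported by ≥ 2 callers or flagged high-quality by the top-priority caller
  (cuteSV > sniffles > nanovar); cohort merging takes the transitive closure
  of the match relation (single linkage) per (chromosome, type).
* **F_ST** — Weir & Cockerham (1984) variance components per site
  (a, b, c with θ̂ = a/(a+b+c)); the cohort statistic is the weighted estimate
  Σa/Σ(a+b+c). A variant is population-specific when its carrier frequency is
  ≥ 0.2, at least twice the other population's, and θ̂ > 0.1.
* **Hotspots** — Gaussian-kernel density of SV midpoints (bandwidth 200 kb)
  against a uniform permutation null (1000 trials by default), thresholded at
  the 95th percentile of per-trial maxima (family-wise control).
* **LD bridge** — r² = squared Pearson correlation of genotype dosages
  (pairwise-complete) for SNPs within 1 Mb of an SV breakpoint; pairs with
  r² ≥ 0.8 transfer GWAS-catalog phenotypes to the SV.
* **Regulatory overlap** — candidate SVs padded ±100 bp and intersected
  (half-open) with enhancer / silencer / promoter / TAD-boundary tracks.

## Worked example

```python
from svpopscan import (
    SimParams, simulate_cohort_truth, simulate_caller_calls,
    within_sample_consensus, merge_cohort, carrier_frequency,
    weir_cockerham_fst, population_specific_svs,
)

params = SimParams(n_pop_a=30, n_pop_b=30, m_svs=300, n_selected=10, seed=11)
truth, matrix, cohort = simulate_cohort_truth(params)
calls = simulate_caller_calls(truth, matrix, params)
consensus = {s: within_sample_consensus(calls[s]) for s in cohort.samples}
clusters, merged = merge_cohort(consensus, cohort)
fst = weir_cockerham_fst(merged, cohort)
print(len(clusters), round(fst.weighted, 3))
```

prints `236 0.108`: the 60-sample cohort's consensus calls collapse to
236 nonredundant SVs (the truth set has 234 carried SVs — per-caller false
calls are removed by the ≥2-caller rule, jittered duplicates merge), and the
weighted F_ST ≈ 0.11 tracks the simulation's differentiation parameter 0.1,
slightly inflated by the ten implanted population-specific loci.

The `examples/` directory holds one short script per capability
(simulate+merge, F_ST scan, hotspots, LD bridge, regulatory overlap); each
prints the numbers it computes and what they mean. A thin CLI covers the
shell-facing workflows:

```bash
svpopscan simulate --seed 7 --out simdir/     # synthetic cohort + VCFs + tracks
svpopscan run --seed 7 --out rundir/          # full pipeline, report.json
svpopscan compare --query a.vcf --ref b.vcf   # shared/novel call-set comparison
```

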