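# Methods

This note documents the models, rules and numerical choices behind
`svpopscan`, what the synthetic cohort generator does and does not emulate,
and the design decisions taken where more than one reading was defensible.

## Coordinates and records

All internal coordinates are 0-based half-open; conversion happens only at
the VCF boundary (BED is already half-open). An insertion is a point
(`end == start`) with its insert length carried separately, since no END
convention exists for insertions; deletions, duplications and inversions
satisfy `length == end − start`. Multi-allelic records are treated as
biallelic throughout. Partially genotyped calls (`./1`) are treated as
missing. Missing genotypes count as non-carriers in presence-based statistics
(carrier frequency, PCA, clustering, saturation) and are excluded
pairwise in dosage-based statistics (HWE, F_ST, LD r²) — the behaviour of
the standard VCF tooling for these analyses.

One writer detail: the VCF writer emits `SVLEN` only for insertions. Recent
htslib recomputes `END = POS + |SVLEN|` for symbolic ALT alleles (VCF 4.4
padding-base semantics), which would silently shift the span of
deletion/duplication/inversion records carrying both keys; `END` is
authoritative for spanned types, `SVLEN` for insertions, and round-trips are
exact.

## Matching and merging

Two SVs match when (i) they are the same type, (ii) their breakpoints are
within `max_dist` (default 1 kb; both breakpoints for spanned types, the
insertion point for INS), (iii) spanned types reciprocally overlap by at
least `min_overlap` (default 40%) of *each* span, and (iv) insertions differ
in length by less than `ins_len_factor` (default 2) times the shorter
insert. Choices where one convention had to be fixed:

* "Distance of the variant coordinates" is read as the maximum over both
  breakpoints for spanned types (configurable to start-only).
* The overlap requirement is reciprocal (configurable to either-span).
* The insertion-length rule is read literally as |L₁−L₂| < 2·min(L₁,L₂);
  this is permissive, and a stricter length-ratio mode
  (`ins_rule="ratio"`: min/max ≥ 1/factor) is available.
* The distance and overlap rules are applied conjunctively at every size.

Cohort merging is single-linkage (transitive closure of the match relation),
computed with a sorted sweep per (chromosome, type): records are sorted
canonically, pairs whose start difference is below `max_dist` are tested and
unioned. Because every matching pair satisfies the start-window bound, the
sweep is exactly equivalent to the all-pairs transitive closure — the test
suite asserts this against a brute-force oracle. Single linkage was chosen
over greedy alternatives precisely so this equivalence is exact, making the
partition independent of input order (also asserted, over random
permutations at ~5,000 calls).

A cluster's representative is the member with the most caller support, ties
broken by caller priority (cuteSV > sniffles > nanovar), then smallest
start. When members of a cluster disagree on one sample's genotype, the
highest-priority caller wins and remaining ties go to the more-alternate
genotype. Both rules are deterministic; neither is dictated by the
underlying method description, which leaves representative choice open.

Merging the merged representatives is a fixed point: representatives of
distinct clusters cannot match (a match would have joined their clusters),
so re-merging changes nothing.

## Cohort statistics

Two frequency notions coexist deliberately. *Carrier frequency* — the
fraction of samples carrying ≥ 1 copy — drives the frequency spectrum
(levels (0, 0.1], (0.1, 0.4], (0.4, 1), {1}, plus singletons) and the
population-specificity filter. *Allele frequency* from diploid dosages
drives HWE and F_ST.

**HWE** uses the χ² test with df = 1 and no continuity correction
(expected counts p²n, 2pqn, q²n over non-missing samples), with Bonferroni
correction across tested variants at α = 0.05. Type-I error at the nominal
0.05 level calibrates to [0.03, 0.07] in simulation (n = 200, p = 0.3).

**F_ST** is the Weir & Cockerham (1984) two-population method-of-moments
estimator. Per site, with r = 2 populations of sizes n₁, n₂, allele
frequencies p̂ᵢ and observed heterozygote frequencies hᵢ:

    n̄ = (n₁+n₂)/r,  n_c = (n₁+n₂ − (n₁²+n₂²)/(n₁+n₂))/(r−1)
    p̄ = Σnᵢp̂ᵢ/Σnᵢ,  s² = Σnᵢ(p̂ᵢ−p̄)²/((r−1)n̄),  h̄ = Σnᵢhᵢ/Σnᵢ
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2,   θ̂ = a/(a+b+c)

The cohort-wide statistic is the weighted ratio Σa/Σ(a+b+c) over sites with
defined θ̂ (monomorphic and under-covered sites are excluded and counted).
A fully fixed difference with 10 diploids per population gives a = 0.5,
b = c = 0, θ̂ = 1 exactly. Under Balding–Nichols simulation the weighted
estimate recovers the generating F to within 0.02 on average
(2,000 loci, 100 per population, F ∈ {0.05, 0.1, 0.2}).

The verbal description "(total heterozygosity − mean subpopulation
heterozygosity)/total heterozygosity" names a different quantity
(a Wright/Hudson-style 1 − H_S/H_T) that does not coincide numerically with
the Weir–Cockerham estimator; since the named estimator is Weir–Cockerham,
that is the default, and `hudson_fst` provides the other form.

**Selection filter.** A variant is A-specific iff carrier frequency
freq_A ≥ 0.2, freq_A ≥ 2·freq_B, and θ̂ > 0.1 (strict, matching "greater
than"); B-specific symmetrically; at most one direction per variant.
freq_B = 0 with freq_A ≥ 0.2 satisfies the ratio criterion (ratio with a
zero denominator is treated as satisfied). "Population frequency" here is
carrier frequency, the same definition the spectrum uses. Upstream/downstream
gene annotation is strand-agnostic genomic left/right of the SV span.

**Power-law fit** of the frequency spectrum is a Clauset-style continuous
MLE: for each candidate lower cutoff x_min (at most 100, quantile-spaced),
α̂ = 1 + n/Σln(xᵢ/x_min) over the tail, x_min chosen to minimize the KS
distance between the empirical and fitted tail CDFs; the goodness-of-fit
p-value is a semi-parametric bootstrap (body resampled empirically, tail
from the fitted law, each replicate refit). The implementation is
hand-written because no power-law fitting package is available in the
Python environment; it recovers α = 2.5 within ±0.2 in ≥ 80% of seeds at
n = 5,000 and its GoF p is approximately uniform under the null.

**PCA** decomposes the column-centered presence matrix by SVD, with signs
fixed by making each component's largest-magnitude loading positive.
**Hierarchical clustering** uses Manhattan distance on presence rows with
average (default) or complete linkage, serialized as Newick.

## Hotspots and enrichment

SV "position" for density purposes is the span midpoint (insertion point
for INS). Binned density uses 500 kb bins with the last partial bin kept.
The hotspot scan evaluates a Gaussian kernel sum (events per bp, bandwidth
200 kb) on a 10 kb grid per chromosome, and compares it against `num_trial`
uniform re-placements of the same number of midpoints on the same
chromosome. The threshold is the (1−α) quantile of the per-trial *maximum*
density — family-wise control per chromosome — and each maximal
above-threshold grid run becomes one call with empirical p
(1 + #trials with max ≥ observed peak)/(num_trial + 1). A pointwise-quantile
mode exists. The referenced hotspot procedure does not describe its exact
null; the family-wise max-null was chosen because it gives an interpretable
per-chromosome false-positive guarantee (measured ≈ 5–7% at α = 0.05 with
200 trials; the finite null sample makes the threshold itself slightly
noisy).

Track enrichment is observed overlap fraction over the mean fraction under
random re-placement preserving each SV's chromosome and length, with a
two-sided permutation p. The genome-fraction shortcut (track bp / genome bp)
is reported alongside, since "expected" is sometimes quoted that way.

## LD and the phenotype bridge

r² is the squared Pearson correlation of unphased dosages over
pairwise-complete samples — composite LD, the behaviour of PLINK's `--r2`
on unphased genotypes; haplotype-EM r² is out of scope. Pairs need ≥ 3
complete samples and non-constant vectors (constant → undefined, flagged,
never 0). The scan tests SNPs within 1 Mb of the nearer SV breakpoint and
reports pairs with r² ≥ 0.2; pairs with r² ≥ 0.8 transfer each catalog
phenotype of the SNP to the SV, deduplicated per (SV, SNP, phenotype).

## The synthetic cohort generator

The generator emulates the *structure* of a two-population long-read SV
cohort, not its sequence content:

* Sample sizes default to 119 + 201 (the cohort proportions of the study
  design it emulates); the default SV count is 2,000 — enough for stable
  F_ST estimation while keeping the full pipeline fast on one CPU.
* Ancestral frequencies are Beta(0.5, 3) (low-frequency-heavy, as real SV
  spectra are); per-population frequencies follow Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.1 by default, so the
  Weir–Cockerham estimand is known by construction. Genotypes are two
  independent haploid draws (HWE within population, no inbreeding).
* 20 selected loci are overridden to target carrier frequencies 0.6 vs 0.05
  (alternating direction), comfortably inside the specificity criteria.
* SV lengths are a bimodal lognormal mixture (~300 bp and ~6 kb modes,
  echoing Alu/LINE peaks); types are drawn at DEL 52% / INS 42% / DUP 5% /
  INV 1%.
* Caller models: sensitivity 0.92/0.90/0.85 (cuteSV/sniffles/nanovar),
  breakpoint jitter sd 30 bp, length jitter sd 10 bp, false calls
  Poisson(0.2/Mb) placed uniformly and independently per caller (so the
  ≥2-caller rule removes them; a shared-false-call mode exercises the
  high-quality-flag pathway), cuteSV HQ probability 0.3. Read-support AF
  and depth are drawn so true calls pass the raw filter and roughly half
  of false calls fail it.
* Tag SNPs: each selected SV gets one SNP whose haplotype copies the SV
  haplotype with probability λ and is otherwise an independent draw at the
  same population frequency — allele frequencies are preserved exactly.
  Because the SNP inherits the SV's between-population contrast, the pooled
  dosage correlation is (λW + 2B)/(W + 2B), with W the mean within-population
  haplotype variance and B the between-population variance; λ is solved per
  locus so the pooled r² equals the target (default 0.95 — far enough above
  the 0.8 strong-LD cutoff that implanted bridges survive the genotype
  noise introduced by imperfect caller sensitivity). Targets below the
  structural floor (2B/(W+2B))² raise an error.
* Annotations: repeats tile the genome at a requested coverage fraction
  (default 50%), genes are non-overlapping labelled intervals, one enhancer
  is placed 50 bp beyond each selected SV's right breakpoint (inside the
  ±100 bp pad), TAD boundaries are regular 10 kb intervals, and the
  GWAS-catalog table links every tag SNP to a phenotype string plus decoy
  rows.

Every generator is a pure function of its parameter block including the
seed; per-stage seeds derive from the global seed through `SeedSequence`.

What the generator does **not** emulate: sequence-resolved breakpoints and
homology, realistic LD decay (only the tag SNPs are linked), segmental
structure of real genomes (hotspots arise only when implanted), admixture
or demographic history, genotype error biased by SV size or repeat context.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the stated generative model, not performance on real
long-read data.

## Problem sizes and determinism

The default test suite and the acceptance script use desk-scale problem
sizes chosen as sufficient for their statistical claims: estimator-recovery
checks at 2,000 loci × 200 samples × 20 seeds (standard error of the
weighted F_ST mean ≪ the 0.02 band), hotspot calibration at 500 events /
10 Mb × 200 null trials × 50 seeds, end-to-end runs at 120 samples × 400–600
SVs. All stochastic steps take explicit seeds; identical configuration and
seed reproduce byte-identical outputs.

## Known limitations

* F_ST supports exactly two populations (the comparison the pipeline is
  for); the r-population generalization is not implemented.
* Insertions are compared by position and length only, never by sequence.
* The power-law GoF bootstrap refits at most 100 x_min candidates; with
  heavy ties this can slightly discretize the p-value.
* `GenotypeMatrix` is dense int8; cohorts beyond ~10⁵ variants × 10³
  samples would need a sparse backend.
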