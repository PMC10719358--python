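"""Cohort-level SV statistics.

Two frequency notions coexist deliberately: *carrier frequency* (the fraction of
samples carrying at least one copy, the definition used for the AF spectrum and
population-specificity filters) and *allele frequency* from diploid dosages
(used for Hardy-Weinberg tests and the Weir-Cockerham F_ST estimator).

F_ST follows Weir & Cockerham (1984) method-of-moments variance components for
r=2 populations, with the cohort-wide "weighted" estimate sum(a)/sum(a+b+c),
matching VCFtools' weighted Fst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .records import MISSING, Cohort, GenotypeMatrix, SVRecord, SVType

__all__ = [
    "FstComponents",
    "FstResult",
    "HweResult",
    "PowerLawFit",
    "AfSpectrum",
    "carrier_frequency",
    "af_spectrum",
    "hwe_test",
    "weir_cockerham_fst",
    "hudson_fst",
    "powerlaw_fit",
    "saturation_curve",
    "gc_content_profile",
    "presence_pca",
    "cluster_tree",
]


# ---------------------------------------------------------------------------
# frequencies and spectrum
# ---------------------------------------------------------------------------

def carrier_frequency(
    matrix: GenotypeMatrix, samples: Sequence[str] | None = None
) -> dict[str, float]:
    """Per-variant fraction of samples carrying >= 1 copy.

    ``samples`` restricts to a subpopulation; missing genotypes count as
    non-carriers (presence-view convention).
    """
    sub = matrix if samples is None else matrix.subset_samples(list(samples))
    if sub.n_samples == 0:
        raise ValueError("empty population")
    freq = sub.presence.mean(axis=0)
    return dict(zip(sub.variant_ids, freq.astype(float)))


@dataclass
class AfSpectrum:
    """Counts of SVs in carrier-frequency classes (0-0.1], (0.1-0.4], (0.4-1), {1}."""

    low: int = 0          # (0, 0.1]
    intermediate: int = 0  # (0.1, 0.4]
    high: int = 0          # (0.4, 1)
    fixed: int = 0         # exactly 1
    singletons: int = 0    # carried by exactly one sample

    @property
    def bins(self) -> tuple[int, int, int, int]:
        return (self.low, self.intermediate, self.high, self.fixed)


def af_spectrum(freqs: Mapping[str, float], matrix: GenotypeMatrix | None = None) -> AfSpectrum:
    """Bin carrier frequencies into the four frequency levels; count singletons."""
    spec = AfSpectrum()
    for v, f in freqs.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"frequency {f} outside [0, 1] for {v}")
        if f == 0:
            continue
        if f == 1.0:
            spec.fixed += 1
        elif f <= 0.1:
            spec.low += 1
        elif f <= 0.4:
            spec.intermediate += 1
        else:
            spec.high += 1
    if matrix is not None:
        carriers = matrix.presence.sum(axis=0)
        spec.singletons = int((carriers == 1).sum())
    return spec


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    variant_id: str
    chi2: float
    p: float
    bonferroni_p: float
    in_hwe: bool
    counts: tuple[int, int, int] = (0, 0, 0)


def _hwe_chi2(n_rr: int, n_ra: int, n_aa: int) -> tuple[float, float]:
    n = n_rr + n_ra + n_aa
    p = (2 * n_rr + n_ra) / (2 * n)
    q = 1 - p
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([n_rr, n_ra, n_aa], dtype=float)
    if p == 0 or q == 0:
        return 0.0, 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_test(matrix: GenotypeMatrix, alpha: float = 0.05) -> tuple[list[HweResult], float]:
    """Chi-square HWE test (df=1, no continuity correction) per variant with
    Bonferroni correction across the tested variants.

    Returns the per-variant results and the fraction of tested variants in HWE.
    Variants with no non-missing genotypes are excluded from testing and from m.
    """
    tested: list[tuple[str, float, float, tuple[int, int, int]]] = []
    untested: list[str] = []
    D = matrix.dosage
    for j, vid in enumerate(matrix.variant_ids):
        d = D[:, j]
        ok = d != MISSING
        if not ok.any():
            untested.append(vid)
            continue
        n_rr = int((d[ok] == 0).sum())
        n_ra = int((d[ok] == 1).sum())
        n_aa = int((d[ok] == 2).sum())
        chi2, p = _hwe_chi2(n_rr, n_ra, n_aa)
        tested.append((vid, chi2, p, (n_rr, n_ra, n_aa)))
    m = len(tested)
    results = []
    n_in = 0
    for vid, chi2, p, counts in tested:
        bp = min(1.0, p * m)
        in_hwe = bp >= alpha
        n_in += in_hwe
        results.append(HweResult(vid, chi2, p, bp, in_hwe, counts))
    frac = n_in / m if m else float("nan")
    return results, frac


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstComponents:
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float
    a: float
    b: float
    c: float
    theta: float | None  # None when undefined (monomorphic / insufficient data)


@dataclass
class FstResult:
    per_site: dict[str, FstComponents]
    weighted: float
    mean: float
    n_undefined: int = 0

    def theta_of(self, variant_id: str) -> float | None:
        comp = self.per_site.get(variant_id)
        return comp.theta if comp is not None else None


def _wc_site(d1: np.ndarray, d2: np.ndarray) -> FstComponents | None:
    """Weir & Cockerham (1984) components for one biallelic site, two populations.

    ``d1``/``d2`` are dosage vectors with missing entries already removed.
    Returns None when either population has < 2 genotypes.
    """
    n1, n2 = len(d1), len(d2)
    if n1 < 2 or n2 < 2:
        return None
    r = 2
    p1 = d1.sum() / (2 * n1)
    p2 = d2.sum() / (2 * n2)
    h1 = (d1 == 1).mean()
    h2 = (d2 == 1).mean()
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (pq - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        pq - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0 else None
    if p_bar in (0.0, 1.0):
        theta = None  # monomorphic across the cohort
    return FstComponents(n_bar, n_c, p_bar, s2, h_bar, a, b, c, theta)


def weir_cockerham_fst(matrix: GenotypeMatrix, cohort: Cohort) -> FstResult:
    """Per-site and cohort-wide Weir-Cockerham theta-hat for a two-population cohort.

    Missing genotypes are excluded per site.  Monomorphic or under-covered sites
    carry an undefined theta and are excluded from the weighted and mean summaries.
    """
    pops = cohort.populations
    if len(pops) != 2:
        raise ValueError(f"exactly 2 populations required, got {len(pops)}")
    idx1, idx2 = cohort.indices(pops[0]), cohort.indices(pops[1])
    D = matrix.dosage
    per_site: dict[str, FstComponents] = {}
    sum_a = sum_abc = 0.0
    thetas = []
    n_undef = 0
    for j, vid in enumerate(matrix.variant_ids):
        d1 = D[idx1, j]
        d2 = D[idx2, j]
        comp = _wc_site(d1[d1 != MISSING].astype(float), d2[d2 != MISSING].astype(float))
        if comp is None:
            n_undef += 1
            continue
        per_site[vid] = comp
        if comp.theta is None:
            n_undef += 1
            continue
        sum_a += comp.a
        sum_abc += comp.a + comp.b + comp.c
        thetas.append(comp.theta)
    weighted = sum_a / sum_abc if sum_abc > 0 else float("nan")
    mean = float(np.mean(thetas)) if thetas else float("nan")
    return FstResult(per_site, weighted, mean, n_undef)


def hudson_fst(matrix: GenotypeMatrix, cohort: Cohort) -> dict[str, float]:
    """Alternative 1 - H_S/H_T differentiation measure (Wright/Hudson style).

    Provided because the verbal definition "(total heterozygosity - mean
    subpopulation heterozygosity) / total heterozygosity" differs numerically
    from the Weir-Cockerham estimator that is the package default.
    """
    pops = cohort.populations
    if len(pops) != 2:
        raise ValueError("exactly 2 populations required")
    idx1, idx2 = cohort.indices(pops[0]), cohort.indices(pops[1])
    out: dict[str, float] = {}
    D = matrix.dosage
    for j, vid in enumerate(matrix.variant_ids):
        d1 = D[idx1, j]
        d2 = D[idx2, j]
        d1 = d1[d1 != MISSING]
        d2 = d2[d2 != MISSING]
        if len(d1) == 0 or len(d2) == 0:
            continue
        p1 = d1.sum() / (2 * len(d1))
        p2 = d2.sum() / (2 * len(d2))
        p_t = (d1.sum() + d2.sum()) / (2 * (len(d1) + len(d2)))
        h_t = 2 * p_t * (1 - p_t)
        if h_t == 0:
            continue
        h_s = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
        out[vid] = (h_t - h_s) / h_t
    return out


# ---------------------------------------------------------------------------
# power-law fit (Clauset-style MLE + KS xmin scan + bootstrap GoF)
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    alpha: float
    xmin: float
    ks_stat: float
    gof_p: float | None
    n_tail: int


def _fit_continuous(x: np.ndarray, max_candidates: int = 100) -> tuple[float, float, float, int]:
    """Continuous MLE power-law fit with xmin chosen by minimal KS distance."""
    x = np.sort(x)
    uniq = np.unique(x)
    if len(uniq) > max_candidates:
        qs = np.linspace(0, 0.95, max_candidates)
        candidates = np.unique(np.quantile(uniq, qs, method="nearest"))
    else:
        candidates = uniq[:-1] if len(uniq) > 1 else uniq
    best = None
    for xmin in candidates:
        tail = x[x >= xmin]
        n = len(tail)
        if n < 10:
            continue
        s = np.log(tail / xmin).sum()
        if s <= 0:
            continue
        alpha = 1.0 + n / s
        # KS distance between empirical and fitted CDF on the tail
        cdf = 1.0 - (tail / xmin) ** (1.0 - alpha)
        emp_hi = np.arange(1, n + 1) / n
        emp_lo = np.arange(0, n) / n
        ks = max(np.abs(emp_hi - cdf).max(), np.abs(emp_lo - cdf).max())
        if best is None or ks < best[2]:
            best = (alpha, float(xmin), float(ks), n)
    if best is None:
        raise ValueError("no viable xmin candidate (degenerate input)")
    return best


def _rpowerlaw(rng: np.random.Generator, n: int, alpha: float, xmin: float) -> np.ndarray:
    return xmin * (1.0 - rng.random(n)) ** (-1.0 / (alpha - 1.0))


def powerlaw_fit(
    values: Sequence[float],
    n_bootstrap: int = 100,
    seed: int = 0,
    max_candidates: int = 100,
) -> PowerLawFit:
    """Fit a continuous power law by MLE with a KS-minimizing lower cutoff and a
    semi-parametric bootstrap goodness-of-fit p-value.

    The bootstrap resamples the body (below xmin) empirically and the tail from
    the fitted law, refits each replicate, and reports the fraction of replicate
    KS distances at least as large as the observed one.  ``n_bootstrap=0`` skips
    the GoF step (``gof_p=None``).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 positive values")
    if (x <= 0).any():
        raise ValueError("values must be positive")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all values identical")
    alpha, xmin, ks, n_tail = _fit_continuous(x, max_candidates)
    gof_p = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        body = x[x < xmin]
        n = len(x)
        p_tail = n_tail / n
        exceed = 0
        for _ in range(n_bootstrap):
            n_t = rng.binomial(n, p_tail)
            parts = []
            if n - n_t > 0 and len(body) > 0:
                parts.append(rng.choice(body, size=n - n_t, replace=True))
            parts.append(_rpowerlaw(rng, max(n_t, 1), alpha, xmin))
            boot = np.concatenate(parts)
            try:
                _, _, ks_b, _ = _fit_continuous(boot, max_candidates)
            except ValueError:
                continue
            if ks_b >= ks:
                exceed += 1
        gof_p = exceed / n_bootstrap
    return PowerLawFit(alpha=alpha, xmin=xmin, ks_stat=ks, gof_p=gof_p, n_tail=n_tail)


# ---------------------------------------------------------------------------
# saturation, GC, PCA, clustering
# ---------------------------------------------------------------------------

def saturation_curve(
    matrix: GenotypeMatrix, n_orders: int = 1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative distinct-SV counts as samples are added in random orders.

    Returns ``(mean_curve, per_order_curves)`` with shape (n_samples,) and
    (n_orders, n_samples).  Every curve is nondecreasing and ends at the number
    of SVs with at least one carrier.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    P = matrix.presence.astype(bool)
    n = matrix.n_samples
    curves = np.zeros((n_orders, n), dtype=int)
    for k in range(n_orders):
        order = rng.permutation(n)
        seen = np.zeros(matrix.n_variants, dtype=bool)
        for i, s in enumerate(order):
            seen |= P[s]
            curves[k, i] = seen.sum()
    return curves.mean(axis=0), curves


def gc_content_profile(
    svs: Sequence[SVRecord],
    reference: Callable[[str, int, int], str] | Mapping[str, str],
    high_gc_cut: float = 0.55,
    ins_flank: int = 150,
) -> tuple[dict[str, float], float]:
    """Per-SV GC fraction and the share of SVs in high-GC (>= cut) regions.

    ``reference`` is either a ``fetch(chrom, start, end)`` callable (e.g.
    ``pyfaidx``/``pysam.FastaFile.fetch``) or a plain chrom -> sequence mapping.
    Insertions use a +/- ``ins_flank`` bp window around the insertion point.
    """
    if callable(reference):
        fetch = reference
    else:
        seqs = reference

        def fetch(chrom: str, start: int, end: int) -> str:
            seq = seqs[chrom]
            if end > len(seq):
                raise ValueError(f"span {chrom}:{start}-{end} outside reference")
            return seq[start:end]

    out: dict[str, float] = {}
    n_high = 0
    for sv in svs:
        if sv.svtype is SVType.INS:
            s, e = max(0, sv.start - ins_flank), sv.start + ins_flank
        else:
            s, e = sv.start, sv.end
        seq = fetch(sv.chrom, s, e).upper()
        counts = {b: seq.count(b) for b in "ACGT"}
        denom = sum(counts.values())
        gc = (counts["G"] + counts["C"]) / denom if denom else float("nan")
        out[sv.id] = gc
        if gc >= high_gc_cut:
            n_high += 1
    share = n_high / len(svs) if svs else float("nan")
    return out, share


def presence_pca(matrix: GenotypeMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the column-centered 0/1 presence matrix via SVD.

    Returns (scores, explained_variance_ratio); scores have a deterministic sign
    (largest-magnitude loading of each component made positive).
    """
    if k >= matrix.n_samples:
        raise ValueError("k must be below the number of samples")
    X = matrix.presence.astype(float)
    X -= X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(len(S)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = S**2
    ratio = var / var.sum() if var.sum() > 0 else var
    scores = U[:, :k] * S[:k]
    return scores, ratio[:k]


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[n + len(Z) - 1] + ";"


def cluster_tree(matrix: GenotypeMatrix, linkage: str = "average") -> str:
    """Hierarchical clustering of samples on Manhattan presence distance.

    Returns the dendrogram serialized as Newick; linkage is "average" or
    "complete".
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.presence.astype(float)
    dist = pdist(X, metric="cityblock")
    Z = _scipy_linkage(dist, method=linkage)
    return _to_newick(Z, matrix.samples)
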