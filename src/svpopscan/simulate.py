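"""Synthetic two-population SV cohort generator with a machine-readable truth table.

The generator emulates the structure of a long-read SV cohort study: two
populations whose SV allele frequencies are differentiated under the
Balding-Nichols model (per-population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
around an ancestral frequency p), Hardy-Weinberg genotypes within populations,
a handful of strongly differentiated "selected" loci with stated target carrier
frequencies, per-caller call files with breakpoint/length jitter and independent
false calls, tag SNPs in tunable LD with selected SVs, and annotation tracks
(repeats, genes, enhancers, TAD boundaries) plus a GWAS-catalog-style table.

Everything is a pure function of the parameter block including its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import Cohort, Genotype, GenotypeMatrix, GwasCatalog, IntervalSet, SVRecord, SVType

__all__ = [
    "CallerModel",
    "SimParams",
    "TruthTable",
    "simulate_cohort_truth",
    "simulate_caller_calls",
    "simulate_caller_vcfs",
    "simulate_linked_snps",
    "simulate_annotations",
]

#: SV type mixture, dominated by deletions and insertions as in long-read cohorts
TYPE_PROBS: dict[SVType, float] = {
    SVType.DEL: 0.52,
    SVType.INS: 0.42,
    SVType.DUP: 0.05,
    SVType.INV: 0.01,
}

PHENOTYPES = (
    "red blood cell count",
    "body fat distribution",
    "offspring birth weight",
    "HDL cholesterol",
    "heel bone mineral density",
    "diastolic blood pressure",
    "insomnia symptoms",
    "triglyceride levels",
)


@dataclass(frozen=True)
class CallerModel:
    """Noise model for one SV caller."""

    sensitivity: float = 0.9
    fp_per_mb: float = 0.2
    breakpoint_jitter_sd: float = 30.0
    length_jitter_sd: float = 10.0
    hq_prob: float = 0.0  # probability a call is flagged high-quality


@dataclass(frozen=True)
class SimParams:
    """Study conditions of the default synthetic cohort.

    Sample sizes mirror a two-population long-read cohort (119 vs 201); the
    differentiation parameter F is directly the Weir-Cockerham estimand.
    Selected loci get target *carrier* frequencies (converted internally to
    allele frequencies assuming HWE).
    """

    n_pop_a: int = 119
    n_pop_b: int = 201
    m_svs: int = 2000
    fst_param: float = 0.1
    n_selected: int = 20
    selected_carrier_a: float = 0.6
    selected_carrier_b: float = 0.05
    beta_a: float = 0.5
    beta_b: float = 3.0
    genome: tuple[tuple[str, int], ...] = (("chr1", 50_000_000), ("chr2", 50_000_000))
    caller_models: Mapping[str, CallerModel] = field(
        default_factory=lambda: {
            "cuteSV": CallerModel(sensitivity=0.92, hq_prob=0.3),
            "sniffles": CallerModel(sensitivity=0.90),
            "nanovar": CallerModel(sensitivity=0.85),
        }
    )
    mean_depth: float = 20.0
    #: tag target sits well above the 0.8 strong-LD cutoff so implanted bridges
    #: survive the r2 attenuation caused by imperfect caller sensitivity
    tag_r2: float = 0.95
    n_background_snps: int = 200
    shared_false_calls: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pop_a, self.n_pop_b, self.m_svs) <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.fst_param < 1):
            raise ValueError("fst_param must be in [0, 1)")
        for f in (self.selected_carrier_a, self.selected_carrier_b, self.tag_r2):
            if not (0 <= f <= 1):
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort."""

    sv_ids: list[str]
    records: list[SVRecord]  # true coordinates, no sample/caller provenance
    ancestral_freq: np.ndarray
    freq_a: np.ndarray  # per-population allele frequencies
    freq_b: np.ndarray
    selected: np.ndarray  # bool mask
    expected_direction: list[str]  # "A_specific" / "B_specific" / "none"
    haplotypes: np.ndarray  # (2, n_samples, m_svs) int8, HWE phasing
    snp_tags: dict[str, tuple[str, float]] = field(default_factory=dict)  # snp -> (sv, target r2)

    def carrier_freq_a(self) -> np.ndarray:
        return 1.0 - (1.0 - self.freq_a) ** 2

    def carrier_freq_b(self) -> np.ndarray:
        return 1.0 - (1.0 - self.freq_b) ** 2


def _carrier_to_allele(c: float) -> float:
    """Invert c = 1 - (1-p)^2 under HWE."""
    return 1.0 - np.sqrt(1.0 - c)


def _draw_sv_layout(rng: np.random.Generator, params: SimParams) -> list[SVRecord]:
    chroms = [c for c, _ in params.genome]
    sizes = np.array([s for _, s in params.genome], dtype=float)
    probs = sizes / sizes.sum()
    types = list(TYPE_PROBS)
    type_p = np.array([TYPE_PROBS[t] for t in types])
    records = []
    for i in range(params.m_svs):
        chrom_i = rng.choice(len(chroms), p=probs)
        chrom, size = chroms[chrom_i], int(sizes[chrom_i])
        # bimodal length mixture: Alu-scale (~300 bp) and LINE-scale (~6 kb)
        if rng.random() < 0.8:
            length = int(np.clip(rng.lognormal(np.log(300), 0.6), 50, 50_000))
        else:
            length = int(np.clip(rng.lognormal(np.log(6000), 0.5), 50, 50_000))
        svtype = types[rng.choice(len(types), p=type_p)]
        start = int(rng.integers(10_000, size - length - 10_000))
        end = start if svtype is SVType.INS else start + length
        records.append(
            SVRecord(
                id=f"truth{i:05d}",
                chrom=chrom,
                start=start,
                end=end,
                svtype=svtype,
                length=length,
            )
        )
    return records


def simulate_cohort_truth(params: SimParams) -> tuple[TruthTable, GenotypeMatrix, Cohort]:
    """Draw the true cohort: SV layout, Balding-Nichols frequencies, HWE genotypes.

    Selected loci are overridden to the stated target carrier frequencies
    (population A high, population B low), alternating direction every other
    locus so both specificity directions are exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    samples = [f"A{i:04d}" for i in range(params.n_pop_a)] + [
        f"B{i:04d}" for i in range(params.n_pop_b)
    ]
    pops = {s: ("POP_A" if s.startswith("A") else "POP_B") for s in samples}
    cohort = Cohort(tuple(samples), pops)

    records = _draw_sv_layout(rng, params)
    m = params.m_svs
    p_anc = rng.beta(params.beta_a, params.beta_b, size=m)
    p_anc = np.clip(p_anc, 0.01, 0.99)
    F = params.fst_param
    if F > 0:
        k = (1 - F) / F
        pa = rng.beta(p_anc * k, (1 - p_anc) * k)
        pb = rng.beta(p_anc * k, (1 - p_anc) * k)
    else:
        pa = p_anc.copy()
        pb = p_anc.copy()
    pa = np.clip(pa, 1e-4, 1 - 1e-4)
    pb = np.clip(pb, 1e-4, 1 - 1e-4)

    selected = np.zeros(m, dtype=bool)
    direction = ["none"] * m
    n_sel = min(params.n_selected, m)
    sel_idx = rng.choice(m, size=n_sel, replace=False)
    hi = _carrier_to_allele(params.selected_carrier_a)
    lo = _carrier_to_allele(params.selected_carrier_b)
    for j, idx in enumerate(sorted(sel_idx)):
        selected[idx] = True
        if j % 2 == 0:
            pa[idx], pb[idx] = hi, lo
            direction[idx] = "A_specific"
        else:
            pa[idx], pb[idx] = lo, hi
            direction[idx] = "B_specific"

    n = len(samples)
    hap = np.zeros((2, n, m), dtype=np.int8)
    a_mask = np.array([s.startswith("A") for s in samples])
    for h in range(2):
        u = rng.random((n, m))
        hap[h] = (u < np.where(a_mask[:, None], pa[None, :], pb[None, :])).astype(np.int8)
    dosage = hap.sum(axis=0).astype(np.int8)

    matrix = GenotypeMatrix(
        dosage,
        samples,
        [r.id for r in records],
        variants=records,
    )
    truth = TruthTable(
        sv_ids=[r.id for r in records],
        records=records,
        ancestral_freq=p_anc,
        freq_a=pa,
        freq_b=pb,
        selected=selected,
        expected_direction=direction,
        haplotypes=hap,
    )
    return truth, matrix, cohort


def _jitter_record(
    rng: np.random.Generator, rec: SVRecord, model: CallerModel
) -> tuple[int, int, int]:
    ds = int(round(rng.normal(0, model.breakpoint_jitter_sd))) if model.breakpoint_jitter_sd else 0
    dl = int(round(rng.normal(0, model.length_jitter_sd))) if model.length_jitter_sd else 0
    length = int(np.clip(rec.length + dl, 50, 50_000))
    start = max(0, rec.start + ds)
    if rec.svtype is SVType.INS:
        return start, start, length
    return start, start + length, length


def simulate_caller_calls(
    truth: TruthTable,
    matrix: GenotypeMatrix,
    params: SimParams,
) -> dict[str, dict[str, list[SVRecord]]]:
    """Noisy per-sample, per-caller call sets: sample -> caller -> records.

    Each carried true SV is emitted per caller with that caller's sensitivity,
    with jittered breakpoints/lengths; false calls are Poisson per Mb, placed
    uniformly and (by default) independently per caller so the >=2-caller
    consensus rule removes them.  Read-support AF and depth are drawn so true
    calls pass the raw filter while roughly half of false calls fail it.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 2)))
    genome_mb = sum(s for _, s in params.genome) / 1e6
    chroms = [c for c, _ in params.genome]
    sizes = {c: s for c, s in params.genome}
    out: dict[str, dict[str, list[SVRecord]]] = {}
    dosage = matrix.dosage
    callers = list(params.caller_models)
    for si, sample in enumerate(matrix.samples):
        carried = np.nonzero(dosage[si] >= 1)[0]
        per_caller: dict[str, list[SVRecord]] = {c: [] for c in callers}
        shared_fp: list[SVRecord] | None = None
        for caller in callers:
            model = params.caller_models[caller]
            calls: list[SVRecord] = []
            for j in carried:
                if rng.random() >= model.sensitivity:
                    continue
                rec = truth.records[j]
                start, end, length = _jitter_record(rng, rec, model)
                calls.append(
                    SVRecord(
                        id=f"{sample}_{caller}_{rec.id}",
                        chrom=rec.chrom,
                        start=start,
                        end=end,
                        svtype=rec.svtype,
                        length=length,
                        caller=caller,
                        hq_flag=bool(rng.random() < model.hq_prob),
                        sample=sample,
                        genotype=Genotype.from_dosage(int(dosage[si, j])),
                        depth=float(rng.uniform(0.5, 1.5) * params.mean_depth),
                        af_read=float(rng.uniform(0.35, 1.0)),
                    )
                )
            if params.shared_false_calls and shared_fp is not None:
                fp_calls = [
                    f.with_(id=f"{sample}_{caller}_fp{k}", caller=caller,
                            hq_flag=bool(rng.random() < model.hq_prob))
                    for k, f in enumerate(shared_fp)
                ]
            else:
                n_fp = rng.poisson(model.fp_per_mb * genome_mb)
                fp_calls = []
                for k in range(n_fp):
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    length = int(np.clip(rng.lognormal(np.log(300), 0.8), 50, 50_000))
                    start = int(rng.integers(0, sizes[chrom] - length))
                    svtype = SVType.DEL if rng.random() < 0.6 else SVType.INS
                    end = start if svtype is SVType.INS else start + length
                    fp_calls.append(
                        SVRecord(
                            id=f"{sample}_{caller}_fp{k}",
                            chrom=chrom,
                            start=start,
                            end=end,
                            svtype=svtype,
                            length=length,
                            caller=caller,
                            hq_flag=False,
                            sample=sample,
                            genotype=Genotype.HET,
                            depth=float(rng.uniform(0.5, 1.5) * params.mean_depth),
                            # half of false calls drawn below the 0.3 AF filter
                            af_read=float(rng.uniform(0.05, 0.55)),
                        )
                    )
                if params.shared_false_calls and shared_fp is None:
                    shared_fp = fp_calls
            calls.extend(fp_calls)
            calls.sort(key=SVRecord.sort_key)
            per_caller[caller] = calls
        out[sample] = per_caller
    return out


def simulate_caller_vcfs(
    truth: TruthTable,
    matrix: GenotypeMatrix,
    params: SimParams,
    out_dir: str | os.PathLike,
) -> dict[str, dict[str, str]]:
    """Write the per-sample, per-caller call sets as VCF files.

    Returns sample -> caller -> path.  File contents are deterministic given the
    parameter seed.
    """
    from .vcfio import write_sv_vcf

    calls = simulate_caller_calls(truth, matrix, params)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, dict[str, str]] = {}
    for sample, per_caller in calls.items():
        paths[sample] = {}
        for caller, recs in per_caller.items():
            path = os.path.join(os.fspath(out_dir), f"{sample}.{caller}.vcf")
            sub_cohort = Cohort((sample,), {sample: "NA"})
            write_sv_vcf(recs, sub_cohort, path)
            paths[sample][caller] = path
    return paths


def simulate_linked_snps(
    matrix: GenotypeMatrix,
    truth: TruthTable,
    params: SimParams,
) -> GenotypeMatrix:
    """Tag SNPs in LD with every selected SV plus independent background SNPs.

    Each selected SV gets one tag SNP whose haplotype copies the SV haplotype
    with probability lambda and is otherwise an independent draw at the same
    population frequency; this preserves allele frequencies exactly.  Because
    the SNP inherits the SV's between-population frequency contrast, the pooled
    two-population dosage correlation is (lambda*W + 2B)/(W + 2B) with W the
    mean within-population variance and B the between-population haplotype
    variance, so lambda is solved per locus to make the pooled r2 equal the
    target.  A target below the structural floor (2B/(W+2B))^2 is unreachable
    and raises.  Background SNPs are Balding-Nichols draws independent of
    every SV.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 3)))
    n = matrix.n_samples
    a_mask = np.array([s.startswith("A") for s in matrix.samples])
    w1 = a_mask.mean()
    w2 = 1.0 - w1
    rho_target = float(np.sqrt(params.tag_r2))
    snp_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    columns: list[np.ndarray] = []
    truth.snp_tags = {}
    sel_indices = np.nonzero(truth.selected)[0]
    for j in sel_indices:
        rec = truth.records[j]
        snp_id = f"rs{j:05d}"
        offset = int(rng.integers(1000, 500_000)) * (1 if rng.random() < 0.5 else -1)
        pos = max(0, rec.start + offset)
        pa, pb = float(truth.freq_a[j]), float(truth.freq_b[j])
        W = w1 * pa * (1 - pa) + w2 * pb * (1 - pb)
        # dosage-level between-population variance is doubled relative to within:
        # cross-haplotype covariance also carries the population contrast
        B2 = 2.0 * w1 * w2 * (pa - pb) ** 2
        if W <= 0:
            continue  # monomorphic in both populations: nothing to tag
        lam = (rho_target * (W + B2) - B2) / W
        if lam < 0:
            raise ValueError(
                f"target r2 {params.tag_r2} below the structural floor "
                f"{(B2 / (W + B2)) ** 2:.3f} imposed by population differentiation at {rec.id}"
            )
        lam = min(lam, 1.0)
        hap_snp = np.zeros((2, n), dtype=np.int8)
        p_by_sample = np.where(a_mask, pa, pb)
        for h in range(2):
            copy = rng.random(n) < lam
            indep = (rng.random(n) < p_by_sample).astype(np.int8)
            hap_snp[h] = np.where(copy, truth.haplotypes[h, :, j], indep)
        columns.append(hap_snp.sum(axis=0).astype(np.int8))
        snp_ids.append(snp_id)
        positions.append((rec.chrom, pos))
        truth.snp_tags[snp_id] = (rec.id, params.tag_r2)
    chroms = [c for c, _ in params.genome]
    sizes = {c: s for c, s in params.genome}
    F = params.fst_param
    for k in range(params.n_background_snps):
        snp_id = f"bg{k:05d}"
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, sizes[chrom]))
        p = float(np.clip(rng.beta(0.8, 0.8), 0.05, 0.95))
        if F > 0:
            kk = (1 - F) / F
            p_a = float(np.clip(rng.beta(p * kk, (1 - p) * kk), 1e-4, 1 - 1e-4))
            p_b = float(np.clip(rng.beta(p * kk, (1 - p) * kk), 1e-4, 1 - 1e-4))
        else:
            p_a = p_b = p
        p_by_sample = np.where(a_mask, p_a, p_b)
        d = (
            (rng.random(n) < p_by_sample).astype(np.int8)
            + (rng.random(n) < p_by_sample).astype(np.int8)
        )
        columns.append(d.astype(np.int8))
        snp_ids.append(snp_id)
        positions.append((chrom, pos))
    dosage = np.stack(columns, axis=1) if columns else np.zeros((n, 0), dtype=np.int8)
    return GenotypeMatrix(dosage, matrix.samples, snp_ids, variants=None, positions=positions)


def simulate_annotations(
    params: SimParams,
    truth: TruthTable | None = None,
    repeat_fraction: float = 0.5,
    n_enhancer_selected: int | None = None,
) -> tuple[dict[str, IntervalSet], GwasCatalog]:
    """Annotation tracks and a GWAS-catalog table for the simulated genome.

    Repeats tile the genome at the requested coverage fraction; genes are
    nonoverlapping labelled intervals; enhancers include one element placed
    50 bp from each of the first ``n_enhancer_selected`` selected SVs (so a
    +/-100 bp pad is guaranteed to pick them up) plus background elements;
    TAD boundaries are regular narrow intervals.  Catalog rows link every tag
    SNP to a phenotype string.
    """
    if repeat_fraction > 1:
        raise ValueError("repeat coverage fraction cannot exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 4)))
    repeats: list[tuple[str, int, int]] = []
    genes: list[tuple[str, int, int]] = []
    gene_labels: list[str] = []
    enhancers: list[tuple[str, int, int]] = []
    enh_labels: list[str] = []
    tads: list[tuple[str, int, int]] = []
    g = 0
    if repeat_fraction > 0:
        unit = 5000
        period = int(round(unit / repeat_fraction))
        for chrom, size in params.genome:
            phase = int(rng.integers(0, period))
            pos = phase
            while pos + unit <= size:
                repeats.append((chrom, pos, pos + unit))
                pos += period
    for chrom, size in params.genome:
        pos = 50_000
        while pos + 60_000 < size:
            length = int(rng.integers(10_000, 50_000))
            genes.append((chrom, pos, pos + length))
            gene_labels.append(f"GENE{g:05d}")
            g += 1
            pos += 100_000
        for t in range(1_000_000, size, 1_000_000):
            tads.append((chrom, t - 5_000, t + 5_000))
        for _ in range(int(size / 1e6)):
            s = int(rng.integers(0, size - 2000))
            enhancers.append((chrom, s, s + int(rng.integers(200, 2000))))
            enh_labels.append(f"enh_bg{len(enh_labels):04d}")
    if truth is not None:
        sel = np.nonzero(truth.selected)[0]
        n_enh = len(sel) if n_enhancer_selected is None else min(n_enhancer_selected, len(sel))
        for j in sel[:n_enh]:
            rec = truth.records[j]
            s = rec.end + 50  # within a 100 bp pad of the right breakpoint
            enhancers.append((rec.chrom, s, s + 500))
            enh_labels.append(f"enh_{rec.id}")
    entries = []
    if truth is not None:
        for snp_id, (sv_id, _r2) in truth.snp_tags.items():
            rec = next(r for r in truth.records if r.id == sv_id)
            pheno = PHENOTYPES[len(entries) % len(PHENOTYPES)]
            entries.append((snp_id, rec.chrom, rec.start, pheno))
    # decoy catalog rows pointing at SNPs absent from the simulated data
    for k in range(20):
        entries.append((f"decoy{k:03d}", "chr1", 1000 + k, PHENOTYPES[k % len(PHENOTYPES)]))
    tracks = {
        "repeats": IntervalSet("repeats", repeats),
        "genes": IntervalSet("genes", genes, gene_labels),
        "enhancers": IntervalSet("enhancers", enhancers, enh_labels),
        "tad_boundaries": IntervalSet("tad_boundaries", tads),
    }
    return tracks, GwasCatalog(entries)
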