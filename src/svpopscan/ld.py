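"""LD between SVs and nearby SNPs, and the SV -> SNP -> phenotype bridge.

r-squared is the squared Pearson correlation of unphased genotype dosages over
pairwise-complete samples (composite LD; the behaviour of PLINK's ``--r2`` on
unphased input).  An SV inherits a phenotype when a SNP within the window is in
strong LD (r2 >= 0.8 by default) and carries that phenotype in the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import MISSING, GenotypeMatrix, GwasCatalog, SVRecord, SVType

__all__ = [
    "LdParams",
    "AssociationRecord",
    "r2_dosage",
    "ld_scan",
    "phenotype_bridge",
]


@dataclass(frozen=True)
class LdParams:
    window: int = 1_000_000
    report_cutoff: float = 0.2
    strong_cutoff: float = 0.8

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (0 <= self.report_cutoff <= self.strong_cutoff <= 1):
            raise ValueError("need 0 <= report_cutoff <= strong_cutoff <= 1")


@dataclass
class AssociationRecord:
    sv_id: str
    snp_id: str
    r2: float
    phenotype: str
    n_samples: int


def r2_dosage(g1: Sequence[int], g2: Sequence[int]) -> float | None:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    samples; ``None`` when fewer than 3 complete pairs or a constant vector."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        return None
    da = a - a.mean()
    db = b - b.mean()
    va = (da * da).sum()
    vb = (db * db).sum()
    if va == 0 or vb == 0:
        return None
    cov = (da * db).sum()
    return float(cov * cov / (va * vb))


def _sv_breakpoints(sv: SVRecord) -> tuple[int, int]:
    if sv.svtype is SVType.INS:
        return sv.start, sv.start
    return sv.start, sv.end


def ld_scan(
    sv_matrix: GenotypeMatrix,
    snp_matrix: GenotypeMatrix,
    params: LdParams = LdParams(),
) -> list[tuple[str, str, float]]:
    """All (SV, SNP, r2) pairs with the SNP within ``window`` bp of the nearer SV
    breakpoint and r2 >= ``report_cutoff``.  Matrices must share sample order."""
    if sv_matrix.samples != snp_matrix.samples:
        raise ValueError("SV and SNP matrices must share the same sample ordering")
    if sv_matrix.positions is None or snp_matrix.positions is None:
        raise ValueError("both matrices must carry variant positions")
    snp_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, (chrom, pos) in enumerate(snp_matrix.positions):
        snp_by_chrom.setdefault(chrom, []).append((pos, j))
    for chrom in snp_by_chrom:
        snp_by_chrom[chrom].sort()
    out: list[tuple[str, str, float]] = []
    Dsv = sv_matrix.dosage
    Dsnp = snp_matrix.dosage
    for i, vid in enumerate(sv_matrix.variant_ids):
        chrom, start = sv_matrix.positions[i]
        sv = sv_matrix.variants[i] if sv_matrix.variants else None
        bp1, bp2 = _sv_breakpoints(sv) if sv is not None else (start, start)
        snps = snp_by_chrom.get(chrom, [])
        if not snps:
            continue
        positions = np.array([p for p, _ in snps])
        lo = int(np.searchsorted(positions, min(bp1, bp2) - params.window, "left"))
        hi = int(np.searchsorted(positions, max(bp1, bp2) + params.window, "right"))
        for pos, j in snps[lo:hi]:
            dist = min(abs(pos - bp1), abs(pos - bp2))
            if dist > params.window:
                continue
            r2 = r2_dosage(Dsv[:, i], Dsnp[:, j])
            if r2 is not None and r2 >= params.report_cutoff:
                out.append((vid, snp_matrix.variant_ids[j], r2))
    return out


def phenotype_bridge(
    ld_pairs: Sequence[tuple[str, str, float]],
    catalog: GwasCatalog,
    params: LdParams = LdParams(),
    n_samples: int = 0,
) -> list[AssociationRecord]:
    """Bridge SVs to phenotypes through strongly linked catalog SNPs.

    One association per distinct (sv, snp, phenotype) triple with
    r2 >= ``strong_cutoff``.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[AssociationRecord] = []
    for sv_id, snp_id, r2 in ld_pairs:
        if r2 < params.strong_cutoff:
            continue
        for pheno in catalog.phenotypes_of(snp_id):
            key = (sv_id, snp_id, pheno)
            if key in seen:
                continue
            seen.add(key)
            out.append(AssociationRecord(sv_id, snp_id, r2, pheno, n_samples))
    return out
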