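"""Population-differentiation scan: specificity filters, F_ST ranking and
nearest-gene annotation.

A variant is called A-specific when its carrier frequency in population A is at
least ``min_freq`` (default 0.2), at least ``ratio`` (default 2x) times the
frequency in population B, and its F_ST exceeds ``min_fst`` (default 0.1); the
B-specific rule is symmetric.  "Population frequency" here is carrier
frequency, the same definition the frequency spectrum uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .popgen import FstResult
from .records import IntervalSet, SVRecord, SVType

__all__ = [
    "SelectionParams",
    "SelectionCall",
    "population_specific_svs",
    "rank_by_fst",
    "annotate_nearest_genes",
    "gene_set_overlap",
]


@dataclass(frozen=True)
class SelectionParams:
    min_freq: float = 0.2
    ratio: float = 2.0
    min_fst: float = 0.1
    top_fst: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.min_freq <= 1):
            raise ValueError("min_freq must be in (0, 1]")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if not (0 <= self.min_fst <= self.top_fst <= 1):
            raise ValueError("need 0 <= min_fst <= top_fst <= 1")


@dataclass
class SelectionCall:
    variant_id: str
    freq_a: float
    freq_b: float
    fst: float | None
    direction: str  # "A_specific" | "B_specific" | "none"
    rank: int | None = None


def _specific(freq_hi: float, freq_lo: float, fst: float | None, p: SelectionParams) -> bool:
    if fst is None or not fst > p.min_fst:
        return False
    if freq_hi < p.min_freq:
        return False
    # zero frequency in the other population satisfies the ratio criterion
    return freq_lo == 0 or freq_hi >= p.ratio * freq_lo


def population_specific_svs(
    freqs_a: Mapping[str, float],
    freqs_b: Mapping[str, float],
    fst: FstResult,
    params: SelectionParams = SelectionParams(),
) -> list[SelectionCall]:
    """Label each variant A-specific, B-specific or neither under the
    three-criterion rule; at most one direction per variant.  Calls are ranked
    by descending F_ST among the labelled variants."""
    calls: list[SelectionCall] = []
    for vid in freqs_a:
        if vid not in freqs_b:
            raise ValueError(f"variant {vid} missing from population-B frequencies")
        fa, fb = freqs_a[vid], freqs_b[vid]
        theta = fst.theta_of(vid)
        if _specific(fa, fb, theta, params):
            direction = "A_specific"
        elif _specific(fb, fa, theta, params):
            direction = "B_specific"
        else:
            direction = "none"
        calls.append(SelectionCall(vid, fa, fb, theta, direction))
    missing = [v for v in freqs_b if v not in freqs_a]
    if missing:
        raise ValueError(f"variant {missing[0]} missing from population-A frequencies")
    labelled = sorted(
        (c for c in calls if c.direction != "none"),
        key=lambda c: (-(c.fst if c.fst is not None else -1), c.variant_id),
    )
    for r, c in enumerate(labelled, start=1):
        c.rank = r
    return calls


def rank_by_fst(
    fst: FstResult,
    threshold: float,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> tuple[list[str], int]:
    """Variants with defined theta above ``threshold``, sorted descending;
    ties broken by (chrom, start) when positions are supplied, else by id."""
    entries = []
    for vid, comp in fst.per_site.items():
        if comp.theta is not None and comp.theta > threshold:
            tiebreak = positions.get(vid, ("", 0)) if positions else (vid,)
            entries.append((-comp.theta, tiebreak, vid))
    entries.sort()
    ordered = [vid for _t, _tb, vid in entries]
    return ordered, len(ordered)


def annotate_nearest_genes(
    svs: Sequence[SVRecord],
    genes: IntervalSet,
    k: int = 10,
) -> dict[str, dict[str, list[tuple[str, int]]]]:
    """For each SV, the <= k nearest genes upstream (genomic left), overlapping,
    and downstream (genomic right), with signed distances (0 for overlap,
    negative upstream, positive downstream).  Strand-agnostic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if genes.labels is None:
        raise ValueError("gene track must carry name labels")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for (chrom, s, e), label in zip(genes.intervals, genes.labels):
        by_chrom.setdefault(chrom, []).append((s, e, label))
    out: dict[str, dict[str, list[tuple[str, int]]]] = {}
    for sv in svs:
        if sv.svtype is SVType.INS:
            sv_start, sv_end = sv.start, sv.start + 1
        else:
            sv_start, sv_end = sv.start, sv.end
        up: list[tuple[int, str]] = []
        over: list[tuple[int, str]] = []
        down: list[tuple[int, str]] = []
        for gs, ge, name in by_chrom.get(sv.chrom, []):
            if ge > sv_start and gs < sv_end:
                over.append((0, name))
            elif ge <= sv_start:
                up.append((sv_start - ge, name))
            else:
                down.append((gs - sv_end, name))
        up.sort()
        down.sort()
        over.sort(key=lambda t: t[1])
        out[sv.id] = {
            "upstream": [(n, -d) for d, n in up[:k]],
            "overlapping": [(n, 0) for _d, n in over],
            "downstream": [(n, d) for d, n in down[:k]],
        }
    return out


def gene_set_overlap(
    genes_sv: set[str], genes_snp: set[str], genes_indel: set[str]
) -> dict[str, object]:
    """Counts for the seven regions of a three-set Venn diagram plus the genes
    present in at least two sets."""
    sv, snp, ind = set(genes_sv), set(genes_snp), set(genes_indel)
    triple = sv & snp & ind
    regions = {
        "sv_only": len(sv - snp - ind),
        "snp_only": len(snp - sv - ind),
        "indel_only": len(ind - sv - snp),
        "sv_snp": len((sv & snp) - ind),
        "sv_indel": len((sv & ind) - snp),
        "snp_indel": len((snp & ind) - sv),
        "all_three": len(triple),
    }
    shared = sorted((sv & snp) | (sv & ind) | (snp & ind))
    return {
        "regions": regions,
        "total_distinct": len(sv | snp | ind),
        "in_two_or_more": shared,
    }
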