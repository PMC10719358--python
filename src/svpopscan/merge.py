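"""Multi-caller consensus and nonredundant cross-sample SV merging.

The matching rule: two SVs of the same type match when their breakpoints lie
within ``max_dist`` (default 1 kb), spanned types (DEL/DUP/INV) additionally
reciprocally overlap by at least ``min_overlap`` (default 40%) of each span,
and insertions additionally have a length difference below ``ins_len_factor``
times the shorter insert.  Cohort-wide merging takes the transitive closure of
this pairwise relation (single linkage) within each (chrom, svtype) stratum.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import Cohort, Genotype, GenotypeMatrix, SVRecord, SVType
from .vcfio import build_genotype_matrix

__all__ = [
    "MergeParams",
    "MergeCluster",
    "CALLER_PRIORITY",
    "filter_raw_calls",
    "sv_match",
    "within_sample_consensus",
    "merge_cohort",
    "compare_callsets",
]

#: caller priority for consensus genotypes/coordinates, best first
CALLER_PRIORITY: tuple[str, ...] = ("cuteSV", "sniffles", "nanovar")


def _caller_rank(caller: str | None) -> int:
    try:
        return CALLER_PRIORITY.index(caller)  # type: ignore[arg-type]
    except ValueError:
        return len(CALLER_PRIORITY)


@dataclass(frozen=True)
class MergeParams:
    """Thresholds of the matching/merging rule and the size window for comparisons."""

    max_dist: int = 1000
    min_overlap: float = 0.40
    ins_len_factor: float = 2.0
    min_len: int = 50
    max_len: int = 50_000
    require_same_type: bool = True
    #: distance rule uses both breakpoints (max) for spanned types; "start" uses start only
    distance_mode: str = "both"
    #: "reciprocal" requires >= min_overlap of both spans; "either" of at least one
    overlap_mode: str = "reciprocal"
    #: insertion-length rule: "literal" |L1-L2| < f*min(L1,L2); "ratio" min/max >= 1/f
    ins_rule: str = "literal"

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")
        if not (0 < self.min_overlap <= 1):
            raise ValueError("min_overlap must be in (0, 1]")
        if self.ins_len_factor <= 0:
            raise ValueError("ins_len_factor must be positive")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be below max_len")
        if self.distance_mode not in ("both", "start"):
            raise ValueError("distance_mode must be 'both' or 'start'")
        if self.overlap_mode not in ("reciprocal", "either"):
            raise ValueError("overlap_mode must be 'reciprocal' or 'either'")
        if self.ins_rule not in ("literal", "ratio"):
            raise ValueError("ins_rule must be 'literal' or 'ratio'")


@dataclass
class MergeCluster:
    """A connected set of mutually matched calls collapsed to one representative."""

    members: list[SVRecord]
    representative: SVRecord
    carrier_samples: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class FilterCounts:
    """Calls removed by each raw-call criterion."""

    low_af: int = 0
    high_depth: int = 0
    bad_length: int = 0


def filter_raw_calls(
    calls: Sequence[SVRecord],
    mean_depth: float,
    params: MergeParams = MergeParams(),
) -> tuple[list[SVRecord], FilterCounts]:
    """Apply the raw-call filter: read-support AF > 0.3, depth < 2x the sample mean,
    and length within [min_len, max_len].  Calls without AF/depth annotations pass
    those criteria.  Order is preserved."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    kept: list[SVRecord] = []
    counts = FilterCounts()
    for c in calls:
        if c.af_read is not None and not c.af_read > 0.3:
            counts.low_af += 1
            continue
        if c.depth is not None and not c.depth < 2 * mean_depth:
            counts.high_depth += 1
            continue
        if not (params.min_len <= c.length <= params.max_len):
            counts.bad_length += 1
            continue
        kept.append(c)
    return kept, counts


def sv_match(a: SVRecord, b: SVRecord, params: MergeParams = MergeParams()) -> bool:
    """Pairwise matching predicate; symmetric and reflexive, total (never raises)."""
    if a.chrom != b.chrom:
        return False
    if params.require_same_type and a.svtype != b.svtype:
        return False
    if a.svtype is SVType.INS and b.svtype is SVType.INS:
        if abs(a.start - b.start) >= params.max_dist:
            return False
        lo, hi = min(a.length, b.length), max(a.length, b.length)
        if params.ins_rule == "literal":
            return (hi - lo) < params.ins_len_factor * lo
        return lo / hi >= 1.0 / params.ins_len_factor
    if a.svtype is SVType.INS or b.svtype is SVType.INS:
        # mixed INS vs spanned (only reachable with require_same_type=False)
        return abs(a.start - b.start) < params.max_dist
    if params.distance_mode == "both":
        dist = max(abs(a.start - b.start), abs(a.end - b.end))
    else:
        dist = abs(a.start - b.start)
    if dist >= params.max_dist:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    frac_a = ov / (a.end - a.start)
    frac_b = ov / (b.end - b.start)
    if params.overlap_mode == "reciprocal":
        return frac_a >= params.min_overlap and frac_b >= params.min_overlap
    return frac_a >= params.min_overlap or frac_b >= params.min_overlap


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _cluster_records(
    records: list[SVRecord], params: MergeParams
) -> list[list[SVRecord]]:
    """Single-linkage clusters under sv_match, computed with a sorted sweep.

    Records are first canonically sorted so the partition is independent of input
    order.  Within a (chrom, svtype) stratum a pair can only match if the start
    difference is below max_dist, which bounds the sweep window.
    """
    records = sorted(records, key=lambda r: (r.sort_key(), r.sample or "", r.caller or ""))
    strata: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, r in enumerate(records):
        key = (r.chrom, r.svtype.value if params.require_same_type else "")
        strata[key].append(i)
    uf = _UnionFind(len(records))
    for idxs in strata.values():
        for wi, i in enumerate(idxs):
            ri = records[i]
            for j in idxs[wi + 1 :]:
                rj = records[j]
                if rj.start - ri.start >= params.max_dist:
                    break
                if sv_match(ri, rj, params):
                    uf.union(i, j)
    groups: dict[int, list[SVRecord]] = defaultdict(list)
    for i, r in enumerate(records):
        groups[uf.find(i)].append(r)
    # deterministic cluster order: by first (sorted) member
    return [groups[root] for root in sorted(groups)]


def _pick_representative(members: list[SVRecord]) -> SVRecord:
    """Most caller support, then highest-priority caller, then smallest start."""
    return min(
        members,
        key=lambda r: (-r.n_callers, _caller_rank(r.caller), r.start, r.end, r.id),
    )


def within_sample_consensus(
    calls_by_caller: Mapping[str, Sequence[SVRecord]],
    params: MergeParams = MergeParams(),
) -> list[SVRecord]:
    """Collapse one sample's per-caller calls into consensus calls.

    A cluster is retained when it is supported by >= 2 distinct callers, or when
    any member is a cuteSV call flagged high-quality.  The emitted genotype and
    coordinates come from the highest-priority caller present
    (cuteSV > sniffles > nanovar).
    """
    all_calls: list[SVRecord] = []
    for caller, calls in calls_by_caller.items():
        for c in calls:
            all_calls.append(c if c.caller == caller else c.with_(caller=caller))
    samples = {c.sample for c in all_calls}
    if len(samples) > 1:
        raise ValueError(f"within_sample_consensus saw multiple samples: {sorted(map(str, samples))}")
    out: list[SVRecord] = []
    for members in _cluster_records(all_calls, params):
        callers = {m.caller for m in members}
        hq_cutesv = any(m.caller == "cuteSV" and m.hq_flag for m in members)
        if len(callers) < 2 and not hq_cutesv:
            continue
        best = min(members, key=lambda m: (_caller_rank(m.caller), m.start, m.id))
        out.append(best.with_(n_callers=len(callers), hq_flag=hq_cutesv or best.hq_flag))
    out.sort(key=SVRecord.sort_key)
    return out


def _consensus_genotype(members: list[SVRecord]) -> Genotype:
    """Highest-priority caller wins; ties go to the more-alternate genotype."""
    typed = [m for m in members if m.genotype is not Genotype.MISSING]
    if not typed:
        return Genotype.HET  # carrier with unknown zygosity
    best_rank = min(_caller_rank(m.caller) for m in typed)
    pool = [m for m in typed if _caller_rank(m.caller) == best_rank]
    return max((m.genotype for m in pool), key=lambda g: g.dosage)


def merge_cohort(
    per_sample_calls: Mapping[str, Sequence[SVRecord]],
    cohort: Cohort,
    params: MergeParams = MergeParams(),
) -> tuple[list[MergeCluster], GenotypeMatrix]:
    """Merge all samples' consensus calls into a nonredundant cohort SV set.

    Clustering is single-linkage under :func:`sv_match` per (chrom, svtype);
    each cluster yields one representative record and one genotype-matrix column
    (samples not carrying the SV are hom-ref).  The result is independent of
    sample and call input order.
    """
    all_calls: list[SVRecord] = []
    for sample, calls in per_sample_calls.items():
        for c in calls:
            all_calls.append(c if c.sample == sample else c.with_(sample=sample))
    clusters: list[MergeCluster] = []
    records_by_variant: dict[str, list[SVRecord]] = {}
    representatives: dict[str, SVRecord] = {}
    for k, members in enumerate(_cluster_records(all_calls, params)):
        rep = _pick_representative(members)
        carriers = {m.sample for m in members if m.sample is not None}
        rep_id = f"sv{k:06d}_{rep.chrom}_{rep.start}_{rep.svtype.value}"
        rep = rep.with_(id=rep_id, sample=None, genotype=Genotype.MISSING)
        by_sample: dict[str, list[SVRecord]] = defaultdict(list)
        for m in members:
            if m.sample is not None:
                by_sample[m.sample].append(m)
        var_records = [
            SVRecord(
                id=rep_id,
                chrom=rep.chrom,
                start=rep.start,
                end=rep.end,
                svtype=rep.svtype,
                length=rep.length,
                sample=s,
                genotype=_consensus_genotype(ms),
            )
            for s, ms in by_sample.items()
        ]
        clusters.append(MergeCluster(members=members, representative=rep, carrier_samples=carriers))
        records_by_variant[rep_id] = var_records
        representatives[rep_id] = rep
    matrix = build_genotype_matrix(records_by_variant, cohort, representatives)
    return clusters, matrix


def compare_callsets(
    query: Sequence[SVRecord],
    reference: Sequence[SVRecord],
    params: MergeParams = MergeParams(),
) -> tuple[int, int, list[tuple[SVRecord, SVRecord]]]:
    """Count query SVs shared with / novel against a reference set.

    Both sets are first restricted to [min_len, max_len].  A query SV is shared
    when it matches at least one reference SV; it is paired with the best match
    (smallest breakpoint distance, then smallest length difference, then id).
    """
    q = [r for r in query if params.min_len <= r.length <= params.max_len]
    ref = [r for r in reference if params.min_len <= r.length <= params.max_len]
    ref_by_chrom: dict[tuple[str, str], list[SVRecord]] = defaultdict(list)
    for r in ref:
        key = (r.chrom, r.svtype.value if params.require_same_type else "")
        ref_by_chrom[key].append(r)
    matched: list[tuple[SVRecord, SVRecord]] = []
    for qr in q:
        key = (qr.chrom, qr.svtype.value if params.require_same_type else "")
        candidates = [r for r in ref_by_chrom.get(key, []) if sv_match(qr, r, params)]
        if candidates:
            best = min(
                candidates,
                key=lambda r: (
                    max(abs(qr.start - r.start), abs(qr.end - r.end)),
                    abs(qr.length - r.length),
                    r.id,
                ),
            )
            matched.append((qr, best))
    shared = len(matched)
    return shared, len(q) - shared, matched
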