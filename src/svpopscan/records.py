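"""Core domain types: structural variants, cohorts, genotype matrices and interval tracks.

Coordinates are 0-based half-open everywhere inside the package; conversion to and
from 1-based VCF happens only at the I/O boundary.  Insertions are represented as
points (``end == start``) with the insert length carried separately.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SVType",
    "Genotype",
    "SVRecord",
    "Cohort",
    "GenotypeMatrix",
    "IntervalSet",
    "GwasCatalog",
    "MISSING",
]

#: sentinel dosage for a missing genotype in integer matrices
MISSING: int = -1


class SVType(str, enum.Enum):
    """The four structural-variant classes handled by the pipeline."""

    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    INV = "INV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Genotype(str, enum.Enum):
    """Diploid genotype of one sample at one biallelic variant."""

    HOM_REF = "0/0"
    HET = "0/1"
    HOM_ALT = "1/1"
    MISSING = "./."

    @property
    def dosage(self) -> int:
        """Alternate-allele count; :data:`MISSING` when unknown."""
        return {"0/0": 0, "0/1": 1, "1/1": 2, "./.": MISSING}[self.value]

    @classmethod
    def from_dosage(cls, d: int) -> "Genotype":
        return {0: cls.HOM_REF, 1: cls.HET, 2: cls.HOM_ALT, MISSING: cls.MISSING}[int(d)]


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call.

    ``start``/``end`` are 0-based half-open.  For DEL/DUP/INV, ``length == end - start``;
    for INS, ``end == start`` and ``length`` is the declared insert length.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    length: int
    caller: str | None = None
    hq_flag: bool = False
    sample: str | None = None
    genotype: Genotype = Genotype.MISSING
    depth: float | None = None
    af_read: float | None = None
    n_callers: int = 1

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.id}: negative start {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.id}: end {self.end} < start {self.start}")
        if self.length < 1:
            raise ValueError(f"{self.id}: non-positive length {self.length}")
        if self.svtype is SVType.INS:
            if self.end != self.start:
                raise ValueError(f"{self.id}: INS must have end == start")
        elif self.length != self.end - self.start:
            raise ValueError(
                f"{self.id}: {self.svtype} length {self.length} != span {self.end - self.start}"
            )

    @property
    def midpoint(self) -> int:
        """Density anchor: span midpoint for spanned types, insertion point for INS."""
        if self.svtype is SVType.INS:
            return self.start
        return (self.start + self.end) // 2

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.start, self.end)

    def with_(self, **kwargs) -> "SVRecord":
        return replace(self, **kwargs)

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.svtype.value, self.id)


@dataclass(frozen=True)
class Cohort:
    """Ordered samples with a two-way population partition (e.g. highland vs lowland cohorts)."""

    samples: tuple[str, ...]
    population: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in cohort")
        missing = [s for s in self.samples if s not in self.population]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, str]]) -> "Cohort":
        items = list(items)
        return cls(tuple(s for s, _ in items), {s: p for s, p in items})

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population[s], None)
        return tuple(seen)

    def members(self, pop: str) -> list[str]:
        return [s for s in self.samples if self.population[s] == pop]

    def indices(self, pop: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.population[s] == pop], dtype=int
        )

    def __len__(self) -> int:
        return len(self.samples)


class GenotypeMatrix:
    """Samples x variants dosage matrix with a derived presence view.

    Dosages are 0/1/2 with :data:`MISSING` (-1) for unknown genotypes.  Presence is
    1 iff dosage >= 1; a missing dosage counts as absent in the presence view (the
    convention used for carrier-frequency statistics) while dosage-based statistics
    exclude missing entries pairwise.
    """

    def __init__(
        self,
        dosage: np.ndarray,
        samples: Sequence[str],
        variant_ids: Sequence[str],
        variants: Sequence[SVRecord] | None = None,
        positions: Sequence[tuple[str, int]] | None = None,
    ):
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        if dosage.shape != (len(samples), len(variant_ids)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(samples)} samples x {len(variant_ids)} variants"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        self.dosage = dosage
        self.samples = list(samples)
        self.variant_ids = list(variant_ids)
        self.variants = list(variants) if variants is not None else None
        if positions is None and variants is not None:
            positions = [(v.chrom, v.start) for v in variants]
        self.positions = list(positions) if positions is not None else None
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def presence(self) -> np.ndarray:
        """0/1 carrier matrix; missing dosage counts as 0."""
        return (self.dosage >= 1).astype(np.int8)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self._variant_index[variant_id]]

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in samples]
        return GenotypeMatrix(
            self.dosage[idx, :], list(samples), self.variant_ids, self.variants, self.positions
        )


@dataclass
class IntervalSet:
    """A named track of (chrom, start, end) half-open intervals with optional labels."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        for chrom, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"{self.name}: empty/inverted interval {chrom}:{s}-{e}")
        order = sorted(range(len(self.intervals)), key=lambda i: self.intervals[i])
        self.intervals = [self.intervals[i] for i in order]
        if self.labels is not None:
            if len(self.labels) != len(self.intervals):
                raise ValueError("labels length mismatch")
            self.labels = [self.labels[i] for i in order]
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        idxs: dict[str, list[int]] = {}
        for i, (chrom, s, e) in enumerate(self.intervals):
            starts.setdefault(chrom, []).append(s)
            ends.setdefault(chrom, []).append(e)
            idxs.setdefault(chrom, []).append(i)
        for chrom in starts:
            self._by_chrom[chrom] = (
                np.array(starts[chrom], dtype=np.int64),
                np.array(ends[chrom], dtype=np.int64),
                idxs[chrom],
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Indices (into ``intervals``) of intervals intersecting [start, end)."""
        if chrom not in self._by_chrom or start >= end:
            return []
        starts, ends, idxs = self._by_chrom[chrom]
        # intervals sorted by start: only those with start < end can intersect
        hi = int(np.searchsorted(starts, end, "left"))
        return [idxs[i] for i in range(hi) if ends[i] > start]

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom or start >= end:
            return False
        starts, ends, _ = self._by_chrom[chrom]
        hi = int(np.searchsorted(starts, end, "left"))
        if hi == 0:
            return False
        return bool(np.max(ends[:hi]) > start)

    def covered_bp(self, chrom_sizes: Mapping[str, int] | None = None) -> int:
        """Total base pairs covered (union of intervals)."""
        total = 0
        for chrom, (starts, ends, _) in self._by_chrom.items():
            cur_s, cur_e = None, None
            for s, e in zip(starts.tolist(), ends.tolist()):
                if chrom_sizes is not None:
                    e = min(e, chrom_sizes.get(chrom, e))
                if cur_e is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
            if cur_e is not None:
                total += cur_e - cur_s
        return total


@dataclass
class GwasCatalog:
    """GWAS-catalog-style table of (snp_id, chrom, pos, phenotype) associations."""

    entries: list[tuple[str, str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for snp_id, _chrom, pos, _pheno in self.entries:
            if not snp_id:
                raise ValueError("empty snp_id in catalog")
            if pos < 0:
                raise ValueError(f"negative position for {snp_id}")
        # deduplicate (snp_id, phenotype) keeping first occurrence
        seen: set[tuple[str, str]] = set()
        unique = []
        for entry in self.entries:
            key = (entry[0], entry[3])
            if key not in seen:
                seen.add(key)
                unique.append(entry)
        self.entries = unique
        self._by_snp: dict[str, list[str]] = {}
        for snp_id, _c, _p, pheno in self.entries:
            self._by_snp.setdefault(snp_id, []).append(pheno)

    def phenotypes_of(self, snp_id: str) -> list[str]:
        return self._by_snp.get(snp_id, [])

    def __len__(self) -> int:
        return len(self.entries)
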