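"""Genome-wide SV density, hotspot calling and repeat enrichment.

Hotspots are intervals where the Gaussian-kernel density of SV midpoints
(bandwidth 200 kb by default) exceeds the (1 - alpha) quantile of the per-trial
*maximum* density under a uniform-replacement null (family-wise control), per
chromosome.  Enrichment of SVs in an annotation track is measured against
random length- and chromosome-preserving re-placements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import IntervalSet, SVRecord, SVType

__all__ = [
    "HotspotParams",
    "HotspotCall",
    "binned_density",
    "density_correlation",
    "kde_hotspots",
    "repeat_enrichment",
]


@dataclass(frozen=True)
class HotspotParams:
    bw: float = 200_000.0
    num_trial: int = 1000
    alpha: float = 0.05
    grid_step: int = 10_000
    #: "max" = family-wise threshold from per-trial maxima; "pointwise" quantile per grid point
    null_mode: str = "max"

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError("bw must be positive")
        if self.num_trial < 1:
            raise ValueError("num_trial must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.null_mode not in ("max", "pointwise"):
            raise ValueError("null_mode must be 'max' or 'pointwise'")


@dataclass
class HotspotCall:
    chrom: str
    start: int
    end: int
    peak_density: float
    empirical_p: float


def binned_density(
    svs: Sequence[SVRecord],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 500_000,
    tracks: Sequence[IntervalSet] | None = None,
) -> pd.DataFrame:
    """Per-bin counts of SVs by type (and of track intervals), 500 kb bins by default.

    An SV falls in the bin containing its midpoint; the last partial bin is kept.
    Rows are (chrom, bin_start, bin_end); columns DEL/INS/DUP/INV plus one per track.
    """
    rows = []
    index = {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_bins = max(1, math.ceil(size / bin_size))
        for b in range(n_bins):
            index[(chrom, b)] = len(rows)
            rows.append((chrom, b * bin_size, min((b + 1) * bin_size, size)))
    cols = [t.value for t in SVType]
    if tracks:
        cols += [t.name for t in tracks]
    data = np.zeros((len(rows), len(cols)), dtype=int)
    col_index = {c: i for i, c in enumerate(cols)}
    for sv in svs:
        if sv.chrom not in chrom_sizes:
            raise ValueError(f"SV {sv.id} on unknown chromosome {sv.chrom}")
        b = min(sv.midpoint // bin_size, math.ceil(chrom_sizes[sv.chrom] / bin_size) - 1)
        data[index[(sv.chrom, b)], col_index[sv.svtype.value]] += 1
    if tracks:
        for t in tracks:
            for chrom, s, e in t.intervals:
                if chrom not in chrom_sizes:
                    continue
                mid = (s + e) // 2
                b = min(mid // bin_size, math.ceil(chrom_sizes[chrom] / bin_size) - 1)
                data[index[(chrom, b)], col_index[t.name]] += 1
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "chrom", [r[0] for r in rows])
    df.insert(1, "bin_start", [r[1] for r in rows])
    df.insert(2, "bin_end", [r[2] for r in rows])
    return df


def density_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-bin count columns.

    Constant columns get NaN correlations (flagged undefined) off-diagonal, 1 on
    the diagonal.  Requires >= 3 bins and >= 2 numeric columns.
    """
    numeric = table.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("bin_start", "bin_end") if c in table.columns]
    )
    if len(numeric) < 3:
        raise ValueError("need at least 3 bins")
    if numeric.shape[1] < 2:
        raise ValueError("need at least 2 count columns")
    corr = numeric.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _kde_density(mids: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    """Sum of Gaussian kernels (events per bp) evaluated on the grid."""
    if len(mids) == 0:
        return np.zeros(len(grid))
    z = (grid[:, None] - mids[None, :]) / bw
    return np.exp(-0.5 * z * z).sum(axis=1) / (bw * math.sqrt(2 * math.pi))


def kde_hotspots(
    svs: Sequence[SVRecord],
    chrom_sizes: Mapping[str, int],
    params: HotspotParams = HotspotParams(),
    seed: int = 0,
) -> list[HotspotCall]:
    """Call SV hotspots per chromosome against a uniform permutation null.

    The observed midpoint density is compared with ``num_trial`` uniform
    re-placements of the same number of midpoints; grid runs above the null
    threshold become hotspot calls with an empirical family-wise p-value
    (1 + #trials with max >= observed peak) / (num_trial + 1).
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    for sv in svs:
        by_chrom.setdefault(sv.chrom, []).append(sv.midpoint)
    calls: list[HotspotCall] = []
    for chrom in sorted(by_chrom):
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom}")
        size = chrom_sizes[chrom]
        mids = np.sort(np.array(by_chrom[chrom], dtype=float))
        grid = np.arange(0, size + 1, params.grid_step, dtype=float)
        obs = _kde_density(mids, grid, params.bw)
        null_max = np.empty(params.num_trial)
        null_grid = np.zeros((params.num_trial, len(grid))) if params.null_mode == "pointwise" else None
        for t in range(params.num_trial):
            fake = rng.uniform(0, size, size=len(mids))
            dens = _kde_density(fake, grid, params.bw)
            null_max[t] = dens.max()
            if null_grid is not None:
                null_grid[t] = dens
        if params.null_mode == "max":
            threshold = np.quantile(null_max, 1 - params.alpha)
            above = obs > threshold
        else:
            thresholds = np.quantile(null_grid, 1 - params.alpha, axis=0)
            above = obs > thresholds
        # maximal runs of above-threshold grid points
        i = 0
        while i < len(grid):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grid) and above[j + 1]:
                j += 1
            peak = float(obs[i : j + 1].max())
            p = (1 + int((null_max >= peak).sum())) / (params.num_trial + 1)
            calls.append(
                HotspotCall(
                    chrom=chrom,
                    start=int(grid[i]),
                    end=int(min(grid[j] + params.grid_step, size)),
                    peak_density=peak,
                    empirical_p=p,
                )
            )
            i = j + 1
    return calls


def _overlap_fraction(
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    track: IntervalSet,
) -> float:
    n = len(chroms)
    hits = 0
    for c, s, e in zip(chroms, starts, ends):
        if track.overlaps_any(str(c), int(s), int(e)):
            hits += 1
    return hits / n if n else float("nan")


def repeat_enrichment(
    svs: Sequence[SVRecord],
    track: IntervalSet,
    chrom_sizes: Mapping[str, int],
    n_perm: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Fold enrichment of SV spans in a track against length-preserving random
    re-placement, with a two-sided permutation p-value.

    Returns observed and expected overlap fractions, the fold ratio, the
    permutation p, and the genome-fraction shortcut expectation
    (track bp / genome bp) for reference.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = np.array([sv.chrom for sv in svs])
    starts = np.array(
        [sv.start if sv.svtype is not SVType.INS else sv.start for sv in svs], dtype=np.int64
    )
    ends = np.array(
        [sv.end if sv.svtype is not SVType.INS else sv.start + 1 for sv in svs], dtype=np.int64
    )
    lengths = ends - starts
    observed = _overlap_fraction(chroms, starts, ends, track)
    perm_fracs = np.empty(n_perm)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    for t in range(n_perm):
        max_start = np.maximum(sizes - lengths, 1)
        new_starts = (rng.random(len(svs)) * max_start).astype(np.int64)
        perm_fracs[t] = _overlap_fraction(chroms, new_starts, new_starts + lengths, track)
    expected = float(perm_fracs.mean())
    if expected == 0:
        raise ValueError("expected overlap fraction is zero; fold undefined")
    diff = abs(observed - expected)
    p = (1 + int((np.abs(perm_fracs - expected) >= diff).sum())) / (n_perm + 1)
    genome_bp = sum(chrom_sizes.values())
    return {
        "observed": observed,
        "expected": expected,
        "fold": observed / expected,
        "p": p,
        "expected_genome_fraction": track.covered_bp(chrom_sizes) / genome_bp,
    }
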