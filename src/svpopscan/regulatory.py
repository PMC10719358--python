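"""Overlap of candidate SVs with regulatory tracks, with breakpoint padding.

Candidate SVs (typically those above an F_ST threshold) are extended by a
tolerance pad (default +/- 100 bp) and intersected, half-open, with enhancer,
silencer, promoter and TAD/loop-boundary tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .records import IntervalSet, SVRecord, SVType

__all__ = ["RegulatoryParams", "extend_breakpoints", "intersect_elements"]


@dataclass
class RegulatoryParams:
    pad: int = 100
    tracks: list[IntervalSet] = field(default_factory=list)
    #: "hull": pad the whole span; "breakpoints": two pad-windows around each breakpoint
    mode: str = "hull"

    def __post_init__(self) -> None:
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        names = [t.name for t in self.tracks]
        if len(set(names)) != len(names):
            raise ValueError("track names must be unique")
        if self.mode not in ("hull", "breakpoints"):
            raise ValueError("mode must be 'hull' or 'breakpoints'")


def extend_breakpoints(sv: SVRecord, pad: int) -> tuple[int, int]:
    """Padded half-open interval for an SV: the span +/- pad for spanned types,
    the insertion point +/- pad for INS; clipped at 0."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if sv.svtype is SVType.INS:
        return max(0, sv.start - pad), sv.start + pad
    return max(0, sv.start - pad), sv.end + pad


def _query_windows(sv: SVRecord, params: RegulatoryParams) -> list[tuple[int, int]]:
    if params.mode == "hull" or sv.svtype is SVType.INS:
        return [extend_breakpoints(sv, params.pad)]
    return [
        (max(0, sv.start - params.pad), sv.start + params.pad),
        (max(0, sv.end - params.pad), sv.end + params.pad),
    ]


def intersect_elements(
    svs: Sequence[SVRecord], params: RegulatoryParams
) -> tuple[dict[str, dict[str, list[str]]], dict[str, int]]:
    """Intersect padded SVs with every track.

    Returns
    -------
    table
        SV id -> track name -> labels of overlapped elements (interval
        coordinates when the track is unlabelled).
    summary
        Per-track count of SVs overlapping >= 1 element, plus an ``"any"``
        entry counting SVs overlapping any track at least once.
    """
    table: dict[str, dict[str, list[str]]] = {}
    summary = {t.name: 0 for t in params.tracks}
    summary["any"] = 0
    for sv in svs:
        windows = _query_windows(sv, params)
        per_track: dict[str, list[str]] = {}
        hit_any = False
        for track in params.tracks:
            idx: set[int] = set()
            for s, e in windows:
                idx.update(track.overlapping(sv.chrom, s, e))
            labels = []
            for i in sorted(idx):
                chrom, s, e = track.intervals[i]
                if track.labels is not None and track.labels[i]:
                    labels.append(track.labels[i])
                else:
                    labels.append(f"{chrom}:{s}-{e}")
            per_track[track.name] = labels
            if labels:
                summary[track.name] += 1
                hit_any = True
        if hit_any:
            summary["any"] += 1
        table[sv.id] = per_track
    return table, summary
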