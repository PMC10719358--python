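"""Readers and writers for the standard formats the pipeline touches.

VCF handling goes through :mod:`pysam`; coordinates are converted between VCF
1-based and the package's internal 0-based half-open convention only here.
All readers transparently accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import io
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .records import (
    MISSING,
    Cohort,
    Genotype,
    GenotypeMatrix,
    GwasCatalog,
    IntervalSet,
    SVRecord,
    SVType,
)

__all__ = [
    "SVParseError",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_intervals",
    "read_gwas_catalog",
    "read_cohort",
    "build_genotype_matrix",
]


class SVParseError(ValueError):
    """Record-level parsing failure, carrying the offending position/line."""


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _info_get(info, key: str, default=None):
    """INFO access tolerant of keys absent from the header (pysam raises)."""
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _gt_from_tuple(gt: tuple | None) -> Genotype:
    if gt is None:
        return Genotype.MISSING
    alleles = [a for a in gt if a is not None]
    if len(alleles) < 2:
        # partially genotyped (./1): treated as missing, see package docs
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a != 0)
    return Genotype.from_dosage(min(n_alt, 2))


def read_sv_vcf(
    path: str | os.PathLike,
    sample: str | None = None,
    hq_key: str = "HQ",
    caller: str | None = None,
) -> tuple[list[SVRecord], int]:
    """Load SV records from a VCF 4.x file.

    Parameters
    ----------
    path
        VCF file; ``SVTYPE`` required in INFO, ``END`` or ``SVLEN`` required for
        non-insertion records.
    sample
        Sample whose FORMAT/GT is attached to each record; defaults to the first
        sample in the file (if any).
    hq_key
        INFO flag marking caller high-quality calls.
    caller
        Caller name to stamp on records when the VCF does not carry one in the
        ``CALLER`` INFO key.

    Returns
    -------
    (records, n_skipped)
        Parsed records and the count of records skipped for an unknown SVTYPE.
    """
    records: list[SVRecord] = []
    n_skipped = 0
    with pysam.VariantFile(os.fspath(path)) as vf:
        vcf_samples = list(vf.header.samples)
        use_sample = sample if sample is not None else (vcf_samples[0] if vcf_samples else None)
        for line_no, rec in enumerate(vf, start=1):
            info = rec.info
            if "SVTYPE" not in info:
                raise SVParseError(f"{path}: record {line_no} ({rec.chrom}:{rec.pos}) lacks SVTYPE")
            svtype_raw = info["SVTYPE"]
            try:
                svtype = SVType(svtype_raw)
            except ValueError:
                n_skipped += 1
                continue
            start = rec.pos - 1  # VCF POS is 1-based
            svlen = _info_get(info, "SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svtype is SVType.INS:
                if svlen is not None:
                    length = abs(int(svlen))
                elif rec.alts and rec.alts[0] and not rec.alts[0].startswith("<"):
                    length = max(len(rec.alts[0]) - len(rec.ref or ""), 1)
                else:
                    raise SVParseError(
                        f"{path}: INS record {line_no} ({rec.chrom}:{rec.pos}) lacks SVLEN/sequence"
                    )
                end = start
            else:
                end_info = _info_get(info, "END", rec.stop if rec.stop > rec.pos else None)
                if end_info is not None and int(end_info) > start + 1:
                    end = int(end_info)  # VCF END is 1-based inclusive == 0-based exclusive
                    length = end - start
                elif svlen is not None:
                    length = abs(int(svlen))
                    end = start + length
                else:
                    raise SVParseError(
                        f"{path}: record {line_no} ({rec.chrom}:{rec.pos}) lacks both END and SVLEN"
                    )
            gt = Genotype.MISSING
            if use_sample is not None and use_sample in rec.samples:
                gt = _gt_from_tuple(rec.samples[use_sample].get("GT"))
            rec_caller = _info_get(info, "CALLER", caller)
            depth = _info_get(info, "DP")
            af = _info_get(info, "AF")
            if isinstance(af, tuple):
                af = af[0]
            records.append(
                SVRecord(
                    id=rec.id or f"{rec.chrom}_{rec.pos}_{svtype.value}",
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    length=max(int(length), 1),
                    caller=rec_caller,
                    hq_flag=bool(_info_get(info, hq_key, False)),
                    sample=use_sample,
                    genotype=gt,
                    depth=float(depth) if depth is not None else None,
                    af_read=float(af) if af is not None else None,
                )
            )
    return records, n_skipped


def _vcf_header(records: Sequence[SVRecord], samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=HQ,Number=0,Type=Flag,Description="High-quality call">')
    header.add_line('##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contig_max: dict[str, int] = {}
    for r in records:
        contig_max[r.chrom] = max(contig_max.get(r.chrom, 0), r.end + r.length + 1)
    for chrom, size in contig_max.items():
        header.add_line(f"##contig=<ID={chrom},length={size}>")
    for s in samples:
        header.add_sample(s)
    return header


def write_sv_vcf(
    records: Sequence[SVRecord],
    cohort: Cohort | None,
    path: str | os.PathLike,
    genotypes: Mapping[str, Mapping[str, Genotype]] | None = None,
) -> None:
    """Write records as VCF 4.2, one ALT line per SV, with per-sample GT columns.

    ``genotypes`` maps variant id -> sample -> Genotype; records' own ``genotype``
    and ``sample`` fields are used when it is omitted.  Records must be sorted by
    (chrom, start).
    """
    keys = [(r.chrom, r.start) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, start) before writing")
    samples = list(cohort.samples) if cohort is not None else []
    header = _vcf_header(records, samples)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vf:
        for r in records:
            out = vf.new_record()
            out.chrom = r.chrom
            out.pos = r.start + 1
            out.id = r.id
            out.ref = "N"
            out.alts = (f"<{r.svtype.value}>",)
            out.info["SVTYPE"] = r.svtype.value
            # SVLEN on symbolic ALTs makes htslib recompute END=POS+|SVLEN|
            # (VCF 4.4 padding-base semantics); span types carry END instead
            if r.svtype is SVType.INS:
                out.info["SVLEN"] = r.length
            else:
                out.stop = r.end
            if r.hq_flag:
                out.info["HQ"] = True
            if r.caller:
                out.info["CALLER"] = r.caller
            for s in samples:
                if genotypes is not None:
                    gt = genotypes.get(r.id, {}).get(s, Genotype.HOM_REF)
                elif r.sample == s:
                    gt = r.genotype
                else:
                    gt = Genotype.HOM_REF
                if gt is Genotype.MISSING:
                    out.samples[s]["GT"] = (None, None)
                else:
                    d = gt.dosage
                    out.samples[s]["GT"] = (0, 1) if d == 1 else ((1, 1) if d == 2 else (0, 0))
            vf.write(out)


def read_intervals(path: str | os.PathLike, name: str) -> IntervalSet:
    """Load a BED3+ track (0-based half-open); a 4th column becomes the label."""
    intervals: list[tuple[str, int, int]] = []
    labels: list[str] = []
    any_label = False
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{line_no}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
            if len(parts) >= 4:
                any_label = True
                labels.append(parts[3])
            else:
                labels.append("")
    return IntervalSet(name=name, intervals=intervals, labels=labels if any_label else None)


def read_gwas_catalog(path: str | os.PathLike) -> GwasCatalog:
    """Load a TSV of snp_id / chrom / pos / phenotype rows (header required)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "phenotype": str})
    required = ["snp_id", "chrom", "pos", "phenotype"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    entries = [
        (str(r.snp_id), str(r.chrom), int(r.pos), str(r.phenotype)) for r in df.itertuples()
    ]
    return GwasCatalog(entries=entries)


def read_cohort(path: str | os.PathLike) -> Cohort:
    """Load a two-column TSV (sample, population), with or without a header."""
    items: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0].lower() in ("sample", "sample_id") and not items:
                continue
            items.append((parts[0], parts[1]))
    return Cohort.from_items(items)


def build_genotype_matrix(
    records_by_variant: Mapping[str, Iterable[SVRecord]],
    cohort: Cohort,
    representatives: Mapping[str, SVRecord] | None = None,
) -> GenotypeMatrix:
    """Assemble a samples x variants dosage matrix from per-variant record groups.

    Samples absent from a variant's record group are hom-ref (dosage 0);
    explicitly missing genotypes stay missing.
    """
    variant_ids = list(records_by_variant)
    sample_idx = {s: i for i, s in enumerate(cohort.samples)}
    dosage = np.zeros((len(cohort.samples), len(variant_ids)), dtype=np.int8)
    for j, vid in enumerate(variant_ids):
        for rec in records_by_variant[vid]:
            if rec.sample is None or rec.sample not in sample_idx:
                raise ValueError(f"variant {vid}: sample {rec.sample!r} not in cohort")
            dosage[sample_idx[rec.sample], j] = rec.genotype.dosage
    variants = None
    positions = None
    if representatives is not None:
        variants = [representatives[v] for v in variant_ids]
    return GenotypeMatrix(dosage, list(cohort.samples), variant_ids, variants, positions)
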