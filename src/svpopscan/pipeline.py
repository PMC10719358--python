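"""End-to-end orchestration: simulate -> filter -> consensus -> merge -> popgen
-> selection -> hotspots -> LD bridge -> regulatory overlap, with one report.

A single global seed fans out to per-stage seeds through ``SeedSequence`` so
each stage is reproducible independently of stage order.  Every threshold
actually applied is recorded in the report's ``parameters`` block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import hotspots as hs
from . import ld as ldmod
from . import popgen, regulatory, selection, simulate
from .merge import MergeParams, filter_raw_calls, merge_cohort, within_sample_consensus
from .records import Cohort, GenotypeMatrix
from .simulate import SimParams, TruthTable

logger = logging.getLogger("svpopscan")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    merge: MergeParams = field(default_factory=MergeParams)
    select: selection.SelectionParams = field(default_factory=selection.SelectionParams)
    hotspot: hs.HotspotParams = field(default_factory=lambda: hs.HotspotParams(num_trial=200))
    ld: ldmod.LdParams = field(default_factory=ldmod.LdParams)
    pad: int = 100
    seed: int = 0
    output_dir: str | None = None
    saturation_orders: int = 5
    enrichment_perms: int = 100

    def validate(self) -> None:
        # parameter blocks self-validate in __post_init__; re-run for mutated configs
        for block in (self.sim, self.merge, self.select, self.hotspot, self.ld):
            type(block).__post_init__(block)  # type: ignore[misc]
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence((root, stage)).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full synthetic-cohort pipeline and return a machine-readable report.

    With ``config.output_dir`` set, TSV/BED/Newick/JSON artifacts are written
    there alongside ``report.json``.  Reruns with the same config and seed
    produce identical outputs.
    """
    config.validate()
    sim_params = dataclasses.replace(config.sim, seed=config.seed)
    report: dict[str, Any] = {
        "parameters": {
            "raw_filter_af": 0.3,
            "raw_filter_depth_factor": 2.0,
            "merge_max_dist_bp": config.merge.max_dist,
            "merge_min_overlap": config.merge.min_overlap,
            "sv_length_window_bp": [config.merge.min_len, config.merge.max_len],
            "selection_min_freq": config.select.min_freq,
            "selection_ratio": config.select.ratio,
            "selection_min_fst": config.select.min_fst,
            "selection_top_fst": config.select.top_fst,
            "hotspot_bw_bp": config.hotspot.bw,
            "hotspot_trials": config.hotspot.num_trial,
            "ld_window_bp": config.ld.window,
            "ld_report_cutoff": config.ld.report_cutoff,
            "ld_strong_cutoff": config.ld.strong_cutoff,
            "regulatory_pad_bp": config.pad,
            "seed": config.seed,
        }
    }

    logger.info("stage: simulate (seed=%d)", config.seed)
    truth, true_matrix, cohort = simulate.simulate_cohort_truth(sim_params)
    calls = simulate.simulate_caller_calls(truth, true_matrix, sim_params)

    logger.info("stage: raw filter + within-sample consensus")
    consensus: dict[str, list] = {}
    n_raw = n_filtered = 0
    for sample, per_caller in calls.items():
        filtered = {}
        for caller, recs in per_caller.items():
            kept, _counts = filter_raw_calls(recs, sim_params.mean_depth, config.merge)
            n_raw += len(recs)
            n_filtered += len(kept)
            filtered[caller] = kept
        consensus[sample] = within_sample_consensus(filtered, config.merge)
    report["consensus"] = {
        "raw_calls": n_raw,
        "after_raw_filter": n_filtered,
        "consensus_calls": sum(len(v) for v in consensus.values()),
    }

    logger.info("stage: cohort merge")
    clusters, matrix = merge_cohort(consensus, cohort, config.merge)
    by_type: dict[str, int] = {}
    for cl in clusters:
        by_type[cl.representative.svtype.value] = by_type.get(cl.representative.svtype.value, 0) + 1
    report["merge"] = {"n_svs": len(clusters), "by_type": by_type}

    logger.info("stage: population statistics")
    pop_a, pop_b = cohort.populations
    freqs_all = popgen.carrier_frequency(matrix)
    freqs_a = popgen.carrier_frequency(matrix, cohort.members(pop_a))
    freqs_b = popgen.carrier_frequency(matrix, cohort.members(pop_b))
    spectrum = popgen.af_spectrum(freqs_all, matrix)
    hwe_results, hwe_frac = popgen.hwe_test(matrix)
    fst = popgen.weir_cockerham_fst(matrix, cohort)
    mean_sat, _ = popgen.saturation_curve(
        matrix, config.saturation_orders, _stage_seed(config.seed, 10)
    )
    report["popgen"] = {
        "af_spectrum": {
            "low": spectrum.low,
            "intermediate": spectrum.intermediate,
            "high": spectrum.high,
            "fixed": spectrum.fixed,
            "singletons": spectrum.singletons,
        },
        "hwe_fraction": hwe_frac,
        "weighted_fst": fst.weighted,
        "mean_fst": fst.mean,
        "saturation_final": float(mean_sat[-1]),
    }

    logger.info("stage: selection scan")
    sel_calls = selection.population_specific_svs(freqs_a, freqs_b, fst, config.select)
    positions = {vid: pos for vid, pos in zip(matrix.variant_ids, matrix.positions or [])}
    ranked, n_above = selection.rank_by_fst(fst, config.select.min_fst, positions)
    specific = [c for c in sel_calls if c.direction != "none"]
    report["selection"] = {
        "n_fst_above_threshold": n_above,
        "n_specific": len(specific),
        "n_a_specific": sum(c.direction == "A_specific" for c in specific),
        "n_b_specific": sum(c.direction == "B_specific" for c in specific),
    }

    logger.info("stage: hotspots and density")
    # tag-SNP simulation must precede annotation so catalog rows cover the tags
    snp_matrix = simulate.simulate_linked_snps(true_matrix, truth, sim_params)
    reps = [cl.representative for cl in clusters]
    chrom_sizes = sim_params.chrom_sizes
    density = hs.binned_density(reps, chrom_sizes)
    hotspot_calls = hs.kde_hotspots(
        reps, chrom_sizes, config.hotspot, _stage_seed(config.seed, 11)
    )
    tracks, catalog = simulate.simulate_annotations(sim_params, truth)
    enrich = hs.repeat_enrichment(
        reps, tracks["repeats"], chrom_sizes, config.enrichment_perms, _stage_seed(config.seed, 12)
    )
    report["hotspots"] = {
        "n_hotspots": len(hotspot_calls),
        "hotspot_bp": sum(h.end - h.start for h in hotspot_calls),
        "repeat_fold_enrichment": enrich["fold"],
        "repeat_observed_fraction": enrich["observed"],
    }

    logger.info("stage: LD bridge")
    ld_pairs = ldmod.ld_scan(matrix, snp_matrix, config.ld)
    associations = ldmod.phenotype_bridge(ld_pairs, catalog, config.ld, matrix.n_samples)
    report["ld_bridge"] = {
        "n_pairs_reported": len(ld_pairs),
        "n_strong": sum(1 for _s, _n, r in ld_pairs if r >= config.ld.strong_cutoff),
        "n_associations": len(associations),
        "n_svs_with_phenotype": len({a.sv_id for a in associations}),
    }

    logger.info("stage: regulatory overlap")
    candidate_ids = set(ranked)
    candidates = [r for r in reps if r.id in candidate_ids]
    reg_params = regulatory.RegulatoryParams(
        pad=config.pad,
        tracks=[tracks["enhancers"], tracks["tad_boundaries"]],
    )
    _table, summary = regulatory.intersect_elements(candidates, reg_params)
    report["regulatory"] = {
        "n_candidates": len(candidates),
        "overlap_summary": summary,
    }

    if config.output_dir:
        _write_outputs(config, report, clusters, matrix, cohort, fst, hotspot_calls, associations)
    return report


def _write_outputs(config, report, clusters, matrix, cohort, fst, hotspot_calls, associations):
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(os.path.join(out, "fst.tsv"), "w") as fh:
        fh.write("# svpopscan fst v1\nvariant\ttheta\ta\tb\tc\n")
        for vid, comp in fst.per_site.items():
            theta = "NA" if comp.theta is None else f"{comp.theta:.6g}"
            fh.write(f"{vid}\t{theta}\t{comp.a:.6g}\t{comp.b:.6g}\t{comp.c:.6g}\n")
    with open(os.path.join(out, "hotspots.bed"), "w") as fh:
        for h in hotspot_calls:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.peak_density:.4g}\t{h.empirical_p:.4g}\n")
    with open(os.path.join(out, "associations.tsv"), "w") as fh:
        fh.write("# svpopscan associations v1\nsv\tsnp\tr2\tphenotype\n")
        for a in associations:
            fh.write(f"{a.sv_id}\t{a.snp_id}\t{a.r2:.4f}\t{a.phenotype}\n")
    tree = popgen.cluster_tree(matrix)
    with open(os.path.join(out, "tree.nwk"), "w") as fh:
        fh.write(tree + "\n")
    reps = sorted((cl.representative for cl in clusters), key=lambda r: (r.chrom, r.start))
    from .vcfio import write_sv_vcf

    write_sv_vcf(reps, None, os.path.join(out, "merged.vcf"))
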