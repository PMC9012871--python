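"""End-to-end orchestration: config validation, the full analysis sequence
(bins -> depth -> normalize -> {CBS arm, HMM arm} -> metrics -> recurrence
-> cohort stats) and a one-command demo on simulated data."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from shallowcn import __version__
from shallowcn.bins import (
    BinScheme,
    annotate_bins,
    build_adaptive_bins,
    build_fixed_bins,
    mask_bins,
)
from shallowcn.cbs import assign_copy_states, merge_adjacent_same_state, segment_cbs, write_seg
from shallowcn.coverage import load_depth_table
from shallowcn.fragments import periodicity_score, size_histogram
from shallowcn.genome import GenomeLayout, Track
from shallowcn.hmm import HMMConfig, estimate_tumor_fraction
from shallowcn.metrics import compare_methods, summarize_segments
from shallowcn.normalize import build_panel, normalize_profile
from shallowcn.recurrence import gscore, permutation_significance
from shallowcn.simulate import SimConfig, simulate_cohort, simulate_fragments
from shallowcn.stats import cohort_report

logger = logging.getLogger(__name__)

_SCHEMA: dict = {
    "seed": int,
    "out_dir": str,
    "genome": str,
    "gc_track": str,
    "mappability_track": str,
    "bins_bed": str,
    "depth_table": str,
    "controls": list,
    "cohort_table": str,
    "bins": {"mode": str, "width": int, "n_bins": int, "min_mappable_fraction": float},
    "normalize": {"mode": str, "span": float},
    "cbs": {"alpha": float, "n_perm": int, "gain_threshold": float, "loss_threshold": float},
    "hmm": {
        "normal_grid": list,
        "self_transition": float,
        "emission_df": float,
        "max_iter": int,
        "tol": float,
        "use_autosomes_only": bool,
    },
    "recurrence": {"n_perm": int, "q_threshold": float},
}


def validate_config(config: dict) -> dict:
    """Reject unknown keys (recursively) before any stage runs."""

    def check(block: dict, schema: dict, prefix: str = "") -> None:
        for key, val in block.items():
            if key not in schema:
                raise ValueError(f"unknown config key: {prefix}{key}")
            expected = schema[key]
            if isinstance(expected, dict):
                if not isinstance(val, dict):
                    raise ValueError(f"config key {prefix}{key} must be a mapping")
                check(val, expected, prefix=f"{prefix}{key}.")

    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    check(config, _SCHEMA)
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _require(config: dict, key: str):
    if key not in config:
        raise ValueError(f"pipeline config missing required field: {key}")
    return config[key]


def _analyze(
    scheme: BinScheme,
    controls,
    cases: dict,
    cohort: pd.DataFrame | None,
    out: Path,
    seed: int,
    params: dict,
    manifest: dict,
) -> dict:
    """Shared analysis core over in-memory depth profiles."""
    norm_cfg = params.get("normalize", {})
    cbs_cfg = params.get("cbs", {})
    hmm_cfg_d = params.get("hmm", {})
    rec_cfg = params.get("recurrence", {})

    pon = build_panel(
        controls, scheme, mode=norm_cfg.get("mode", "median"), span=norm_cfg.get("span", 0.3)
    )
    pon.to_tsv(scheme, out / "panel_of_normals.tsv")

    hmm_config = HMMConfig(
        normal_grid=tuple(hmm_cfg_d.get("normal_grid", (0.7, 0.8, 0.9, 0.95, 0.99))),
        self_transition=hmm_cfg_d.get("self_transition", 0.9999),
        emission_df=hmm_cfg_d.get("emission_df", 3.0),
        max_iter=hmm_cfg_d.get("max_iter", 50),
        tol=hmm_cfg_d.get("tol", 1e-3),
        use_autosomes_only=hmm_cfg_d.get("use_autosomes_only", True),
    )

    cbs_sets, hmm_sets, estimates = [], [], {}
    sds_cbs, sds_hmm = [], []
    seg_counts = {"cbs_arm": [], "hmm_arm": []}
    for i, (sid, profile) in enumerate(sorted(cases.items())):
        norm = normalize_profile(profile, pon, scheme, span=norm_cfg.get("span", 0.3))
        segs = segment_cbs(
            norm,
            scheme,
            alpha=cbs_cfg.get("alpha", 0.01),
            n_perm=cbs_cfg.get("n_perm", 1000),
            seed=seed + i,
        )
        segs = merge_adjacent_same_state(
            assign_copy_states(
                segs,
                gain_threshold=cbs_cfg.get("gain_threshold", 0.2),
                loss_threshold=cbs_cfg.get("loss_threshold", -0.2),
            )
        )
        cbs_sets.append(segs)
        hseg, est = estimate_tumor_fraction(norm, scheme, hmm_config)
        hmm_sets.append(hseg)
        estimates[sid] = est
        s_cbs = summarize_segments(norm, segs)
        s_hmm = summarize_segments(norm, hseg)
        sds_cbs.extend(s_cbs.within_segment_sds)
        sds_hmm.extend(s_hmm.within_segment_sds)
        seg_counts["cbs_arm"].append(s_cbs.n_segments)
        seg_counts["hmm_arm"].append(s_hmm.n_segments)

    write_seg(cbs_sets, out / "segments_cbs.seg")
    write_seg(hmm_sets, out / "segments_hmm.seg")
    with open(out / "tumor_fractions.json", "w") as fh:
        json.dump(
            {sid: dataclasses.asdict(est) for sid, est in estimates.items()}, fh, indent=2
        )

    comparison = compare_methods(sds_hmm, sds_cbs) if sds_cbs and sds_hmm else None
    metrics_report = {
        "mean_segments_per_sample": {
            k: float(np.mean(v)) if v else None for k, v in seg_counts.items()
        },
        "within_segment_sd_comparison": None
        if comparison is None
        else {
            "p_value": comparison.p_value,
            "statistic": comparison.statistic,
            "median_hmm_arm": comparison.extra["median_a"],
            "median_cbs_arm": comparison.extra["median_b"],
        },
    }
    with open(out / "method_metrics.json", "w") as fh:
        json.dump(metrics_report, fh, indent=2)

    results: dict = {"metrics": metrics_report, "estimates": estimates}

    if cohort is not None:
        tf_by_sample = {sid: est.tumor_fraction for sid, est in estimates.items()}
        table = cohort.copy()
        table["tumor_fraction"] = table["sample_id"].map(tf_by_sample)
        table.to_csv(out / "cohort_estimates.tsv", sep="\t", index=False)
        report = cohort_report(table)
        with open(out / "cohort_stats.json", "w") as fh:
            json.dump(report, fh, indent=2)
        results["cohort"] = report

        # recurrence over the max-tf sample per malignant dog (HMM arm)
        mal = table[table["group"] == "malignant"]
        by_sid = {ss.sample_id: ss for ss in hmm_sets}
        picked = []
        for dog, grp in mal.groupby("dog_id", sort=False):
            best = grp.loc[grp["tumor_fraction"].idxmax(), "sample_id"]
            if best in by_sid:
                picked.append(by_sid[best])
        if picked:
            rec_results = {}
            for direction in ("gain", "loss"):
                track = gscore(picked, scheme, direction)
                track = permutation_significance(
                    track,
                    picked,
                    scheme,
                    n_perm=rec_cfg.get("n_perm", 1000),
                    seed=seed,
                    q_threshold=rec_cfg.get("q_threshold", 0.25),
                )
                track.to_tsv(scheme, out / f"recurrence_{direction}.tsv")
                track.regions_to_bed(out / f"recurrence_{direction}_regions.bed")
                rec_results[direction] = len(track.significant_regions)
            results["recurrence_regions"] = rec_results

    manifest["stages"] = manifest.get("stages", []) + [
        "panel",
        "normalize",
        "cbs_arm",
        "hmm_arm",
        "metrics",
    ] + (["cohort_stats", "recurrence"] if cohort is not None else [])
    manifest["parameters"] = {
        "normalize": {"mode": pon.mode, "span": norm_cfg.get("span", 0.3)},
        "cbs": {
            "alpha": cbs_cfg.get("alpha", 0.01),
            "n_perm": cbs_cfg.get("n_perm", 1000),
            "gain_threshold": cbs_cfg.get("gain_threshold", 0.2),
            "loss_threshold": cbs_cfg.get("loss_threshold", -0.2),
        },
        "hmm": dataclasses.asdict(hmm_config),
        "recurrence": {
            "n_perm": rec_cfg.get("n_perm", 1000),
            "q_threshold": rec_cfg.get("q_threshold", 0.25),
        },
    }
    return results


def run_pipeline(config: dict) -> dict:
    """File-driven end-to-end run. Idempotent given the same config."""
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(_require(config, "out_dir"))
    depth_path = _require(config, "depth_table")
    control_names = _require(config, "controls")
    out.mkdir(parents=True, exist_ok=True)

    bins_cfg = config.get("bins", {})
    if "bins_bed" in config:
        scheme = BinScheme.from_bed(config["bins_bed"])
    else:
        layout = GenomeLayout.from_tsv(_require(config, "genome"))
        gc_track = Track.from_bedgraph(_require(config, "gc_track"))
        map_track = Track.from_bedgraph(_require(config, "mappability_track"))
        if bins_cfg.get("mode", "fixed") == "adaptive":
            scheme = build_adaptive_bins(layout, map_track, bins_cfg.get("n_bins", 5500))
        else:
            scheme = build_fixed_bins(layout, bins_cfg.get("width", 500_000))
        scheme = annotate_bins(scheme, gc_track, map_track)
        scheme = mask_bins(scheme, bins_cfg.get("min_mappable_fraction", 0.9))
        scheme.to_bed(out / "bins.bed")

    profiles = load_depth_table(depth_path, scheme)
    control_ids = set(control_names)
    controls = [p for p in profiles if p.sample_id in control_ids]
    cases = {p.sample_id: p for p in profiles if p.sample_id not in control_ids}
    if len(controls) < 2:
        raise ValueError("config field 'controls' must name >= 2 columns of the depth table")

    cohort = None
    if "cohort_table" in config:
        cohort = pd.read_csv(config["cohort_table"], sep="\t")

    manifest: dict = {"version": __version__, "seed": seed, "config": config, "stages": ["bins"]}
    results = _analyze(scheme, controls, cases, cohort, out, seed, config, manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["out_dir"] = str(out)
    return results


def run_demo(seed: int, out_dir, sim_config: SimConfig | None = None, params: dict | None = None) -> dict:
    """Simulate a full cohort and run the complete analysis on it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = sim_config or SimConfig(seed=seed)
    params = params or {}
    bundle = simulate_cohort(config)
    bundle.layout.to_tsv(out / "genome.tsv")
    bundle.scheme.to_bed(out / "bins.bed")
    bundle.cohort.to_csv(out / "cohort_truth.tsv", sep="\t", index=False)

    rng = np.random.default_rng(seed)
    frags = simulate_fragments(config, 100_000, rng, sample_id="demo_fragments")
    prof = size_histogram(frags)
    prof.periodicity_score = periodicity_score(prof)
    prof.to_tsv(out / "fragment_histogram.tsv")
    prof.summary_json(out / "fragment_profile.json")

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "sim_config": dataclasses.asdict(config),
        "stages": ["simulate", "bins", "fragmentomics"],
    }
    cohort = bundle.cohort.rename(columns={"true_tf": "truth_tf"})
    results = _analyze(
        bundle.scheme, bundle.controls, bundle.cases, cohort, out, seed, params, manifest
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["fragment_modal_size"] = prof.modal_size
    results["out_dir"] = str(out)
    return results
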