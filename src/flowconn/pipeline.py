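"""End-to-end pipeline driver: synth -> flow -> group/assortativity -> classifier.

A single :class:`RunConfig` (JSON/YAML-serializable dict of plain values)
drives every stage; a master seed deterministically spawns per-stage child
seeds so each stage is reproducible independently of which stages are
enabled.  Every stage writes its outputs under its own subdirectory and
registers them in a manifest; the bundle records the config snapshot and all
seeds for provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import ModelConfig, run_ensemble
from .flow import InformationFlow
from .group import (compare_groups, mean_group_matrix, permutation_null,
                    pool_group_values, subsample_shape_features, top_k)
from .io import (write_flow_matrix, write_group_stats, write_ranked_connections,
                 write_raw_recording, write_roi_series)
from .synthetic import (CONCUSSED, CONTROL, gen_raw_eeg_cohort, gen_var_cohort)
from .topology import compare_assortativity, degree_assortativity

log = logging.getLogger("flowconn")

STAGES = ("synth", "ifr", "group", "assort", "concnet")


@dataclass
class RunConfig:
    out_dir: str = "flowconn_out"
    stages: tuple = STAGES
    seed: int = 0
    # synthetic cohort
    n_per_group: int = 6
    group_gain: float = 1.5
    n_samples: int = 5000
    dt: float = 0.004
    # classifier cohort
    n_per_class: int = 6
    fs: float = 250.0
    duration: float = 40.0
    class_effect_size: float = 1.0
    # analysis parameters
    threshold: float = 0.05
    n_perm: int = 100
    subsample_k: int = 6
    subsample_reps: int = 100_000
    repeats: int = 1
    folds: int = 3
    time_decimation: int = 10
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence(
            [self.seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class ResultBundle:
    manifests: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def save(self, out_dir: Path):
        (out_dir / "manifest.json").write_text(json.dumps(
            {"manifests": self.manifests, "provenance": self.provenance},
            indent=1, default=str))
        (out_dir / "results.json").write_text(json.dumps(
            self.results, indent=1, default=float))


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the enabled stages in dependency order."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(provenance={
        "config": asdict(config), "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
    })

    cohort = None
    matrices = None
    if "synth" in config.stages:
        cohort = _stage_synth(config, out, bundle)
    if "ifr" in config.stages:
        if cohort is None:
            raise ValueError("ifr stage requires the synth stage")
        matrices = _stage_ifr(config, out, bundle, cohort)
    if "group" in config.stages:
        _stage_group(config, out, bundle, cohort, matrices)
    if "assort" in config.stages:
        _stage_assort(config, out, bundle, cohort, matrices)
    if "concnet" in config.stages:
        _stage_concnet(config, out, bundle)
    bundle.save(out)
    return bundle


def _stage_synth(config, out, bundle):
    seed = config.stage_seed("synth")
    from .synthetic import default_coupling_spec
    base = default_coupling_spec(dt=config.dt, n_samples=config.n_samples)
    cohort = gen_var_cohort(config.n_per_group, base_spec=base,
                            group_gain=config.group_gain, seed=seed)
    d = out / "synth"
    d.mkdir(exist_ok=True)
    files = []
    for ts in cohort.participants:
        files.append(str(write_roi_series(ts, d / f"{ts.participant_id}.csv")))
    manifest = {"files": files,
                "labels": dict(zip([p.participant_id
                                    for p in cohort.participants],
                                   cohort.group_labels))}
    (d / "labels.json").write_text(json.dumps(manifest["labels"], indent=1))
    bundle.manifests["synth"] = manifest
    log.info("synth: %d participants written", len(files))
    return cohort


def _stage_ifr(config, out, bundle, cohort):
    d = out / "ifr"
    d.mkdir(exist_ok=True)
    est = InformationFlow(dt=config.dt)
    matrices, files = [], []
    for ts in cohort.participants:
        fm = est.matrix(ts)
        matrices.append(fm)
        files.extend(map(str, write_flow_matrix(fm, d / ts.participant_id)))
    bundle.manifests["ifr"] = {"files": files}
    log.info("ifr: %d flow matrices", len(matrices))
    return matrices


def _split_groups(cohort, matrices):
    groups = {CONTROL: [], CONCUSSED: []}
    for fm, lab in zip(matrices, cohort.group_labels):
        groups[lab].append(fm)
    return groups


def _stage_group(config, out, bundle, cohort, matrices):
    if matrices is None:
        raise ValueError("group stage requires the ifr stage")
    seed = config.stage_seed("group")
    d = out / "group"
    d.mkdir(exist_ok=True)
    groups = _split_groups(cohort, matrices)
    files, results = [], {}
    pooled = {}
    for lab, mats in groups.items():
        mean = mean_group_matrix(mats, group_name=lab)
        ranked = top_k(mean, k=10)
        files.append(str(write_ranked_connections(
            ranked, d / f"top10_{lab}.csv")))
        pooled[lab] = pool_group_values(mats, group_name=lab)
        n_active = sum(1 for *_ , v in top_k(mean, k=mean.n_rois ** 2)
                       if v > config.threshold)
        null = permutation_null(
            [ts for ts, g in zip(cohort.participants, cohort.group_labels)
             if g == lab], n_perm=config.n_perm, seed=seed)
        results[lab] = {"top10": ranked, "n_active": n_active,
                        "pooled": pooled[lab].summary(),
                        "perm_p95": null.p95, "perm_p5": null.p5}
        feats = subsample_shape_features(
            mats, k=min(config.subsample_k, len(mats)),
            reps=config.subsample_reps, seed=seed)
        np.savetxt(d / f"subsample_features_{lab}.csv", feats.triplets,
                   delimiter=",", header="cov,skewness,kurtosis", comments="")
        files.append(str(d / f"subsample_features_{lab}.csv"))
    comp = compare_groups(pooled[CONCUSSED], pooled[CONTROL])
    results["comparison"] = vars(comp)
    files.append(str(write_group_stats(
        {lab: pooled[lab].summary() for lab in groups},
        d / "group_stats.csv")))
    (d / "comparison.json").write_text(json.dumps(vars(comp), indent=1))
    bundle.manifests["group"] = {"files": files}
    bundle.results["group"] = results


def _stage_assort(config, out, bundle, cohort, matrices):
    if matrices is None:
        raise ValueError("assort stage requires the ifr stage")
    d = out / "assort"
    d.mkdir(exist_ok=True)
    groups = _split_groups(cohort, matrices)
    rws = {lab: [degree_assortativity(m) for m in mats]
           for lab, mats in groups.items()}
    comp = compare_assortativity(rws[CONCUSSED], rws[CONTROL])
    rows = [f"{r.participant_id},{lab},{r.r_w}"
            for lab, rs in rws.items() for r in rs]
    (d / "rw_per_participant.csv").write_text(
        "participant_id,group,r_w\n" + "\n".join(rows) + "\n")
    (d / "comparison.json").write_text(json.dumps(vars(comp), indent=1))
    bundle.manifests["assort"] = {
        "files": [str(d / "rw_per_participant.csv"),
                  str(d / "comparison.json")]}
    bundle.results["assort"] = vars(comp)


def _stage_concnet(config, out, bundle):
    seed = config.stage_seed("concnet")
    d = out / "concnet"
    d.mkdir(exist_ok=True)
    cohort = gen_raw_eeg_cohort(config.n_per_class, fs=config.fs,
                                duration=config.duration,
                                class_effect_size=config.class_effect_size,
                                seed=seed)
    mc = ModelConfig(time_decimation=config.time_decimation, seed=seed)
    metrics = run_ensemble(cohort, mc, seed=seed, repeats=config.repeats,
                           folds=config.folds)
    (d / "metrics.json").write_text(json.dumps(
        {"summary": metrics.summary, "total_cm": metrics.total_cm,
         "misclassification": metrics.misclassification},
        indent=1, default=float))
    np.savetxt(d / "median_roc.csv",
               np.column_stack([metrics.median_roc["fpr"],
                                metrics.median_roc["tpr"]]),
               delimiter=",", header="fpr,tpr", comments="")
    bundle.manifests["concnet"] = {
        "files": [str(d / "metrics.json"), str(d / "median_roc.csv")]}
    bundle.results["concnet"] = {"summary": metrics.summary,
                                 "total_cm": metrics.total_cm}
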