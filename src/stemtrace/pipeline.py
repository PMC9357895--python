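"""End-to-end orchestration with a single config, seed fan-out and a manifest.

``run_pipeline`` executes simulate -> preprocess -> dayspec -> cluster ->
diff -> compare.  Stage toggles control which stages *write their outputs*;
the in-memory chain always preprocesses the simulated raw matrix so that
later stages never see unnormalized data with missing entries.  Every
stochastic stage receives its own substream seed derived deterministically
from the single run seed, and the manifest records the config, package
version, stage status and a sha256 checksum of every output file, so a
re-run of the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    build_profiles,
    kmeans_profiles,
    peak_day_clusters,
    replicate_composition,
    top_shared_proteins,
)
from .dayspec import day_specific_sets, scan_threshold, zscore_abundance
from .differential import log_transform, moderated_t_test, volcano_table
from .preprocess import preprocess, write_matrix
from .reference import compare_conditions
from .simulate import SimConfig, simulate_condition_pair, simulate_timecourse, write_truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "dayspec", "cluster", "diff", "compare")


def _stage_seed(seed: int, index: int) -> int:
    """Deterministic substream seed for stage ``index`` (kept below 2**31)."""
    return (seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1)


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run."""

    out_dir: str = "stemtrace_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    dayspec: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    diff: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        stages = {s: True for s in STAGES}
        stages.update(self.stages or {})
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        self.stages = stages

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; write outputs and manifest; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": {},
    }
    written: dict[str, list[str]] = {}

    def emit(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        written.setdefault(stage, []).append(name)

    current = "simulate"
    try:
        # ---- simulate -----------------------------------------------------
        sim_cfg = SimConfig(**{**config.sim, "seed": _stage_seed(config.seed, 0)})
        matrix, meta, truth = simulate_timecourse(sim_cfg)
        if config.stages["simulate"]:
            emit("simulate", "matrix.tsv", lambda p: write_matrix(matrix, meta, p, out / "samples.tsv"))
            written["simulate"].append("samples.tsv")
            write_truth(truth, out)
            written["simulate"] += ["truth_proteins.tsv", "truth_sample_scales.tsv"]

        # ---- preprocess (always computed for the in-memory chain) ---------
        current = "preprocess"
        pp = config.preprocess
        processed, factors = preprocess(
            matrix,
            min_unique_peptides=pp.get("min_unique_peptides", 3),
            normalize=pp.get("normalize", True),
        )
        if config.stages["preprocess"]:
            emit("preprocess", "normalized.tsv", lambda p: write_matrix(processed, meta, p))
            emit(
                "preprocess",
                "scale_factors.tsv",
                lambda p: factors.rename_axis("sample_id").to_csv(p, sep="\t"),
            )

        # ---- day specificity ----------------------------------------------
        current = "dayspec"
        if config.stages["dayspec"]:
            ds = config.dayspec
            res = zscore_abundance(processed, meta, log=ds.get("log", False))
            res = day_specific_sets(res, ds.get("threshold", 1.5))
            emit("dayspec", "zscores.tsv", lambda p: res.zscores.to_csv(p, sep="\t"))
            for day, proteins in res.specific_sets.items():
                name = f"day_{day}_specific.tsv"
                emit(
                    "dayspec",
                    name,
                    lambda p, proteins=proteins: Path(p).write_text(
                        "protein_id\n" + "".join(f"{x}\n" for x in proteins)
                    ),
                )
            if ds.get("scan", True):
                scan = scan_threshold(res, tol=ds.get("tol", 0.05))
                emit(
                    "dayspec",
                    "threshold_scan.tsv",
                    lambda p: scan.table.to_csv(p, sep="\t", index=False),
                )

        # ---- clustering ----------------------------------------------------
        current = "cluster"
        if config.stages["cluster"]:
            cl = config.cluster
            profiles = build_profiles(processed, meta, norm=cl.get("norm", "sum"))
            k = min(cl.get("k", 20), len(profiles.profiles))
            model = kmeans_profiles(
                profiles,
                k=k,
                seed=_stage_seed(config.seed, 3),
                restarts=cl.get("restarts", 10),
            )
            emit(
                "cluster",
                "assignments.tsv",
                lambda p: model.assignment.to_frame().to_csv(p, sep="\t"),
            )
            emit("cluster", "centroids.tsv", lambda p: model.centroids.to_csv(p, sep="\t"))
            comp = replicate_composition(model, profiles)
            emit("cluster", "replicate_composition.tsv", lambda p: comp.to_csv(p, sep="\t"))
            peaks = peak_day_clusters(model)
            peak_rows = [
                {"day": d, "clusters": ",".join(map(str, cs))} for d, cs in peaks.items()
            ]
            emit(
                "cluster",
                "peak_days.tsv",
                lambda p: pd.DataFrame(peak_rows).to_csv(p, sep="\t", index=False),
            )
            for day, clusters in peaks.items():
                for cluster_id in clusters[:1]:  # leading cluster per day
                    tab = top_shared_proteins(
                        model, profiles, processed, meta, cluster_id, n=cl.get("top_n", 10)
                    )
                    emit(
                        "cluster",
                        f"top_shared_day{day}_cluster{cluster_id}.tsv",
                        lambda p, tab=tab: tab.to_csv(p, sep="\t"),
                    )

        # ---- differential abundance ----------------------------------------
        current = "diff"
        if config.stages["diff"]:
            dc = config.diff
            logm = log_transform(processed, dc.get("pseudocount", 1.0))
            days = sorted(meta["day"].unique())
            pairs = list(zip(days, days[1:]))
            if len(days) > 2:
                pairs.append((days[0], days[-1]))
            for g1, g2 in pairs:
                result = moderated_t_test(
                    logm,
                    meta,
                    g1,
                    g2,
                    prior=dc.get("prior", "fit"),
                    p_cutoff=dc.get("p_cutoff", 0.05),
                    lfc_cutoff=dc.get("lfc_cutoff", 1.0),
                )
                tab = result.table.join(volcano_table(result)[["class"]])
                tab = tab.sort_values("p_adjusted", kind="mergesort")
                emit(
                    "diff",
                    f"diff_day{g1}_vs_day{g2}.tsv",
                    lambda p, tab=tab: tab.to_csv(p, sep="\t"),
                )

        # ---- reference comparison -------------------------------------------
        current = "compare"
        if config.stages["compare"]:
            cc = dict(config.compare)
            conditions = tuple(cc.pop("conditions", ("NM", "OM")))
            timepoints = tuple(cc.pop("timepoints", (10, 17)))
            derived, dmeta, refm, rmeta, _ = simulate_condition_pair(
                conditions=conditions,
                timepoints=timepoints,
                seed=_stage_seed(config.seed, 5),
                **cc,
            )
            reports = compare_conditions(
                derived, dmeta, refm, rmeta, conditions, timepoints
            )
            rows = [
                {
                    "label": r.label,
                    "n_shared": len(r.shared_proteins),
                    "r_full": r.r_full,
                    "top_influencer": r.top_influencer,
                    "delta_r": float(r.influence[r.top_influencer]),
                    "r_without_top": r.r_without_top,
                }
                for r in reports
            ]
            emit(
                "compare",
                "comparison_report.tsv",
                lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False),
            )
            for r in reports:
                emit(
                    "compare",
                    f"influence_{r.label}.tsv",
                    lambda p, r=r: r.influence.to_csv(p, sep="\t"),
                )
    except Exception as exc:
        logger.exception("pipeline failed in stage %r", current)
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    for stage in STAGES:
        if config.stages[stage]:
            files = written.get(stage, [])
            manifest["stages"][stage] = {
                "status": "completed",
                "outputs": {name: _sha256(out / name) for name in sorted(files)},
            }
        else:
            manifest["stages"][stage] = {"status": "skipped", "outputs": {}}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
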