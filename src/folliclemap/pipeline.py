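"""End-to-end orchestration: simulate -> features -> classify -> statistics ->
clustering -> linearization, as one reproducible run.

A run is described by a :class:`RunConfig` (round-trippable through YAML);
every stage writes its tidy table into the output directory and the composite
summary lands in ``summary.json``. Any stage failure is re-raised as a
:class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import classify, composition, apply_exclusion
from .clustering import (
    build_mixed_matrix, club_subtype_split, gower_matrix, subtype_comparison,
    WardClusterer,
)
from .frames import VerticalBands
from .io import write_feature_table, write_swc
from .linearization import evaluate_models
from .stats import crossing_index, gradient_analysis, group_test, polarization_scan
from .synthetic import ClubSubtypeParams, SyntheticConfig, generate_follicle

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger("folliclemap")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one reproducible run needs, with documented defaults."""

    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    scan_step: float = 20.0
    height_split: float = 850.0
    cluster_k: int = 4
    cluster_mode: str = "axonal"
    linearization_cut: float = 0.0
    seed: int = 0
    out_dir: str = "follicle_run"
    write_swc_files: bool = False

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sim = payload.pop("simulate", {})
        if isinstance(sim, dict):
            sub = sim.pop("club_subtype_params", {})
            if isinstance(sub, dict):
                sub = ClubSubtypeParams(**{k: tuple(v) if isinstance(v, list) else v
                                           for k, v in sub.items()})
            sim = SyntheticConfig(club_subtype_params=sub, **sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(simulate=sim, **payload)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write tables, summary and log to ``out_dir``.

    Returns the machine-readable summary dict (also written as summary.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "stage_rows": {}, "warnings": {}}
    try:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        recons, features, truth = _simulate(sim)
        summary["stage_rows"]["simulate"] = len(features)
        if config.write_swc_files:
            swc_dir = out / "swc"
            swc_dir.mkdir(exist_ok=True)
            for r in recons:
                write_swc(r, swc_dir / f"{r.afferent_id}.swc")
        write_feature_table(features, out / "features.csv")
        truth.to_csv(out / "ground_truth.csv", index=False)

        included, log = _exclude(recons)
        log.to_csv(out / "exclusion_log.csv", index=False)
        kept_ids = {r.afferent_id for r in included}
        feats = features[features["afferent_id"].isin(kept_ids)].reset_index(drop=True)
        summary["stage_rows"]["after_exclusion"] = len(feats)

        feats, comp = _classify(feats, sim.bands)
        feats.to_csv(out / "classified_features.csv", index=False)
        comp.as_frame().to_csv(out / "composition.csv", index=False)
        summary["composition_percent"] = comp.percentages
        myel = feats[feats["myelinated"] & ~feats["superficial"]]
        typed = myel[myel["afferent_type"] != "Unclassified"]
        type_comp = composition(
            typed["afferent_type"].value_counts().to_dict()) if len(typed) else None
        if type_comp is not None:
            summary["myelinated_type_percent"] = type_comp.percentages
        summary["warnings"]["unclassified_myelinated"] = int(
            (myel["afferent_type"] == "Unclassified").sum())

        scan = _polarization(feats, config.scan_step)
        scan.to_csv(out / "polarization.csv", index=False)
        summary["polarization_min_p"] = _scan_minima(scan)

        deep_myel = feats[~feats["superficial"] & feats["myelinated"]]
        grad = _gradient(deep_myel, config.height_split)
        summary["gradient"] = {
            "velocity_r": grad.velocity_fit["r"],
            "velocity_slope": grad.velocity_fit["slope"],
            "area_r": grad.area_fit["r"],
            "area_slope": grad.area_fit["slope"],
            "median_diameter_below": grad.median_diameter_below,
            "median_diameter_above": grad.median_diameter_above,
        }

        deep = feats[~feats["superficial"]]
        cross = _crossing(deep)
        cross.to_csv(out / "crossing_index.csv", index=False)
        summary["crossing_index_mean"] = float(cross["crossing_index"].mean())

        gt = _group_test(typed)
        if gt is not None:
            gt.pairwise.to_csv(out / "type_pairwise_tests.csv", index=False)
            summary["fiber_area_kruskal"] = {"H": gt.H, "p": gt.p_value}

        cluster_summary = _cluster(typed, config, out)
        summary.update(cluster_summary)

        lin = _linearize(deep_myel, config.linearization_cut)
        lin.summary().to_csv(out / "linearization.csv", index=False)
        summary["linearization"] = {
            "linear_r": lin.linear["r"], "linear_p": lin.linear["p_value"],
            "radial_r": lin.radial["r"], "radial_p": lin.radial["p_value"],
        }
        summary["layout_mode"] = sim.nerve_layout
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


@_stage("simulate")
def _simulate(sim: SyntheticConfig):
    return generate_follicle(sim)


@_stage("exclusion")
def _exclude(recons):
    return apply_exclusion(recons)


@_stage("classify")
def _classify(feats: pd.DataFrame, bands: VerticalBands):
    feats = feats.copy()
    labels = classify(feats, bands=bands)
    labels = np.where(feats["superficial"], "Superficial", labels)
    labels = np.where(~feats["myelinated"], "Unmyelinated", labels)
    feats["afferent_type"] = labels
    comp = composition({
        "superficial": int(feats["superficial"].sum()),
        "unmyelinated": int((~feats["myelinated"]).sum()),
        "myelinated": int((feats["myelinated"] & ~feats["superficial"]).sum()),
    })
    return feats, comp


@_stage("polarization")
def _polarization(feats: pd.DataFrame, step: float):
    deep = feats[~feats["superficial"]]
    by_class = {
        "myelinated": deep.loc[deep["myelinated"], "terminal_angle"].to_numpy(),
        "unmyelinated": deep.loc[~deep["myelinated"], "terminal_angle"].to_numpy(),
    }
    by_class = {k: v for k, v in by_class.items() if v.size}
    return polarization_scan(by_class, step=step)


def _scan_minima(scan: pd.DataFrame) -> dict:
    out = {}
    for name, sub in scan.groupby("class"):
        sub = sub.dropna(subset=["p_value"])
        if len(sub):
            best = sub.loc[sub["p_value"].idxmin()]
            out[name] = {"cut_deg": float(best["cut_deg"]),
                         "p_value": float(best["p_value"])}
    return out


@_stage("gradient")
def _gradient(deep_myel: pd.DataFrame, split: float):
    return gradient_analysis(
        deep_myel["terminal_height"], deep_myel["fiber_area"],
        deep_myel["conduction_velocity"], split=split)


@_stage("crossing")
def _crossing(deep: pd.DataFrame):
    return crossing_index(
        deep["angle_ref"].to_numpy(), deep["terminal_angle"].to_numpy(),
        deep["arm_id"].to_numpy(), axon_ids=deep["afferent_id"].to_numpy())


@_stage("group_test")
def _group_test(typed: pd.DataFrame):
    groups = {t: g["fiber_area"].to_numpy()
              for t, g in typed.groupby("afferent_type") if len(g)}
    if len(groups) < 2:
        return None
    return group_test(groups)


@_stage("clustering")
def _cluster(typed: pd.DataFrame, config: RunConfig, out: Path) -> dict:
    result: dict = {}
    if len(typed) < config.cluster_k + 1:
        return result
    X = build_mixed_matrix(typed, mode=config.cluster_mode)
    model = WardClusterer(n_clusters=config.cluster_k).fit(gower_matrix(X))
    labels = pd.DataFrame({"afferent_id": typed["afferent_id"].to_numpy(),
                           "cluster": model.labels_})
    labels.to_csv(out / "cluster_labels.csv", index=False)
    pd.DataFrame(model.linkage_,
                 columns=["left", "right", "height", "size"]).to_csv(
        out / "cluster_merges.csv", index=False)
    result["cluster_sizes"] = {
        int(k): int(v) for k, v in labels["cluster"].value_counts().items()}
    club = typed[typed["afferent_type"] == "ClubLike"]
    if len(club) >= 4:
        club, sub_labels = club_subtype_split(typed)
        cmp = subtype_comparison(
            sub_labels,
            {"fiber_area": club["fiber_area"].to_numpy(),
             "median_internode_length": club["median_internode_length"].to_numpy()},
            angles=club["terminal_angle"].to_numpy())
        cmp.table.to_csv(out / "club_subtype_comparison.csv", index=False)
        result["club_subtypes"] = {
            row["variable"]: row["p_value"] for _, row in cmp.table.iterrows()}
    return result


@_stage("linearization")
def _linearize(deep_myel: pd.DataFrame, cut: float):
    ok = deep_myel.dropna(subset=["nerve_entry_x", "nerve_entry_y"])
    return evaluate_models(
        ok[["nerve_entry_x", "nerve_entry_y"]].to_numpy(),
        ok["terminal_angle"].to_numpy(), cut_angle=cut)
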