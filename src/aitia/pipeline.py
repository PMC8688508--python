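"""Pipeline orchestration: clean -> pre-process -> select -> evaluate -> interrogate.

Wires the stages into one reproducible run behind a single configuration.
Stages communicate through files in the output directory, so any stage can
be re-run in isolation, and a manifest records the configuration hash,
per-stage seeds and timings, and a checksum of every artifact; identical
configurations yield identical artifact checksums.

Default conditions are a synthetic 126-record cohort (29 good / 97 poor
outcomes), a reduced classifier battery (logistic regression, linear SVM,
KNN) and the full 5x30 nested cross-validation protocol; the 8-model
battery is one switch away.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (FeatureSet, build_stats_feature_sets,
                           cohort_stats_report, feature_sets_to_json)
from .feature_selection import (DEFAULT_EXPERT_FEATURES, TagaConfig,
                                build_taga_sets, merge_expert_set,
                                rank_feature_sets)
from .interrogation import difficulty_sweep, hardness_profile
from .model_evaluation import CVConfig, default_battery, nested_cv
from .preprocessing import PROCESSED_FEATURES, preprocess_cohort
from .synthetic_data import CohortSpec, generate_raw_cohort, read_cohort_csv, \
    write_cohort_csv

__all__ = ["RunConfig", "run_aitia"]

logging.basicConfig(format="%(name)s: %(message)s")
log = logging.getLogger("aitia")
log.setLevel(logging.INFO)

ALL_STAGES = ("simulate", "preprocess", "stats", "select", "evaluate",
              "interrogate")


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "aitia_run"
    raw_csv: str | None = None            # if None, the simulate stage runs
    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    taga: TagaConfig = dataclasses.field(
        default_factory=lambda: TagaConfig(runs=5, population=20,
                                           generations=20))
    cv: CVConfig = dataclasses.field(default_factory=CVConfig)
    battery_reduced: bool = True
    expert_features: tuple[str, ...] = DEFAULT_EXPERT_FEATURES
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.raw_csv is not None and not Path(self.raw_csv).exists():
            raise FileNotFoundError(self.raw_csv)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("cohort", CohortSpec), ("taga", TagaConfig),
                         ("cv", CVConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "expert_features" in raw:
            raw["expert_features"] = tuple(raw["expert_features"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_aitia(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    Artifacts are written under ``config.out_dir``; a stage failure aborts
    the run with the stage name in the exception, retaining the artifacts
    of completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "versions": {"aitia": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "seeds": {"cohort": config.cohort.seed, "taga": config.taga.seed,
                  "cv": config.cv.seed},
        "stages": {},
        "artifacts": {},
    }
    artifacts: dict[str, Path] = {}

    def _record(name: str, path: Path) -> None:
        artifacts[name] = path
        manifest["artifacts"][name] = {"path": str(path),
                                       "sha256": _sha256(path)}

    def _run_stage(name, fn):
        if name not in config.stages:
            return
        log.info("stage %s: start", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s: done", name)

    state: dict = {}

    def simulate():
        df = generate_raw_cohort(config.cohort)
        path = out / "cohort.csv"
        write_cohort_csv(df, path, config.cohort)
        state["raw"] = df
        _record("cohort", path)

    def preprocess():
        if "raw" in state:
            raw = state["raw"]
        elif config.raw_csv is not None:
            raw = read_cohort_csv(config.raw_csv)
        elif (out / "cohort.csv").exists():
            raw = read_cohort_csv(out / "cohort.csv")
        else:
            raise FileNotFoundError("no raw cohort: run simulate or set raw_csv")
        matrix, report = preprocess_cohort(
            raw, imputation_mode=config.cv.imputation_mode)
        path = out / "processed.csv"
        matrix.to_csv(path, index=False)
        state["matrix"] = matrix.reset_index(drop=True)
        _record("processed", path)
        if report is not None:
            rpath = out / "outlier_report.json"
            report.to_json(rpath)
            _record("outlier_report", rpath)

    def _matrix() -> pd.DataFrame:
        if "matrix" not in state:
            path = out / "processed.csv"
            if not path.exists():
                raise FileNotFoundError("processed matrix missing: run preprocess")
            state["matrix"] = pd.read_csv(path)
        return state["matrix"]

    def stats():
        m = _matrix()
        report = cohort_stats_report(m)
        report.to_json(out / "stats_report.json")
        report.correlation.to_csv(out / "correlation.csv")
        state["stats_report"] = report
        _record("stats_report", out / "stats_report.json")
        _record("correlation", out / "correlation.csv")

    def select():
        m = _matrix()
        y = m["outcome"].to_numpy()
        feats = m[PROCESSED_FEATURES]
        report = state.get("stats_report") or cohort_stats_report(m)
        stats_sets = build_stats_feature_sets(report)
        taga_sets = build_taga_sets(feats, y, config.taga)
        # Best-by-p stats set and the largest TAGA set stand in for the
        # AUC-ranked winners when evaluation has not run yet; the expert
        # combination is validated against their union where possible.
        stats_best = stats_sets[0] if stats_sets else None
        taga_best = taga_sets[-1]
        try:
            if stats_best is None:
                raise ValueError("no statistically-derived set available")
            final = merge_expert_set(stats_best, taga_best,
                                     list(config.expert_features))
        except ValueError as exc:
            log.warning("expert merge fell back to raw expert list (%s)", exc)
            final = FeatureSet("Expert", tuple(config.expert_features),
                               "expert")
        all_sets = stats_sets + taga_sets + [final]
        feature_sets_to_json(all_sets, out / "feature_sets.json")
        state["final_set"] = final
        _record("feature_sets", out / "feature_sets.json")

    def evaluate():
        m = _matrix()
        y = m["outcome"].to_numpy()
        final = state.get("final_set")
        if final is None:
            sets_path = out / "feature_sets.json"
            if not sets_path.exists():
                raise FileNotFoundError("feature sets missing: run select")
            from .cohort_stats import feature_sets_from_json
            final = feature_sets_from_json(sets_path)[-1]
        battery = default_battery(reduced=config.battery_reduced)
        result = nested_cv(m, y, battery, final, config.cv)
        result.metrics.to_csv(out / "cv_metrics.csv", index=False)
        result.mean_oof.to_csv(out / "mean_oof.csv", index=False)
        result.chosen_params.to_csv(out / "chosen_params.csv", index=False)
        # cross-model AUC summary feeds the ranking table when several
        # candidate sets are evaluated; with one set it is a 1-row table
        test = result.metrics[result.metrics["split"] == "test"]
        auc_row = test.groupby("model")["auc"].mean()
        rank = rank_feature_sets(pd.DataFrame([auc_row], index=[final.name]))
        (out / "ranking.json").write_text(json.dumps({
            "winner": rank.winner,
            "summed_rank": rank.summed_rank.to_dict(),
            "auc": rank.auc.to_dict(),
        }, indent=2))
        state["cv_result"] = result
        _record("cv_metrics", out / "cv_metrics.csv")
        _record("mean_oof", out / "mean_oof.csv")
        _record("chosen_params", out / "chosen_params.csv")
        _record("ranking", out / "ranking.json")

    def interrogate():
        m = _matrix()
        y = m["outcome"].to_numpy()
        result = state.get("cv_result")
        if result is not None:
            mean_oof = result.mean_oof
        else:
            path = out / "mean_oof.csv"
            if not path.exists():
                raise FileNotFoundError(
                    "evaluation artifacts missing: run evaluate first")
            mean_oof = pd.read_csv(path)
        profile = hardness_profile(m[PROCESSED_FEATURES], y, mean_oof)
        profile.to_csv(out / "hardness_profile.csv")
        _record("hardness_profile", out / "hardness_profile.csv")
        from .interrogation import correlate_hardness
        try:
            rho = correlate_hardness(profile)
            (out / "hardness_correlations.json").write_text(
                rho.to_json(indent=2))
            _record("hardness_correlations",
                    out / "hardness_correlations.json")
        except ValueError as exc:
            log.warning("hardness correlation skipped: %s", exc)
        for measure, higher in (("kdn", True), ("cld", False)):
            curve = difficulty_sweep(
                mean_oof, y, profile.frame[measure].to_numpy(),
                direction="accumulating-hard", higher_is_harder=higher)
            cpath = out / f"sweep_{measure}.csv"
            curve.to_csv(cpath)
            _record(f"sweep_{measure}", cpath)

    for name, fn in (("simulate", simulate), ("preprocess", preprocess),
                     ("stats", stats), ("select", select),
                     ("evaluate", evaluate), ("interrogate", interrogate)):
        _run_stage(name, fn)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
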