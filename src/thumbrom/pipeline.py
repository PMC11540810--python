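"""Config-driven orchestration: simulate/load -> featurize -> train ->
evaluate -> explain -> report, plus the landmark-noise calibration utility.

An experiment is described by an :class:`ExperimentConfig` (loadable from a
YAML file, see :func:`load_config`).  :func:`run_experiment` executes every
stage, writes a diffable text report tree (``report.json``, ``metrics.csv``,
per-model residual/importance/SHAP CSVs, ``correlations.csv`` and, for
simulated data, ``dataset.csv``) and returns the in-memory report.  All
randomness flows from the config's global seed, so rerunning an identical
config reproduces every number exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluation, explain, features, models, synthetic_hand
from .errors import CalibrationError, ValidationError
from .landmarks_io import LandmarkDataset, read_landmark_table, write_landmark_table

logger = logging.getLogger("thumbrom")


@dataclass
class ExplainConfig:
    models: str | Sequence[str] = "best"   # "best", "all", or explicit names
    n_background: int = 100
    n_instances: int = 40
    n_repeats: int = 10
    metric: str = "r2"


@dataclass
class ExperimentConfig:
    """Full experiment description; exactly one data source must be set."""

    sim: synthetic_hand.SimConfig | None = None
    landmark_path: str | None = None
    normalize_palm_areas: bool = True
    specs: list[models.ModelSpec] = field(default_factory=models.default_specs)
    train_fraction: float = 0.8
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    output_dir: str | None = None
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.landmark_path is None):
            raise ValidationError(
                "config must set exactly one data source (sim or landmark_path)")

    # Component seeds all derive from the single global seed so that a
    # config file with one `seed:` key is fully reproducible.
    def resolved_seeds(self) -> dict[str, int]:
        base = int(self.seed) % (2**31 - 5)
        return {"sim": base, "split": base + 1, "model": base + 2,
                "explain": base + 3, "background": base + 4}


@dataclass
class ExperimentReport:
    config: dict
    metrics: dict[str, dict]
    direct_cc: float | None
    residuals: dict[str, evaluation.ResidualTable]
    correlations: pd.DataFrame
    importances: dict[str, explain.ImportanceTable]
    shap: dict[str, explain.ShapSummary]
    output_dir: str | None


def direct_estimator_cc(dataset: LandmarkDataset,
                        reference: str = "index_mcp_ray") -> float:
    """Pearson CC between the direct geometric estimate and the labels."""
    est = np.array([features.direct_angle_estimate(f, reference) for f in dataset])
    return float(np.corrcoef(dataset.labels(), est)[0, 1])


def calibrate_noise(target_direct_cc: float,
                    sim: synthetic_hand.SimConfig | None = None,
                    tolerance: float = 0.02, n_seeds: int = 5,
                    max_sigma: float = 64.0) -> float:
    """Find the landmark jitter sigma reproducing a target direct-estimator CC.

    The direct estimator's correlation with the commanded angle decreases
    monotonically (in expectation) with the jitter magnitude, so a bisection
    over sigma converges on the smallest sigma whose ensemble-mean CC falls
    within ``tolerance`` of ``target_direct_cc``.  The ensemble averages
    ``n_seeds`` re-simulations of ``sim`` (frontal views required).
    """
    if not (0.0 < target_direct_cc < 1.0):
        raise ValidationError("target CC must lie in (0, 1)")
    if sim is None:
        sim = synthetic_hand.SimConfig()
    if any(a != 0.0 for a in sim.azimuths_deg):
        raise ValidationError("noise calibration requires frontal azimuths only")
    seeds = [sim.seed + 1000 * i for i in range(n_seeds)]

    def mean_cc(sigma: float) -> float:
        ccs = []
        for s in seeds:
            cfg = dataclasses.replace(
                sim, seed=s,
                noise=synthetic_hand.NoiseModel(sigma_px=sigma, seed=None))
            ccs.append(direct_estimator_cc(synthetic_hand.generate_dataset(cfg)))
        return float(np.mean(ccs))

    lo, hi = 0.0, 8.0
    cc_lo = mean_cc(lo)
    if cc_lo < target_direct_cc - tolerance:
        raise CalibrationError(
            f"target CC {target_direct_cc} unreachable: even sigma=0 gives "
            f"CC {cc_lo:.3f}")
    if abs(cc_lo - target_direct_cc) <= tolerance:
        return lo
    cc_hi = mean_cc(hi)
    while cc_hi > target_direct_cc and hi < max_sigma:
        lo, cc_lo = hi, cc_hi
        hi *= 2.0
        cc_hi = mean_cc(hi)
    if cc_hi > target_direct_cc:
        raise CalibrationError(
            f"target CC {target_direct_cc} not bracketed up to sigma "
            f"{max_sigma}: CC({max_sigma}) = {cc_hi:.3f}")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        cc_mid = mean_cc(mid)
        if abs(cc_mid - target_direct_cc) <= tolerance:
            return mid
        if cc_mid > target_direct_cc:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    raise CalibrationError(
        f"bisection did not reach target {target_direct_cc} within tolerance "
        f"{tolerance}; bracket sigma [{lo:.3f}, {hi:.3f}]")


def _select_explain_models(cfg: ExplainConfig, metric_rows: dict[str, dict]) -> list[str]:
    if isinstance(cfg.models, str):
        if cfg.models == "all":
            return list(metric_rows)
        if cfg.models == "best":
            if not metric_rows:
                return []
            return [max(metric_rows, key=lambda m: metric_rows[m]["cc"])]
        return [cfg.models]
    return list(cfg.models)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute every stage of the experiment described by ``config``."""
    t0 = time.monotonic()
    seeds = config.resolved_seeds()

    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=seeds["sim"])
        dataset = synthetic_hand.generate_dataset(sim)
        logger.info("simulated %d frames in %.1fs", len(dataset),
                    time.monotonic() - t0)
    else:
        dataset = read_landmark_table(config.landmark_path)
        logger.info("loaded %d frames from %s", len(dataset), config.landmark_path)

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        if config.sim is not None:
            write_landmark_table(dataset, outdir / "dataset.csv")

    table = features.feature_table(dataset, config.normalize_palm_areas)
    corr = explain.correlation_matrix(table) if dataset.labeled else pd.DataFrame()
    direct_cc = direct_estimator_cc(dataset) if dataset.labeled else None

    t1 = time.monotonic()
    bundle = models.fit_all(
        dataset, specs=config.specs,
        split=models.SplitConfig(config.train_fraction, seed=seeds["split"]),
        model_seed=seeds["model"],
        normalize_palm_areas=config.normalize_palm_areas)
    logger.info("fitted %d models in %.1fs", len(bundle.results),
                time.monotonic() - t1)

    metric_rows: dict[str, dict] = {}
    residuals: dict[str, evaluation.ResidualTable] = {}
    for name, result in bundle.results.items():
        y_true = result.predictions["true_angle_deg"].to_numpy()
        y_pred = result.predictions["predicted_angle_deg"].to_numpy()
        metric_rows[name] = evaluation.metrics(y_true, y_pred).as_dict()
        residuals[name] = evaluation.residual_table(y_true, y_pred)

    X = bundle.feature_frame[features.FEATURE_NAMES]
    y = bundle.feature_frame["true_angle_deg"].to_numpy(dtype=float)
    bg_rng = np.random.default_rng(seeds["background"])
    importances: dict[str, explain.ImportanceTable] = {}
    shap_results: dict[str, explain.ShapSummary] = {}
    for name in _select_explain_models(config.explain, metric_rows):
        t2 = time.monotonic()
        result = bundle.results[name]
        test_X = X.iloc[bundle.test_idx]
        importances[name] = explain.permutation_importance(
            result.model, test_X, y[bundle.test_idx],
            metric=config.explain.metric, n_repeats=config.explain.n_repeats,
            seed=seeds["explain"])
        n_bg = min(config.explain.n_background, len(bundle.train_idx))
        bg_idx = bg_rng.choice(bundle.train_idx, size=n_bg, replace=False)
        n_inst = min(config.explain.n_instances, len(bundle.test_idx))
        inst_idx = bg_rng.choice(bundle.test_idx, size=n_inst, replace=False)
        shap_results[name] = explain.shap_summary(
            result.model, X.iloc[inst_idx], X.iloc[bg_idx])
        logger.info("explained %s in %.1fs", name, time.monotonic() - t2)

    report = ExperimentReport(
        config=_config_record(config, seeds), metrics=metric_rows,
        direct_cc=direct_cc, residuals=residuals, correlations=corr,
        importances=importances, shap=shap_results,
        output_dir=str(outdir) if outdir else None)
    if outdir is not None:
        _write_report(report, bundle, outdir, plots=config.plots)
    logger.info("experiment finished in %.1fs", time.monotonic() - t0)
    return report


def _config_record(config: ExperimentConfig, seeds: dict[str, int]) -> dict:
    rec = {
        "seed": config.seed,
        "resolved_seeds": seeds,
        "normalize_palm_areas": config.normalize_palm_areas,
        "train_fraction": config.train_fraction,
        "landmark_path": config.landmark_path,
        "specs": [{"name": s.name, "hyperparameters": s.hyperparameters,
                   "standardize_inputs": s.standardize_inputs}
                  for s in config.specs],
        "explain": dataclasses.asdict(config.explain),
    }
    if config.sim is not None:
        sim = config.sim
        rec["sim"] = {
            "n_subjects": sim.n_subjects,
            "angles_deg": list(sim.angles_deg),
            "frames_per_angle": sim.frames_per_angle,
            "azimuths_deg": list(sim.azimuths_deg),
            "sigma_px": sim.noise.sigma_px,
            "scale_jitter": sim.scale_jitter,
            "camera": dataclasses.asdict(sim.camera),
        }
    return rec


def _write_report(report: ExperimentReport, bundle: models.ResultBundle,
                  outdir: Path, plots: bool = False) -> None:
    bundle.feature_frame.to_csv(outdir / "features.csv", index=False)
    rows = [{"model": name, **vals} for name, vals in report.metrics.items()]
    pd.DataFrame(rows, columns=["model", "rmse", "mae", "r2", "cc", "n"]).to_csv(
        outdir / "metrics.csv", index=False)
    if len(report.correlations):
        report.correlations.to_csv(outdir / "correlations.csv")
    for name, result in bundle.results.items():
        result.predictions.to_csv(outdir / f"predictions_{name}.csv", index=False)
    for name, resid in report.residuals.items():
        frame = resid.frame.copy()
        frame.insert(0, "frame_id",
                     bundle.results[name].predictions["frame_id"].to_numpy())
        frame.to_csv(outdir / f"residuals_{name}.csv", index=False)
        if plots:
            evaluation.residual_plot(resid, outdir / f"residuals_{name}.png",
                                     title=name)
    for name, imp in report.importances.items():
        imp.table.to_csv(outdir / f"importance_{name}.csv", index=False)
    for name, summary in report.shap.items():
        summary.ranking.to_csv(outdir / f"shap_{name}.csv", index=False)
        summary.phi.to_csv(outdir / f"shap_values_{name}.csv", index=False)
    if plots and len(report.correlations):
        explain.correlation_heatmap(report.correlations,
                                    outdir / "correlations.png")
    payload = {
        "config": report.config,
        "direct_estimator_cc": report.direct_cc,
        "metrics": report.metrics,
        "mean_residuals": {k: v.mean_residual for k, v in report.residuals.items()},
        "importance": {k: v.table.set_index("feature")["importance"].to_dict()
                       for k, v in report.importances.items()},
        "shap_ranking": {k: v.ranking["feature"].tolist()
                         for k, v in report.shap.items()},
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# YAML config loading

def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a plain (YAML-loaded) dict."""
    data = raw.get("data", {})
    sim = None
    landmark_path = data.get("landmarks")
    if "simulator" in data:
        simd = dict(data["simulator"])
        noise = synthetic_hand.NoiseModel(
            sigma_px=simd.pop("sigma_px", synthetic_hand.DEFAULT_SIGMA_PX))
        camera_kwargs = simd.pop("camera", {})
        if "principal_point" in camera_kwargs:
            camera_kwargs["principal_point"] = tuple(camera_kwargs["principal_point"])
        sim = synthetic_hand.SimConfig(
            noise=noise, camera=synthetic_hand.CameraPose(**camera_kwargs),
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in simd.items()})
    model_cfg = raw.get("models", {})
    spec_items = model_cfg.get("specs", models.MODEL_NAMES)
    specs = []
    for item in spec_items:
        if isinstance(item, str):
            specs.append(models.ModelSpec(item))
        else:
            specs.append(models.ModelSpec(
                item["name"], item.get("hyperparameters", {}),
                item.get("standardize_inputs")))
    explain_cfg = ExplainConfig(**raw.get("explain", {}))
    return ExperimentConfig(
        sim=sim, landmark_path=landmark_path,
        normalize_palm_areas=raw.get("features", {}).get(
            "normalize_palm_areas", True),
        specs=specs,
        train_fraction=model_cfg.get("train_fraction", 0.8),
        explain=explain_cfg,
        output_dir=raw.get("output_dir"),
        seed=raw.get("seed", 0),
        plots=raw.get("plots", False))


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)
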