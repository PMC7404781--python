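"""End-to-end screening pipeline.

Orchestrates one study run: generate (or load) spectra, select a wavenumber
region, preprocess, fit the chosen one-class classifier on the pure
calibration set, classify every validation set, and write the model,
per-sample classification tables, metrics and a JSON report.  One classifier
per run; runs are compared, not fused.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dataset import SpectrumSet, read_spectra_csv, select_region
from .ddsimca import (
    DDSIMCAModel,
    classify_ddsimca,
    extreme_plot,
    fit_ddsimca,
    select_pcs_by_target_sensitivity,
)
from .metrics import ConfusionSummary, confusion_summary, per_level_detection
from .ocpls import OCPLSModel, classify_ocpls, fit_ocpls, mccv_select_lvs
from .preprocess import PreprocessConfig, apply_preprocess
from .synthetic import generate_study, preset_design

_version = "0.1.0"  # kept in sync with the package version

log = logging.getLogger("specocc.pipeline")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    classifier: str = "ddsimca"                 # exactly one of {ddsimca, ocpls}
    preset: Optional[str] = "separable"         # synthetic preset, or None with paths
    region: str = "mir"
    data_paths: Optional[dict] = None           # {"calibration": ..., "<set name>": ...}
    region_bounds: Optional[tuple[float, float]] = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_components: Optional[int] = 4             # k (DD-SIMCA) or A (OCPLS); None = select
    alpha: float = 0.01
    gamma: float = 0.01
    dof_method: str = "moments"
    mccv_splits: int = 100
    mccv_holdout: float = 0.2
    mccv_max_lvs: int = 10
    select_folds: int = 5
    outlier_refit: bool = True
    convention: str = "results_adulterated_positive"
    outdir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in {"ddsimca", "ocpls"}:
            raise PipelineError(
                f"exactly one classifier per run; got {self.classifier!r}"
            )
        if isinstance(self.preprocess, dict):
            self.preprocess = PreprocessConfig(**self.preprocess)
        if self.preset is None and not self.data_paths:
            raise PipelineError("either a synthetic preset or data_paths is required")
        if self.data_paths:
            missing = [p for p in self.data_paths.values() if not Path(p).exists()]
            if missing:
                raise PipelineError(f"data paths do not exist: {missing}")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = dataclasses.asdict(self)
        doc["preprocess"] = dataclasses.asdict(self.preprocess)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "classifier" in doc and isinstance(doc["classifier"], (list, tuple)):
            raise PipelineError("exactly one classifier per run")
        if doc.get("region_bounds") is not None:
            doc["region_bounds"] = tuple(doc["region_bounds"])
        return cls(**doc)


@dataclass
class RunReport:
    """Everything a run computed, plus provenance."""

    config: RunConfig
    summaries: dict[str, ConfusionSummary]
    per_level: pd.DataFrame
    model_summary: dict
    outdir: Path
    seed: int
    timestamp: str
    version: str = _version

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [s.to_row(group=name) for name, s in self.summaries.items()]
        )


def _load_sets(config: RunConfig) -> dict[str, SpectrumSet]:
    if config.data_paths:
        sets = {name: read_spectra_csv(p) for name, p in config.data_paths.items()}
        if "calibration" not in sets:
            raise PipelineError("data_paths must include a 'calibration' entry")
        return sets
    sets: dict[str, SpectrumSet] = {}
    for adulterant in ("apricot", "peanut"):
        design = preset_design(
            config.preset, region=config.region, adulterant=adulterant, seed=config.seed
        )
        study = generate_study(design)
        sets["calibration"] = study["calibration"]  # adulterant-independent
        sets[f"validation1_{adulterant}"] = study["validation1"]
        sets[f"validation2_{adulterant}"] = study["validation2"]
    return sets


def run_study(config: RunConfig) -> RunReport:
    """Execute one full screening run and write its artifacts.

    Deterministic for a fixed config (including seed).  Writes under
    ``config.outdir``: ``config.yaml``, ``model.json``,
    ``classification_<set>.csv``, ``metrics.csv``, ``per_level.csv``,
    ``report.json`` and ``run.log``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_study(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_study(config: RunConfig, outdir: Path) -> RunReport:
    t0 = time.time()
    config.to_yaml(outdir / "config.yaml")

    stage = "load"
    try:
        sets = _load_sets(config)
        log.info("load: %s", {k: v.n_samples for k, v in sets.items()})

        if config.region_bounds is not None:
            stage = "region"
            lo, hi = config.region_bounds
            sets = {k: select_region(v, lo, hi) for k, v in sets.items()}
            log.info("region [%s, %s]: %d points kept", lo, hi,
                     next(iter(sets.values())).n_points)

        stage = "preprocess"
        msc_ref = sets["calibration"].intensities.mean(axis=0)
        sets = {
            k: apply_preprocess(config.preprocess, v, msc_reference=msc_ref)
            for k, v in sets.items()
        }
        log.info("preprocess: %s", config.preprocess.method)

        calibration = sets["calibration"]
        validation = {k: v for k, v in sets.items() if k != "calibration"}

        stage = "fit"
        model_summary: dict = {"classifier": config.classifier}
        if config.classifier == "ddsimca":
            k = config.n_components
            if k is None:
                sel = select_pcs_by_target_sensitivity(
                    calibration,
                    alpha=config.alpha,
                    gamma=config.gamma,
                    dof_method=config.dof_method,
                    folds=config.select_folds,
                    seed=config.seed,
                )
                k = sel.chosen_k
                model_summary["selection"] = {
                    "candidates": sel.candidates,
                    "acceptance": sel.acceptance,
                }
            model = fit_ddsimca(
                calibration, k, alpha=config.alpha, gamma=config.gamma,
                dof_method=config.dof_method,
            )
            if config.outlier_refit:
                rec = classify_ddsimca(model, calibration)
                keep = (rec["category"] != "outlier").to_numpy()
                if not keep.all() and keep.sum() > model.k:
                    log.info("outlier refit: dropping %d calibration samples",
                             int((~keep).sum()))
                    calibration = calibration.take(np.where(keep)[0])
                    model = fit_ddsimca(
                        calibration, k, alpha=config.alpha, gamma=config.gamma,
                        dof_method=config.dof_method,
                    )
            classify = classify_ddsimca
            model_summary.update(
                k=model.k, N_h=model.N_h, N_v=model.N_v, h0=model.h0, v0=model.v0,
                c_crit=model.c_crit, c_out=model.c_out, alpha=model.alpha,
                gamma=model.gamma, n_train=model.n_train,
            )
            ep = extreme_plot(model, calibration)
            ep.to_frame().to_csv(outdir / "extreme_plot.csv", index=False)
        else:
            A = config.n_components
            if A is None:
                curve = mccv_select_lvs(
                    calibration,
                    max_lvs=config.mccv_max_lvs,
                    splits=config.mccv_splits,
                    holdout_fraction=config.mccv_holdout,
                    seed=config.seed,
                )
                A = curve.chosen_A
                curve.to_frame().to_csv(outdir / "mccv_curve.csv", index=False)
                model_summary["mccv_chosen_A"] = A
            model = fit_ocpls(calibration, A, alpha=config.alpha)
            if config.outlier_refit:
                rec = classify_ocpls(model, calibration)
                keep = rec["accepted"].to_numpy()
                if not keep.all() and keep.sum() > model.A:
                    log.info("outlier refit: dropping %d calibration samples",
                             int((~keep).sum()))
                    calibration = calibration.take(np.where(keep)[0])
                    model = fit_ocpls(calibration, A, alpha=config.alpha)
            classify = classify_ocpls
            model_summary.update(
                A=model.A, t2_limit=model.t2_limit, acr_limit=model.acr_limit,
                residual_sd=model.residual_sd, alpha=model.alpha, n_train=model.n_train,
            )
        model.to_json(outdir / "model.json")
        log.info("fit: %s", model_summary)

        stage = "classify"
        summaries: dict[str, ConfusionSummary] = {}
        level_frames = []
        for name, vset in validation.items():
            rec = classify(model, vset)
            rec = rec.merge(
                vset.meta[["sample_id", "class_label", "concentration"]], on="sample_id"
            )
            rec.to_csv(outdir / f"classification_{name}.csv", index=False)
            summaries[name] = confusion_summary(
                rec["class_label"], rec["accepted"], convention=config.convention
            )
            lv = per_level_detection(rec["concentration"], rec["accepted"])
            lv.insert(0, "set", name)
            level_frames.append(lv)
            log.info("classify %s: n=%d accepted=%d", name, len(rec),
                     int(rec["accepted"].sum()))

        stage = "report"
        per_level = pd.concat(level_frames, ignore_index=True)
        per_level.to_csv(outdir / "per_level.csv", index=False)
        report = RunReport(
            config=config,
            summaries=summaries,
            per_level=per_level,
            model_summary=model_summary,
            outdir=outdir,
            seed=config.seed,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        report.metrics_frame().to_csv(outdir / "metrics.csv", index=False)
        doc = {
            "version": report.version,
            "seed": report.seed,
            "timestamp": report.timestamp,
            "elapsed_s": round(time.time() - t0, 3),
            "model": _jsonable(model_summary),
            "metrics": {
                name: {
                    "counts": {
                        "n_pure": s.n_pure,
                        "n_adulterated": s.n_adulterated,
                        "pure_accepted": s.pure_accepted,
                        "adulterated_rejected": s.adulterated_rejected,
                    },
                    **s.printed(),
                }
                for name, s in summaries.items()
            },
        }
        (outdir / "report.json").write_text(json.dumps(doc, indent=2))
        return report
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def export_plot_data(run_dir: str | Path) -> list[Path]:
    """Export acceptance-plot tables from a completed run directory.

    For DD-SIMCA: per-sample (h, v, c) with the acceptance and outlier
    boundary curves in the (h, v) plane.  For OCPLS: per-sample (t2, acr)
    with the two limit lines.  Tables re-plot to the same categories as the
    classification CSVs.
    """
    run_dir = Path(run_dir)
    model_path = run_dir / "model.json"
    if not model_path.exists():
        raise PipelineError(f"missing run artifact: {model_path}")
    doc = json.loads(model_path.read_text())
    written: list[Path] = []
    if "c_crit" in doc:  # DD-SIMCA run
        model = DDSIMCAModel.from_json(model_path)
        rows = []
        for level, c_level in (("acceptance", model.c_crit), ("outlier", model.c_out)):
            h_max = c_level * model.h0 / model.N_h
            for h in np.linspace(0, h_max, 200):
                rest = c_level - model.N_h * h / model.h0
                v = (
                    rest * model.v0 / model.N_v
                    if not model.degenerate_v and model.N_v > 0
                    else 0.0
                )
                rows.append({"boundary": level, "h": h, "v": v, "c": c_level})
        path = run_dir / "plot_boundaries.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    else:
        model = OCPLSModel.from_json(model_path)
        path = run_dir / "plot_limits.csv"
        pd.DataFrame(
            [
                {"statistic": "t2", "limit": model.t2_limit},
                {"statistic": "acr", "limit": model.acr_limit},
            ]
        ).to_csv(path, index=False)
        written.append(path)
    for cls_path in sorted(run_dir.glob("classification_*.csv")):
        name = cls_path.stem.replace("classification_", "")
        rec = pd.read_csv(cls_path)
        cols = (
            ["sample_id", "h", "v", "c", "category"]
            if "c" in rec.columns
            else ["sample_id", "t2", "acr", "quadrant"]
        )
        path = run_dir / f"plot_points_{name}.csv"
        rec[cols].to_csv(path, index=False)
        written.append(path)
    return written
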