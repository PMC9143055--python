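"""End-to-end orchestration: simulate -> preprocess -> cores -> classify -> refine.

:func:`analyse_dataset` runs the in-memory analysis from raw per-slide runs
plus an annotation table to the full/reduced cross-validation results;
:func:`run_pipeline` wraps it with on-disk inputs/outputs, a stage MANIFEST
and a deterministic JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, PipelineStageError, ValidationError
from .io import MassAxis, PeakList, SpectralMatrix, read_annotations, read_run, \
    write_annotations, write_run
from .synthetic import SimulationConfig, simulate_dataset
from .preprocessing import PreprocessConfig, build_common_axis, estimate_ppm_offset, \
    median_fold_change_normalize, rasterize, reference_intensity_scale, segment_kmeans, \
    spatial_filter_features
from .cores import CoreTable, assign_pixels_to_cores, average_core_spectra, \
    concat_core_tables
from .classify import core_feature_table, cross_validate, slide_aware_stratified_folds
from .features import select_and_refit

logger = logging.getLogger("msitma")

__all__ = ["PipelineConfig", "PipelineResult", "analyse_dataset", "run_pipeline",
           "load_pipeline_config"]

REFERENCE_LABELS = {"reference-kidney", "reference-liver", "reference"}


@dataclass
class PipelineConfig:
    """Composite configuration of the whole workflow."""

    simulation: SimulationConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    core_radius_px: float | None = None  # defaults to the simulation's radius
    n_splits: int = 10
    cv_seed: int = 0
    regularization_strength: float = 1e-2
    threshold: float = 0.5
    alpha: float = 0.05
    reference_scaling: bool = True
    output_dir: str = "msitma-output"

    def validate(self) -> None:
        if self.simulation is not None:
            self.simulation.validate()
        self.preprocess.validate()
        if self.n_splits < 2:
            raise ConfigurationError("n_splits", "must be at least 2")
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold", "must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha", "must lie in (0, 1)")
        if self.radius() is None:
            raise ConfigurationError("core_radius_px", "required when no simulation config is given")

    def radius(self) -> float | None:
        if self.core_radius_px is not None:
            return self.core_radius_px
        return self.simulation.core_radius_px if self.simulation is not None else None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        pre = d.pop("preprocess", None)
        cfg = cls(simulation=SimulationConfig(**sim) if sim else None,
                  preprocess=PreprocessConfig(**pre) if pre else PreprocessConfig(), **d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "preprocess": self.preprocess.to_dict(),
            "core_radius_px": self.radius(),
            "n_splits": self.n_splits, "cv_seed": self.cv_seed,
            "regularization_strength": self.regularization_strength,
            "threshold": self.threshold, "alpha": self.alpha,
            "reference_scaling": self.reference_scaling,
            "output_dir": self.output_dir,
        }


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as f:
        return PipelineConfig.from_dict(yaml.safe_load(f))


@dataclass
class PipelineResult:
    core_table: CoreTable
    refit: "SelectionRefitResult"
    report: dict


def _run_peaklist(run: SpectralMatrix) -> PeakList:
    """Run-level peak list: the run's mean spectrum on its own axis."""
    mean = run.mean_spectrum()
    return PeakList(run.axis.mz, mean, np.zeros_like(mean))


def preprocess_runs(runs: list, annotations: pd.DataFrame, pcfg: PreprocessConfig,
                    radius: float, reference_scaling: bool = True):
    """Common axis + recalibration + rasterisation + ROI + normalisation.

    Returns ``(matrices, tissue_masks, retained_features, info)`` where the
    matrices are on the common axis, restricted to retained features and (when
    enabled) reference-intensity scaled.
    """
    peaklists = [_run_peaklist(r) for r in runs]
    axis = build_common_axis(peaklists, pcfg.ppm_tol)
    offsets = [estimate_ppm_offset(p, axis, pcfg.ppm_tol) for p in peaklists]
    recal = [r.with_intensities(r.intensities,
                                MassAxis(r.axis.mz * (1.0 - off * 1e-6)))
             for r, off in zip(runs, offsets)]
    matrices = rasterize(recal, axis, pcfg.ppm_tol)

    tissue_masks, retained_votes = [], []
    for mat in matrices:
        seg = segment_kmeans(mat, pcfg.kmeans_k, pcfg.kmeans_seed,
                             pcfg.background_tic_fraction)
        mask = seg.tissue_mask
        if not mask.any():  # degenerate segmentation: keep everything
            mask = np.ones(mat.n_pixels, dtype=bool)
        tissue_masks.append(mask)
        retained, _ = spatial_filter_features(mat, mask, pcfg.spatial_filter_min_fraction)
        votes = np.zeros(len(axis), dtype=int)
        votes[retained] = 1
        retained_votes.append(votes)
    # keep features that pass the spatial filter on a majority of runs
    votes = np.sum(retained_votes, axis=0)
    retained_features = np.flatnonzero(votes * 2 >= len(matrices))
    matrices = [m.with_intensities(m.intensities[:, retained_features],
                                   MassAxis(axis.mz[retained_features]))
                for m in matrices]

    scalars = [1.0] * len(matrices)
    if reference_scaling:
        ref_masks = []
        for mat, mask in zip(matrices, tissue_masks):
            ref_ann = annotations[(annotations["slide_id"] == mat.slide_id)
                                  & annotations["label"].isin(REFERENCE_LABELS)]
            if ref_ann.empty:
                raise ValidationError(
                    f"reference_intensity_scale: no reference core annotated on "
                    f"slide '{mat.slide_id}'")
            assigned = assign_pixels_to_cores(mat, ref_ann, radius, mask)
            ref_masks.append(assigned != "")
        matrices, scalars = reference_intensity_scale(matrices, ref_masks)
        scalars = [float(s) for s in scalars]

    info = {"common_axis_size": len(axis),
            "ppm_offsets": {r.run_id: float(o) for r, o in zip(runs, offsets)},
            "retained_features": int(retained_features.size),
            "reference_scalars": {m.run_id: s for m, s in zip(matrices, scalars)}}
    return matrices, tissue_masks, retained_features, info


def extract_cores(matrices: list, tissue_masks: list, annotations: pd.DataFrame,
                  radius: float, mfc: bool = True) -> CoreTable:
    """Per-core average spectra across all runs, MFC-normalised dataset-wide."""
    tables = []
    for mat, mask in zip(matrices, tissue_masks):
        assigned = assign_pixels_to_cores(mat, annotations, radius, mask)
        tables.append(average_core_spectra(mat, assigned, annotations))
    table = concat_core_tables(tables)
    if mfc:
        spectra, _ = median_fold_change_normalize(table.spectra)
        table = CoreTable(table.meta, spectra, table.axis)
    return table


def analyse_dataset(runs: list, annotations: pd.DataFrame, config: PipelineConfig) -> PipelineResult:
    """Run the full in-memory analysis and assemble the report dict."""
    config.validate()
    # output_dir is deployment detail, not an analysis parameter: keeping it
    # out makes reports from identical seeds byte-identical wherever they ran
    report_cfg = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    report = {"config": report_cfg, "stages": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # annotate with the failing stage
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %-16s %6.2fs", name, time.perf_counter() - t0)
        return out

    matrices, masks, retained, info = stage(
        "preprocess", lambda: preprocess_runs(runs, annotations, config.preprocess,
                                              config.radius(), config.reference_scaling))
    report["stages"]["preprocess"] = info

    core_table = stage("extract_cores",
                       lambda: extract_cores(matrices, masks, annotations, config.radius()))
    report["stages"]["extract_cores"] = {
        "n_cores": len(core_table),
        "label_counts": core_table.meta["label"].value_counts().to_dict()}

    def classify_and_refine():
        table = core_feature_table(core_table)
        folds = slide_aware_stratified_folds(table.y, table.slide_ids,
                                             config.n_splits, config.cv_seed)
        return select_and_refit(table, alpha=config.alpha, n_splits=config.n_splits,
                                regularization_strength=config.regularization_strength,
                                folds=folds)

    refit = stage("classify", classify_and_refine)
    report["stages"]["classify"] = {"cv_full": refit.cv_full.to_dict()}
    report["stages"]["feature_selection"] = {
        "n_selected": int(refit.selection.selected.size),
        "selected_mz": [float(core_table.axis.mz[j]) for j in refit.selection.selected],
        "cv_reduced": refit.cv_reduced.to_dict()}
    return PipelineResult(core_table, refit, report)


def demo_run_metrics(seed: int = 1, simulation: SimulationConfig | None = None,
                     with_selection: bool = True) -> dict:
    """Run the bundled demo end to end in memory and return headline metrics.

    Simulates the demo TMA dataset under ``seed`` (or a caller-supplied
    simulation config), runs preprocessing, core extraction and slide-aware
    10-fold cross-validation, and returns the full-model metrics — plus the
    feature-refined model's when ``with_selection`` is set (a no-signal
    simulation has nothing to select, so null studies switch it off).
    """
    from .synthetic import demo_config

    sim = simulation if simulation is not None else demo_config(seed)
    config = PipelineConfig(simulation=sim)
    runs, annotations, truth = simulate_dataset(sim)
    matrices, masks, _, _ = preprocess_runs(runs, annotations, config.preprocess,
                                            config.radius(), config.reference_scaling)
    core_table = extract_cores(matrices, masks, annotations, config.radius())
    table = core_feature_table(core_table)
    folds = slide_aware_stratified_folds(table.y, table.slide_ids,
                                         config.n_splits, config.cv_seed)
    out = {"n_cores": table.n_cores,
           "n_markers_true": int(truth.marker_indices.size)}
    if with_selection:
        refit = select_and_refit(table, alpha=config.alpha, folds=folds,
                                 regularization_strength=config.regularization_strength)
        cv_full, cv_reduced = refit.cv_full, refit.cv_reduced
        out["n_selected"] = int(refit.selection.selected.size)
        out["metrics_reduced"] = cv_reduced.metrics.to_dict()
        out["auc_reduced"] = cv_reduced.roc.auc
    else:
        cv_full = cross_validate(table, folds=folds,
                                 regularization_strength=config.regularization_strength)
    out["metrics_full"] = cv_full.metrics.to_dict()
    out["auc_full"] = cv_full.roc.auc
    return out


def run_pipeline(config: PipelineConfig, runs: list | None = None,
                 annotations: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the pipeline end to end with on-disk outputs.

    ``runs``/``annotations`` may be supplied directly; otherwise the
    simulation stage generates them (requiring ``config.simulation``).
    Outputs (core table CSV, CV JSONs, feature table CSV, ROC CSVs, report
    JSON) land in ``config.output_dir`` together with a MANIFEST of completed
    stages; a stage failure leaves partial outputs plus the MANIFEST behind.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"completed_stages": []}

    def checkpoint(name):
        manifest["completed_stages"].append(name)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    try:
        if runs is None:
            if config.simulation is None:
                raise PipelineStageError("simulate", ValidationError(
                    "no runs supplied and no simulation config present"))
            t0 = time.perf_counter()
            runs, annotations, _truth = simulate_dataset(config.simulation)
            logger.info("stage %-16s %6.2fs", "simulate", time.perf_counter() - t0)
            for run in runs:
                write_run(run, out / f"{run.run_id}.h5")
            write_annotations(annotations, out / "annotations.csv")
            checkpoint("simulate")
        elif annotations is None:
            raise PipelineStageError("inputs", ValidationError("runs given without annotations"))

        result = analyse_dataset(runs, annotations, config)
        # analyse_dataset already ran everything; record stages + write outputs
        for name in ("preprocess", "extract_cores", "classify"):
            checkpoint(name)
        result.core_table.to_csv(out / "core_table.csv")
        with open(out / "cv_full.json", "w") as f:
            json.dump(result.refit.cv_full.to_dict(), f, indent=2, sort_keys=True)
        with open(out / "cv_reduced.json", "w") as f:
            json.dump(result.refit.cv_reduced.to_dict(), f, indent=2, sort_keys=True)
        result.refit.selection.to_dataframe(result.core_table.axis.mz).to_csv(
            out / "feature_selection.csv", index=False)
        result.refit.cv_full.roc.to_frame().to_csv(out / "roc_full.csv", index=False)
        result.refit.cv_reduced.roc.to_frame().to_csv(out / "roc_reduced.csv", index=False)
        with open(out / "report.json", "w") as f:
            json.dump(result.report, f, indent=2, sort_keys=True)
        checkpoint("report")
        return result
    except PipelineStageError:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise
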