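"""Synthetic multi-slide TMA DESI-MSI data with known ground truth.

Real clinical TMA cohorts of this kind are rarely shareable, so the generator
emulates the structural features the downstream pipeline has to cope with:

* several slides/runs, each with its own multiplicative batch factor
  (log-normal) and a run-specific mass-axis shift in ppm,
* cores laid out on a grid, labelled tumour or normal at a strong class
  imbalance (default ~8:1), grouped into patients of 1-4 cores,
* one kidney reference core per slide (used downstream for intensity scaling),
* background (non-tissue) pixels whose intensities are pure noise-floor draws,
* class-dependent intensities: a small panel of marker features is scaled by
  ``2**marker_log2_effect`` in tumour cores, before batch factors and
  multiplicative log-normal noise are applied.

The generator is centroid-level: each run carries intensities at the true m/z
positions shifted by its ppm offset.  :func:`render_profile` can render a peak
list into profile mode (Gaussian peaks) for exercising peak detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io import MassAxis, PeakList, SpectralMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "demo_config",
    "simulate_dataset",
    "simulate_core_table",
    "simulate_ffpe_from_ff",
    "render_profile",
]

TUMOUR = "tumour"
NORMAL = "normal"
REFERENCE_KIDNEY = "reference-kidney"

#: attenuation weight applied to the retention probability of lipid-range
#: (600-900 m/z) peaks in the FFPE simulation: FFPE processing preferentially
#: depletes (phospho)lipids.
LIPID_RANGE = (600.0, 900.0)
LIPID_RETENTION_WEIGHT = 0.3


@dataclass
class SimulationConfig:
    """Parameters of one synthetic TMA dataset.

    The defaults are the bundled demo conditions: 3 slides of 44 annotated
    cores at a tumour fraction of 8/9 (~7.8:1 imbalance), 100 true peaks of
    which 5 are markers with a 2-fold tumour effect, log-normal intensity
    noise sd 0.3, slide batch sd 0.3 (log scale) and 2 ppm mass-axis jitter.
    """

    seed: int
    n_slides: int = 3
    cores_per_slide: int = 44
    tumour_fraction: float = 8.0 / 9.0
    n_features: int = 100
    n_markers: int = 5
    marker_log2_effect: float = 1.0
    slide_batch_sd: float = 0.3
    ppm_jitter_sd: float = 2.0
    noise_sd: float = 0.3
    core_radius_px: int = 3
    pixel_size_um: float = 85.0
    snr_floor: float = 1.0
    ffpe_retention: float = 158.0 / 908.0
    mz_range: tuple = (100.0, 1000.0)
    baseline_log_mean: float = math.log(50.0)
    baseline_log_sd: float = 0.6

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed", "must be an integer")
        for name in ("n_slides", "cores_per_slide", "n_features", "n_markers", "core_radius_px"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(name, "must be a positive count")
        if not 0.0 < self.tumour_fraction < 1.0:
            raise ConfigurationError("tumour_fraction", "must lie strictly between 0 and 1")
        if self.n_markers > self.n_features:
            raise ConfigurationError("n_markers", "cannot exceed n_features")
        for name in ("slide_batch_sd", "ppm_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "must be non-negative")
        if self.snr_floor <= 0:
            raise ConfigurationError("snr_floor", "must be positive")
        if not 0.0 < self.ffpe_retention <= 1.0:
            raise ConfigurationError("ffpe_retention", "must lie in (0, 1]")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um", "must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mz_range"] = list(d["mz_range"])
        return d


def demo_config(seed: int = 1) -> SimulationConfig:
    """The bundled demo simulation (the package's study conditions)."""
    cfg = SimulationConfig(seed=seed)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline has to recover."""

    core_labels: dict  # core_id -> tumour/normal/reference-kidney
    marker_indices: np.ndarray
    true_effects: np.ndarray  # per-marker log2 fold change
    slide_factors: dict  # slide_id -> multiplicative batch factor
    true_mz: np.ndarray
    ppm_offsets: dict  # run_id -> mass-axis shift (ppm)
    tissue_masks: dict  # run_id -> bool array over the run's pixels
    pixel_core_ids: dict  # run_id -> object array of core_id ('' = background)


def _draw_true_mz(rng: np.random.Generator, n: int, lo: float, hi: float,
                  min_gap_ppm: float = 100.0) -> np.ndarray:
    """Sorted m/z positions separated by at least ``min_gap_ppm``."""
    candidates = np.sort(rng.uniform(lo, hi, size=8 * n + 64))
    keep = [candidates[0]]
    for mz in candidates[1:]:
        if (mz - keep[-1]) / keep[-1] * 1e6 >= min_gap_ppm:
            keep.append(mz)
        if len(keep) == n:
            break
    if len(keep) < n:
        raise ConfigurationError("n_features", "too many features for the m/z range")
    return np.asarray(keep)


def _slide_labels(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    n_tumour = int(round(config.tumour_fraction * config.cores_per_slide))
    n_tumour = min(max(n_tumour, 1), config.cores_per_slide - 1)
    labels = np.array([TUMOUR] * n_tumour + [NORMAL] * (config.cores_per_slide - n_tumour), dtype=object)
    return rng.permutation(labels)


def _assign_patients(rng: np.random.Generator, labels: np.ndarray, slide: int) -> list:
    """Group consecutive same-class cores into patients of 1-4 cores."""
    patients = [None] * len(labels)
    counter = 0
    for cls in (TUMOUR, NORMAL):
        idx = [i for i, l in enumerate(labels) if l == cls]
        pos = 0
        while pos < len(idx):
            size = int(rng.integers(1, 5))
            pid = f"S{slide}P{counter}"
            for i in idx[pos:pos + size]:
                patients[i] = pid
            counter += 1
            pos += size
    return patients


def _class_templates(baseline: np.ndarray, markers: np.ndarray, log2_effect: float) -> dict:
    tumour = baseline.copy()
    tumour[markers] = tumour[markers] * (2.0 ** log2_effect)
    return {TUMOUR: tumour, NORMAL: baseline.copy()}


def simulate_dataset(config: SimulationConfig):
    """Generate per-slide pixel-level runs, the core annotation table and truth.

    Returns
    -------
    runs : list of SpectralMatrix
        One centroid-mode run per slide, on that run's jittered mass axis.
    annotations : pandas.DataFrame
        Columns ``core_id, slide_id, patient_id, label, x_center, y_center``.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    true_mz = _draw_true_mz(rng, config.n_features, *config.mz_range)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_features)
    markers = np.sort(rng.choice(config.n_features, size=config.n_markers, replace=False))
    effects = np.full(config.n_markers, config.marker_log2_effect)
    kidney_template = baseline * rng.lognormal(0.0, 0.5, config.n_features)
    templates = _class_templates(baseline, markers, config.marker_log2_effect)
    templates[REFERENCE_KIDNEY] = kidney_template

    slide_factors = {}
    ppm_offsets = {}
    runs, rows = [], []
    tissue_masks, pixel_core_ids, core_labels = {}, {}, {}

    r = config.core_radius_px
    n_cores = config.cores_per_slide + 1  # + kidney reference
    grid = math.ceil(math.sqrt(n_cores))
    spacing = 2 * r + 1
    margin = r + 1

    for s in range(config.n_slides):
        slide_id = f"slide{s}"
        run_id = f"run{s}"
        batch = float(np.exp(rng.normal(0.0, config.slide_batch_sd)))
        offset_ppm = float(rng.normal(0.0, config.ppm_jitter_sd))
        slide_factors[slide_id] = batch
        ppm_offsets[run_id] = offset_ppm

        labels = _slide_labels(rng, config)
        patients = _assign_patients(rng, labels, s)
        centres = [(margin + (i % grid) * spacing, margin + (i // grid) * spacing)
                   for i in range(n_cores)]
        width = 2 * margin + (grid - 1) * spacing + 1

        core_ids = [f"S{s}C{k}" for k in range(config.cores_per_slide)] + [f"S{s}REF"]
        all_labels = list(labels) + [REFERENCE_KIDNEY]
        all_patients = patients + [f"S{s}PREF"]
        for cid, lab, pid, (cx, cy) in zip(core_ids, all_labels, all_patients, centres):
            rows.append({"core_id": cid, "slide_id": slide_id, "patient_id": pid,
                         "label": lab, "x_center": cx, "y_center": cy})
            core_labels[cid] = lab

        xs, ys = np.meshgrid(np.arange(width), np.arange(width), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        m = coords.shape[0]
        centre_arr = np.asarray(centres, dtype=float)
        d2 = ((coords[:, None, :] - centre_arr[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        in_core = d2[np.arange(m), nearest] <= r * r

        pix_core = np.full(m, "", dtype=object)
        pix_core[in_core] = np.asarray(core_ids, dtype=object)[nearest[in_core]]

        intensities = rng.exponential(config.snr_floor, size=(m, config.n_features))
        tissue = in_core
        if tissue.any():
            tmpl = np.empty((m, config.n_features))
            for cid, lab in zip(core_ids, all_labels):
                sel = pix_core == cid
                tmpl[sel] = templates[lab]
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=(int(tissue.sum()), config.n_features)))
            intensities[tissue] = tmpl[tissue] * batch * noise

        run_axis = MassAxis(true_mz * (1.0 + offset_ppm * 1e-6))
        runs.append(SpectralMatrix(run_id, slide_id, coords, intensities, run_axis,
                                   config.pixel_size_um))
        tissue_masks[run_id] = tissue
        pixel_core_ids[run_id] = pix_core

    annotations = pd.DataFrame(rows)
    truth = GroundTruth(core_labels, markers, effects, slide_factors, true_mz,
                        ppm_offsets, tissue_masks, pixel_core_ids)
    return runs, annotations, truth


def simulate_core_table(config: SimulationConfig):
    """Core-level shortcut: draw per-core spectra directly from the intensity model.

    Skips pixel rendering (and therefore pixel averaging, segmentation and
    rasterisation); each core's spectrum is one draw of
    ``template * slide_factor * exp(N(0, noise_sd))``.  Reference cores are not
    generated.  Returns ``(X, y, slide_ids, patient_ids, truth_lite)`` where
    ``truth_lite`` is a dict with ``marker_indices``, ``true_mz`` and
    ``slide_factors``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    true_mz = _draw_true_mz(rng, config.n_features, *config.mz_range)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_features)
    markers = np.sort(rng.choice(config.n_features, size=config.n_markers, replace=False))
    templates = _class_templates(baseline, markers, config.marker_log2_effect)

    X, y, slide_ids, patient_ids = [], [], [], []
    slide_factors = {}
    for s in range(config.n_slides):
        slide_id = f"slide{s}"
        batch = float(np.exp(rng.normal(0.0, config.slide_batch_sd)))
        slide_factors[slide_id] = batch
        labels = _slide_labels(rng, config)
        patients = _assign_patients(rng, labels, s)
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=(len(labels), config.n_features)))
        for i, lab in enumerate(labels):
            X.append(templates[lab] * batch * noise[i])
            y.append(1 if lab == TUMOUR else 0)
            slide_ids.append(slide_id)
            patient_ids.append(patients[i])
    truth_lite = {"marker_indices": markers, "true_mz": true_mz, "slide_factors": slide_factors}
    return (np.asarray(X), np.asarray(y, dtype=int), np.asarray(slide_ids, dtype=object),
            np.asarray(patient_ids, dtype=object), truth_lite)


def simulate_ffpe_from_ff(ff_peaks: PeakList, retention: float, ppm_jitter_sd: float,
                          seed: int) -> PeakList:
    """Simulate the peak panel surviving FFPE processing of a fresh-frozen run.

    Keeps ``round(retention * len(ff_peaks))`` peaks, sampled without
    replacement with lipid-range (600-900 m/z) peaks down-weighted — FFPE
    solvent processing preferentially depletes (phospho)lipids — and perturbs
    each retained m/z by a per-peak ppm offset.  ``retention=1`` with zero
    jitter returns the input unchanged.
    """
    if not 0.0 < retention <= 1.0:
        raise ConfigurationError("retention", "must lie in (0, 1]")
    n = len(ff_peaks)
    if n == 0:
        return PeakList.empty()
    rng = np.random.default_rng(seed)
    n_keep = int(round(retention * n))
    lipid = (ff_peaks.mz >= LIPID_RANGE[0]) & (ff_peaks.mz <= LIPID_RANGE[1])
    weights = np.where(lipid, LIPID_RETENTION_WEIGHT, 1.0)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False, p=weights / weights.sum()))
    mz = ff_peaks.mz[keep] * (1.0 + rng.normal(0.0, ppm_jitter_sd, n_keep) * 1e-6)
    order = np.argsort(mz)
    return PeakList(mz[order], ff_peaks.intensity[keep][order], ff_peaks.snr[keep][order])


def render_profile(peaks: PeakList, axis_mz: np.ndarray, width_mz: float = 0.02,
                   noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render a centroid peak list into a profile-mode spectrum.

    Gaussian peaks of standard deviation ``width_mz`` on the given grid, plus
    optional additive Gaussian noise — used to exercise SNR-based peak
    detection on realistic profile data.
    """
    axis_mz = np.asarray(axis_mz, dtype=float)
    spectrum = np.zeros_like(axis_mz)
    for mz, height in zip(peaks.mz, peaks.intensity):
        spectrum += height * np.exp(-0.5 * ((axis_mz - mz) / width_mz) ** 2)
    if noise_sd > 0:
        spectrum += np.random.default_rng(seed).normal(0.0, noise_sd, axis_mz.size)
    return spectrum
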