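"""MSI pre-processing: peak detection, common-axis construction with
recalibration, segmentation-based ROI selection, spatial feature filtering and
the two-stage intensity normalisation (per-slide reference-core scaling, then
median fold change scaling).

The stages mirror the standard treatment of multi-run DESI-MSI data: per-pixel
SNR-based peak picking removes intra-run (pixel-to-pixel) noise, ppm-tolerance
clustering of pooled centroids builds one common mass axis shared by all runs,
a per-run global ppm recalibration removes inter-run mass drift, and each run
is rasterised into a dense pixels x common-axis matrix.  Kidney reference
cores present on every slide anchor a per-run multiplicative intensity scale,
and median fold change normalisation removes residual dilution-like
per-spectrum intensity differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal
from sklearn.cluster import KMeans

from .errors import ConfigurationError, MsitmaWarning, ValidationError
from .io import MassAxis, PeakList, SpectralMatrix

__all__ = [
    "PreprocessConfig",
    "SegmentationMap",
    "estimate_noise",
    "detect_peaks",
    "build_common_axis",
    "estimate_ppm_offset",
    "recalibrate_run",
    "rasterize",
    "segment_kmeans",
    "spatial_filter_features",
    "reference_intensity_scale",
    "median_fold_change_normalize",
]

MAD_SCALE = 1.4826  # consistency constant: MAD -> Gaussian sigma


@dataclass
class PreprocessConfig:
    """Tunable pre-processing parameters.

    ``snr_min`` (peak-picking threshold, default 3) is a conventional choice;
    ``ppm_tol`` (10 ppm) is the mass-matching window used throughout;
    ``kmeans_k`` defaults to 4 (tumour / stroma / tissue background / slide
    background); ``background_tic_fraction`` flags segmentation clusters whose
    mean raw TIC falls below that fraction of the global median pixel TIC.
    """

    snr_min: float = 3.0
    ppm_tol: float = 10.0
    kmeans_k: int = 4
    kmeans_seed: int = 0
    spatial_filter_min_fraction: float = 0.01
    background_tic_fraction: float = 0.2
    mfc_reference: str = "dataset_median_spectrum"

    def validate(self) -> None:
        if self.snr_min <= 0:
            raise ConfigurationError("snr_min", "must be positive")
        if self.ppm_tol <= 0:
            raise ConfigurationError("ppm_tol", "must be positive")
        if self.kmeans_k < 2:
            raise ConfigurationError("kmeans_k", "must be at least 2")
        if not 0 < self.spatial_filter_min_fraction <= 1:
            raise ConfigurationError("spatial_filter_min_fraction", "must lie in (0, 1]")
        if self.mfc_reference != "dataset_median_spectrum":
            raise ConfigurationError("mfc_reference", "only 'dataset_median_spectrum' is supported")

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_noise(spectrum: np.ndarray) -> float:
    """Robust noise scale of a spectrum's baseline.

    Scaled median absolute deviation (1.4826 x MAD, the Gaussian-consistent
    scaling) of the values at or below the spectrum's median, measured from
    that median.  Restricting to the baseline keeps genuine peaks from
    inflating the estimate; an all-constant spectrum returns 0.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot estimate noise of an empty spectrum")
    med = float(np.median(x))
    dev = med - x[x <= med]
    if dev.size == 0:
        return 0.0
    return float(MAD_SCALE * np.median(dev))


def detect_peaks(axis_mz: np.ndarray, spectrum: np.ndarray, snr_min: float = 3.0) -> PeakList:
    """SNR-based peak detection on a profile-mode spectrum.

    Local maxima whose height exceeds ``snr_min`` times the robust baseline
    noise are kept; each centroid m/z is refined by the intensity-weighted
    mean over the peak's contiguous above-half-maximum bins.
    """
    axis_mz = np.asarray(axis_mz, dtype=float)
    x = np.asarray(spectrum, dtype=float)
    if axis_mz.shape != x.shape:
        raise ValidationError("axis and spectrum must have the same length")
    if x.size == 0 or not np.any(x > 0):
        return PeakList.empty()
    noise = estimate_noise(x)
    idx, _ = signal.find_peaks(x)
    if noise > 0:
        idx = idx[x[idx] / noise >= snr_min]
    else:  # noiseless spectrum: every positive local maximum qualifies
        idx = idx[x[idx] > 0]
    if idx.size == 0:
        return PeakList.empty()
    mzs, heights, snrs = [], [], []
    for i in idx:
        half = x[i] / 2.0
        lo = i
        while lo > 0 and x[lo - 1] >= half and x[lo - 1] <= x[lo]:
            lo -= 1
        hi = i
        while hi < x.size - 1 and x[hi + 1] >= half and x[hi + 1] <= x[hi]:
            hi += 1
        w = x[lo:hi + 1]
        mzs.append(float(np.sum(axis_mz[lo:hi + 1] * w) / np.sum(w)))
        heights.append(float(x[i]))
        snrs.append(float(x[i] / noise) if noise > 0 else np.inf)
    order = np.argsort(mzs)
    return PeakList(np.asarray(mzs)[order], np.asarray(heights)[order], np.asarray(snrs)[order])


def build_common_axis(run_peaklists: list, ppm_tol: float = 10.0) -> MassAxis:
    """Cluster pooled peak centroids into one common mass axis.

    Greedy single-linkage merge over the sorted pooled centroid list: a new
    cluster starts whenever the next centroid lies more than ``ppm_tol`` (ppm,
    relative to the running intensity-weighted cluster mean) above that mean.
    Each axis entry is the cluster's intensity-weighted mean m/z.  Pooling and
    sorting first makes the result invariant to run order.
    """
    if not run_peaklists:
        raise ValidationError("need at least one run to build a common axis")
    mz = np.concatenate([p.mz for p in run_peaklists])
    weight = np.concatenate([p.intensity for p in run_peaklists])
    if mz.size == 0:
        return MassAxis(np.empty(0))
    weight = np.where(weight > 0, weight, 1.0)  # zero-intensity peaks count equally
    order = np.argsort(mz, kind="stable")
    mz, weight = mz[order], weight[order]

    entries = []
    sum_w, sum_wm = weight[0], weight[0] * mz[0]
    for m, w in zip(mz[1:], weight[1:]):
        mean = sum_wm / sum_w
        if (m - mean) / mean * 1e6 > ppm_tol:
            entries.append(mean)
            sum_w, sum_wm = w, w * m
        else:
            sum_w += w
            sum_wm += w * m
    entries.append(sum_wm / sum_w)
    return MassAxis(np.asarray(entries))


def _nearest_axis_match(mz: np.ndarray, axis: MassAxis, ppm_tol: float):
    """Indices of each peak's nearest axis entry and a within-tolerance mask."""
    ax = axis.mz
    if ax.size == 0 or mz.size == 0:
        return np.zeros(mz.size, dtype=int), np.zeros(mz.size, dtype=bool)
    pos = np.searchsorted(ax, mz)
    left = np.clip(pos - 1, 0, ax.size - 1)
    right = np.clip(pos, 0, ax.size - 1)
    nearest = np.where(np.abs(ax[right] - mz) < np.abs(ax[left] - mz), right, left)
    ppm = np.abs(mz - ax[nearest]) / ax[nearest] * 1e6
    return nearest, ppm <= ppm_tol


def estimate_ppm_offset(peaklist: PeakList, axis: MassAxis, ppm_tol: float = 10.0) -> float:
    """Global ppm offset of a run: median relative deviation of matched peaks.

    Peaks are matched to their nearest common-axis entry within ``ppm_tol``;
    with fewer than 3 matches the offset is reported as 0 with a warning.
    """
    nearest, ok = _nearest_axis_match(peaklist.mz, axis, ppm_tol)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 peaks matched the axis; applying zero ppm offset",
                      MsitmaWarning, stacklevel=2)
        return 0.0
    dev = (peaklist.mz[ok] - axis.mz[nearest[ok]]) / axis.mz[nearest[ok]] * 1e6
    return float(np.median(dev))


def recalibrate_run(peaklist: PeakList, axis: MassAxis, ppm_tol: float = 10.0) -> PeakList:
    """Subtract the run's estimated global ppm offset from every peak m/z."""
    offset = estimate_ppm_offset(peaklist, axis, ppm_tol)
    mz = peaklist.mz * (1.0 - offset * 1e-6)
    return PeakList(mz, peaklist.intensity.copy(), peaklist.snr.copy())


def rasterize(runs: list, axis: MassAxis, ppm_tol: float = 10.0) -> list:
    """Project recalibrated runs onto the common axis.

    Each run-axis entry is assigned to its nearest common-axis entry within
    ``ppm_tol``; unmatched entries are dropped and collisions (two run
    features mapping to the same axis entry) are summed.  Absent features
    are zero.
    """
    out = []
    for run in runs:
        nearest, ok = _nearest_axis_match(run.axis.mz, axis, ppm_tol)
        intens = np.zeros((run.n_pixels, len(axis)))
        if ok.any():
            np.add.at(intens.T, nearest[ok], run.intensities[:, ok].T)
        out.append(run.with_intensities(intens, axis))
    return out


@dataclass
class SegmentationMap:
    """K-means segmentation of a run's pixels.

    ``labels`` holds one cluster id per pixel; ``background_cluster_ids``
    are the clusters flagged as non-tissue by the TIC rule.
    """

    labels: np.ndarray
    centroids: np.ndarray  # cluster centres in TIC-normalised spectral space
    background_cluster_ids: set

    @property
    def tissue_mask(self) -> np.ndarray:
        return ~np.isin(self.labels, sorted(self.background_cluster_ids))


def segment_kmeans(matrix: SpectralMatrix, k: int = 4, seed: int = 0,
                   background_tic_fraction: float = 0.2) -> SegmentationMap:
    """Segment a run by k-means on TIC-normalised pixel spectra.

    Clusters whose mean raw TIC is below ``background_tic_fraction`` of the
    global median pixel TIC are flagged as background (slide background and
    off-tissue regions carry little total signal).
    """
    if matrix.n_pixels < k:
        raise ValidationError(f"cannot form {k} clusters from {matrix.n_pixels} pixels")
    tic = matrix.tic()
    norm = np.divide(matrix.intensities, tic[:, None], out=np.zeros_like(matrix.intensities),
                     where=tic[:, None] > 0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(norm)
    median_tic = float(np.median(tic))
    background = {c for c in range(k)
                  if float(tic[labels == c].mean()) < background_tic_fraction * median_tic}
    return SegmentationMap(labels, km.cluster_centers_, background)


def spatial_filter_features(matrix: SpectralMatrix, tissue_mask: np.ndarray,
                            min_fraction: float = 0.01):
    """Drop features whose spatial distribution does not look like tissue signal.

    A simplified spatial-coherence filter with two rules: a feature is dropped
    if it is non-zero in fewer than ``min_fraction`` of tissue pixels
    (occupancy rule), or if its mean intensity on tissue does not exceed its
    mean intensity off tissue (localisation rule).  Returns the retained
    feature index array and a per-feature score table.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape[0] != matrix.n_pixels:
        raise ValidationError("tissue mask length must equal the pixel count")
    if not tissue_mask.any():
        raise ValidationError("tissue mask is empty")
    on = matrix.intensities[tissue_mask]
    off = matrix.intensities[~tissue_mask]
    occupancy = (on > 0).mean(axis=0)
    on_mean = on.mean(axis=0)
    if off.shape[0]:
        off_mean = off.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(off_mean > 0, on_mean / np.where(off_mean > 0, off_mean, 1.0),
                             np.where(on_mean > 0, np.inf, 0.0))
    else:  # no off-tissue pixels: localisation rule cannot reject
        ratio = np.where(on_mean > 0, np.inf, 0.0)
    retained = np.flatnonzero((occupancy >= min_fraction) & (ratio > 1.0))
    scores = {"occupancy": occupancy, "on_off_ratio": ratio,
              "retained": (occupancy >= min_fraction) & (ratio > 1.0)}
    return retained, scores


def reference_intensity_scale(matrices: list, reference_pixel_masks: list):
    """Equalise per-run intensity scale using each slide's reference core.

    Each run is multiplied by one scalar proportional to the inverse of the
    median TIC over its reference-core (kidney) pixels, with the scalars
    normalised to mean 1 so the overall intensity scale of the dataset is
    preserved.  After scaling, every run's reference median TIC is identical.
    """
    if len(matrices) != len(reference_pixel_masks):
        raise ValidationError("need one reference mask per run")
    medians = []
    for run, mask in zip(matrices, reference_pixel_masks):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValidationError(f"empty reference-core mask on slide '{run.slide_id}'")
        med = float(np.median(run.tic()[mask]))
        if med <= 0:
            raise ValidationError(f"zero reference-core median TIC on slide '{run.slide_id}'")
        medians.append(med)
    inv = 1.0 / np.asarray(medians)
    scalars = inv / inv.mean()
    scaled = [run.with_intensities(run.intensities * s) for run, s in zip(matrices, scalars)]
    return scaled, scalars


def median_fold_change_normalize(spectra: np.ndarray, reference: np.ndarray | None = None):
    """Median fold change normalisation against a reference spectrum.

    Each spectrum is divided by the median of its feature-wise ratios to the
    reference (over features where both are positive), so that afterwards the
    median fold change of every spectrum versus the reference equals 1.  The
    default reference is the dataset's feature-wise median spectrum.  Returns
    ``(normalised spectra, per-spectrum dilution factors)``.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValidationError("expected a 2-D array of spectra (rows)")
    ref = np.median(spectra, axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (spectra.shape[1],):
        raise ValidationError("reference spectrum length mismatch")
    factors = np.ones(spectra.shape[0])
    for i, row in enumerate(spectra):
        shared = (row > 0) & (ref > 0)
        if not shared.any():
            warnings.warn(f"spectrum {i} shares no positive feature with the reference; "
                          "dilution factor set to 1", MsitmaWarning, stacklevel=2)
            continue
        factors[i] = float(np.median(row[shared] / ref[shared]))
    return spectra / factors[:, None], factors
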