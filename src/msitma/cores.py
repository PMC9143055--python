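"""Per-core analysis: pixel-to-core assignment, average core spectra,
TIC-mask/optical-mask affine co-registration, and FF/FFPE peak-axis matching.

A tissue-microarray core is a disc of tissue; classification operates on the
arithmetic mean spectrum over each core's assigned pixels, labelled from the
pathologist's (here: the generator's) annotation table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import MsitmaWarning, ValidationError
from .io import MassAxis, SpectralMatrix

__all__ = [
    "CoreTable",
    "AffineParams",
    "assign_pixels_to_cores",
    "average_core_spectra",
    "concat_core_tables",
    "register_affine",
    "match_peak_axes",
]

BACKGROUND = ""  # pixel assignment value for non-core pixels

_LABEL_MAP = {"tumour": "tumour", "normal": "normal",
              "reference-kidney": "reference", "reference-liver": "reference",
              "reference": "reference"}


@dataclass
class CoreTable:
    """One row per TMA core with its averaged spectrum.

    ``meta`` has columns ``core_id, slide_id, patient_id, label, n_pixels``
    with ``label`` in {tumour, normal, reference}; ``spectra`` is the aligned
    (cores x features) matrix on ``axis``.
    """

    meta: pd.DataFrame
    spectra: np.ndarray
    axis: MassAxis

    def __post_init__(self):
        if self.meta.shape[0] != self.spectra.shape[0]:
            raise ValidationError("meta rows and spectra rows differ")
        if self.spectra.ndim != 2 or self.spectra.shape[1] != len(self.axis):
            raise ValidationError("spectra shape inconsistent with axis")
        if self.meta["core_id"].duplicated().any():
            raise ValidationError("duplicate core_id in core table")
        if (self.meta["n_pixels"] < 1).any():
            raise ValidationError("every core must have at least one pixel")
        bad = set(self.meta["label"]) - {"tumour", "normal", "reference"}
        if bad:
            raise ValidationError(f"unknown core labels {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.meta.shape[0])

    def to_csv(self, path) -> None:
        df = self.meta.copy()
        for j, mz in enumerate(self.axis.mz):
            df[f"mz_{mz:.5f}"] = self.spectra[:, j]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CoreTable":
        df = pd.read_csv(path)
        mz_cols = [c for c in df.columns if c.startswith("mz_")]
        axis = MassAxis(np.asarray([float(c[3:]) for c in mz_cols]))
        meta = df[[c for c in df.columns if not c.startswith("mz_")]].copy()
        return cls(meta, df[mz_cols].to_numpy(dtype=float), axis)


def assign_pixels_to_cores(matrix: SpectralMatrix, annotations: pd.DataFrame,
                           radius: float, tissue_mask: np.ndarray | None = None) -> np.ndarray:
    """Assign each pixel to the nearest core centre within ``radius``.

    Pixels outside every core disc — or outside ``tissue_mask`` when one is
    given — are background (empty string).  Ties are broken toward the
    lexicographically lower ``core_id``; overlapping core discs are resolved
    by the nearest-centre rule with a warning.
    """
    ann = annotations[annotations["slide_id"] == matrix.slide_id] \
        if "slide_id" in annotations.columns else annotations
    ann = ann.sort_values("core_id", kind="stable").reset_index(drop=True)
    if ann.empty:
        return np.full(matrix.n_pixels, BACKGROUND, dtype=object)
    centres = ann[["x_center", "y_center"]].to_numpy(dtype=float)
    if matrix.n_pixels:
        lo = matrix.coords.min(axis=0)
        hi = matrix.coords.max(axis=0)
        if np.any(centres < lo - 0.5) or np.any(centres > hi + 0.5):
            raise ValidationError("core centres fall outside the pixel grid")
    d2 = ((matrix.coords[:, None, :].astype(float) - centres[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= radius * radius
    if np.any(within.sum(axis=1) > 1):
        warnings.warn("overlapping core discs; pixels assigned to the nearest centre",
                      MsitmaWarning, stacklevel=2)
    nearest = d2.argmin(axis=1)  # argmin takes the first (lowest core_id) on ties
    in_core = within[np.arange(matrix.n_pixels), nearest]
    if tissue_mask is not None:
        in_core &= np.asarray(tissue_mask, dtype=bool)
    out = np.full(matrix.n_pixels, BACKGROUND, dtype=object)
    ids = ann["core_id"].to_numpy(dtype=object)
    out[in_core] = ids[nearest[in_core]]
    return out


def average_core_spectra(matrix: SpectralMatrix, pixel_core_ids: np.ndarray,
                         annotations: pd.DataFrame) -> CoreTable:
    """Arithmetic mean spectrum per core, with pixel counts and labels.

    Cores listed in the annotation table that received no pixels are excluded
    with a warning.
    """
    ann = annotations[annotations["slide_id"] == matrix.slide_id] \
        if "slide_id" in annotations.columns else annotations
    rows, spectra = [], []
    for _, r in ann.iterrows():
        sel = pixel_core_ids == r["core_id"]
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"core '{r['core_id']}' received no pixels; excluded",
                          MsitmaWarning, stacklevel=2)
            continue
        rows.append({"core_id": r["core_id"], "slide_id": r["slide_id"],
                     "patient_id": r["patient_id"], "label": _LABEL_MAP[r["label"]],
                     "n_pixels": n})
        spectra.append(matrix.intensities[sel].mean(axis=0))
    return CoreTable(pd.DataFrame(rows, columns=["core_id", "slide_id", "patient_id",
                                                 "label", "n_pixels"]),
                     np.asarray(spectra).reshape(len(rows), matrix.n_features),
                     matrix.axis)


def concat_core_tables(tables: list) -> CoreTable:
    if not tables:
        raise ValidationError("no core tables to concatenate")
    axis = tables[0].axis
    for t in tables[1:]:
        if t.axis != axis:
            raise ValidationError("core tables must share one mass axis")
    meta = pd.concat([t.meta for t in tables], ignore_index=True)
    return CoreTable(meta, np.vstack([t.spectra for t in tables]), axis)


@dataclass
class AffineParams:
    """2x3 affine map from moving-image to fixed-image (row, col) coordinates."""

    matrix: np.ndarray  # (2, 3): [linear | translation]
    final_loss: float = np.nan
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValidationError("affine parameter matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValidationError("affine linear part is singular")
        self.matrix = m

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"matrix": self.matrix.tolist(), "final_loss": self.final_loss,
                       "n_iter": self.n_iter, "converged": self.converged}, f, indent=2)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation


def _warp(image: np.ndarray, coords: np.ndarray, shape) -> np.ndarray:
    return ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0
                                   ).reshape(shape)


def register_affine(fixed_mask: np.ndarray, moving_mask: np.ndarray,
                    step_size: float = 1.0, n_iters: int = 300, seed: int = 0,
                    smooth_sigma: float = 2.0) -> AffineParams:
    """Affine registration of two binary masks by gradient descent.

    Minimises the mean squared difference between the Gaussian-smoothed fixed
    mask and the affinely warped smoothed moving mask, starting from the
    identity.  Gradients are analytic (chain rule through bilinear sampling of
    the moving image); the step is scaled so the largest displacement a single
    update can induce is about ``step_size`` pixels, with backtracking halving
    on any loss increase, so the loss is non-increasing over accepted
    iterations.  If no downhill step can be found for 50 consecutive
    iterations the identity is returned with a warning.

    The returned :class:`AffineParams` maps moving-image (row, col)
    coordinates to fixed-image coordinates.
    """
    fixed = np.asarray(fixed_mask, dtype=float)
    moving = np.asarray(moving_mask, dtype=float)
    if fixed.sum() == 0 or moving.sum() == 0:
        raise ValidationError("both masks must be non-empty")
    f = ndimage.gaussian_filter(fixed, smooth_sigma)
    m = ndimage.gaussian_filter(moving, smooth_sigma)
    g_r, g_c = np.gradient(m)

    rows, cols = np.meshgrid(np.arange(fixed.shape[0]), np.arange(fixed.shape[1]),
                             indexing="ij")
    centre_f = (np.asarray(fixed.shape, dtype=float) - 1) / 2
    centre_m = (np.asarray(moving.shape, dtype=float) - 1) / 2
    p = np.stack([rows.ravel() - centre_f[0], cols.ravel() - centre_f[1]])  # (2, M)
    radius2 = float(np.mean(p ** 2))

    B = np.eye(2)  # fixed -> moving, centred coordinates
    b = np.zeros(2)

    def loss_and_grad(B, b):
        q = B @ p + b[:, None] + centre_m[:, None]
        w = _warp(m, q, fixed.shape).ravel()
        r = w - f.ravel()
        gr = ndimage.map_coordinates(g_r, q, order=1, mode="constant", cval=0.0)
        gc = ndimage.map_coordinates(g_c, q, order=1, mode="constant", cval=0.0)
        gb = 2.0 * np.array([np.mean(r * gr), np.mean(r * gc)])
        gB = 2.0 * (np.stack([r * gr, r * gc]) @ p.T) / p.shape[1]
        return float(np.mean(r ** 2)), gB, gb

    loss, gB, gb = loss_and_grad(B, b)
    initial_loss = loss

    # preconditioned step: dividing the linear-part gradient by the mean
    # squared coordinate radius puts both blocks on the same displacement
    # (pixel) scale, so one learning rate serves both
    def disp_norm(gB, gb):
        return float(np.sqrt(np.sum(gB ** 2) / radius2 + np.sum(gb ** 2)))

    norm0 = disp_norm(gB, gb)
    if norm0 < 1e-15:
        return AffineParams(np.hstack([np.eye(2), np.zeros((2, 1))]), loss, 0, True)
    lr = step_size / norm0  # first step displaces ~step_size pixels
    lr_max = lr * 100.0
    fails = 0
    it = 0
    for it in range(1, n_iters + 1):
        newB = B - lr * gB / radius2
        newb = b - lr * gb
        new_loss, ngB, ngb = loss_and_grad(newB, newb)
        if new_loss < loss:
            improved = loss - new_loss
            B, b, loss, gB, gb = newB, newb, new_loss, ngB, ngb
            fails = 0
            lr = min(lr * 1.2, lr_max)
            if improved < 1e-15 * max(initial_loss, 1e-30):
                break
        else:
            lr *= 0.5
            fails += 1
            if fails >= 50:
                warnings.warn("affine registration diverged; returning identity",
                              MsitmaWarning, stacklevel=2)
                ident = np.hstack([np.eye(2), np.zeros((2, 1))])
                return AffineParams(ident, initial_loss, it, converged=False)
        if lr * disp_norm(gB, gb) < 1e-10:
            break

    # convert centred fixed->moving map to absolute moving->fixed parameters
    t_fm = b + centre_m - B @ centre_f  # q_abs = B p_abs + t_fm
    Binv = np.linalg.inv(B)
    params = np.hstack([Binv, (-Binv @ t_fm)[:, None]])
    return AffineParams(params, loss, it, converged=True)


def match_peak_axes(axis_a: MassAxis, axis_b: MassAxis, ppm_tol: float = 10.0):
    """One-to-one greedy matching of two mass axes within a ppm tolerance.

    Candidate pairs within tolerance are accepted in order of increasing ppm
    distance, each entry used at most once.  Returns ``(pairs, shared_fraction)``
    where ``pairs`` is a list of ``(index_a, index_b)`` and the shared fraction
    is relative to the smaller axis (the convention used when quoting, e.g.,
    "41 of 158 peaks shared").
    """
    a, bz = axis_a.mz, axis_b.mz
    if a.size == 0 or bz.size == 0:
        return [], 0.0
    candidates = []
    for i, mz in enumerate(a):
        lo = np.searchsorted(bz, mz * (1 - ppm_tol * 1e-6 * 1.5))
        hi = np.searchsorted(bz, mz * (1 + ppm_tol * 1e-6 * 1.5))
        for j in range(lo, hi):
            ppm = abs(mz - bz[j]) / (0.5 * (mz + bz[j])) * 1e6
            if ppm <= ppm_tol:
                candidates.append((ppm, i, j))
    candidates.sort()
    used_a, used_b, pairs = set(), set(), []
    for ppm, i, j in candidates:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    pairs.sort()
    return pairs, len(pairs) / min(a.size, bz.size)
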