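"""Fine 0.5 mm isotropic reconstruction of the coarse pathology map.

The coarse map's per-pattern indicators (1 where the voxel's Gleason score
contains the pattern) and a cancer-presence indicator are trilinearly
interpolated from coarse voxel centres onto the fine grid and then convolved
with an isotropic Gaussian kernel.  The kernel's single standard deviation
``sigma`` (mm) is tuned to the largest value for which re-sampling the
smoothed fields at the original template grid sites still reproduces the
recorded histology — the clinical-validity constraint of the reconstruction:

* (a) the cancer/benign status of every sampled coarse voxel is reproduced
  (presence field >= 0.5 iff the voxel holds cancer), and
* (b) at cancer voxels the set of Gleason patterns read off the fine fields
  (field >= 0.5) equals the voxel's recorded score patterns (default
  ``patterns`` mode), or the argmax pattern equals the recorded primary
  pattern (``primary`` mode).

Outside the sampled support all fields are zero; the convolution uses zero
padding, so each field's total mass is conserved up to kernel truncation at
the volume boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage

from .coarse_map import BENIGN, CoarseMap, decode_pair
from .grading import PATTERNS
from .grid import GridSpec

__all__ = [
    "FineMap",
    "interpolate_fine",
    "gaussian_smooth",
    "preservation_check",
    "tune_sigma",
    "reconstruct",
]

PRESENCE = "presence"


@dataclass
class FineMap:
    """Scalar fields on the 130 x 130 x 80 fine grid.

    ``fields`` maps ``"presence"`` and each Gleason pattern (3/4/5, only those
    present on the source coarse map) to a float32 volume in [0, 1].  ``sigma``
    is the smoothing parameter in mm (``None`` before smoothing).
    """

    fields: dict
    grid: GridSpec
    sigma: float | None = None

    def __post_init__(self) -> None:
        shape = self.grid.fine_shape
        for key, arr in self.fields.items():
            if arr.shape != shape:
                raise ValueError(f"field {key!r} shape {arr.shape} != fine grid {shape}")

    @property
    def patterns(self) -> list[int]:
        return sorted(k for k in self.fields if k != PRESENCE)

    def pattern_field(self, pattern: int) -> np.ndarray:
        if pattern in self.fields:
            return self.fields[pattern]
        return np.zeros(self.grid.fine_shape, dtype=np.float32)

    @property
    def cancer_mask(self) -> np.ndarray:
        return self.fields[PRESENCE] >= 0.5

    def pattern_present(self, pattern: int) -> np.ndarray:
        """Boolean volume: the pattern is read at this fine voxel."""
        return self.pattern_field(pattern) >= 0.5

    @property
    def label_volume(self) -> np.ndarray:
        """Convenience int8 volume: 0 = benign, else highest pattern present.

        Where the presence field reads cancer but no pattern field reaches the
        0.5 threshold, the argmax pattern (ties toward the higher grade) is
        used as a fallback.
        """
        out = np.zeros(self.grid.fine_shape, dtype=np.int8)
        cancer = self.cancer_mask
        stack = [self.pattern_field(p) for p in PATTERNS]
        for pattern, arr in zip(PATTERNS, stack):
            out[cancer & (arr >= 0.5)] = pattern  # ascending: higher wins
        orphan = cancer & (out == 0)
        if orphan.any():
            arg = np.stack(stack, axis=-1)[orphan]
            # reversed argmax so equal values resolve to the higher pattern
            best = len(PATTERNS) - 1 - np.argmax(arg[:, ::-1], axis=1)
            out[orphan] = np.asarray(PATTERNS, dtype=np.int8)[best]
        return out

    def to_nifti(self, directory) -> None:
        """Export each field as a 0.5 mm isotropic NIfTI plus a JSON sidecar."""
        import pathlib

        import nibabel as nib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag([self.grid.fine_res] * 3 + [1.0])
        for key, arr in self.fields.items():
            name = key if isinstance(key, str) else f"pattern{key}"
            nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), affine),
                     str(directory / f"{name}.nii"))
        nib.save(nib.Nifti1Image(self.label_volume, affine), str(directory / "label.nii"))
        (directory / "sigma.json").write_text(json.dumps({"sigma_mm": self.sigma}))


# ------------------------------------------------------------- interpolation

def _axis_weights(n_fine: int, fine_res: float, pitch: float):
    """Linear-interpolation gather indices/weights for one axis.

    Maps fine point positions onto the (zero-padded) coarse voxel-centre grid:
    coarse index = (mm - pitch/2) / pitch, shifted by +1 for the padding.
    """
    mm = fine_res * np.arange(n_fine)
    ci = (mm - pitch / 2.0) / pitch
    lo = np.floor(ci).astype(np.int64)
    w = (ci - lo).astype(np.float32)
    return lo + 1, w


def _interp_axis(arr: np.ndarray, lo: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    a = np.take(arr, lo, axis=axis)
    b = np.take(arr, lo + 1, axis=axis)
    shape = [1] * a.ndim
    shape[axis] = w.size
    w = w.reshape(shape)
    return a * (1.0 - w) + b * w


def _trilinear_to_fine(coarse: np.ndarray, grid: GridSpec) -> np.ndarray:
    padded = np.pad(coarse.astype(np.float32), 1, mode="constant")
    fx, fy, fz = grid.fine_shape
    lo_x, w_x = _axis_weights(fx, grid.fine_res, grid.spacing)
    lo_y, w_y = _axis_weights(fy, grid.fine_res, grid.spacing)
    lo_z, w_z = _axis_weights(fz, grid.fine_res, grid.coarse_z_res)
    out = _interp_axis(padded, lo_x, w_x, axis=0)
    out = _interp_axis(out, lo_y, w_y, axis=1)
    out = _interp_axis(out, lo_z, w_z, axis=2)
    return np.ascontiguousarray(out, dtype=np.float32)


def interpolate_fine(cmap: CoarseMap) -> FineMap:
    """Trilinearly interpolate the coarse indicators onto the fine grid.

    The fine field evaluated exactly at a coarse voxel centre equals that
    voxel's indicator value; outside the coarse support the fields decay
    linearly to zero within one coarse voxel pitch.
    """
    fields: dict = {
        PRESENCE: _trilinear_to_fine(cmap.cancer_mask.astype(np.float32), cmap.grid)
    }
    for pattern in cmap.patterns_present():
        fields[pattern] = _trilinear_to_fine(
            cmap.pattern_indicator(pattern).astype(np.float32), cmap.grid
        )
    return FineMap(fields=fields, grid=cmap.grid, sigma=None)


# ----------------------------------------------------------------- smoothing

def gaussian_smooth(fine: FineMap, sigma: float) -> FineMap:
    """Convolve every field with an isotropic Gaussian of s.d. ``sigma`` mm.

    ``sigma = 0`` is the identity.  Zero padding outside the volume.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        fields = {k: v.copy() for k, v in fine.fields.items()}
    else:
        sig_vox = sigma / fine.grid.fine_res
        fields = {
            k: ndimage.gaussian_filter(v, sigma=sig_vox, mode="constant", cval=0.0)
            for k, v in fine.fields.items()
        }
    return FineMap(fields=fields, grid=fine.grid, sigma=sigma)


# -------------------------------------------------------------- preservation

def _site_indices(cmap: CoarseMap):
    """Fine-grid indices of every sampled (tissue) coarse voxel centre."""
    grid = cmap.grid
    ii, jj, kk = np.nonzero(cmap.tissue_mask)
    ax = ((grid.spacing * (ii + 0.5)) / grid.fine_res).round().astype(np.int64)
    by = ((grid.spacing * (jj + 0.5)) / grid.fine_res).round().astype(np.int64)
    cz = ((grid.coarse_z_res * (kk + 0.5)) / grid.fine_res).round().astype(np.int64)
    return (ii, jj, kk), (ax, by, cz)


def preservation_check(fine: FineMap, cmap: CoarseMap, mode: str = "patterns"):
    """Does re-sampling the fine map at template grid sites reproduce the
    recorded histology?

    Returns ``(ok, violations)`` where ``violations`` lists the offending
    coarse voxel indices ``(i, j, k)``.  See module docstring for the two
    modes; ``patterns`` (the default) additionally requires that no spurious
    pattern is read at a cancer site.
    """
    if mode not in ("patterns", "primary"):
        raise ValueError(f"mode must be 'patterns' or 'primary', got {mode!r}")
    if fine.grid != cmap.grid:
        raise ValueError("fine map and coarse map geometries differ")
    (ii, jj, kk), (ax, by, cz) = _site_indices(cmap)
    labels = cmap.labels[ii, jj, kk]
    is_cancer = labels > BENIGN
    bad = (fine.fields[PRESENCE][ax, by, cz] >= 0.5) != is_cancer

    if mode == "patterns":
        for pattern in PATTERNS:
            read = fine.pattern_field(pattern)[ax, by, cz] >= 0.5
            expected = is_cancer & ((labels // 10 == pattern) | (labels % 10 == pattern))
            bad |= is_cancer & (read != expected)
    else:
        stack = np.stack([fine.pattern_field(p)[ax, by, cz] for p in PATTERNS], axis=1)
        # argmax with ties resolved toward the higher pattern
        arg = stack.shape[1] - 1 - np.argmax(stack[:, ::-1], axis=1)
        read_primary = np.asarray(PATTERNS)[arg]
        bad |= is_cancer & (read_primary != labels // 10)

    violations = [tuple(int(v) for v in t) for t in zip(ii[bad], jj[bad], kk[bad])]
    return (not violations), violations


# -------------------------------------------------------------------- tuning

def _crop_slices(fine: FineMap, margin_vox: int):
    support = fine.fields[PRESENCE] > 0
    if not support.any():
        return None
    slices = []
    for axis, n in enumerate(fine.grid.fine_shape):
        other = tuple(a for a in range(3) if a != axis)
        profile = support.any(axis=other)
        idx = np.flatnonzero(profile)
        slices.append(slice(max(0, idx[0] - margin_vox), min(n, idx[-1] + 1 + margin_vox)))
    return tuple(slices)


def tune_sigma(
    fine: FineMap,
    cmap: CoarseMap,
    tol: float = 0.05,
    sigma_max: float = 5.0,
    mode: str = "patterns",
) -> float:
    """Largest preserving smoothing parameter, by bisection.

    Returns the largest ``sigma`` in ``[0, sigma_max]`` (to within ``tol`` mm)
    such that :func:`preservation_check` passes on the smoothed map.  The
    unsmoothed interpolation interpolates its nodes, so ``sigma = 0`` always
    satisfies the constraint and the search is well defined; preservation is
    treated as monotone in ``sigma`` (bisection keeps the largest verified
    passing value).  ``sigma_max`` defaults to one grid pitch (5 mm).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if sigma_max < 0:
        raise ValueError("sigma_max must be >= 0")
    if not cmap.cancer_mask.any():
        return sigma_max  # nothing to preserve beyond benign status, all zero fields

    # Smoothing only moves mass within the kernel truncation radius, so the
    # search can run on a crop around the cancer support; sites outside keep
    # zero fields for every sigma and stay trivially preserved.
    margin = int(math.ceil(4.0 * sigma_max / fine.grid.fine_res)) + 1
    box = _crop_slices(fine, margin)
    sub = {k: np.ascontiguousarray(v[box]) for k, v in fine.fields.items()}
    (ii, jj, kk), (ax, by, cz) = _site_indices(cmap)
    inside = np.ones(ax.shape, dtype=bool)
    for coord, sl in zip((ax, by, cz), box):
        inside &= (coord >= sl.start) & (coord < sl.stop)
    sel = (ii[inside], jj[inside], kk[inside])
    site = (ax[inside] - box[0].start, by[inside] - box[1].start, cz[inside] - box[2].start)
    labels = cmap.labels[sel]
    is_cancer = labels > BENIGN

    def preserved(sigma: float) -> bool:
        sig_vox = sigma / fine.grid.fine_res
        if sigma == 0:
            smoothed = sub
        else:
            smoothed = {
                k: ndimage.gaussian_filter(v, sigma=sig_vox, mode="constant", cval=0.0)
                for k, v in sub.items()
            }
        if np.any((smoothed[PRESENCE][site] >= 0.5) != is_cancer):
            return False
        if mode == "patterns":
            for pattern in PATTERNS:
                vals = smoothed[pattern][site] if pattern in smoothed else np.zeros(len(labels))
                expected = is_cancer & ((labels // 10 == pattern) | (labels % 10 == pattern))
                if np.any(is_cancer & ((vals >= 0.5) != expected)):
                    return False
            return True
        stack = np.stack(
            [smoothed[p][site] if p in smoothed else np.zeros(len(labels)) for p in PATTERNS],
            axis=1,
        )
        arg = stack.shape[1] - 1 - np.argmax(stack[:, ::-1], axis=1)
        return not np.any(is_cancer & (np.asarray(PATTERNS)[arg] != labels // 10))

    if preserved(sigma_max):
        return sigma_max
    lo, hi = 0.0, sigma_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if preserved(mid):
            lo = mid
        else:
            hi = mid
    return lo


def reconstruct(
    cmap: CoarseMap,
    tol: float = 0.05,
    sigma_max: float = 5.0,
    mode: str = "patterns",
) -> FineMap:
    """Full reconstruction: interpolate, tune sigma, smooth."""
    fine = interpolate_fine(cmap)
    sigma = tune_sigma(fine, cmap, tol=tol, sigma_max=sigma_max, mode=mode)
    return gaussian_smooth(fine, sigma)
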