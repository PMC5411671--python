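"""Coarse 13 x 13 x 40 labelled voxel map built from per-core pathology.

Each coarse voxel is 5 x 5 x 1 mm.  A voxel is labelled with the Gleason score
of the cancer segment covering it, ``BENIGN`` if the voxel lies within a
sampled core but outside any cancer segment, or ``NO_TISSUE`` if its template
hole was never biopsied.

Cancer core length (CCL) counting rules for discontinuous foci in one core:

* ``separate`` — intervening benign tissue is excluded; the core's segments
  are the reported foci themselves and the CCL is the sum of their lengths.
* ``cumulative`` — the CCL spans from the start of the first focus to the end
  of the last, benign gaps included; the single merged segment carries a
  recombined Gleason score (primary = most abundant pattern weighted by focus
  length, secondary = highest other pattern present).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grading import GleasonPair, pair_str, validate_pair
from .grid import GridSpec
from .io import CoreRecord, ValidationError

__all__ = [
    "NO_TISSUE",
    "BENIGN",
    "CCL_MODES",
    "CCLSegment",
    "CCLResult",
    "CoarseMap",
    "compute_ccl",
    "build_coarse_map",
    "encode_pair",
    "decode_pair",
]

NO_TISSUE = -1
BENIGN = 0
CCL_MODES = ("separate", "cumulative")


def encode_pair(pair: GleasonPair) -> int:
    """Encode a Gleason score as a small integer label (3+4 -> 34)."""
    primary, secondary = validate_pair(pair)
    return 10 * primary + secondary


def decode_pair(label: int) -> GleasonPair:
    if label < 10:
        raise ValueError(f"label {label} is not a Gleason score label")
    return validate_pair((label // 10, label % 10))


@dataclass(frozen=True)
class CCLSegment:
    """One cancer segment in core-local coordinates (mm from the apical end)."""

    start: float
    end: float
    score: GleasonPair

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class CCLResult:
    """CCL of one core under one counting mode.

    ``ccl`` is the scalar cancer core length per the active mode; ``mccl`` is
    the length of the longest single segment (the basis for the per-patient
    maximum CCL).  Under the separate mode ``segments`` are the reported foci;
    under the cumulative mode there is a single merged segment.
    """

    segments: tuple[CCLSegment, ...]
    ccl: float
    mccl: float
    mode: str


def _recombine_score(core: CoreRecord) -> GleasonPair:
    """Merged Gleason score of a cumulative segment.

    Primary = pattern with the largest focus-length-weighted abundance (each
    focus contributes its full length to its primary pattern; ties break toward
    the higher pattern).  Secondary = highest other pattern present in any
    focus score, or the primary itself if the merged segment is pure.
    """
    weights: dict[int, float] = {}
    present: set[int] = set()
    for focus in core.foci:
        weights[focus.primary] = weights.get(focus.primary, 0.0) + focus.length
        present.update((focus.primary, focus.secondary))
    primary = max(weights, key=lambda p: (weights[p], p))
    others = present - {primary}
    secondary = max(others) if others else primary
    return (primary, secondary)


def compute_ccl(core: CoreRecord, mode: str = "separate") -> CCLResult:
    """Cancer core length of ``core`` under the given counting mode."""
    if mode not in CCL_MODES:
        raise ValueError(f"mode must be one of {CCL_MODES}, got {mode!r}")
    if not core.foci:
        return CCLResult(segments=(), ccl=0.0, mccl=0.0, mode=mode)
    if mode == "separate":
        segments = tuple(
            CCLSegment(f.offset, f.end, f.score) for f in core.foci
        )
        ccl = sum(s.length for s in segments)
    else:
        span = CCLSegment(core.foci[0].offset, core.foci[-1].end, _recombine_score(core))
        segments = (span,)
        ccl = span.length
    mccl = max(s.length for s in segments)
    return CCLResult(segments=segments, ccl=ccl, mccl=mccl, mode=mode)


@dataclass
class CoarseMap:
    """Labelled 13 x 13 x 40 voxel map of one patient.

    ``labels[i, j, k]`` is ``NO_TISSUE`` (-1), ``BENIGN`` (0) or an encoded
    Gleason score (:func:`encode_pair`).  z index ``k`` covers physical
    ``z in [k, k+1)`` mm with z = 0 at the apical end of the apex needle.
    """

    labels: np.ndarray
    grid: GridSpec
    ccl_mode: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.shape != self.grid.coarse_shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid {self.grid.coarse_shape}"
            )

    @property
    def cancer_mask(self) -> np.ndarray:
        return self.labels > BENIGN

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels >= BENIGN

    def pattern_indicator(self, pattern: int) -> np.ndarray:
        """Boolean array: voxel's Gleason score contains ``pattern``."""
        primary = self.labels // 10
        secondary = np.where(self.labels > BENIGN, self.labels % 10, 0)
        return (primary == pattern) | (secondary == pattern)

    def patterns_present(self) -> list[int]:
        return sorted(
            {int(p) for lab in np.unique(self.labels[self.labels > BENIGN])
             for p in decode_pair(int(lab))}
        )

    def pair_at(self, i: int, j: int, k: int) -> GleasonPair | None:
        label = int(self.labels[i, j, k])
        return decode_pair(label) if label > BENIGN else None

    def n_cancer_voxels(self) -> int:
        return int(self.cancer_mask.sum())

    def to_nifti(self, path) -> None:
        """Export as NIfTI with 5 x 5 x 1 mm voxel spacing in the header."""
        import nibabel as nib

        affine = np.diag([self.grid.spacing, self.grid.spacing, self.grid.coarse_z_res, 1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))

    def label_dictionary(self) -> dict[str, str]:
        out = {str(NO_TISSUE): "no_tissue", str(BENIGN): "benign"}
        for lab in np.unique(self.labels[self.labels > BENIGN]):
            out[str(int(lab))] = pair_str(decode_pair(int(lab)))
        return out


def _paint_segments(column: np.ndarray, z0: float, result: CCLResult,
                    z_res: float, window_end: float) -> None:
    """Paint a core's segments into one (x, y) label column.

    A voxel ``[k, k+1)`` mm receives a segment's score when the segment covers
    at least half of it (>= 0.5 mm overlap for 1 mm sections).
    """
    for segment in result.segments:
        if segment.end > window_end + 1e-9:
            raise ValidationError(
                f"segment [{segment.start}, {segment.end}] mm extends past the "
                f"{window_end} mm core window"
            )
        gstart = z0 + segment.start
        gend = z0 + segment.end
        k_lo = int(np.floor(gstart / z_res))
        k_hi = int(np.ceil(gend / z_res))
        for k in range(max(k_lo, 0), min(k_hi, column.shape[0])):
            overlap = min(gend, (k + 1) * z_res) - max(gstart, k * z_res)
            if overlap >= 0.5 * z_res - 1e-9:
                column[k] = encode_pair(segment.score)


def build_coarse_map(records, grid: GridSpec | None = None,
                     ccl_mode: str = "separate") -> CoarseMap:
    """Paint one patient's core records into the coarse voxel map.

    Apex cores map core-local z directly to global z (apical end at z = 0);
    base cores are offset by one needle length (20 mm).  Voxels covered by a
    sampled core but by no cancer segment are benign; template holes without a
    record remain ``NO_TISSUE``.  Painting is order-independent because each
    record owns a disjoint (x, y, depth window) region.
    """
    grid = grid or GridSpec()
    if ccl_mode not in CCL_MODES:
        raise ValueError(f"ccl_mode must be one of {CCL_MODES}, got {ccl_mode!r}")
    records = list(records)
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValidationError(f"coarse map expects one patient, got {sorted(patients)}")
    seen: set[tuple[int, int, str]] = set()
    labels = np.full(grid.coarse_shape, NO_TISSUE, dtype=np.int16)
    z_res = grid.coarse_z_res
    for record in records:
        record.validate_grid(grid)
        if record.key in seen:
            raise ValidationError(f"duplicate core at {record.key}")
        seen.add(record.key)
        z0, z1 = grid.depth_window(record.depth)
        k0 = int(round(z0 / z_res))
        k1 = int(round(z1 / z_res))
        column = labels[record.grid_x, record.grid_y]
        column[k0:k1] = np.maximum(column[k0:k1], BENIGN)
        result = compute_ccl(record, ccl_mode)
        _paint_segments(column[k0:k1], 0.0, result, z_res, grid.needle_length)
    return CoarseMap(labels=labels, grid=grid, ccl_mode=ccl_mode)
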