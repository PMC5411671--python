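"""Virtual-needle simulation and per-lesion hotspot concordance.

A virtual biopsy needle is a cranio-caudal (z) track through the fine
reconstructed map at one (x, y) position of the 0.5 mm sampling plane.  For
each lesion:

* the *volume hotspot* is the set of sampling-plane coordinates whose needle
  returns the lesion's longest cancer core length (CCL);
* the *Gleason grade hotspot* is the set of coordinates whose needle samples
  the lesion's highest Gleason pattern.

The two hotspots are *concordant* when the (x, y) sets intersect — a single
needle at the maximum-CCL coordinate would attribute the correct maximum
grade.  When they are disjoint, the 3-D hotspot distance is the minimal
Euclidean distance between volume-hotspot points (x, y, ccl_z) and
grade-hotspot points (x, y, grade_z), where ccl_z is the z midpoint of the
cancer run and grade_z the z centroid of the maximum-grade voxels.

CCL along a track is measured by integrating the 0.5-level set of the
presence field with piecewise-linear (sub-voxel) crossings; on pure indicator
columns this equals 0.5 mm times the cancer-voxel count, but on smooth
reconstructions it avoids spurious 0.5 mm-quantisation plateaus of tied
maximum-CCL columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .coarse_map import CoarseMap, decode_pair
from .grading import GleasonPair, PATTERNS, best_pair, pair_total
from .reconstruction import PRESENCE, FineMap
from .segmentation import LesionLabelMap

__all__ = [
    "NeedleProfile",
    "LesionReport",
    "propagate_lesion_ids",
    "simulate_needle",
    "find_hotspots",
    "classify_heterogeneity",
    "assess_concordance",
    "lesion_volume",
    "analyze_lesions",
]


# ------------------------------------------------------------- lesion labels

def propagate_lesion_ids(fine: FineMap, lesions: LesionLabelMap) -> np.ndarray:
    """Assign each fine cancer voxel the id of the nearest coarse cancer voxel.

    Nearness is Euclidean in mm between the fine voxel position and coarse
    voxel centres (which are exact fine grid points).  Fine voxels outside the
    smoothed cancer mask get id 0.
    """
    if fine.grid != lesions.grid:
        raise ValueError("fine map and lesion map geometries differ")
    grid = fine.grid
    out = np.zeros(grid.fine_shape, dtype=np.int32)
    if lesions.n_lesions == 0:
        return out
    cancer = fine.cancer_mask
    if not cancer.any():
        return out

    ii, jj, kk = np.nonzero(lesions.labels > 0)
    ax = ((grid.spacing * (ii + 0.5)) / grid.fine_res).round().astype(np.int64)
    by = ((grid.spacing * (jj + 0.5)) / grid.fine_res).round().astype(np.int64)
    cz = ((grid.coarse_z_res * (kk + 0.5)) / grid.fine_res).round().astype(np.int64)

    # crop to the joint support to keep the EDT cheap
    box = []
    for coords, mask_axis, n in zip(
        (ax, by, cz),
        [cancer.any(axis=(1, 2)), cancer.any(axis=(0, 2)), cancer.any(axis=(0, 1))],
        grid.fine_shape,
    ):
        idx = np.flatnonzero(mask_axis)
        lo = min(int(coords.min()), int(idx[0]))
        hi = max(int(coords.max()), int(idx[-1])) + 1
        box.append(slice(max(0, lo - 2), min(n, hi + 2)))
    box = tuple(box)

    seed_ids = np.zeros([s.stop - s.start for s in box], dtype=np.int32)
    seed_ids[ax - box[0].start, by - box[1].start, cz - box[2].start] = \
        lesions.labels[ii, jj, kk]
    idx = ndimage.distance_transform_edt(
        seed_ids == 0, return_distances=False, return_indices=True
    )
    out[box] = np.where(cancer[box], seed_ids[tuple(idx)], 0)
    return out


# --------------------------------------------------------------- needle math

def _column_ccl_stats(values: np.ndarray, res: float):
    """Vectorised track statistics from a (nx, ny, nz) presence-like field.

    Returns ``(ccl, z_first, z_last)`` per column, with sub-voxel 0.5-level
    crossings.  Columns never reaching 0.5 get ccl 0 and NaN endpoints.
    Node ``c`` sits at ``z = res * c`` mm; the field is taken as 0 beyond the
    volume ends.
    """
    v = np.pad(values, ((0, 0), (0, 0), (1, 1)), mode="constant")
    a = v[..., :-1]
    b = v[..., 1:]
    above_a = a >= 0.5
    above_b = b >= 0.5
    denom = b - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom != 0, (0.5 - a) / denom, 0.0)
    frac = np.where(
        above_a & above_b, 1.0,
        np.where(above_b, 1.0 - t, np.where(above_a, t, 0.0)),
    )
    ccl = res * frac.sum(axis=2)

    above = v >= 0.5
    any_above = above.any(axis=2)
    first = np.argmax(above, axis=2)          # first padded node >= 0.5 (>= 1)
    last = v.shape[2] - 1 - np.argmax(above[..., ::-1], axis=2)
    cols = np.nonzero(any_above)
    z_first = np.full(values.shape[:2], np.nan)
    z_last = np.full(values.shape[:2], np.nan)
    f = first[cols]
    l = last[cols]
    a_f = v[cols[0], cols[1], f - 1]
    b_f = v[cols[0], cols[1], f]
    t_f = np.where(b_f != a_f, (0.5 - a_f) / (b_f - a_f), 1.0)
    a_l = v[cols[0], cols[1], l]
    b_l = v[cols[0], cols[1], l + 1]
    t_l = np.where(b_l != a_l, (a_l - 0.5) / (a_l - b_l), 1.0)
    # un-pad: physical node index = padded - 1
    z_first[cols] = res * ((f - 2) + t_f)
    z_last[cols] = res * (l - 1 + t_l)
    return ccl, z_first, z_last


@dataclass(frozen=True)
class NeedleProfile:
    """Reading of one virtual needle within one lesion."""

    x_mm: float
    y_mm: float
    ccl: float
    max_grade: int | None
    grade_z: float | None
    ccl_z: float | None


def _lesion_fine_mask(fine: FineMap, lesion_ids: np.ndarray, lesion_id: int) -> np.ndarray:
    if lesion_id < 1 or not (lesion_ids == lesion_id).any():
        raise KeyError(f"unknown lesion id {lesion_id}")
    return lesion_ids == lesion_id


def _lesion_max_pattern(fine: FineMap, mask: np.ndarray,
                        fallback: int | None = None) -> int | None:
    for pattern in sorted(fine.patterns, reverse=True):
        if (mask & (fine.fields[pattern] >= 0.5)).any():
            return pattern
    return fallback


def simulate_needle(fine: FineMap, lesion_ids: np.ndarray, x: int, y: int,
                    lesion_id: int) -> NeedleProfile:
    """Read one cranio-caudal needle at fine sampling-plane position (x, y).

    ``x``/``y`` are fine-grid indices (0.5 mm pitch).  The needle reports the
    lesion's cancer length on the track, the highest Gleason pattern sampled,
    and the representative z positions.
    """
    mask = _lesion_fine_mask(fine, lesion_ids, lesion_id)
    column = np.where(mask, fine.fields[PRESENCE], 0.0)[x:x + 1, y:y + 1, :]
    ccl, z_first, z_last = _column_ccl_stats(column, fine.grid.fine_res)
    ccl = float(ccl[0, 0])
    x_mm = x * fine.grid.fine_res
    y_mm = y * fine.grid.fine_res
    if ccl == 0:
        return NeedleProfile(x_mm, y_mm, 0.0, None, None, None)
    ccl_z = float(0.5 * (z_first[0, 0] + z_last[0, 0]))
    track = mask[x, y, :]
    max_grade = None
    grade_z = None
    for pattern in sorted(fine.patterns, reverse=True):
        hit = track & (fine.fields[pattern][x, y, :] >= 0.5)
        if hit.any():
            max_grade = pattern
            grade_z = float(np.nonzero(hit)[0].mean() * fine.grid.fine_res)
            break
    return NeedleProfile(x_mm, y_mm, ccl, max_grade, grade_z, ccl_z)


@dataclass(frozen=True)
class HotspotSet:
    """One lesion's hotspot as a set of sampling-plane columns.

    ``columns`` is an (n, 2) integer array of fine-grid (x, y) indices;
    ``z_mm`` the matching representative z per column; ``value`` the maximal
    CCL (mm) or the maximal Gleason pattern.
    """

    columns: np.ndarray
    z_mm: np.ndarray
    value: float

    def points_mm(self, res: float) -> np.ndarray:
        return np.column_stack([self.columns * res, self.z_mm])


def find_hotspots(fine: FineMap, lesion_ids: np.ndarray, lesion_id: int):
    """Volume and grade hotspot sets of one lesion.

    Returns ``(volume_hotspot, grade_hotspot)``: the columns attaining the
    maximal per-track CCL, and the columns whose track samples the lesion's
    maximal Gleason pattern.
    """
    res = fine.grid.fine_res
    mask = _lesion_fine_mask(fine, lesion_ids, lesion_id)
    masked_presence = np.where(mask, fine.fields[PRESENCE], 0.0)
    ccl, z_first, z_last = _column_ccl_stats(masked_presence, res)
    max_ccl = float(ccl.max())
    if max_ccl <= 0:
        raise ValueError(f"lesion {lesion_id} has no cancer track on the fine map")
    vol_cols = np.argwhere(ccl >= max_ccl - 1e-6)
    vol_z = 0.5 * (z_first[vol_cols[:, 0], vol_cols[:, 1]]
                   + z_last[vol_cols[:, 0], vol_cols[:, 1]])
    volume_hotspot = HotspotSet(vol_cols, vol_z, max_ccl)

    max_pattern = _lesion_max_pattern(fine, mask)
    if max_pattern is None:
        # degenerate (no pattern field reaches threshold): grade is carried by
        # every cancer track of the lesion
        gmask = mask
        max_pattern_value = 0
    else:
        gmask = mask & (fine.fields[max_pattern] >= 0.5)
        max_pattern_value = max_pattern
    grade_cols = np.argwhere(gmask.any(axis=2))
    z_idx = np.arange(fine.grid.fine_shape[2])
    counts = gmask[grade_cols[:, 0], grade_cols[:, 1], :]
    grade_z = (counts * z_idx).sum(axis=1) / counts.sum(axis=1) * res
    grade_hotspot = HotspotSet(grade_cols, grade_z, float(max_pattern_value))
    return volume_hotspot, grade_hotspot


# ------------------------------------------------------------ classification

def classify_heterogeneity(composition, criterion: str = "grades") -> bool:
    """Is a lesion's Gleason composition heterogeneous?

    ``composition`` is the set of Gleason scores (ordered pairs) present in
    the lesion.  Under the ``grades`` criterion any two distinct ordered pairs
    (e.g. 3+4 vs 4+3) make the lesion heterogeneous; under the ``score``
    criterion pairs with equal total score are identified (3+4 and 4+3 count
    as the same), so heterogeneity needs two different total scores.
    """
    pairs = {tuple(p) for p in composition}
    if not pairs:
        raise ValueError("composition must be non-empty")
    if criterion == "grades":
        return len(pairs) > 1
    if criterion == "score":
        return len({pair_total(p) for p in pairs}) > 1
    raise ValueError(f"criterion must be 'grades' or 'score', got {criterion!r}")


def assess_concordance(volume_hotspot: HotspotSet, grade_hotspot: HotspotSet,
                       res: float = 0.5):
    """Concordance of the two hotspot sets and, if discordant, their distance.

    Concordant iff the (x, y) column sets intersect.  Otherwise the distance
    is the minimal 3-D Euclidean distance (mm) between volume points
    (x, y, ccl_z) and grade points (x, y, grade_z).
    """
    if volume_hotspot.columns.size == 0 or grade_hotspot.columns.size == 0:
        raise ValueError("hotspot sets must be non-empty")
    vol = {tuple(c) for c in volume_hotspot.columns}
    gra = {tuple(c) for c in grade_hotspot.columns}
    if vol & gra:
        return True, None
    p = volume_hotspot.points_mm(res)
    q = grade_hotspot.points_mm(res)
    d2 = ((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
    return False, float(np.sqrt(d2.min()))


def lesion_volume(lesions: LesionLabelMap, lesion_id: int) -> float:
    """Lesion volume in ml: coarse block count x 0.025 ml (5 x 5 x 1 mm)."""
    lesions._check_id(lesion_id)
    count = int((lesions.labels == lesion_id).sum())
    return count * lesions.grid.voxel_volume_ml


# ------------------------------------------------------------------- reports

@dataclass(frozen=True)
class LesionReport:
    """Everything measured about one reconstructed lesion."""

    lesion_id: int
    n_voxels: int
    volume_ml: float
    composition: tuple[GleasonPair, ...]
    score: GleasonPair
    heterogeneous_by_grades: bool
    heterogeneous_by_score: bool
    max_ccl_mm: float
    max_grade: int
    volume_hotspot_mm: tuple[float, float, float]
    grade_hotspot_mm: tuple[float, float, float]
    geometric_concordant: bool
    hotspot_distance_mm: float | None

    def concordant(self, criterion: str = "grades") -> bool:
        """Concordance under a heterogeneity criterion.

        Homogeneous lesions are inherently concordant; heterogeneous lesions
        are concordant iff their hotspot sets intersect.
        """
        return (not self.heterogeneous(criterion)) or self.geometric_concordant

    def heterogeneous(self, criterion: str = "grades") -> bool:
        return (self.heterogeneous_by_grades if criterion == "grades"
                else self.heterogeneous_by_score if criterion == "score"
                else classify_heterogeneity(self.composition, criterion))


def _representative_points(volume_hotspot, grade_hotspot, res, concordant):
    """A representative (x, y, z) mm per hotspot; the closest pair if discordant."""
    p = volume_hotspot.points_mm(res)
    q = grade_hotspot.points_mm(res)
    if concordant:
        vol = {tuple(c): i for i, c in enumerate(map(tuple, volume_hotspot.columns))}
        for j, c in enumerate(map(tuple, grade_hotspot.columns)):
            if c in vol:
                return tuple(p[vol[c]]), tuple(q[j])
    d2 = ((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return tuple(p[i]), tuple(q[j])


def analyze_lesions(cmap: CoarseMap, lesions: LesionLabelMap,
                    fine: FineMap) -> list[LesionReport]:
    """Per-lesion hotspot analysis over a reconstructed patient map."""
    lesion_ids = propagate_lesion_ids(fine, lesions)
    reports = []
    for lesion_id in range(1, lesions.n_lesions + 1):
        vox = lesions.voxels(lesion_id)
        labels = cmap.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
        composition = tuple(sorted({decode_pair(int(l)) for l in labels}))
        score = best_pair(composition)
        if not (lesion_ids == lesion_id).any():
            # smoothed below threshold everywhere (cannot happen when sigma is
            # tuned with the preservation constraint); fall back to the site
            i, j, k = (int(v) for v in vox[0])
            site = cmap.grid.site_center_mm(i, j, k)
            reports.append(LesionReport(
                lesion_id=lesion_id, n_voxels=len(vox),
                volume_ml=lesion_volume(lesions, lesion_id),
                composition=composition, score=score,
                heterogeneous_by_grades=classify_heterogeneity(composition, "grades"),
                heterogeneous_by_score=classify_heterogeneity(composition, "score"),
                max_ccl_mm=0.0, max_grade=max(max(p) for p in composition),
                volume_hotspot_mm=site, grade_hotspot_mm=site,
                geometric_concordant=True, hotspot_distance_mm=None,
            ))
            continue
        volume_hotspot, grade_hotspot = find_hotspots(fine, lesion_ids, lesion_id)
        concordant, distance = assess_concordance(
            volume_hotspot, grade_hotspot, fine.grid.fine_res
        )
        vol_pt, grade_pt = _representative_points(
            volume_hotspot, grade_hotspot, fine.grid.fine_res, concordant
        )
        reports.append(LesionReport(
            lesion_id=lesion_id,
            n_voxels=len(vox),
            volume_ml=lesion_volume(lesions, lesion_id),
            composition=composition,
            score=score,
            heterogeneous_by_grades=classify_heterogeneity(composition, "grades"),
            heterogeneous_by_score=classify_heterogeneity(composition, "score"),
            max_ccl_mm=volume_hotspot.value,
            max_grade=int(grade_hotspot.value) or max(max(p) for p in composition),
            volume_hotspot_mm=tuple(float(v) for v in vol_pt),
            grade_hotspot_mm=tuple(float(v) for v in grade_pt),
            geometric_concordant=concordant,
            hotspot_distance_mm=distance,
        ))
    return reports
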