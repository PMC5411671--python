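"""Synthetic prostates with planted lesions, sampled on the template grid.

The generator builds a ground-truth Gleason-pattern volume at the fine 0.5 mm
resolution (voxel labels in {benign, 3, 4, 5}), then simulates the TPM biopsy
by reading the truth along each template needle track and reporting contiguous
cancer runs as per-core foci — exactly the information a pathologist records.
Because every lesion's geometry is known in closed form, the truth metadata is
sufficient to score hotspot recovery downstream without access to generator
internals.

Lesion model
------------
* Lesions are axis-aligned ellipsoids.  A *homogeneous* lesion carries one
  Gleason score: for a pure score (3+3, 4+4) every voxel holds the single
  pattern; for a mixed score (3+4, 4+3) the secondary pattern occupies a
  mid-chord band sized per column (~40% of each chord, at least one voxel) so
  that every needle chord through the lesion reads exactly the planted score.
  Columns with chords under three voxels are trimmed so no core can read a
  partial score.
* A *heterogeneous* lesion is a single-pattern body with a planted spherical
  focus of a higher grade.  Needles through the focus footprint read the mixed
  score; the rest read the pure body score.
* The focus z-centre coincides with the lesion z-centre: per-focus grading
  reports which patterns a core contains, not where along the core they lie,
  so an off-centre z position would not be recoverable from the report format
  (see the methods note).

Free-placement cohorts (:func:`make_cohort`) place lesions continuously inside
a per-patient gland footprint; grid-aligned phantom cohorts
(:func:`make_offset_phantoms`) centre the lesion and its focus exactly on
template holes so the planted hotspot separation is unambiguous relative to
the 5 mm sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .grading import GleasonPair, validate_pair, validate_pattern
from .grid import DEPTH_SLOTS, GridSpec
from .io import CancerFocus, CoreRecord, write_core_table

__all__ = [
    "FocusSpec",
    "LesionSpec",
    "CohortSpec",
    "TruthLesion",
    "PatientTruth",
    "Cohort",
    "generate_truth_volume",
    "sample_cores",
    "make_cohort",
    "make_offset_phantoms",
]

BENIGN = 0

# fraction of each chord given to the secondary pattern in mixed-score lesions
_SECONDARY_CHORD_FRACTION = 0.4
# minimum chord (in fine voxels) for a column to belong to a mixed-score lesion
_MIN_MIXED_CHORD_VOX = 3
# focus radius (mm) guaranteeing at least one template needle samples it when
# lesions are placed freely: must exceed spacing/2 * sqrt(2) ~ 3.54 mm
FREE_PLACEMENT_FOCUS_RADIUS = 3.6


@dataclass(frozen=True)
class FocusSpec:
    """Planted high-grade spherical sub-region of a lesion."""

    center: tuple[float, float, float]
    radius: float
    grade: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("focus radius must be positive")
        validate_pattern(self.grade)


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth lesion: ellipsoid with optional high-grade focus."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    base_score: GleasonPair = (3, 3)
    focus: FocusSpec | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("ellipsoid radii must be positive")
        validate_pair(self.base_score)
        if self.focus is not None:
            # the focus must lie inside the ellipsoid
            d = [
                abs(f - c) + self.focus.radius
                for f, c in zip(self.focus.center, self.center)
            ]
            if any(di > ri + 1e-9 for di, ri in zip(d, self.radii)):
                raise ValueError("focus sphere extends outside the lesion ellipsoid")

    @property
    def volume_ml(self) -> float:
        rx, ry, rz = self.radii
        return 4.0 / 3.0 * math.pi * rx * ry * rz / 1000.0

    @property
    def planar_offset(self) -> float:
        """Planar distance from lesion centre to focus centre (0 if none)."""
        if self.focus is None:
            return 0.0
        return math.hypot(
            self.focus.center[0] - self.center[0],
            self.focus.center[1] - self.center[1],
        )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a free-placement synthetic cohort.

    Defaults emulate the pilot cohort this pipeline was designed around:
    94 patients, about two lesions per patient, 24% of lesions heterogeneous
    in grade, and 23% of heterogeneous lesions with a discordantly placed
    high-grade focus.
    """

    n_patients: int = 94
    lesions_per_patient: float = 2.0       # Poisson mean
    fraction_heterogeneous: float = 0.24
    discordant_focus_prob: float = 0.23
    discontinuity_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_heterogeneous", "discordant_focus_prob",
                     "discontinuity_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_patients < 0 or self.lesions_per_patient < 0:
            raise ValueError("cohort sizes must be non-negative")


@dataclass(frozen=True)
class TruthLesion:
    """Planted-truth metadata for scoring recovery of one lesion."""

    patient_id: str
    index: int
    spec: LesionSpec
    volume_ml: float
    max_ccl_mm: float                       # longest possible chord, 2*rz
    max_ccl_xy_mm: tuple[float, float]      # column of that chord (the centre)
    grade_focus_center_mm: tuple[float, float, float] | None
    heterogeneous: bool
    concordant: bool
    hotspot_distance_mm: float | None       # closed-form, None when concordant
    n_template_columns_hit: int = 0

    def to_dict(self) -> dict:
        spec = self.spec
        return {
            "patient_id": self.patient_id,
            "index": self.index,
            "center_mm": list(spec.center),
            "radii_mm": list(spec.radii),
            "base_score": list(spec.base_score),
            "focus": None if spec.focus is None else {
                "center_mm": list(spec.focus.center),
                "radius_mm": spec.focus.radius,
                "grade": spec.focus.grade,
            },
            "volume_ml": self.volume_ml,
            "max_ccl_mm": self.max_ccl_mm,
            "max_ccl_xy_mm": list(self.max_ccl_xy_mm),
            "grade_focus_center_mm": None if self.grade_focus_center_mm is None
            else list(self.grade_focus_center_mm),
            "heterogeneous": self.heterogeneous,
            "concordant": self.concordant,
            "hotspot_distance_mm": self.hotspot_distance_mm,
            "n_template_columns_hit": self.n_template_columns_hit,
        }


@dataclass
class PatientTruth:
    patient_id: str
    records: list[CoreRecord]
    lesions: list[TruthLesion]
    footprint: np.ndarray                   # (nx, ny) bool, sampled holes


@dataclass
class Cohort:
    patients: list[PatientTruth]
    grid: GridSpec
    spec: CohortSpec | None = None

    @property
    def lesions(self) -> list[TruthLesion]:
        return [lesion for p in self.patients for lesion in p.lesions]

    def write(self, out_dir: str | Path) -> None:
        """Per-patient core CSVs plus a truth JSON enabling recovery tests."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for patient in self.patients:
            write_core_table(patient.records, out_dir / f"cores_{patient.patient_id}.csv")
        truth = {
            "lesions": [lesion.to_dict() for lesion in self.lesions],
            "n_patients": len(self.patients),
        }
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))


# ----------------------------------------------------------------- truth map

def _truth_metadata(patient_id: str, index: int, spec: LesionSpec) -> TruthLesion:
    cx, cy, cz = spec.center
    heterogeneous = (
        spec.focus is not None
        and spec.focus.grade not in set(spec.base_score)
    )
    concordant = True
    distance = None
    if heterogeneous:
        rho = spec.planar_offset
        concordant = rho <= spec.focus.radius
        if not concordant:
            # both hotspot z representatives sit at the chord mid-plane z = cz
            # (per-focus grading erases the focus z position; see module notes)
            distance = rho - spec.focus.radius
    return TruthLesion(
        patient_id=patient_id,
        index=index,
        spec=spec,
        volume_ml=spec.volume_ml,
        max_ccl_mm=2.0 * spec.radii[2],
        max_ccl_xy_mm=(cx, cy),
        grade_focus_center_mm=None if spec.focus is None else spec.focus.center,
        heterogeneous=heterogeneous,
        concordant=concordant,
        hotspot_distance_mm=distance,
    )


def generate_truth_volume(
    lesions: Sequence[LesionSpec],
    grid: GridSpec | None = None,
    patient_id: str = "P0",
) -> tuple[np.ndarray, list[TruthLesion]]:
    """Rasterise lesions into a fine ground-truth Gleason-pattern volume.

    Returns ``(truth, metadata)``: an int8 volume on the fine grid with voxel
    labels in {0, 3, 4, 5}, and per-lesion truth metadata (true volume, true
    maximum CCL and its column, grade-focus centre, closed-form concordance).
    The generation is deterministic — all randomness lives in the cohort
    builders.
    """
    grid = grid or GridSpec()
    fx, fy, fz = grid.fine_shape
    truth = np.zeros((fx, fy, fz), dtype=np.int8)
    xs = grid.fine_res * np.arange(fx)
    ys = grid.fine_res * np.arange(fy)
    zs = grid.fine_res * np.arange(fz)
    field_x, field_y, field_z = grid.field_mm

    metadata = []
    for index, spec in enumerate(lesions, start=1):
        cx, cy, cz = spec.center
        rx, ry, rz = spec.radii
        if (cx - rx < -1e-9 or cx + rx > field_x + 1e-9
                or cy - ry < -1e-9 or cy + ry > field_y + 1e-9
                or cz - rz < -1e-9 or cz + rz > field_z + 1e-9):
            raise ValueError(
                f"lesion {index} at {spec.center} with radii {spec.radii} "
                f"extends outside the {field_x:g}x{field_y:g}x{field_z:g} mm field"
            )
        # bounding box in fine indices
        sl = tuple(
            slice(max(0, int(math.floor((c - r) / grid.fine_res))),
                  min(n, int(math.ceil((c + r) / grid.fine_res)) + 1))
            for c, r, n in zip(spec.center, spec.radii, (fx, fy, fz))
        )
        gx = (xs[sl[0]] - cx)[:, None, None] / rx
        gy = (ys[sl[1]] - cy)[None, :, None] / ry
        gz = (zs[sl[2]] - cz)[None, None, :] / rz
        inside = gx ** 2 + gy ** 2 + gz ** 2 <= 1.0

        primary, secondary = spec.base_score
        if primary == secondary:
            patch = np.where(inside, np.int8(primary), np.int8(0))
        else:
            patch = _mixed_score_patch(inside, primary, secondary)
        if spec.focus is not None:
            fxc, fyc, fzc = spec.focus.center
            gx = (xs[sl[0]] - fxc)[:, None, None]
            gy = (ys[sl[1]] - fyc)[None, :, None]
            gz = (zs[sl[2]] - fzc)[None, None, :]
            sphere = gx ** 2 + gy ** 2 + gz ** 2 <= spec.focus.radius ** 2
            patch = np.where(sphere & (patch > 0), np.int8(spec.focus.grade), patch)

        target = truth[sl]
        if np.any((target > 0) & (patch > 0)):
            raise ValueError(f"lesion {index} overlaps a previously placed lesion")
        truth[sl] = np.where(patch > 0, patch, target)
        metadata.append(_truth_metadata(patient_id, index, spec))
    return truth, metadata


def _mixed_score_patch(inside: np.ndarray, primary: int, secondary: int) -> np.ndarray:
    """Per-column pattern assignment for a mixed-score (e.g. 3+4) lesion.

    The secondary pattern occupies a centred band of ``max(1, floor(0.4 m))``
    of each column's ``m`` cancer voxels; columns with ``m < 3`` are trimmed
    so every possible core read reproduces the planted score exactly.
    """
    m = inside.sum(axis=2)
    patch = np.where(inside, np.int8(primary), np.int8(0))
    patch[m < _MIN_MIXED_CHORD_VOX] = 0
    cols = np.argwhere(m >= _MIN_MIXED_CHORD_VOX)
    nz = inside.shape[2]
    idx = np.arange(nz)
    for i, j in cols:
        column = inside[i, j]
        run = idx[column]
        count = run.size
        band = max(1, int(math.floor(_SECONDARY_CHORD_FRACTION * count)))
        start = run[0] + (count - band) // 2
        patch[i, j, start:start + band] = secondary
    return patch


# ------------------------------------------------------------------ sampling

def _run_grades(patterns: np.ndarray) -> tuple[int, int, int | None]:
    """Primary / secondary / tertiary Gleason patterns of one cancer run.

    Primary = most abundant pattern (ties toward the higher grade), secondary
    = highest other pattern present (= primary when pure), tertiary = the
    remaining pattern when three are present.
    """
    values, counts = np.unique(patterns, return_counts=True)
    order = sorted(range(len(values)), key=lambda i: (-counts[i], -values[i]))
    primary = int(values[order[0]])
    others = sorted((int(v) for v in values if v != primary), reverse=True)
    secondary = others[0] if others else primary
    tertiary = others[1] if len(others) > 1 else None
    return primary, secondary, tertiary


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Closed index intervals [start, stop] of True runs in a 1-D mask."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    delta = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(delta == 1)
    stops = np.flatnonzero(delta == -1) - 1
    return list(zip(starts, stops))


def _split_run(run_nodes: np.ndarray, patterns: np.ndarray, gap_nodes: int):
    """Split a run's node indices into two parts around a deleted central band.

    The gap is centred on the secondary-pattern band when the run is mixed
    (so both parts keep the full pattern set) and on the run centre otherwise.
    Returns ``None`` when no valid split exists.
    """
    count = run_nodes.size
    if count < gap_nodes + 2:
        return None
    pattern_set = set(int(p) for p in patterns)
    if len(pattern_set) > 1:
        minority = patterns != np.int8(max(pattern_set, key=lambda g: (patterns == g).sum()))
        centre = int(np.round(np.flatnonzero(minority).mean()))
    else:
        centre = count // 2
    start = int(np.clip(centre - gap_nodes // 2, 1, count - gap_nodes - 1))
    left = slice(0, start)
    right = slice(start + gap_nodes, count)
    for part in (left, right):
        if set(int(p) for p in patterns[part]) != pattern_set:
            return None
    return (run_nodes[left], patterns[left]), (run_nodes[right], patterns[right])


def _nodes_to_focus(local_nodes: np.ndarray, patterns: np.ndarray,
                    res: float, window_len: float, n_window: int) -> CancerFocus:
    offset = local_nodes[0] * res - res / 2.0
    end = local_nodes[-1] * res + res / 2.0
    if local_nodes[0] == 0:
        offset = 0.0
    if local_nodes[-1] == n_window - 1:
        end = window_len
    offset = max(0.0, offset)
    end = min(window_len, end)
    primary, secondary, tertiary = _run_grades(patterns)
    return CancerFocus(offset=offset, length=end - offset,
                       primary=primary, secondary=secondary, tertiary=tertiary)


def sample_cores(
    truth: np.ndarray,
    grid: GridSpec | None = None,
    discontinuity_prob: float = 0.0,
    seed: int | None = None,
    footprint: np.ndarray | None = None,
    patient_id: str = "P0",
) -> list[CoreRecord]:
    """Simulate the TPM biopsy of a ground-truth volume.

    One apex and one base record per occupied template hole.  Each record's
    foci are the contiguous cancer runs along the needle track intersected
    with the core's depth window; per-focus grades follow standard biopsy
    convention (primary = most abundant pattern in the run, secondary =
    highest other pattern present).  With probability ``discontinuity_prob`` a
    run of at least 5 mm is reported as two foci separated by a 1-3 mm benign
    band — emulating discontinuous cancer foci within one core — whenever the
    split preserves the run's pattern content.
    """
    grid = grid or GridSpec()
    if truth.shape != grid.fine_shape:
        raise ValueError(f"truth shape {truth.shape} != fine grid {grid.fine_shape}")
    rng = np.random.default_rng(seed)
    if footprint is None:
        footprint = np.ones((grid.nx, grid.ny), dtype=bool)
    res = grid.fine_res
    n_window = int(round(grid.needle_length / res))
    min_split_nodes = int(round(5.0 / res))

    records = []
    for i in range(grid.nx):
        for j in range(grid.ny):
            if not footprint[i, j]:
                continue
            a, b = grid.hole_fine_index(i, j)
            column = truth[a, b, :]
            for slot_index, depth in enumerate(DEPTH_SLOTS[: grid.depth_slots]):
                lo = slot_index * n_window
                window = column[lo:lo + n_window]
                foci = []
                for start, stop in _runs(window > 0):
                    nodes = np.arange(start, stop + 1)
                    patterns = window[start:stop + 1]
                    parts = [(nodes, patterns)]
                    if (nodes.size >= min_split_nodes
                            and rng.random() < discontinuity_prob):
                        gap_nodes = int(rng.integers(2, 7))  # 1-3 mm
                        split = _split_run(nodes, patterns, gap_nodes)
                        if split is not None:
                            parts = list(split)
                    for part_nodes, part_patterns in parts:
                        foci.append(_nodes_to_focus(
                            part_nodes, part_patterns, res,
                            grid.needle_length, n_window,
                        ))
                records.append(CoreRecord(
                    patient_id=patient_id,
                    grid_x=i,
                    grid_y=j,
                    depth=depth,
                    core_length=grid.needle_length,
                    foci=tuple(foci),
                ))
    return records


# ------------------------------------------------------------------- cohorts

def _count_columns_hit(truth: np.ndarray, lesions: list[TruthLesion],
                       grid: GridSpec, footprint: np.ndarray) -> list[TruthLesion]:
    """Fill in how many sampled template columns intersect each lesion."""
    from dataclasses import replace

    out = []
    for lesion in lesions:
        cx, cy, _ = lesion.spec.center
        rx, ry, _ = lesion.spec.radii
        hits = 0
        for i in range(grid.nx):
            for j in range(grid.ny):
                if not footprint[i, j]:
                    continue
                hx, hy = grid.hole_center_mm(i, j)
                if ((hx - cx) / rx) ** 2 + ((hy - cy) / ry) ** 2 <= 1.0:
                    a, b = grid.hole_fine_index(i, j)
                    if (truth[a, b, :] > 0).any():
                        hits += 1
        out.append(replace(lesion, n_template_columns_hit=hits))
    return out


def _footprint_mask(grid: GridSpec, center, semi_axes) -> np.ndarray:
    mask = np.zeros((grid.nx, grid.ny), dtype=bool)
    for i in range(grid.nx):
        for j in range(grid.ny):
            hx, hy = grid.hole_center_mm(i, j)
            if (((hx - center[0]) / semi_axes[0]) ** 2
                    + ((hy - center[1]) / semi_axes[1]) ** 2) <= 1.0:
                mask[i, j] = True
    return mask


_HOMOGENEOUS_SCORES: list[tuple[GleasonPair, float]] = [
    ((3, 3), 0.61),
    ((3, 4), 0.34),
    ((4, 3), 0.05),
]


def _draw_radii(rng: np.random.Generator, volume_ml: float) -> np.ndarray:
    r_eq = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    u = rng.uniform(0.75, 1.35, size=3)
    u /= u.prod() ** (1.0 / 3.0)
    return r_eq * u


def _place_lesion(rng, grid, footprint_center, footprint_axes, radii, placed,
                  depth_slot: int) -> tuple[float, float, float] | None:
    """Rejection-sample a lesion centre inside the gland, one depth window,
    clear of previously placed lesions."""
    field_x, field_y, _ = grid.field_mm
    rx, ry, rz = radii
    z0 = depth_slot * grid.needle_length + rz + 0.5
    z1 = (depth_slot + 1) * grid.needle_length - rz - 0.5
    if z1 <= z0:
        return None
    bound = max(radii)
    for _ in range(120):
        t = rng.uniform(0, 2 * math.pi)
        r = math.sqrt(rng.uniform(0, 1))
        cx = footprint_center[0] + 0.82 * footprint_axes[0] * r * math.cos(t)
        cy = footprint_center[1] + 0.82 * footprint_axes[1] * r * math.sin(t)
        cz = rng.uniform(z0, z1)
        if not (rx + 0.3 <= cx <= field_x - rx - 0.3
                and ry + 0.3 <= cy <= field_y - ry - 0.3):
            continue
        ok = True
        for (px, py, pz), pbound in placed:
            if math.dist((cx, cy, cz), (px, py, pz)) < bound + pbound + 11.0:
                ok = False
                break
        if ok:
            return (cx, cy, cz)
    return None


def _heterogeneous_lesion(rng, grid, footprint_center, footprint_axes, placed,
                          discordant: bool) -> LesionSpec | None:
    rf = FREE_PLACEMENT_FOCUS_RADIUS
    body = 3 if rng.random() < 0.85 else 4
    volume = math.exp(rng.uniform(math.log(0.6), math.log(4.0)))
    radii = _draw_radii(rng, volume)
    radii = np.maximum(radii, rf + 1.2)           # the focus must fit
    rho = 0.0
    if discordant:
        rho = rng.uniform(rf + 3.0, rf + 8.0)
    else:
        rho = rng.uniform(0.0, 0.6 * rf)
    # focus displaced along the wider planar axis; grow it if needed
    axis = 0 if radii[0] >= radii[1] else 1
    radii[axis] = max(radii[axis], rho + rf + 0.8)
    radii[2] = min(radii[2], grid.needle_length / 2.0 - 1.0)
    radii[2] = max(radii[2], rf + 0.8)
    slot = int(rng.integers(grid.depth_slots))
    center = _place_lesion(rng, grid, footprint_center, footprint_axes,
                           radii, placed, slot)
    if center is None:
        return None
    direction = 1.0 if rng.random() < 0.5 else -1.0
    offset = [0.0, 0.0, 0.0]
    offset[axis] = direction * rho
    focus_center = tuple(c + o for c, o in zip(center, offset))
    return LesionSpec(
        center=center,
        radii=tuple(float(r) for r in radii),
        base_score=(body, body),
        focus=FocusSpec(center=focus_center, radius=rf, grade=body + 1),
    )


def _homogeneous_lesion(rng, grid, footprint_center, footprint_axes,
                        placed) -> LesionSpec | None:
    scores, probs = zip(*_HOMOGENEOUS_SCORES)
    score = scores[rng.choice(len(scores), p=np.asarray(probs) / sum(probs))]
    volume = math.exp(rng.uniform(math.log(0.03), math.log(4.0)))
    radii = _draw_radii(rng, volume)
    radii[2] = min(radii[2], grid.needle_length / 2.0 - 1.0)
    slot = int(rng.integers(grid.depth_slots))
    center = _place_lesion(rng, grid, footprint_center, footprint_axes,
                           radii, placed, slot)
    if center is None:
        return None
    return LesionSpec(center=center, radii=tuple(float(r) for r in radii),
                      base_score=score, focus=None)


def make_cohort(spec: CohortSpec | None = None,
                grid: GridSpec | None = None,
                out_dir: str | Path | None = None) -> Cohort:
    """Generate a free-placement synthetic cohort.

    Deterministic given ``spec.seed``.  Optionally writes per-patient CSVs and
    a truth JSON to ``out_dir`` (the tpm_io schema).
    """
    spec = spec or CohortSpec()
    grid = grid or GridSpec()
    rng = np.random.default_rng(spec.seed)
    field_x, field_y, _ = grid.field_mm
    gland_center = (field_x / 2.0, field_y / 2.0)

    patients = []
    for p in range(spec.n_patients):
        patient_id = f"P{p + 1:03d}"
        footprint_axes = rng.uniform(15.0, 21.0, size=2)
        footprint = _footprint_mask(grid, gland_center, footprint_axes)
        n_lesions = int(rng.poisson(spec.lesions_per_patient))
        lesion_specs: list[LesionSpec] = []
        placed: list[tuple[tuple[float, float, float], float]] = []
        for _ in range(n_lesions):
            if rng.random() < spec.fraction_heterogeneous:
                lesion = _heterogeneous_lesion(
                    rng, grid, gland_center, footprint_axes, placed,
                    discordant=rng.random() < spec.discordant_focus_prob,
                )
            else:
                lesion = _homogeneous_lesion(
                    rng, grid, gland_center, footprint_axes, placed,
                )
            if lesion is None:
                continue
            lesion_specs.append(lesion)
            placed.append((lesion.center, max(lesion.radii)))
        truth, metadata = generate_truth_volume(lesion_specs, grid, patient_id)
        records = sample_cores(
            truth, grid,
            discontinuity_prob=spec.discontinuity_prob,
            seed=int(rng.integers(2 ** 31)),
            footprint=footprint,
            patient_id=patient_id,
        )
        metadata = _count_columns_hit(truth, metadata, grid, footprint)
        patients.append(PatientTruth(patient_id, records, metadata, footprint))

    cohort = Cohort(patients=patients, grid=grid, spec=spec)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def make_offset_phantoms(
    offsets_mm: Sequence[float] = (0.0, 5.0, 10.0, 15.0),
    n_per_offset: int = 50,
    seed: int = 0,
    grid: GridSpec | None = None,
    focus_radius: float = 2.5,
    body: int = 3,
    focus_grade: int = 4,
) -> Cohort:
    """Grid-aligned single-lesion phantoms with planted focus offsets.

    Each phantom patient holds one ellipsoidal body-grade lesion centred on a
    template hole at the apex/base boundary (z = 20 mm) with a spherical
    higher-grade focus centred on the hole ``offset`` mm away along a grid
    axis.  The closed-form hotspot separation is ``max(0, offset - r_focus)``;
    an offset of 0 plants a concordant focus.  Offsets must be multiples of
    the grid pitch so the focus is itself hole-centred.
    """
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    for offset in offsets_mm:
        if offset and (offset / grid.spacing) % 1.0:
            raise ValueError("phantom offsets must be multiples of the grid pitch")
    if not 0 < focus_radius < grid.spacing:
        raise ValueError("focus radius must be in (0, spacing) for hole-aligned phantoms")

    field_x, field_y, _ = grid.field_mm
    cz = grid.needle_length  # apex/base boundary: both cores sample the focus
    footprint = np.ones((grid.nx, grid.ny), dtype=bool)
    patients = []
    n = 0
    for offset in offsets_mm:
        holes_away = int(round(offset / grid.spacing))
        for _ in range(n_per_offset):
            n += 1
            patient_id = f"PH{n:03d}"
            axis = int(rng.integers(2))
            direction = 1 if rng.random() < 0.5 else -1
            r_axis = max(10.0, offset + focus_radius + 2.0)
            r_other = rng.uniform(8.0, 11.0)
            rz = rng.uniform(6.5, 8.0)
            radii = [r_other, r_other, rz]
            radii[axis] = r_axis

            # admissible centre holes: lesion inside the field, focus hole on-grid
            lo_i = int(math.ceil((radii[0] - grid.spacing / 2.0) / grid.spacing))
            hi_i = grid.nx - 1 - lo_i
            lo_j = int(math.ceil((radii[1] - grid.spacing / 2.0) / grid.spacing))
            hi_j = grid.ny - 1 - lo_j
            if axis == 0 and direction > 0:
                hi_i -= holes_away
            elif axis == 0:
                lo_i += holes_away
            elif direction > 0:
                hi_j -= holes_away
            else:
                lo_j += holes_away
            ci = int(rng.integers(lo_i, hi_i + 1))
            cj = int(rng.integers(lo_j, hi_j + 1))
            cx, cy = grid.hole_center_mm(ci, cj)
            center = (cx, cy, cz)
            shift = [0.0, 0.0, 0.0]
            shift[axis] = direction * offset
            focus = FocusSpec(
                center=(cx + shift[0], cy + shift[1], cz),
                radius=focus_radius,
                grade=focus_grade,
            )
            lesion = LesionSpec(center=center, radii=tuple(radii),
                                base_score=(body, body), focus=focus)
            truth, metadata = generate_truth_volume([lesion], grid, patient_id)
            records = sample_cores(truth, grid, discontinuity_prob=0.0,
                                   seed=int(rng.integers(2 ** 31)),
                                   footprint=footprint, patient_id=patient_id)
            metadata = _count_columns_hit(truth, metadata, grid, footprint)
            patients.append(PatientTruth(patient_id, records, metadata, footprint))
    return Cohort(patients=patients, grid=grid, spec=None)
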