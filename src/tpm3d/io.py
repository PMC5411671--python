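"""Core-level TPM pathology records: data model, validation, CSV round-trip,
risk stratification and the per-patient colour-coded visual map.

File format
-----------
One CSV row per biopsy core.  Fixed columns::

    patient_id, grid_x, grid_y, depth, core_length_mm

``grid_x`` is a template column letter A-M (mapped to index 0-12 left to
right), ``grid_y`` a row number 1-13 (mapped to 0-12), ``depth`` is ``apex`` or
``base``.  Cancer foci are packed as repeated column groups::

    focus{n}_offset_mm, focus{n}_length_mm, focus{n}_primary,
    focus{n}_secondary, focus{n}_tertiary        (n = 1, 2, ...)

``offset_mm`` is the distance of the focus start from the apical (India-inked)
end of the core.  Unused focus columns are left empty; a benign core has all
focus columns empty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grading import GleasonPair, best_pair, pair_rank, validate_pattern
from .grid import DEPTH_SLOTS, GridSpec

__all__ = [
    "CancerFocus",
    "CoreRecord",
    "RiskClass",
    "ValidationError",
    "ParseError",
    "read_core_table",
    "write_core_table",
    "classify_core_risk",
    "core_mccl",
    "core_best_score",
    "render_visual_map",
    "COLUMN_LETTERS",
    "RISK_COLORS",
]

COLUMN_LETTERS = "ABCDEFGHIJKLM"


class ValidationError(ValueError):
    """A record violates the TPM data model invariants."""


class ParseError(ValueError):
    """A file row could not be interpreted."""


@dataclass(frozen=True)
class CancerFocus:
    """One contiguous focus of cancer within a biopsy core.

    ``offset`` is measured in mm from the apical end of the core; ``length`` is
    the focus extent in mm.  ``primary``/``secondary`` are the Gleason patterns
    of the focus (equal for a pure focus); ``tertiary`` is optional.
    """

    offset: float
    length: float
    primary: int
    secondary: int
    tertiary: int | None = None

    def __post_init__(self) -> None:
        if not (self.offset >= 0 and math.isfinite(self.offset)):
            raise ValidationError(f"focus offset must be >= 0, got {self.offset}")
        if not (self.length > 0 and math.isfinite(self.length)):
            raise ValidationError(f"focus length must be > 0, got {self.length}")
        validate_pattern(self.primary)
        validate_pattern(self.secondary)
        if self.tertiary is not None:
            validate_pattern(self.tertiary)

    @property
    def end(self) -> float:
        return self.offset + self.length

    @property
    def score(self) -> GleasonPair:
        return (self.primary, self.secondary)


@dataclass(frozen=True)
class CoreRecord:
    """One biopsy core: template position, depth slot and its cancer foci."""

    patient_id: str
    grid_x: int
    grid_y: int
    depth: str
    core_length: float
    foci: tuple[CancerFocus, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.depth not in DEPTH_SLOTS:
            raise ValidationError(f"depth must be one of {DEPTH_SLOTS}, got {self.depth!r}")
        if not (0 < self.core_length <= 20.0):
            raise ValidationError(
                f"core_length must be in (0, 20] mm, got {self.core_length}"
            )
        object.__setattr__(self, "foci", tuple(self.foci))
        prev_end = -math.inf
        for focus in self.foci:
            if focus.offset < prev_end:
                raise ValidationError(
                    f"foci must be sorted by offset and non-overlapping "
                    f"(focus at {focus.offset} mm starts before {prev_end} mm)"
                )
            prev_end = focus.end
            if focus.end > self.core_length + 1e-9:
                raise ValidationError(
                    f"focus [{focus.offset}, {focus.end}] mm extends past the "
                    f"{self.core_length} mm core"
                )

    def validate_grid(self, grid: GridSpec) -> None:
        if not (0 <= self.grid_x < grid.nx and 0 <= self.grid_y < grid.ny):
            raise ValidationError(
                f"grid coordinate ({self.grid_x}, {self.grid_y}) outside the "
                f"{grid.nx}x{grid.ny} template"
            )

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.grid_x, self.grid_y, self.depth)


class RiskClass(str, Enum):
    """Per-core clinical-significance stratum (UCL definitions)."""

    DEFINITION1 = "definition1"
    DEFINITION2 = "definition2"
    INSIGNIFICANT = "insignificant"
    NO_CANCER = "no_cancer"


def core_mccl(core: CoreRecord) -> float:
    """Maximum single-focus cancer length of the core in mm (0 if benign)."""
    return max((f.length for f in core.foci), default=0.0)


def core_best_score(core: CoreRecord) -> GleasonPair | None:
    """Highest Gleason score among the core's foci, ``None`` if benign."""
    if not core.foci:
        return None
    return best_pair([f.score for f in core.foci])


def classify_core_risk(mccl: float, best_score: GleasonPair | None) -> RiskClass:
    """Risk stratum of a core from its MCCL and best Gleason score.

    Definition 1 (most significant): MCCL >= 6 mm and/or score >= 4+3.
    Definition 2: MCCL >= 4 mm and/or score >= 3+4.  Cores at most 3 mm with
    score <= 3+3 are insignificant.  Definition 1 takes precedence.
    """
    if mccl < 0:
        raise ValueError(f"MCCL must be >= 0, got {mccl}")
    if mccl == 0:
        return RiskClass.NO_CANCER
    rank = pair_rank(best_score) if best_score is not None else (0, 0)
    if mccl >= 6 or rank >= pair_rank((4, 3)):
        return RiskClass.DEFINITION1
    if mccl >= 4 or rank >= pair_rank((3, 4)):
        return RiskClass.DEFINITION2
    return RiskClass.INSIGNIFICANT


# --------------------------------------------------------------------- reading

_FIXED_COLUMNS = ["patient_id", "grid_x", "grid_y", "depth", "core_length_mm"]
_FOCUS_FIELDS = ("offset_mm", "length_mm", "primary", "secondary", "tertiary")


def _focus_columns(n: int) -> list[str]:
    cols = []
    for i in range(1, n + 1):
        cols.extend(f"focus{i}_{f}" for f in _FOCUS_FIELDS)
    return cols


def _parse_cell(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)


def read_core_table(path: str | Path, grid: GridSpec | None = None) -> list[CoreRecord]:
    """Read a core-level TPM pathology CSV into validated :class:`CoreRecord` s.

    Raises :class:`ParseError` for malformed rows (naming row and column) and
    :class:`ValidationError` for rows violating the data model (coordinates
    outside the template, foci beyond the core length, duplicates).
    """
    grid = grid or GridSpec()
    frame = pd.read_csv(path, dtype={"patient_id": str, "grid_x": str}, skipinitialspace=True)
    missing = [c for c in _FIXED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    n_focus = 0
    while f"focus{n_focus + 1}_offset_mm" in frame.columns:
        n_focus += 1

    records: list[CoreRecord] = []
    seen: set[tuple[str, int, int, str]] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            letter = str(row["grid_x"]).strip().upper()
            if letter not in COLUMN_LETTERS[: grid.nx]:
                raise ParseError(
                    f"row {row_number}, column grid_x: letter {letter!r} outside "
                    f"template columns A-{COLUMN_LETTERS[grid.nx - 1]}"
                )
            grid_x = COLUMN_LETTERS.index(letter)
            grid_y = int(row["grid_y"]) - 1
            if not (0 <= grid_y < grid.ny):
                raise ParseError(
                    f"row {row_number}, column grid_y: row number {row['grid_y']} "
                    f"outside 1-{grid.ny}"
                )
            foci = []
            for i in range(1, n_focus + 1):
                cells = {f: _parse_cell(row[f"focus{i}_{f}"]) for f in _FOCUS_FIELDS}
                if all(v is None for v in cells.values()):
                    continue
                if cells["offset_mm"] is None or cells["length_mm"] is None or \
                        cells["primary"] is None or cells["secondary"] is None:
                    raise ParseError(
                        f"row {row_number}, focus {i}: incomplete focus "
                        "(offset, length, primary and secondary are required)"
                    )
                foci.append(
                    CancerFocus(
                        offset=cells["offset_mm"],
                        length=cells["length_mm"],
                        primary=int(cells["primary"]),
                        secondary=int(cells["secondary"]),
                        tertiary=None if cells["tertiary"] is None else int(cells["tertiary"]),
                    )
                )
            record = CoreRecord(
                patient_id=str(row["patient_id"]),
                grid_x=grid_x,
                grid_y=grid_y,
                depth=str(row["depth"]).strip(),
                core_length=float(row["core_length_mm"]),
                foci=tuple(foci),
            )
        except (ParseError, ValidationError):
            raise
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {row_number}: {exc}") from exc
        record.validate_grid(grid)
        full_key = (record.patient_id, *record.key)
        if full_key in seen:
            raise ValidationError(
                f"row {row_number}: duplicate core at {full_key}"
            )
        seen.add(full_key)
        records.append(record)
    return records


def write_core_table(records: Sequence[CoreRecord], path: str | Path) -> None:
    """Write records to CSV; ``read_core_table(write_core_table(r)) == r``."""
    n_focus = max((len(r.foci) for r in records), default=0)
    columns = _FIXED_COLUMNS + _focus_columns(n_focus)
    rows = []
    for record in records:
        row = {
            "patient_id": record.patient_id,
            "grid_x": COLUMN_LETTERS[record.grid_x],
            "grid_y": record.grid_y + 1,
            "depth": record.depth,
            "core_length_mm": record.core_length,
        }
        for i, focus in enumerate(record.foci, start=1):
            row[f"focus{i}_offset_mm"] = focus.offset
            row[f"focus{i}_length_mm"] = focus.length
            row[f"focus{i}_primary"] = focus.primary
            row[f"focus{i}_secondary"] = focus.secondary
            row[f"focus{i}_tertiary"] = focus.tertiary
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    # keep integer-valued grade columns free of trailing ".0"
    for col in frame.columns:
        if col.endswith(("_primary", "_secondary", "_tertiary")):
            frame[col] = frame[col].astype("Int64")
    frame.to_csv(path, index=False)


# ------------------------------------------------------------------ visual map

RISK_COLORS = {
    RiskClass.DEFINITION1: "#d62728",
    RiskClass.DEFINITION2: "#f0d01f",
    RiskClass.INSIGNIFICANT: "#2ca02c",
    RiskClass.NO_CANCER: "#ffffff",
}


def render_visual_map(
    records: Sequence[CoreRecord],
    grid: GridSpec | None = None,
    png_path: str | Path | None = None,
    json_path: str | Path | None = None,
):
    """Per-patient colour-coded TPM visual report.

    One 13 x 13 panel per needle depth; each sampled cell carries the core's
    MCCL (longest single cancer focus, mm) and is coloured by its risk class
    (red = definition 1, yellow = definition 2, green = insignificant, white =
    no cancer).  Unsampled cells are blank (grey).

    Returns ``(figure, grid_dict)`` where ``grid_dict`` is a machine-readable
    per-cell ``{"mccl": ..., "risk": ...}`` mapping; optionally writes a PNG
    and/or a JSON file.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    grid = grid or GridSpec()
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValidationError(f"visual map expects one patient, got {sorted(patients)}")
    seen: set[tuple[int, int, str]] = set()
    for record in records:
        record.validate_grid(grid)
        if record.key in seen:
            raise ValidationError(f"duplicate core at {record.key}")
        seen.add(record.key)

    grid_dict: dict[str, list[list[dict | None]]] = {}
    fig, axes = plt.subplots(1, grid.depth_slots, figsize=(5.2 * grid.depth_slots, 5.6))
    axes = np.atleast_1d(axes)
    for axis, depth in zip(axes, DEPTH_SLOTS[: grid.depth_slots]):
        cells: list[list[dict | None]] = [
            [None] * grid.nx for _ in range(grid.ny)
        ]
        axis.set_title(f"{depth} cores")
        axis.set_xlim(0, grid.nx)
        axis.set_ylim(0, grid.ny)
        axis.set_xticks(np.arange(grid.nx) + 0.5)
        axis.set_xticklabels(list(COLUMN_LETTERS[: grid.nx]))
        axis.set_yticks(np.arange(grid.ny) + 0.5)
        axis.set_yticklabels([str(j + 1) for j in range(grid.ny)])
        axis.set_aspect("equal")
        for record in records:
            if record.depth != depth:
                continue
            mccl = core_mccl(record)
            risk = classify_core_risk(mccl, core_best_score(record))
            cells[record.grid_y][record.grid_x] = {"mccl": mccl, "risk": risk.value}
            axis.add_patch(
                Rectangle(
                    (record.grid_x, record.grid_y), 1, 1,
                    facecolor=RISK_COLORS[risk], edgecolor="black", linewidth=0.6,
                )
            )
            if mccl > 0:
                axis.text(
                    record.grid_x + 0.5, record.grid_y + 0.5, f"{mccl:g}",
                    ha="center", va="center", fontsize=7,
                )
        for j in range(grid.ny):
            for i in range(grid.nx):
                if cells[j][i] is None:
                    axis.add_patch(
                        Rectangle((i, j), 1, 1, facecolor="#dddddd",
                                  edgecolor="#bbbbbb", linewidth=0.3)
                    )
        grid_dict[depth] = cells
    patient = next(iter(patients)) if patients else ""
    fig.suptitle(f"TPM visual report — patient {patient}")
    fig.tight_layout()
    if png_path is not None:
        fig.savefig(png_path, dpi=150)
    if json_path is not None:
        Path(json_path).write_text(json.dumps({"patient_id": patient, "grid": grid_dict}, indent=1))
    return fig, grid_dict
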