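"""Template-grid geometry.

A transperineal template mapping (TPM) biopsy samples the prostate through a
brachytherapy grid of 13 x 13 holes at a 5 mm pitch.  Each hole is sampled at
two stacked needle depths ("apex" and "base") of 20 mm each, giving a coarse
pathology map of 13 x 13 x 40 voxels of 5 x 5 x 1 mm, and a fine reconstruction
grid of 130 x 130 x 80 sample points at 0.5 mm isotropic resolution.

Coordinate conventions
----------------------
* ``x`` runs along grid columns (letters A-M in report files), ``y`` along grid
  rows (numbers 1-13), ``z`` cranio-caudally with ``z = 0`` at the apical end of
  the apex needle (the India-inked end of the apex core).
* The apex needle covers ``z in [0, 20)`` mm, the base needle ``z in [20, 40)``.
* Coarse voxel ``(i, j, k)`` covers ``x in [5i, 5(i+1))``, ``y in [5j, 5(j+1))``,
  ``z in [k, k+1)`` mm; its centre (the template "grid site" for that z section)
  is at ``(5i + 2.5, 5j + 2.5, k + 0.5)`` mm.
* Fine grid point ``(a, b, c)`` is the sample location ``(0.5a, 0.5b, 0.5c)`` mm.
  With the default spacing every coarse voxel centre coincides exactly with a
  fine grid point, which makes "re-sampling at the template grid sites" an exact
  array lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GridSpec", "DEPTH_SLOTS"]

#: Valid needle depth slots, apical first.
DEPTH_SLOTS = ("apex", "base")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the template grid and of the derived voxel maps.

    Parameters
    ----------
    nx, ny
        Number of grid columns / rows (13 x 13 template).
    spacing
        Lateral grid pitch in mm (5 mm template).
    needle_length
        Length of one biopsy needle in mm (20 mm).
    depth_slots
        Number of stacked needle depths (2: apex and base).
    coarse_z_res
        Thickness of one coarse z section in mm (1 mm).
    fine_res
        Edge of the isotropic fine reconstruction voxel in mm (0.5 mm).
    """

    nx: int = 13
    ny: int = 13
    spacing: float = 5.0
    needle_length: float = 20.0
    depth_slots: int = 2
    coarse_z_res: float = 1.0
    fine_res: float = 0.5

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.depth_slots < 1:
            raise ValueError("grid dimensions must be positive")
        for name in ("spacing", "needle_length", "coarse_z_res", "fine_res"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.needle_length / self.coarse_z_res) % 1.0:
            raise ValueError("needle_length must be a multiple of coarse_z_res")
        # grid-site alignment: every coarse voxel centre must be a fine grid point
        for centre in (self.spacing / 2.0, self.coarse_z_res / 2.0):
            if (centre / self.fine_res) % 1.0:
                raise ValueError(
                    "coarse voxel centres must fall on fine grid points "
                    "(spacing/2 and coarse_z_res/2 must be multiples of fine_res)"
                )
        if (self.spacing / self.fine_res) % 1.0:
            raise ValueError("spacing must be a multiple of fine_res")

    # ------------------------------------------------------------------ coarse
    @property
    def nz(self) -> int:
        """Number of coarse z sections (40 for the default grid)."""
        return int(round(self.depth_slots * self.needle_length / self.coarse_z_res))

    @property
    def coarse_shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def z_extent(self) -> float:
        """Total cranio-caudal extent in mm (40 mm)."""
        return self.depth_slots * self.needle_length

    @property
    def field_mm(self) -> tuple[float, float, float]:
        """Physical extent of the mapped field in mm (65 x 65 x 40)."""
        return (self.nx * self.spacing, self.ny * self.spacing, self.z_extent)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one coarse block in ml (0.025 ml for 5 x 5 x 1 mm)."""
        return self.spacing * self.spacing * self.coarse_z_res / 1000.0

    def hole_center_mm(self, i: int, j: int) -> tuple[float, float]:
        """Physical (x, y) of template hole ``(i, j)`` — the needle track."""
        return (self.spacing * (i + 0.5), self.spacing * (j + 0.5))

    def site_center_mm(self, i: int, j: int, k: int) -> tuple[float, float, float]:
        """Physical centre of coarse voxel ``(i, j, k)``."""
        x, y = self.hole_center_mm(i, j)
        return (x, y, self.coarse_z_res * (k + 0.5))

    def depth_window(self, slot: str) -> tuple[float, float]:
        """``[z_start, z_end)`` in mm of one needle depth slot."""
        s = DEPTH_SLOTS.index(slot)
        return (s * self.needle_length, (s + 1) * self.needle_length)

    # -------------------------------------------------------------------- fine
    @property
    def fine_shape(self) -> tuple[int, int, int]:
        return (
            int(round(self.nx * self.spacing / self.fine_res)),
            int(round(self.ny * self.spacing / self.fine_res)),
            int(round(self.z_extent / self.fine_res)),
        )

    def fine_index_of_site(self, i: int, j: int, k: int) -> tuple[int, int, int]:
        """Fine grid indices of the coarse voxel centre (exact by construction)."""
        x, y, z = self.site_center_mm(i, j, k)
        return (
            int(round(x / self.fine_res)),
            int(round(y / self.fine_res)),
            int(round(z / self.fine_res)),
        )

    def hole_fine_index(self, i: int, j: int) -> tuple[int, int]:
        x, y = self.hole_center_mm(i, j)
        return (int(round(x / self.fine_res)), int(round(y / self.fine_res)))
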