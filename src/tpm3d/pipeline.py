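"""End-to-end per-patient and per-cohort analysis orchestration."""

from __future__ import annotations

from dataclasses import dataclass

from .coarse_map import CoarseMap, build_coarse_map
from .grid import GridSpec
from .hotspots import LesionReport, analyze_lesions
from .io import CoreRecord
from .reconstruction import FineMap, gaussian_smooth, interpolate_fine, tune_sigma
from .segmentation import LesionLabelMap, label_lesions

__all__ = ["PatientAnalysis", "analyze_patient", "analyze_cohort"]


@dataclass
class PatientAnalysis:
    """All intermediate and final products of one patient's reconstruction."""

    patient_id: str
    ccl_mode: str
    coarse: CoarseMap
    lesions: LesionLabelMap
    fine: FineMap
    reports: list[LesionReport]

    @property
    def sigma(self) -> float | None:
        return self.fine.sigma


def analyze_patient(
    records: list[CoreRecord],
    grid: GridSpec | None = None,
    ccl_mode: str = "separate",
    tol: float = 0.05,
    sigma_max: float = 5.0,
    preservation_mode: str = "patterns",
) -> PatientAnalysis:
    """Coarse map -> lesion labels -> tuned fine reconstruction -> reports.

    Lesion delineation and reconstruction depend only on the CCL counting
    mode; the heterogeneity criterion is applied later, at summary time.
    """
    grid = grid or GridSpec()
    patient_id = records[0].patient_id if records else ""
    coarse = build_coarse_map(records, grid, ccl_mode)
    lesions = label_lesions(coarse)
    fine = interpolate_fine(coarse)
    sigma = tune_sigma(fine, coarse, tol=tol, sigma_max=sigma_max,
                       mode=preservation_mode)
    fine = gaussian_smooth(fine, sigma)
    reports = analyze_lesions(coarse, lesions, fine)
    return PatientAnalysis(
        patient_id=patient_id,
        ccl_mode=ccl_mode,
        coarse=coarse,
        lesions=lesions,
        fine=fine,
        reports=reports,
    )


def analyze_cohort(
    patient_records: list[tuple[str, list[CoreRecord]]],
    grid: GridSpec | None = None,
    ccl_modes: tuple[str, ...] = ("separate", "cumulative"),
    tol: float = 0.05,
    sigma_max: float = 5.0,
) -> dict[str, list[PatientAnalysis]]:
    """Run every requested CCL mode over a cohort of per-patient records."""
    grid = grid or GridSpec()
    out: dict[str, list[PatientAnalysis]] = {}
    for mode in ccl_modes:
        out[mode] = [
            analyze_patient(records, grid, mode, tol=tol, sigma_max=sigma_max)
            for _, records in patient_records
        ]
    return out
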