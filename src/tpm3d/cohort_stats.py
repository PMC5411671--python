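"""Cohort-level summary statistics across the four analysis configurations.

An analysis configuration is a (CCL counting rule, heterogeneity criterion)
pair; the four combinations mirror the standard primary/secondary analysis
matrix: separate or cumulative CCL count crossed with the Gleason-grades or
Gleason-score heterogeneity criterion.  Proportions carry Wald binomial 95%
confidence intervals (p +/- 1.96 sqrt(p(1-p)/n), in percent); continuous
variables are summarised by median, interquartile range and range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .grading import GleasonPair, pair_str
from .hotspots import LesionReport

__all__ = [
    "AnalysisConfig",
    "ALL_CONFIGS",
    "CohortSummary",
    "binomial_wald_ci",
    "display_round",
    "format_count_ci",
    "median_iqr",
    "summarize_cohort",
]

_Z95 = 1.96


@dataclass(frozen=True)
class AnalysisConfig:
    """One column of the analysis matrix."""

    ccl_mode: str = "separate"
    criterion: str = "grades"

    def __post_init__(self) -> None:
        if self.ccl_mode not in ("separate", "cumulative"):
            raise ValueError(f"unknown ccl_mode {self.ccl_mode!r}")
        if self.criterion not in ("grades", "score"):
            raise ValueError(f"unknown criterion {self.criterion!r}")

    @property
    def label(self) -> str:
        return f"{self.ccl_mode} count / Gleason {self.criterion}"


ALL_CONFIGS = (
    AnalysisConfig("separate", "grades"),
    AnalysisConfig("separate", "score"),
    AnalysisConfig("cumulative", "grades"),
    AnalysisConfig("cumulative", "score"),
)


def binomial_wald_ci(k: int, n: int) -> tuple[float, float]:
    """Wald (normal-approximation) 95% CI for a proportion, in percent.

    Returns ``(percent, half_width_percent)`` unrounded; use
    :func:`display_round` (percent to integer, half-width to one decimal)
    for display.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    p = k / n
    half = _Z95 * math.sqrt(p * (1.0 - p) / n)
    return (100.0 * p, 100.0 * half)


def display_round(value: float, decimals: int = 0) -> float:
    """Round half away from zero, as printed tables conventionally do."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def format_count_ci(k: int, n: int) -> str:
    """``"148 (76±6.0%)"``-style cell for a count out of n."""
    percent, half = binomial_wald_ci(k, n)
    return f"{k} ({display_round(percent):.0f}±{display_round(half, 1):.1f}%)"


class MedianIQR(NamedTuple):
    median: float
    q1: float
    q3: float
    min: float
    max: float


def median_iqr(values: Sequence[float]) -> MedianIQR:
    """Median, quartiles (linear interpolation between order statistics) and range."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of an empty sequence")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return MedianIQR(float(med), float(q1), float(q3),
                     float(arr.min()), float(arr.max()))


@dataclass
class CohortSummary:
    """Counts, proportions with Wald CIs and medians for one configuration."""

    config: AnalysisConfig
    n_lesions: int
    score_counts: dict[str, int]                 # per-lesion Gleason score
    volume_stats: MedianIQR | None
    n_homogeneous: int
    n_heterogeneous: int
    n_het_concordant: int
    n_het_discordant: int
    n_total_concordant: int
    distance_stats: MedianIQR | None             # discordant lesions only
    quantile_rule: str = "linear"

    def __post_init__(self) -> None:
        assert self.n_homogeneous + self.n_heterogeneous == self.n_lesions
        assert self.n_het_concordant + self.n_het_discordant == self.n_heterogeneous
        assert self.n_total_concordant == self.n_homogeneous + self.n_het_concordant

    def to_dict(self) -> dict:
        def ci(k, n):
            if n == 0:
                return None
            percent, half = binomial_wald_ci(k, n)
            return {"k": k, "n": n,
                    "percent": display_round(percent),
                    "half_width": display_round(half, 1)}

        def stats(s):
            return None if s is None else {
                "median": s.median, "q1": s.q1, "q3": s.q3,
                "min": s.min, "max": s.max,
            }

        return {
            "config": {"ccl_mode": self.config.ccl_mode,
                       "criterion": self.config.criterion},
            "n_lesions": self.n_lesions,
            "score_counts": {
                s: ci(k, self.n_lesions) for s, k in self.score_counts.items()
            },
            "volume_ml": stats(self.volume_stats),
            "homogeneous": ci(self.n_homogeneous, self.n_lesions),
            "heterogeneous": ci(self.n_heterogeneous, self.n_lesions),
            "het_concordant": ci(self.n_het_concordant, self.n_heterogeneous),
            "het_discordant": ci(self.n_het_discordant, self.n_heterogeneous),
            "total_concordant": ci(self.n_total_concordant, self.n_lesions),
            "discordant_distance_mm": stats(self.distance_stats),
            "quantile_rule": self.quantile_rule,
        }

    def to_text(self) -> str:
        """Formatted table mirroring the standard analysis-matrix row layout."""
        lines = [f"Analysis: {self.config.label}",
                 f"No. of independent lesions        {self.n_lesions}"]
        lines.append("Gleason score, no (±95% CI)")
        for score, k in sorted(self.score_counts.items()):
            lines.append(f"  {score:<6} {format_count_ci(k, self.n_lesions)}")
        if self.volume_stats:
            v = self.volume_stats
            lines.append(
                f"Lesion volume, ml, median (IQR)   {v.median:g} "
                f"({v.q1:g}-{v.q3:g}), range ({v.min:g}-{v.max:g})"
            )
        if self.n_lesions:
            lines.append(f"Homogeneous lesions               "
                         f"{format_count_ci(self.n_homogeneous, self.n_lesions)}")
            lines.append(f"Heterogeneous lesions             "
                         f"{format_count_ci(self.n_heterogeneous, self.n_lesions)}")
        if self.n_heterogeneous:
            lines.append(
                f"Heterogeneous, concordant         "
                f"{self.n_het_concordant}/{self.n_heterogeneous} "
                f"{format_count_ci(self.n_het_concordant, self.n_heterogeneous)}"
            )
            lines.append(
                f"Heterogeneous, discordant         "
                f"{self.n_het_discordant}/{self.n_heterogeneous} "
                f"{format_count_ci(self.n_het_discordant, self.n_heterogeneous)}"
            )
        if self.distance_stats:
            d = self.distance_stats
            lines.append(f"3-D hotspot distance, mm          "
                         f"{d.median:.1f} ({d.q1:.1f}-{d.q3:.1f})")
        if self.n_lesions:
            lines.append(
                f"Total concordant lesions          "
                f"{self.n_total_concordant}/{self.n_lesions} "
                f"{format_count_ci(self.n_total_concordant, self.n_lesions)}"
            )
        return "\n".join(lines)


def summarize_cohort(reports: Iterable[LesionReport],
                     config: AnalysisConfig) -> CohortSummary:
    """Aggregate per-lesion reports (computed under ``config.ccl_mode``) into
    the analysis-matrix summary for ``config``.

    Per-lesion Gleason score rows use the highest ordered score present in
    the lesion.  Homogeneous lesions are inherently concordant; discordance
    distances are tabulated over heterogeneous-discordant lesions only.
    """
    reports = list(reports)
    n = len(reports)
    score_counts: dict[str, int] = {}
    for report in reports:
        key = pair_str(report.score)
        score_counts[key] = score_counts.get(key, 0) + 1

    het = [r for r in reports if r.heterogeneous(config.criterion)]
    het_concordant = [r for r in het if r.geometric_concordant]
    het_discordant = [r for r in het if not r.geometric_concordant]
    distances = [r.hotspot_distance_mm for r in het_discordant
                 if r.hotspot_distance_mm is not None]

    return CohortSummary(
        config=config,
        n_lesions=n,
        score_counts=score_counts,
        volume_stats=median_iqr([r.volume_ml for r in reports]) if reports else None,
        n_homogeneous=n - len(het),
        n_heterogeneous=len(het),
        n_het_concordant=len(het_concordant),
        n_het_discordant=len(het_discordant),
        n_total_concordant=(n - len(het)) + len(het_concordant),
        distance_stats=median_iqr(distances) if distances else None,
    )
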