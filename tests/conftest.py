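"""Shared fixtures: small record sets and session-scoped analyzed cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from tpm3d import (
    CancerFocus,
    CohortSpec,
    CoreRecord,
    GridSpec,
    analyze_patient,
    make_cohort,
)


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture
def simple_records() -> list[CoreRecord]:
    """One patient: a 3-core 26-connected heterogeneous lesion spanning the
    apex/base boundary, plus a benign core."""
    return [
        CoreRecord("P01", 5, 5, "apex", 20.0, (CancerFocus(14.0, 6.0, 3, 3),)),
        CoreRecord("P01", 6, 5, "apex", 20.0, (CancerFocus(12.0, 8.0, 3, 4),)),
        CoreRecord("P01", 5, 5, "base", 20.0, (CancerFocus(0.0, 3.0, 3, 3),)),
        CoreRecord("P01", 9, 9, "apex", 20.0, ()),
    ]


@pytest.fixture(scope="session")
def cohort20():
    """20-patient free-placement synthetic cohort under default conditions."""
    return make_cohort(CohortSpec(n_patients=20, seed=20))


@pytest.fixture(scope="session")
def cohort20_analyses(cohort20):
    """The cohort analyzed under both CCL counting modes (expensive, shared)."""
    return {
        mode: [analyze_patient(p.records, cohort20.grid, mode)
               for p in cohort20.patients]
        for mode in ("separate", "cumulative")
    }
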