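"""Virtual needles, heterogeneity classification and hotspot concordance."""

from __future__ import annotations

import numpy as np
import pytest

from tpm3d import (
    CancerFocus,
    CoreRecord,
    GridSpec,
    analyze_patient,
    assess_concordance,
    build_coarse_map,
    classify_heterogeneity,
    find_hotspots,
    interpolate_fine,
    label_lesions,
    lesion_volume,
    make_offset_phantoms,
    simulate_needle,
)
from tpm3d.hotspots import HotspotSet, propagate_lesion_ids


@pytest.fixture(scope="module")
def indicator_patient(grid):
    """Unsmoothed single-lesion map: 14 contiguous grade-3 mm at one hole."""
    records = [CoreRecord("P", 6, 6, "apex", 20.0, (CancerFocus(3.0, 14.0, 3, 3),))]
    cmap = build_coarse_map(records, grid)
    lesions = label_lesions(cmap)
    fine = interpolate_fine(cmap)
    ids = propagate_lesion_ids(fine, lesions)
    return cmap, lesions, fine, ids


# ----------------------------------------------------------------- needles

def test_needle_outside_lesion_reads_zero(grid, indicator_patient):
    _, _, fine, ids = indicator_patient
    profile = simulate_needle(fine, ids, 5, 5, 1)
    assert profile.ccl == 0.0 and profile.max_grade is None


def test_needle_counts_contiguous_voxels(grid, indicator_patient):
    """A 14 mm grade-3 column reads ccl 14 mm (28 fine voxels x 0.5 mm)."""
    _, _, fine, ids = indicator_patient
    a, b = grid.hole_fine_index(6, 6)
    profile = simulate_needle(fine, ids, a, b, 1)
    assert profile.ccl == pytest.approx(14.0, abs=1e-6)
    assert profile.max_grade == 3
    assert profile.ccl_z == pytest.approx(10.0, abs=1e-6)  # mid-run of [3, 17]


def test_unknown_lesion_id_rejected(indicator_patient):
    _, _, fine, ids = indicator_patient
    with pytest.raises(KeyError):
        simulate_needle(fine, ids, 0, 0, 99)


def test_needle_through_phantom_centre_recovers_z_extent(grid):
    cohort = make_offset_phantoms(offsets_mm=(0.0,), n_per_offset=1, seed=4)
    patient = cohort.patients[0]
    lesion = patient.lesions[0]
    analysis = analyze_patient(patient.records, grid)
    ids = propagate_lesion_ids(analysis.fine, analysis.lesions)
    cx, cy, _ = lesion.spec.center
    a, b = int(cx / grid.fine_res), int(cy / grid.fine_res)
    profile = simulate_needle(analysis.fine, ids, a, b, 1)
    assert profile.ccl == pytest.approx(lesion.max_ccl_mm, abs=1.0)


# ---------------------------------------------------------------- hotspots

def test_homogeneous_lesion_grade_set_covers_volume_set(grid, indicator_patient):
    """Every cancer track of a single-grade lesion carries the only grade."""
    _, _, fine, ids = indicator_patient
    volume_hotspot, grade_hotspot = find_hotspots(fine, ids, 1)
    vol = {tuple(c) for c in volume_hotspot.columns}
    gra = {tuple(c) for c in grade_hotspot.columns}
    assert vol <= gra
    concordant, distance = assess_concordance(volume_hotspot, grade_hotspot)
    assert concordant and distance is None


def test_phantom_hotspot_recovery_concordant_and_discordant(grid):
    cohort = make_offset_phantoms(offsets_mm=(0.0, 10.0), n_per_offset=1, seed=11)
    for patient in cohort.patients:
        lesion = patient.lesions[0]
        analysis = analyze_patient(patient.records, grid)
        report = analysis.reports[0]
        assert report.heterogeneous_by_grades
        assert report.geometric_concordant == lesion.concordant
        if not lesion.concordant:
            assert report.hotspot_distance_mm == pytest.approx(
                lesion.hotspot_distance_mm, abs=1.0
            )


# ----------------------------------------------------------- heterogeneity

@pytest.mark.parametrize("composition,by_grades,by_score", [
    ({(3, 3)}, False, False),
    ({(3, 4), (4, 3)}, True, False),   # same total score: homogeneous by score
    ({(3, 3), (4, 4)}, True, True),
    ({(3, 3), (3, 4)}, True, True),
    ({(4, 4), (3, 5)}, True, False),   # both total 8
])
def test_heterogeneity_criteria(composition, by_grades, by_score):
    assert classify_heterogeneity(composition, "grades") == by_grades
    assert classify_heterogeneity(composition, "score") == by_score


def test_score_heterogeneity_implies_grades_heterogeneity():
    rng = np.random.default_rng(0)
    pairs = [(p, s) for p in (3, 4, 5) for s in (3, 4, 5)]
    for _ in range(200):
        size = rng.integers(1, 5)
        composition = {pairs[i] for i in rng.choice(len(pairs), size)}
        if classify_heterogeneity(composition, "score"):
            assert classify_heterogeneity(composition, "grades")


def test_empty_composition_rejected():
    with pytest.raises(ValueError):
        classify_heterogeneity(set(), "grades")


# -------------------------------------------------------------- concordance

def test_identical_singleton_sets_are_concordant():
    a = HotspotSet(np.array([[20, 20]]), np.array([10.0]), 8.0)
    b = HotspotSet(np.array([[20, 20]]), np.array([12.0]), 4.0)
    concordant, distance = assess_concordance(a, b)
    assert concordant and distance is None


def test_disjoint_sets_give_euclidean_distance():
    # 6 mm apart in y only, equal z
    a = HotspotSet(np.array([[20, 20]]), np.array([10.0]), 8.0)
    b = HotspotSet(np.array([[20, 32]]), np.array([10.0]), 4.0)
    concordant, distance = assess_concordance(a, b, res=0.5)
    assert not concordant
    assert distance == pytest.approx(6.0)
    # symmetric
    assert assess_concordance(b, a, res=0.5)[1] == pytest.approx(6.0)
    # z displacement enters the 3-D distance
    c = HotspotSet(np.array([[20, 32]]), np.array([18.0]), 4.0)
    assert assess_concordance(a, c, res=0.5)[1] == pytest.approx(10.0)


def test_empty_hotspot_set_rejected():
    a = HotspotSet(np.array([[20, 20]]), np.array([10.0]), 8.0)
    empty = HotspotSet(np.empty((0, 2), dtype=int), np.empty(0), 0.0)
    with pytest.raises(ValueError):
        assess_concordance(a, empty)


# ------------------------------------------------------------------ volume

def test_lesion_volume_counts_blocks(grid):
    records = [CoreRecord("P", 6, 6, "apex", 20.0, (CancerFocus(3.0, 3.0, 3, 3),)),
               CoreRecord("P", 0, 0, "base", 20.0, (CancerFocus(0.0, 1.0, 3, 3),))]
    cmap = build_coarse_map(records, grid)
    lesions = label_lesions(cmap)
    volumes = sorted(lesion_volume(lesions, i) for i in (1, 2))
    assert volumes[0] == pytest.approx(0.025)   # one 5 x 5 x 1 mm block
    assert volumes[1] == pytest.approx(0.075)   # three blocks
    with pytest.raises(KeyError):
        lesion_volume(lesions, 3)


def test_ellipsoid_volume_close_to_analytic(grid):
    cohort = make_offset_phantoms(offsets_mm=(0.0,), n_per_offset=1, seed=8)
    patient = cohort.patients[0]
    analysis = analyze_patient(patient.records, grid)
    measured = analysis.reports[0].volume_ml
    truth = patient.lesions[0].volume_ml
    # block quantisation of a 5 mm-sampled ellipsoid: agreement within ~35%
    assert measured == pytest.approx(truth, rel=0.35)
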