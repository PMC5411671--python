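"""Ground-truth generator and template sampling."""

from __future__ import annotations

import numpy as np
import pytest

from tpm3d import (
    CohortSpec,
    FocusSpec,
    GridSpec,
    LesionSpec,
    build_coarse_map,
    generate_truth_volume,
    make_cohort,
    make_offset_phantoms,
    sample_cores,
)
from tpm3d.coarse_map import BENIGN, decode_pair


def _ellipsoid(center=(32.5, 32.5, 10.0), radii=(8.0, 8.0, 6.0), score=(3, 3),
               focus=None):
    return LesionSpec(center=center, radii=radii, base_score=score, focus=focus)


# ------------------------------------------------------------- truth volume

def test_homogeneous_lesion_is_single_pattern(grid):
    truth, meta = generate_truth_volume([_ellipsoid()], grid)
    values = set(np.unique(truth))
    assert values == {0, 3}
    lesion = meta[0]
    assert not lesion.heterogeneous and lesion.concordant
    assert lesion.hotspot_distance_mm is None
    assert lesion.max_ccl_mm == pytest.approx(12.0)
    assert lesion.max_ccl_xy_mm == (32.5, 32.5)


def test_centred_focus_plants_concordant_hotspots(grid):
    focus = FocusSpec(center=(32.5, 32.5, 10.0), radius=2.5, grade=4)
    truth, meta = generate_truth_volume([_ellipsoid(focus=focus)], grid)
    assert set(np.unique(truth)) == {0, 3, 4}
    assert meta[0].heterogeneous and meta[0].concordant


def test_offset_focus_distance_in_closed_form(grid):
    """Planted discordance distance = planar offset minus the focus radius."""
    focus = FocusSpec(center=(42.5, 32.5, 10.0), radius=2.5, grade=4)
    lesion = _ellipsoid(radii=(14.0, 8.0, 6.0), focus=focus)
    _, meta = generate_truth_volume([lesion], grid)
    assert meta[0].heterogeneous and not meta[0].concordant
    assert meta[0].hotspot_distance_mm == pytest.approx(10.0 - 2.5)


def test_lesion_outside_field_rejected(grid):
    with pytest.raises(ValueError):
        generate_truth_volume([_ellipsoid(center=(2.0, 32.5, 10.0))], grid)


def test_mixed_score_lesion_reads_planted_score_everywhere(grid):
    truth, _ = generate_truth_volume([_ellipsoid(score=(3, 4))], grid)
    records = sample_cores(truth, grid)
    scores = {f.score for r in records for f in r.foci}
    assert scores == {(3, 4)}


def test_overlapping_lesions_rejected(grid):
    with pytest.raises(ValueError):
        generate_truth_volume([_ellipsoid(), _ellipsoid(center=(35.0, 32.5, 10.0))], grid)


# ----------------------------------------------------------------- sampling

def test_track_outside_lesions_has_no_foci(grid):
    truth, _ = generate_truth_volume([_ellipsoid()], grid)
    records = sample_cores(truth, grid)
    by_key = {(r.grid_x, r.grid_y, r.depth): r for r in records}
    assert by_key[(0, 0, "apex")].foci == ()
    assert by_key[(0, 0, "base")].foci == ()


def test_central_track_reads_the_planted_chord(grid):
    truth, _ = generate_truth_volume([_ellipsoid()], grid)
    records = sample_cores(truth, grid)
    by_key = {(r.grid_x, r.grid_y, r.depth): r for r in records}
    apex = by_key[(6, 6, "apex")]  # hole centred on the lesion
    assert len(apex.foci) == 1
    focus = apex.foci[0]
    # central chord is 2*rz = 12 mm around z = 10
    assert focus.score == (3, 3)
    assert focus.length == pytest.approx(12.0, abs=0.5)
    assert focus.offset == pytest.approx(4.0, abs=0.5)


def test_sampling_is_deterministic(grid):
    truth, _ = generate_truth_volume([_ellipsoid(score=(3, 4))], grid)
    a = sample_cores(truth, grid, discontinuity_prob=0.5, seed=9)
    b = sample_cores(truth, grid, discontinuity_prob=0.5, seed=9)
    assert a == b
    c = sample_cores(truth, grid, discontinuity_prob=0.5, seed=10)
    assert a != c  # some split decision differs under another seed


def test_discontinuity_splits_preserve_pattern_content(grid):
    truth, _ = generate_truth_volume([_ellipsoid(score=(3, 4))], grid)
    whole = sample_cores(truth, grid, discontinuity_prob=0.0, seed=1)
    split = sample_cores(truth, grid, discontinuity_prob=1.0, seed=1)
    n_split_cores = 0
    whole_by_key = {r.key: r for r in whole}
    for record in split:
        reference = whole_by_key[record.key]
        if len(record.foci) > len(reference.foci):
            n_split_cores += 1
            # the reported patterns survive the split on every sub-focus
            assert {f.score for f in record.foci} == {f.score for f in reference.foci}
            # 1-3 mm of cancer length is re-attributed to the benign gap
            gap = sum(f.length for f in reference.foci) - sum(f.length for f in record.foci)
            assert 1.0 - 1e-9 <= gap <= 3.0 + 1e-9
    assert n_split_cores > 0


def test_sampled_coarse_map_matches_truth_at_grid_sites(grid):
    """Sampling invents no information: rebuilding the coarse map reproduces
    the truth volume's cancer status and patterns at every grid site."""
    focus = FocusSpec(center=(40.5, 32.5, 10.0), radius=3.6, grade=4)
    lesions = [
        _ellipsoid(radii=(12.0, 9.0, 7.0), focus=focus),
        _ellipsoid(center=(15.0, 15.0, 30.0), radii=(6.0, 6.0, 5.0), score=(3, 4)),
    ]
    truth, _ = generate_truth_volume(lesions, grid)
    records = sample_cores(truth, grid, patient_id="PX")
    cmap = build_coarse_map(records, grid)
    for i in range(grid.nx):
        for j in range(grid.ny):
            a, b = grid.hole_fine_index(i, j)
            for k in range(grid.nz):
                truth_label = int(truth[a, b, 2 * k + 1])
                painted = int(cmap.labels[i, j, k])
                assert (painted > BENIGN) == (truth_label > 0)
                if truth_label > 0:
                    assert truth_label in decode_pair(painted)


# ------------------------------------------------------------------ cohorts

def test_cohort_is_reproducible_and_writable(tmp_path, cohort20):
    again = make_cohort(CohortSpec(n_patients=20, seed=20))
    assert [p.records for p in again.patients] == [p.records for p in cohort20.patients]
    out = tmp_path / "cohort"
    cohort20.write(out)
    assert (out / "truth.json").exists()
    assert len(list(out.glob("cores_*.csv"))) == 20


def test_zero_heterogeneous_fraction_plants_none():
    cohort = make_cohort(CohortSpec(n_patients=10, fraction_heterogeneous=0.0, seed=5))
    assert all(not lesion.heterogeneous for lesion in cohort.lesions)


def test_heterogeneous_fraction_matches_spec_at_larger_n():
    """Planted heterogeneity rate recovers the configured 24% within
    binomial error, both in truth metadata and in the sampled composition."""
    cohort = make_cohort(CohortSpec(n_patients=60, seed=17))
    lesions = cohort.lesions
    n = len(lesions)
    het = sum(lesion.heterogeneous for lesion in lesions)
    p = 0.24
    margin = 3 * np.sqrt(p * (1 - p) / n)
    assert abs(het / n - p) < margin

    # downstream: composition of detected lesions (coarse maps are enough)
    from tpm3d import label_lesions
    from tpm3d.hotspots import classify_heterogeneity

    detected = het_detected = 0
    for patient in cohort.patients:
        cmap = build_coarse_map(patient.records, cohort.grid)
        lesion_map = label_lesions(cmap)
        for lesion_id in range(1, lesion_map.n_lesions + 1):
            vox = lesion_map.voxels(lesion_id)
            pairs = {decode_pair(int(l))
                     for l in cmap.labels[vox[:, 0], vox[:, 1], vox[:, 2]]}
            detected += 1
            het_detected += classify_heterogeneity(pairs, "grades")
    assert abs(het_detected / detected - p) < 3 * np.sqrt(p * (1 - p) / detected)


def test_phantoms_are_grid_aligned_with_expected_truth(grid):
    cohort = make_offset_phantoms(offsets_mm=(0.0, 10.0), n_per_offset=3, seed=2)
    assert len(cohort.patients) == 6
    for patient, offset in zip(cohort.patients, [0.0] * 3 + [10.0] * 3):
        lesion = patient.lesions[0]
        cx, cy, cz = lesion.spec.center
        assert cz == grid.needle_length
        assert (cx - 2.5) % 5 == 0 and (cy - 2.5) % 5 == 0
        if offset == 0:
            assert lesion.concordant
        else:
            assert not lesion.concordant
            assert lesion.hotspot_distance_mm == pytest.approx(offset - 2.5)
        assert lesion.n_template_columns_hit > 0


def test_phantom_offsets_must_sit_on_the_grid():
    with pytest.raises(ValueError):
        make_offset_phantoms(offsets_mm=(3.0,), n_per_offset=1)
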