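"""Interpolation, smoothing and the grid-site-preservation tuning."""

from __future__ import annotations

import numpy as np
import pytest

from tpm3d import (
    CancerFocus,
    CoreRecord,
    GridSpec,
    build_coarse_map,
    gaussian_smooth,
    interpolate_fine,
    preservation_check,
    tune_sigma,
)
from tpm3d.coarse_map import CoarseMap
from tpm3d.reconstruction import PRESENCE


def _single_voxel_map(grid, i=6, j=6, k=20, label=34):
    labels = np.zeros(grid.coarse_shape, dtype=np.int16)
    labels[i, j, k] = label
    return CoarseMap(labels=labels, grid=grid, ccl_mode="separate")


@pytest.fixture(scope="module")
def hat_fine(grid):
    return interpolate_fine(_single_voxel_map(grid))


# ------------------------------------------------------------ interpolation

def test_fine_equals_coarse_at_voxel_centers(grid, simple_records):
    """Trilinear interpolation interpolates its nodes exactly."""
    cmap = build_coarse_map(simple_records, grid)
    fine = interpolate_fine(cmap)
    ii, jj, kk = np.nonzero(cmap.tissue_mask)
    for pattern in cmap.patterns_present() + [PRESENCE]:
        coarse = (cmap.cancer_mask if pattern == PRESENCE
                  else cmap.pattern_indicator(pattern)).astype(float)
        for i, j, k in zip(ii, jj, kk):
            a, b, c = grid.fine_index_of_site(i, j, k)
            assert fine.fields[pattern][a, b, c] == pytest.approx(coarse[i, j, k])


def test_single_voxel_gives_trilinear_hat(grid, hat_fine):
    presence = hat_fine.fields[PRESENCE]
    a, b, c = grid.fine_index_of_site(6, 6, 20)
    assert presence[a, b, c] == pytest.approx(1.0)
    # linear decay to zero at the adjacent voxel centres
    assert presence[a + 5, b, c] == pytest.approx(0.5)
    assert presence[a + 10, b, c] == pytest.approx(0.0)
    assert presence[a, b, c + 1] == pytest.approx(0.5)
    assert presence[a, b, c + 2] == pytest.approx(0.0)
    assert presence.max() == pytest.approx(1.0)


def test_all_benign_map_interpolates_to_zero(grid):
    labels = np.zeros(grid.coarse_shape, dtype=np.int16)
    fine = interpolate_fine(CoarseMap(labels=labels, grid=grid, ccl_mode="separate"))
    assert fine.fields[PRESENCE].max() == 0.0
    assert fine.patterns == []


# ---------------------------------------------------------------- smoothing

def test_sigma_zero_is_identity(hat_fine):
    smoothed = gaussian_smooth(hat_fine, 0.0)
    for key in hat_fine.fields:
        assert (smoothed.fields[key] == hat_fine.fields[key]).all()


def test_negative_sigma_rejected(hat_fine):
    with pytest.raises(ValueError):
        gaussian_smooth(hat_fine, -0.1)


def test_constant_field_unchanged(grid):
    fine = interpolate_fine(_single_voxel_map(grid))
    fine.fields[PRESENCE][:] = 0.7
    smoothed = gaussian_smooth(fine, 1.5)
    inner = smoothed.fields[PRESENCE][20:-20, 20:-20, 20:-20]
    assert np.allclose(inner, 0.7, atol=1e-4)


def test_impulse_matches_sampled_gaussian_kernel(grid):
    """Smoothing an impulse reproduces the sampled, normalised 3-D kernel."""
    fine = interpolate_fine(_single_voxel_map(grid))
    for key in fine.fields:
        fine.fields[key][:] = 0.0
    a, b, c = grid.fine_index_of_site(6, 6, 20)
    fine.fields[PRESENCE][a, b, c] = 1.0
    sigma_mm = 1.0
    smoothed = gaussian_smooth(fine, sigma_mm)

    sig = sigma_mm / grid.fine_res
    radius = int(4 * sig)  # matches truncate=4
    x = np.arange(-radius, radius + 1)
    kernel_1d = np.exp(-0.5 * (x / sig) ** 2)
    kernel_1d /= kernel_1d.sum()
    kernel = kernel_1d[:, None, None] * kernel_1d[None, :, None] * kernel_1d[None, None, :]
    window = smoothed.fields[PRESENCE][
        a - radius:a + radius + 1, b - radius:b + radius + 1, c - radius:c + radius + 1
    ]
    assert np.allclose(window, kernel, atol=1e-6)


def test_smoothing_conserves_mass(hat_fine):
    for sigma in (0.5, 1.0, 2.5):
        smoothed = gaussian_smooth(hat_fine, sigma)
        for key in hat_fine.fields:
            assert smoothed.fields[key].sum() == pytest.approx(
                hat_fine.fields[key].sum(), rel=1e-4
            )


# ------------------------------------------------------------- preservation

def _two_grade_neighbours(grid):
    """Two z-adjacent voxels of different primary patterns, plus benign cores."""
    records = [
        CoreRecord("P", 6, 6, "apex", 20.0,
                   (CancerFocus(8.0, 1.0, 3, 3), CancerFocus(9.0, 1.0, 4, 4))),
        CoreRecord("P", 7, 6, "apex", 20.0, ()),
    ]
    return build_coarse_map(records, grid)


def test_unsmoothed_interpolation_always_preserves(grid, simple_records):
    cmap = build_coarse_map(simple_records, grid)
    ok, violations = preservation_check(interpolate_fine(cmap), cmap)
    assert ok and violations == []


def test_oversmoothing_flips_sites_and_lists_them(grid):
    cmap = _two_grade_neighbours(grid)
    fine = gaussian_smooth(interpolate_fine(cmap), 4.0)
    ok, violations = preservation_check(fine, cmap)
    assert not ok
    flipped = {(6, 6, 8), (6, 6, 9)}
    assert flipped & set(violations)


def test_all_benign_map_preserved_for_any_sigma(grid):
    labels = np.zeros(grid.coarse_shape, dtype=np.int16)
    cmap = CoarseMap(labels=labels, grid=grid, ccl_mode="separate")
    fine = gaussian_smooth(interpolate_fine(cmap), 3.0)
    ok, _ = preservation_check(fine, cmap)
    assert ok


def test_geometry_mismatch_rejected(grid):
    other = GridSpec(nx=10, ny=10, needle_length=5.0)
    cmap = _single_voxel_map(grid)
    small = CoarseMap(labels=np.zeros(other.coarse_shape, np.int16),
                      grid=other, ccl_mode="separate")
    with pytest.raises(ValueError):
        preservation_check(interpolate_fine(cmap), small)


# ------------------------------------------------------------------- tuning

def test_isolated_lesions_allow_maximal_sigma(grid):
    """Bulky lesions far apart never interact: tuning returns sigma_max.

    (The search cap must stay below the scale at which a lesion's own support
    boundary erodes its edge sites — about one coarse z section here.)
    """
    records = []
    for x in range(1, 4):
        for y in range(1, 4):
            records.append(CoreRecord("P", x, y, "apex", 20.0,
                                      (CancerFocus(0.0, 20.0, 3, 3),)))
    for x in range(9, 12):
        for y in range(9, 12):
            records.append(CoreRecord("P", x, y, "base", 20.0,
                                      (CancerFocus(0.0, 20.0, 3, 3),)))
    cmap = build_coarse_map(records, grid)
    fine = interpolate_fine(cmap)
    assert tune_sigma(fine, cmap, sigma_max=1.0) == 1.0


def test_tuned_sigma_satisfies_preservation(grid):
    cmap = _two_grade_neighbours(grid)
    fine = interpolate_fine(cmap)
    sigma = tune_sigma(fine, cmap, tol=0.05)
    ok, _ = preservation_check(gaussian_smooth(fine, sigma), cmap)
    assert ok
    assert 0 <= sigma < 5.0  # interacting labels cannot take sigma_max


def test_bisection_matches_grid_search_oracle(grid):
    """Brute-force scan over sigma agrees with the bisection to tolerance."""
    cmap = _two_grade_neighbours(grid)
    fine = interpolate_fine(cmap)
    tol = 0.05
    tuned = tune_sigma(fine, cmap, tol=tol)

    step = 0.01
    largest = 0.0
    for sigma in np.arange(0.0, 5.0 + step, step):
        ok, _ = preservation_check(gaussian_smooth(fine, float(sigma)), cmap)
        if ok:
            largest = float(sigma)
        else:
            break  # preservation is monotone for this construction
    assert abs(tuned - largest) <= tol + step
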