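"""Laplace solver and streamline thickness against closed-form geometry."""

import numpy as np
import pytest

from octdr.thickness import (HarmonicField, ThicknessError, compute_layer_thickness,
                             extract_boundaries, jacobi_step,
                             layer_thickness_features, layer_thickness_map,
                             solve_laplace)
from octdr.thickness import _jacobi_sweep_numpy, _weights
from octdr.volio import GridSpacing

SP = GridSpacing()


def slab_labels(shape=(32, 24, 8), top=10, bottom=20):
    """Layer 1 occupying axial rows [top, bottom), vitreous above, layer 2 below."""
    lab = np.zeros(shape, dtype=np.int16)
    lab[:top] = 13
    lab[top:bottom] = 1
    lab[bottom:] = 2
    return lab


def tilted_labels(n=64, nz=6, lo=30.0, hi=40.0):
    """45-degree slab of perpendicular thickness hi-lo, normal (1,1,0)/sqrt2."""
    x, y, _ = np.meshgrid(np.arange(n), np.arange(n), np.arange(nz),
                          indexing="ij")
    d = (x + y) / np.sqrt(2)
    lab = np.zeros((n, n, nz), dtype=np.int16)
    lab[d < lo] = 13
    lab[(d >= lo) & (d < hi)] = 1
    lab[d >= hi] = 2
    return lab


def shell_labels(n=64, a=20.0, b=26.0):
    c = (n - 1) / 2
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    lab = np.zeros((n, n, n), dtype=np.int16)
    lab[r < a] = 13
    lab[(r >= a) & (r < b)] = 1
    lab[r >= b] = 2
    return lab, r


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------

def test_slab_boundaries_are_the_face_rows():
    ref, tgt, mask = extract_boundaries(slab_labels(), 1)
    assert set(np.argwhere(ref)[:, 0]) == {10}
    assert set(np.argwhere(tgt)[:, 0]) == {19}
    assert mask.sum() == 10 * 24 * 8


def test_one_voxel_thick_layer_rejected():
    lab = slab_labels(top=10, bottom=11)
    with pytest.raises(ThicknessError, match="too thin"):
        extract_boundaries(lab, 1)


def test_empty_layer_rejected():
    with pytest.raises(ThicknessError, match="empty"):
        extract_boundaries(slab_labels(), 3)


def test_shell_boundaries_near_analytic_spheres():
    lab, r = shell_labels()
    ref, tgt, _ = extract_boundaries(lab, 1)
    assert np.all(np.abs(r[ref] - 20.0) <= 1.0)
    assert np.all(np.abs(r[tgt] - 26.0) <= 1.0)


# ---------------------------------------------------------------------------
# Jacobi update
# ---------------------------------------------------------------------------

def _field_from_labels(lab, gamma):
    ref, tgt, mask = extract_boundaries(lab, 1)
    return HarmonicField(gamma=gamma, mask=mask, reference_boundary=ref,
                         target_boundary=tgt, spacing=SP, final_residual=0.0)


def test_jacobi_step_fixed_point_and_mean():
    lab = slab_labels()
    g = np.full(lab.shape, 0.5)
    fld = _field_from_labels(lab, g.copy())
    out = jacobi_step(fld)
    interior = fld.mask & ~fld.reference_boundary & ~fld.target_boundary
    assert np.allclose(out.gamma[interior], 0.5)  # all-equal neighbors: fixed

    # neighbors {0,0,0,1,1,1} at isotropic spacing average to 0.5
    g2 = np.zeros((8, 8, 8))
    g2[4, 4, 5] = g2[4, 5, 4] = g2[5, 4, 4] = 1.0
    mask = np.ones((8, 8, 8), bool)
    interior = np.zeros_like(mask)
    interior[4, 4, 4] = True
    new = _jacobi_sweep_numpy(g2, mask, interior, _weights(SP))
    assert new[4, 4, 4] == pytest.approx(0.5)


def test_linear_profile_is_discretely_harmonic():
    """gamma linear in the axial coordinate is unchanged by a Jacobi step."""
    lab = slab_labels()
    z = np.arange(32)[:, None, None]
    g = np.clip((z - 10) / 9.0, 0, 1) * np.ones(lab.shape)
    fld = _field_from_labels(lab, g.copy())
    out = jacobi_step(fld)
    assert np.allclose(out.gamma, g, atol=1e-12)


def test_numba_kernel_matches_numpy_sweep():
    """One kernel iteration equals the vectorized reference update."""
    rng = np.random.default_rng(0)
    lab = slab_labels((20, 12, 6), top=5, bottom=15)
    ref, tgt, mask = extract_boundaries(lab, 1)
    g = np.where(mask, rng.random(lab.shape), 0.0)
    g[ref], g[tgt] = 0.0, 1.0
    interior = mask & ~ref & ~tgt
    expected = _jacobi_sweep_numpy(g, mask, interior, _weights(SP))

    from scipy import ndimage
    from octdr.thickness import _STRUCT6, _jacobi_iterate
    free = interior.copy()
    free[[0, -1], :, :] = False
    free[:, [0, -1], :] = False
    free[:, :, [0, -1]] = False
    free &= ndimage.binary_erosion(mask, _STRUCT6, border_value=0)
    flags = np.zeros(mask.shape, dtype=np.uint8)
    flags[interior] = 2
    flags[free] = 1
    got, it, res, status = _jacobi_iterate(
        np.ascontiguousarray(g), flags, np.ascontiguousarray(mask),
        *_weights(SP), 1e-30, 1)
    assert np.allclose(got, expected, atol=1e-14)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def test_slab_solution_matches_linear_profile():
    lab = slab_labels()
    ref, tgt, mask = extract_boundaries(lab, 1)
    fld = solve_laplace(mask, ref, tgt, SP, tol=1e-6)
    z = np.argwhere(mask)[:, 0]
    assert np.abs(fld.gamma[mask] - (z - 10) / 9.0).max() < 1e-3
    # clamping contract and maximum principle
    assert np.all(fld.gamma[ref] == 0.0)
    assert np.all(fld.gamma[tgt] == 1.0)
    assert fld.gamma[mask].min() >= 0.0 and fld.gamma[mask].max() <= 1.0


def test_halving_tol_reduces_slab_error_monotonically():
    lab = slab_labels((48, 12, 6), top=5, bottom=40)
    ref, tgt, mask = extract_boundaries(lab, 1)
    z = np.argwhere(mask)[:, 0]
    exact = (z - 5) / 34.0
    errs = []
    for tol in (1e-3, 5e-4, 2.5e-4, 1.25e-4):
        fld = solve_laplace(mask, ref, tgt, SP, tol=tol)
        errs.append(np.abs(fld.gamma[mask] - exact).max())
    assert all(e2 <= e1 for e1, e2 in zip(errs, errs[1:]))


def test_disconnected_component_rejected():
    ref, tgt, mask = extract_boundaries(slab_labels((32, 24, 8)), 1)
    mask = mask.copy()
    mask[25:27, 2:4, 2:4] = True    # floating blob touching neither boundary
    with pytest.raises(ThicknessError, match="component"):
        solve_laplace(mask, ref, tgt, SP)


def test_nonconvergence_raises():
    lab = slab_labels()
    ref, tgt, mask = extract_boundaries(lab, 1)
    with pytest.raises(ThicknessError, match="converge"):
        solve_laplace(mask, ref, tgt, SP, tol=1e-12, max_iter=5)


# ---------------------------------------------------------------------------
# thickness maps
# ---------------------------------------------------------------------------

def test_flat_slab_thickness_exact():
    tmap = compute_layer_thickness(slab_labels(), 1, SP)
    assert tmap.failure_fraction == 0.0
    assert np.abs(tmap.valid_lengths - 10.0).max() <= 0.25


def test_tilted_slab_returns_perpendicular_distance():
    tmap = compute_layer_thickness(tilted_labels(), 1, SP)
    mean = tmap.valid_lengths.mean()
    assert abs(mean - 10.0) <= 0.4        # perpendicular, not 14.1 axial


def test_shell_thickness_is_radial_gap():
    lab, _ = shell_labels()
    tmap = compute_layer_thickness(lab, 1, SP)
    assert abs(tmap.valid_lengths.mean() - 6.0) <= 0.3


def test_rotation_invariance_of_mean_thickness():
    lab = tilted_labels()
    base = compute_layer_thickness(lab, 1, SP).valid_lengths.mean()
    rot = compute_layer_thickness(np.rot90(lab, axes=(0, 1)).copy(), 1, SP
                                  ).valid_lengths.mean()
    assert rot == pytest.approx(base, rel=0.02)


def test_doubling_dz_doubles_thickness():
    """Slab along the slice axis: thickness is measured in physical units."""
    lab = np.zeros((8, 8, 32), dtype=np.int16)
    lab[:, :, :10] = 13
    lab[:, :, 10:20] = 1
    lab[:, :, 20:] = 2
    t1 = compute_layer_thickness(lab, 1, GridSpacing(1, 1, 1)).valid_lengths.mean()
    t2 = compute_layer_thickness(lab, 1, GridSpacing(1, 1, 2)).valid_lengths.mean()
    assert t2 == pytest.approx(2 * t1, rel=1e-6)
    assert t1 == pytest.approx(10.0, abs=0.25)


def test_thickness_features_match_length_stats():
    lab = slab_labels()
    tmap = compute_layer_thickness(lab, 1, SP)
    fv = layer_thickness_features(tmap)
    got = dict(zip(fv.stat_names, fv.values))
    assert got["mean"] == pytest.approx(tmap.valid_lengths.mean())
    assert got["sd"] == pytest.approx(tmap.valid_lengths.std())
    assert fv.kind == "thickness"


def test_too_few_streamlines_rejected():
    tmap = compute_layer_thickness(slab_labels(), 1, SP)
    tmap.lengths[:] = np.nan
    with pytest.raises(ThicknessError, match="streamlines"):
        layer_thickness_features(tmap)
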