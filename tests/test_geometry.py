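"""Geometry builders, optical-property algebra, internal reflectance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coraloptics.geometry import (SKELETON, TISSUE, WATER, CoralModelParams,
                                  OpticalProperties, build_bare_skeleton,
                                  build_coral_model, build_homogeneous_slab,
                                  internal_reflectance, make_medium,
                                  replace_skeleton_with_tissue)


@pytest.mark.parametrize("msp, g, expected_mus", [
    (10.0, 0.9, 100.0),   # tissue: reduced scattering 10 at g=0.9
    (5.0, 0.0, 5.0),      # isotropic: mu_s' = mu_s
    (3.4, 0.9, 34.0),     # skeleton best fit
])
def test_make_medium_scales_mus_by_one_minus_g(msp, g, expected_mus):
    med = make_medium(mu_a=0.5, mu_s_prime=msp, g=g)
    assert med.mu_s == pytest.approx(expected_mus)
    assert med.mu_s_prime == pytest.approx(msp)  # round-trips exactly


@pytest.mark.parametrize("kwargs", [
    dict(mu_a=-1.0, mu_s_prime=1.0),
    dict(mu_a=1.0, mu_s_prime=-1.0),
    dict(mu_a=1.0, mu_s_prime=1.0, g=1.0),
])
def test_make_medium_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        make_medium(**kwargs)


@pytest.fixture(scope="module")
def coral():
    params = CoralModelParams()
    return params, build_coral_model(params, tissue=make_medium(1.8, 10.0),
                                     skeleton=make_medium(0.01, 3.4))


def test_coral_model_has_three_media_and_expected_layers(coral):
    params, grid = coral
    assert set(np.unique(grid.labels)) == {WATER, TISSUE, SKELETON}
    # tissue drapes the wall crest for its full thickness
    for z in (params.water_depth + 0.1, params.crest_depth - 0.1):
        assert grid.label_at(0.0, 0.0, z) == TISSUE
    # skeleton below the crest at the wall center
    assert grid.label_at(0.0, 0.0, params.crest_depth + 5.0) == SKELETON
    # water fills the corallite cup above the tissue lining
    assert grid.label_at(params.corallite_width / 2.0, 0.0,
                         params.water_depth + 1.0) == WATER


def test_coral_model_is_extruded_along_y(coral):
    _, grid = coral
    assert all(np.array_equal(grid.labels[:, 0, :], grid.labels[:, j, :])
               for j in range(grid.shape[1]))


def test_tissue_layer_thickness_at_wall_top(coral):
    params, grid = coral
    ix, iy, _ = grid.index_of(0.0, 0.0, params.water_depth + 0.1)
    column = grid.labels[ix, iy, :]
    n_tissue = int((column == TISSUE).sum())
    assert abs(n_tissue * params.dz - params.tissue_thickness) <= params.dz


def test_bare_skeleton_removes_tissue_conserves_skeleton(coral):
    params, grid = coral
    bare = build_bare_skeleton(params, skeleton=grid.media[SKELETON])
    assert set(np.unique(bare.labels)) == {WATER, SKELETON}
    assert (bare.labels == SKELETON).sum() == (grid.labels == SKELETON).sum()
    # every former tissue voxel is now water
    assert np.all(bare.labels[grid.labels == TISSUE] == WATER)


def test_replace_skeleton_with_tissue_changes_media_only(coral):
    _, grid = coral
    tissue = grid.media[TISSUE]
    swapped = replace_skeleton_with_tissue(grid, tissue)
    assert swapped.labels is grid.labels  # label volume shared unchanged
    assert swapped.media[SKELETON] == tissue
    again = replace_skeleton_with_tissue(swapped, tissue)
    assert again.media == swapped.media  # idempotent


def test_replace_skeleton_requires_skeleton_label():
    slab = build_homogeneous_slab(make_medium(1.0, 1.0), thickness_mm=2.0)
    with pytest.raises(ValueError):
        replace_skeleton_with_tissue(slab, make_medium(1.0, 1.0))


def test_coarse_voxels_rejected():
    params = CoralModelParams(dx=0.6, dy=0.6, dz=0.6)
    with pytest.raises(ValueError):
        build_coral_model(params, tissue=make_medium(1.8, 10.0),
                          skeleton=make_medium(0.01, 3.4))


def test_zero_thickness_slab_rejected():
    with pytest.raises(ValueError):
        build_homogeneous_slab(make_medium(1.0, 1.0), thickness_mm=0.0)


@pytest.mark.parametrize("n_rel, expected, tol", [
    (1.38 / 1.33, 0.08, 0.01),   # coral tissue under seawater
    (1.38 / 1.00, 0.51, 0.01),   # coral tissue in air
    (1.0, 0.0, 0.01),            # matched indices
])
def test_internal_reflectance_reference_values(n_rel, expected, tol):
    assert internal_reflectance(n_rel) == pytest.approx(expected, abs=tol)


@settings(max_examples=50, derandomize=True)
@given(st.floats(min_value=1.0, max_value=2.0),
       st.floats(min_value=0.001, max_value=0.5))
def test_internal_reflectance_monotone_in_index(n, dn):
    assert internal_reflectance(n + dn) > internal_reflectance(n)


def test_internal_reflectance_rejects_nonpositive():
    with pytest.raises(ValueError):
        internal_reflectance(0.0)
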