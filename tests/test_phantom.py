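import numpy as np
import pytest
from scipy import ndimage

from soctmi import StructureSet, VoxelGrid, read_mask, read_volume, write_volume
from soctmi.phantom import (PhantomConfig, debug_sphere_phantom, generate_phantom,
                            integral_dose_region, ptv_mask)


def test_body_only_config_gives_uniform_soft_tissue():
    cfg = PhantomConfig(spacing=(1.0, 1.0, 1.0), organs=())
    grid, structures = generate_phantom(cfg)
    assert structures.names == ["body"]
    body = structures["body"]
    assert np.all(grid.density[body] == cfg.density_soft)
    assert np.all(grid.density[~body] == cfg.density_air)


def test_generation_is_deterministic_for_fixed_seed():
    cfg = PhantomConfig(spacing=(1.0, 1.0, 1.0), seed=3)
    g1, s1 = generate_phantom(cfg)
    g2, s2 = generate_phantom(cfg)
    assert np.array_equal(g1.density, g2.density)
    for name in s1.names:
        assert np.array_equal(s1[name], s2[name])
    g3, _ = generate_phantom(PhantomConfig(spacing=(1.0, 1.0, 1.0), seed=4))
    assert not np.array_equal(g1.density, g3.density)


def test_debug_sphere_volume_matches_analytic():
    radius, spacing = 4.0, 0.5
    grid, structures = debug_sphere_phantom(radius, spacing)
    count = structures["skeleton"].sum()
    analytic = 4.0 / 3.0 * np.pi * radius**3 / spacing**3
    assert abs(count - analytic) / analytic < 0.05


def test_ptv_margin_zero_is_exact_union(default_phantom):
    _, structures = default_phantom
    ptv = ptv_mask(structures, 0.0)
    assert np.array_equal(ptv, structures["skeleton"] | structures["spleen"])


def test_ptv_margin_is_monotone_and_matches_dilated_sphere_volume():
    radius, spacing, margin = 4.0, 0.5, 1.0
    _, structures = debug_sphere_phantom(radius, spacing)
    p0 = ptv_mask(structures, 0.0)
    p1 = ptv_mask(structures, spacing)
    assert np.all(p0 <= p1) and p1.sum() > p0.sum()
    dilated = ptv_mask(structures, margin)
    analytic = 4.0 / 3.0 * np.pi * (radius + margin) ** 3 / spacing**3
    assert abs(dilated.sum() - analytic) / analytic < 0.05


def test_ptv_requires_target_masks(water_grid):
    structures = StructureSet(water_grid, {"body": np.ones(water_grid.dims, bool)})
    with pytest.raises(KeyError, match="skeleton"):
        ptv_mask(structures, 0.0)


def test_integral_region_set_arithmetic(default_phantom, body_only_structures):
    _, structures = default_phantom
    region = integral_dose_region(structures)
    expected = structures["body"] & ~(structures["skeleton"] | structures["spleen"])
    assert np.array_equal(region, expected)
    assert region.sum() == structures["body"].sum() - (
        structures["skeleton"] | structures["spleen"]).sum()
    # degenerate cases: empty target -> whole body; skeleton == body -> empty
    assert np.array_equal(integral_dose_region(body_only_structures),
                          body_only_structures["body"])
    grid = body_only_structures.grid
    full = StructureSet(grid, {"body": np.ones(grid.dims, bool),
                               "skeleton": np.ones(grid.dims, bool),
                               "spleen": np.zeros(grid.dims, bool)})
    assert not integral_dose_region(full).any()


def test_organ_escaping_the_body_is_reported_by_name():
    cfg = PhantomConfig(spacing=(1.0, 1.0, 1.0), body_radii_xy=(7.0, 7.0))
    with pytest.raises(ValueError, match="tibias|skeleton|outside"):
        generate_phantom(cfg)


def test_anatomy_adjacencies_and_mask_invariants():
    grid, structures = generate_phantom(PhantomConfig())  # 0.5 mm default
    dist = ndimage.distance_transform_edt(~structures["skeleton"],
                                          sampling=grid.spacing)
    labels, n = ndimage.label(structures["kidneys"])
    assert n == 2
    for lbl in range(1, n + 1):
        assert dist[labels == lbl].min() <= 1.0
    # lungs flank the thoracic spine
    assert dist[structures["lungs"]].min() <= 1.0
    body = structures["body"]
    names = set(structures.names) - {"body"}
    for a in names:
        assert not np.any(structures[a] & ~body)
        for b in names - {a}:
            assert not np.any(structures[a] & structures[b])
    # spine runs cranio-caudally: skeleton spans most of the body z extent
    zs = np.argwhere(structures["skeleton"])[:, 2] * grid.spacing[2]
    assert zs.max() - zs.min() > 0.7 * (grid.dims[2] * grid.spacing[2])


def test_structure_set_rejects_inconsistent_masks(water_grid):
    dims = water_grid.dims
    with pytest.raises(ValueError, match="outside the body"):
        StructureSet(water_grid, {"body": np.zeros(dims, bool),
                                  "skeleton": np.ones(dims, bool)})
    half = np.zeros(dims, bool)
    half[:20] = True
    with pytest.raises(ValueError, match="overlap"):
        StructureSet(water_grid, {"body": np.ones(dims, bool),
                                  "lungs": half, "kidneys": half.copy()})


def test_volume_io_round_trip(tmp_path, default_phantom):
    grid, structures = default_phantom
    p = write_volume(tmp_path / "density.mha", grid)
    back = read_volume(p)
    assert back.dims == grid.dims
    assert back.spacing == grid.spacing
    assert back.origin == grid.origin
    assert np.array_equal(back.density, grid.density)
    mp = write_volume(tmp_path / "skel.nrrd", structures["skeleton"], grid)
    mask = read_mask(mp, grid)
    assert mask.sum() == structures["skeleton"].sum()


def test_volume_io_error_paths(tmp_path, water_grid, default_phantom):
    grid, _ = default_phantom
    with pytest.raises(ValueError, match="extension"):
        write_volume(tmp_path / "x.foo", grid)
    p = write_volume(tmp_path / "d.mha", grid)
    with pytest.raises(ValueError, match="dims"):
        read_mask(p, water_grid)  # 40^3 reference vs phantom dims
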