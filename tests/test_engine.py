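import numpy as np
import pytest

from soctmi import (AttenuationModel, BeamGeometry, VoxelGrid,
                    assemble_influence, beamlet_dose, dose_from_fluence,
                    fixed_field_dose, radiological_path, seven_field_geometries)
from soctmi.engine import DoseInfluenceMatrix


@pytest.fixture(scope="module")
def att():
    return AttenuationModel()


@pytest.fixture(scope="module")
def geo():
    return BeamGeometry(0.0, (20.0, 20.0, 20.0), 305.4, n_rows=21, n_cols=21)


def central_axis_prediction(geometry, attenuation, ys):
    """Closed form on the beam axis of a water cube: inverse square x exp(-mu d)."""
    src = geometry.source()
    dist = np.abs(ys - src[1])
    return (attenuation.output_gy * (geometry.sid_mm / dist) ** 2
            * np.exp(-attenuation.mu_over_rho_water * ys / 10.0))


def test_open_field_depth_dose_matches_closed_form(water_grid, geo, att):
    dose = fixed_field_dose(water_grid, geo, att, ("square", 21.0))
    ys = np.arange(40) + 0.5
    prof = dose[20, :, 20]
    pred = central_axis_prediction(geo, att, ys)
    assert np.max(np.abs(prof / pred - 1.0)) < 0.01


def test_vacuum_limit_is_pure_inverse_square(geo, att):
    grid = VoxelGrid(np.zeros((40, 40, 40)), (1, 1, 1), (0.5, 0.5, 0.5))
    dose = fixed_field_dose(grid, geo, att, ("square", 21.0))
    src = geo.source()
    ys = np.arange(40) + 0.5
    dist = np.sqrt((ys - src[1]) ** 2 + 2 * 0.5**2)  # column is half a voxel off-axis
    pred = att.output_gy * (geo.sid_mm / dist) ** 2
    assert np.max(np.abs(dose[20, :, 20] / pred - 1.0)) < 1e-6


def test_bone_enhancement_at_equal_water_equivalent_depth(water_grid, geo, att):
    """A bone voxel receives the configured enhancement times the water dose
    once the (small) extra attenuation of its own upstream half-voxel is
    divided out."""
    dens = np.ones((40, 40, 40))
    dens[20, 25, 20] = 1.85
    bone_grid = VoxelGrid(dens, (1, 1, 1), (0.5, 0.5, 0.5))
    d_water = fixed_field_dose(water_grid, geo, att, ("square", 21.0))
    d_bone = fixed_field_dose(bone_grid, geo, att, ("square", 21.0))
    voxel_center = (20.5, 25.5, 20.5)
    src = geo.source()
    extra = (radiological_path(bone_grid, src, voxel_center)
             - radiological_path(water_grid, src, voxel_center))
    ratio = (d_bone[20, 25, 20] / d_water[20, 25, 20]
             * np.exp(att.mu_over_rho_water * extra))
    assert ratio == pytest.approx(att.enhancement_bone, rel=1e-9)
    assert att.enhancement_bone >= 2.5


def test_beamlet_dose_decreases_with_depth_and_respects_corridor(water_grid, geo, att):
    center = geo.n_beamlets // 2  # central beamlet (odd grid)
    dose = beamlet_dose(water_grid, geo, att, center)
    prof = dose[20, :, 20]
    assert np.all(np.diff(prof) < 0)
    # zero outside the kernel-widened corridor (> 3 sigma + half cell away)
    assert dose[20 + 10, :, 20].max() == 0.0
    with pytest.raises(IndexError):
        beamlet_dose(water_grid, geo, att, geo.n_beamlets)


def test_seven_field_influence_has_a_column_per_beamlet(water_grid, att):
    geoms = seven_field_geometries((20, 20, 20), n_rows=5, n_cols=5)
    assert [g.gantry_deg for g in geoms] == pytest.approx(
        [k * 360.0 / 7.0 for k in range(7)])
    support = np.zeros(water_grid.dims, bool)
    support[14:26, 14:26, 14:26] = True
    D = assemble_influence(water_grid, support, geoms, att)
    assert D.matrix.shape[1] == 7 * 25
    with pytest.raises(ValueError, match="support"):
        assemble_influence(water_grid, np.zeros(water_grid.dims, bool), geoms, att)


def test_superposition_unit_weights_equal_open_field(water_grid, geo, att):
    support = np.ones(water_grid.dims, bool)
    D = assemble_influence(water_grid, support, [geo], att, floor_rel=1e-4)
    summed = dose_from_fluence(D, np.ones(D.matrix.shape[1]))
    open_field = fixed_field_dose(water_grid, geo, att, ("square", 21.0))
    assert np.max(np.abs(summed - open_field)) <= 0.005 * open_field.max()


def test_dose_from_fluence_is_linear_and_validates(water_grid, geo, att):
    support = np.ones(water_grid.dims, bool)
    D = assemble_influence(water_grid, support, [geo], att)
    n = D.matrix.shape[1]
    assert dose_from_fluence(D, np.zeros(n)).max() == 0.0
    rng = np.random.default_rng(0)
    w = rng.uniform(0, 2, n)
    assert np.allclose(dose_from_fluence(D, 2 * w), 2 * dose_from_fluence(D, w))
    # unit weights equal the column-sum oracle
    colsum = np.asarray(D.matrix.sum(axis=1)).ravel()
    got = dose_from_fluence(D, np.ones(n)).reshape(-1)[D.voxel_indices]
    assert np.allclose(got, colsum)
    with pytest.raises(ValueError, match="non-negative"):
        dose_from_fluence(D, -np.ones(n))
    with pytest.raises(ValueError, match="weights"):
        dose_from_fluence(D, np.ones(n - 1))


def test_fixed_field_apertures(water_grid, geo, att):
    circle = fixed_field_dose(water_grid, geo, att, ("circle", 5.0))
    square = fixed_field_dose(water_grid, geo, att, ("square", 5.0))
    assert np.all(circle <= square + 1e-12)
    assert fixed_field_dose(water_grid, geo, att, ("square", 0.0)).max() == 0.0
    named = fixed_field_dose(water_grid, geo, att, "circle5")
    assert np.array_equal(named, circle)
    with pytest.raises(ValueError, match="shape|collimator"):
        fixed_field_dose(water_grid, geo, att, ("hexagon", 5.0))


def test_open_square_equals_beamlet_superposition_oracle(water_grid, geo, att):
    """Summing every beamlet column reproduces the closed-form open field.

    Columns are truncated outside the kernel-widened ray corridor
    (3 sigma), so agreement is bounded by the Gaussian tail mass there,
    well inside the 0.5% sparsity-floor allowance.
    """
    support = np.ones(water_grid.dims, bool)
    D = assemble_influence(water_grid, support, [geo], att, floor_rel=0.0)
    total = dose_from_fluence(D, np.ones(D.matrix.shape[1]))
    open_field = fixed_field_dose(water_grid, geo, att, ("square", 21.0))
    assert np.max(np.abs(total - open_field)) <= 5e-4 * open_field.max()


def test_influence_matrix_round_trip(tmp_path, water_grid, geo, att):
    support = np.zeros(water_grid.dims, bool)
    support[15:25, 15:25, 15:25] = True
    D = assemble_influence(water_grid, support, [geo], att)
    D.save(tmp_path / "influence")
    back = DoseInfluenceMatrix.load(tmp_path / "influence")
    assert (back.matrix != D.matrix).nnz == 0
    assert np.array_equal(back.voxel_indices, D.voxel_indices)
    assert back.geometries[0].to_dict() == geo.to_dict()


def test_geometry_validation():
    with pytest.raises(ValueError, match="field"):
        BeamGeometry(0.0, (0, 0, 0), 305.4, n_rows=200, n_cols=10, beamlet_mm=1.0)
    with pytest.raises(ValueError, match="SID"):
        BeamGeometry(0.0, (0, 0, 0), -1.0)
    with pytest.raises(ValueError, match="bone enhancement"):
        AttenuationModel(enhancement_bone=0.9)
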