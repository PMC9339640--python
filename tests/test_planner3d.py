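import numpy as np
import pytest

from soctmi import StructureSet, VoxelGrid
from soctmi.engine import AttenuationModel
from soctmi.planner3d import (REGION_NAMES, RegionBeamSet, auto_place_regions,
                              compute_3d_plan, junction_report)


def water_structures(n=40):
    grid = VoxelGrid(np.ones((n, n, n)), (1.0, 1.0, 1.0), (0.5, 0.5, 0.5))
    empty = np.zeros(grid.dims, bool)
    return grid, StructureSet(grid, {"body": np.ones(grid.dims, bool),
                                     "skeleton": empty.copy(), "spleen": empty.copy()})


def sphere_target_structures(radius=4.0, n=40):
    grid, structures = water_structures(n)
    centers = grid.voxel_centers().reshape(*grid.dims, 3)
    c = n / 2.0
    structures.masks["skeleton"] = (
        np.sum((centers - c) ** 2, axis=-1) <= radius**2)
    return grid, structures


def test_compact_spherical_target_gets_one_region_with_10mm_square():
    _, structures = sphere_target_structures(radius=4.0)  # 8 mm sphere
    regions = auto_place_regions(structures)
    assert len(regions) == 1
    assert regions[0].collimator == "10x10"


def test_default_phantom_yields_seven_matched_regions(default_phantom):
    _, structures = default_phantom
    regions = auto_place_regions(structures)
    assert [r.name for r in regions] == list(REGION_NAMES)
    for a, b in zip(regions, regions[1:]):
        assert a.z_range[1] == b.z_range[0]  # shared boundary plane, exact
    # limbs and the spleen region use the perpendicular pair
    axes = {r.name: r.axis for r in regions}
    assert axes["femurs"] == axes["tibias"] == axes["dorsal spine and spleen"] == "dorsoventral"
    assert axes["lumbar spine"] == axes["head"] == "lateral"


def test_normalization_point_receives_prescription():
    grid, structures = water_structures()
    region = RegionBeamSet("single", (20.0, 20.0, 20.0), "40x40", "lateral",
                           (20.0, 20.0, 20.0))
    plan = compute_3d_plan(grid, structures, [region], prescription_gy=12.0)
    idx = tuple(np.rint(grid.world_to_index((20.0, 20.0, 20.0))).astype(int)[0])
    assert plan.dose[idx] == pytest.approx(12.0, rel=1e-3)


def test_matched_abutting_fields_keep_junction_within_ten_percent():
    grid, structures = water_structures()
    # rasterized 20x20 apertures span +/- 9.5 mm: isocenters 19 mm apart
    # make the field edges coincide exactly at z = 20 mm
    ra = RegionBeamSet("a", (20.0, 20.0, 10.5), "20x20", "lateral", (20.0, 20.0, 10.5))
    rb = RegionBeamSet("b", (20.0, 20.0, 29.5), "20x20", "lateral", (20.0, 20.0, 29.5))
    plan = compute_3d_plan(grid, structures, [ra, rb], prescription_gy=12.0)
    profile = plan.dose[20, 20, 14:26] / 12.0
    assert np.all(profile >= 0.90) and np.all(profile <= 1.10)


def test_perpendicular_crossings_produce_junction_hot_spots(default_phantom):
    grid, structures = default_phantom
    regions = auto_place_regions(structures)
    plan = compute_3d_plan(grid, structures, regions, prescription_gy=12.0)
    assert len(plan.junctions) > 0
    assert plan.junctions[0]["peak_pct"] > 110.0


def test_oversized_target_cross_section_names_the_slab():
    n = 60
    grid = VoxelGrid(np.ones((n, n, n)), (1.0, 1.0, 1.0), (0.5, 0.5, 0.5))
    skeleton = np.zeros(grid.dims, bool)
    skeleton[3:53, 28:32, 2:58] = True  # 50 mm wide, 56 mm long
    structures = StructureSet(grid, {"body": np.ones(grid.dims, bool),
                                     "skeleton": skeleton,
                                     "spleen": np.zeros(grid.dims, bool)})
    with pytest.raises(ValueError, match="tibias"):
        auto_place_regions(structures)


def test_junction_report_cases():
    dose = np.full((10, 10, 10), 12.0)
    assert junction_report(dose, 12.0, 110.0) == []
    dose[4, 4, 4] = 18.0
    rep = junction_report(dose, 12.0, 110.0)
    assert len(rep) == 1 and rep[0]["size_voxels"] == 1
    assert rep[0]["peak_pct"] == pytest.approx(150.0)
    # two orthogonal 60% slabs cross in a 120% box
    dose = np.zeros((12, 12, 12))
    dose[3:6, :, :] += 7.2
    dose[:, :, 7:10] += 7.2
    rep = junction_report(dose, 12.0, 110.0)
    assert len(rep) == 1
    assert rep[0]["size_voxels"] == 3 * 12 * 3
    assert rep[0]["peak_pct"] == pytest.approx(120.0)
    with pytest.raises(ValueError, match="100"):
        junction_report(dose, 12.0, 95.0)


def test_region_validation():
    with pytest.raises(ValueError, match="collimator"):
        RegionBeamSet("x", (0, 0, 0), "30x30", "lateral", (0, 0, 0))
    with pytest.raises(ValueError, match="axis"):
        RegionBeamSet("x", (0, 0, 0), "20x20", "oblique", (0, 0, 0))
    # a normalization point far outside the field receives no dose -> error
    grid, structures = water_structures()
    outside = RegionBeamSet("x", (20.0, 20.0, 5.0), "10x10", "lateral",
                            (20.0, 20.0, 38.0))
    with pytest.raises(ValueError, match="normalization point"):
        compute_3d_plan(grid, structures, [outside], 12.0)
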