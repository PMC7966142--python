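"""Geometry construction, coiling cuts and patch invariants."""

import numpy as np
import pytest

from coilpd import (
    AneurysmSpec,
    BranchSpec,
    CoilSurfaceSpec,
    apply_real_coiling,
    apply_virtual_coiling,
    build_pre_coiling,
    n_patch_components,
)
from coilpd.errors import ResolutionError, SpecError
from scipy import ndimage


def _face_set(geom, name):
    return {tuple(r) for r in geom.patches[name].tolist()}


def test_no_dome_limit_matches_analytic_tube_volume(tube_spec):
    h = 0.25e-3
    geom = build_pre_coiling(tube_spec, h)
    L = tube_spec.inlet_extension + tube_spec.parent_length
    analytic = 2.0 * tube_spec.parent_radius * L
    # one cell-layer tolerance along the perimeter
    perim = 2 * L + 4 * tube_spec.parent_radius
    assert abs(geom.fluid_volume() - analytic) <= perim * h


@pytest.mark.parametrize("which", ["side", "term"])
def test_voxel_volume_converges_under_refinement(which, side_spec, term_spec):
    spec = side_spec if which == "side" else term_spec
    vols = {h: build_pre_coiling(spec, h).fluid_volume() for h in (0.5e-3, 0.25e-3)}
    assert abs(vols[0.5e-3] - vols[0.25e-3]) / vols[0.25e-3] < 0.05


def test_branch_gives_two_outlets(side_spec):
    import dataclasses

    spec = dataclasses.replace(side_spec, branch=BranchSpec(radius=1e-3, angle=-np.pi / 4))
    geom = build_pre_coiling(spec, 0.25e-3)
    assert n_patch_components(geom, "outlet") == 2
    assert n_patch_components(build_pre_coiling(side_spec, 0.25e-3), "outlet") == 1


def test_virtual_cut_is_planar_and_strictly_shrinks(side_spec):
    pre = build_pre_coiling(side_spec, 0.25e-3)
    vm = apply_virtual_coiling(pre, side_spec)
    faces = vm.patches["coil_plane"]
    assert faces.shape[0] > 0
    # all faces share one lattice plane and one orientation: a flat cut
    assert np.unique(faces[:, 1]).size == 1
    assert np.all(faces[:, 2] == 0) and np.all(faces[:, 3] == 1)
    assert vm.fluid_volume() < pre.fluid_volume()


def test_virtual_cut_of_no_dome_geometry_is_identity(tube_spec):
    pre = build_pre_coiling(tube_spec, 0.25e-3)
    vm = apply_virtual_coiling(pre, tube_spec)
    assert np.array_equal(vm.fluid, pre.fluid)
    assert vm.patches["coil_plane"].shape[0] == 0


def test_real_coiling_zero_roughness_equals_virtual(side_spec):
    pre = build_pre_coiling(side_spec, 0.25e-3)
    vm = apply_virtual_coiling(pre, side_spec)
    rm = apply_real_coiling(
        pre, side_spec, CoilSurfaceSpec(roughness_amplitude=0.0, seed=42)
    )
    assert np.array_equal(vm.fluid, rm.fluid)
    assert _face_set(vm, "coil_plane") == _face_set(rm, "coil_plane")


def test_real_coiling_is_deterministic_per_seed(side_spec):
    pre = build_pre_coiling(side_spec, 0.25e-3)
    coil = CoilSurfaceSpec(roughness_amplitude=0.2, seed=7)
    a = apply_real_coiling(pre, side_spec, coil)
    b = apply_real_coiling(pre, side_spec, coil)
    assert np.array_equal(a.fluid, b.fluid)
    c = apply_real_coiling(pre, side_spec, CoilSurfaceSpec(roughness_amplitude=0.2, seed=8))
    assert not np.array_equal(a.fluid, c.fluid)


@pytest.mark.parametrize("which", ["side", "term"])
def test_roughness_elevation_bounded_over_many_seeds(which, side_spec, term_spec):
    spec = side_spec if which == "side" else term_spec
    h = 0.5e-3
    amp = 0.2
    pre = build_pre_coiling(spec, h)
    dome = pre.meta["dome_region"]
    n_vec = pre.meta["cut_normal"]
    p0 = pre.meta["cut_point"]
    ii, jj = np.nonzero(dome)
    cx = pre.origin[0] + (ii + 0.5) * h
    cy = pre.origin[1] + (jj + 0.5) * h
    s = (cx - p0[0]) * n_vec[0] + (cy - p0[1]) * n_vec[1]
    bound = amp * spec.neck_width
    for seed in range(50):
        rm = apply_real_coiling(pre, spec, CoilSurfaceSpec(roughness_amplitude=amp, seed=seed))
        kept = rm.fluid[ii, jj]
        if kept.any():
            assert s[kept].max() <= bound + 1e-12


@pytest.mark.parametrize("stage", ["pre", "vm", "rm"])
@pytest.mark.parametrize("which", ["side", "term"])
def test_patch_partition_and_connectivity(stage, which, side_spec, term_spec):
    spec = side_spec if which == "side" else term_spec
    pre = build_pre_coiling(spec, 0.25e-3)
    geom = {
        "pre": pre,
        "vm": apply_virtual_coiling(pre, spec),
        "rm": apply_real_coiling(pre, spec, CoilSurfaceSpec(roughness_amplitude=0.2, seed=1)),
    }[stage]
    inlet, outlet, wall = (_face_set(geom, n) for n in ("inlet", "outlet", "wall"))
    coil = _face_set(geom, "coil_plane")
    assert not inlet & outlet and not inlet & wall and not outlet & wall
    assert coil <= wall  # the coil plane is part of the rigid boundary
    # flood fill from the inlet reaches every fluid cell
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(geom.fluid, structure=structure)
    assert n == 1
    i0, j0 = geom.patches["inlet"][0, :2]
    assert labels[i0, j0] == 1


def test_spec_validation_rejects_bad_inputs(side_spec):
    import dataclasses

    with pytest.raises(SpecError):
        dataclasses.replace(side_spec, neck_width=7e-3).validate()  # > dome diameter
    with pytest.raises(SpecError):
        dataclasses.replace(side_spec, branch=BranchSpec(radius=3e-3, angle=0.5)).validate()
    with pytest.raises(SpecError):
        dataclasses.replace(side_spec, dome_offset_angle=0.3).validate()  # unsupported tilt
    with pytest.raises(ResolutionError):
        build_pre_coiling(side_spec, 1.0e-3)  # < 8 cells across the diameter
    with pytest.raises(SpecError):
        CoilSurfaceSpec(roughness_amplitude=0.7).validate()


def test_branch_overlapping_dome_is_rejected(side_spec):
    import dataclasses

    spec = dataclasses.replace(side_spec, branch=BranchSpec(radius=1e-3, angle=np.pi / 2))
    with pytest.raises(SpecError):
        build_pre_coiling(spec, 0.25e-3)
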