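"""Shared fixtures: small geometries and cached (session-scoped) solves.

Problem sizes are deliberately desk-scale: short inlet extensions (the
inflow profile is prescribed fully developed) and 0.25-0.5 mm grids, so
the whole suite runs in minutes on one CPU.
"""

import numpy as np
import pytest

from coilpd import (
    AneurysmSpec,
    FluidProperties,
    SimulationConfig,
    apply_real_coiling,
    apply_virtual_coiling,
    build_pre_coiling,
    make_waveform,
    solve_steady,
    solve_transient,
    summarize_at_peak,
)
from coilpd.geometry import CoilSurfaceSpec


@pytest.fixture(scope="session")
def props():
    return FluidProperties()


@pytest.fixture(scope="session")
def wave():
    return make_waveform()


@pytest.fixture(scope="session")
def sim():
    return SimulationConfig()


@pytest.fixture(scope="session")
def tube_spec():
    """Straight vessel (degenerate no-dome limit)."""
    return AneurysmSpec(
        parent_radius=2e-3, parent_length=12e-3, dome_radius=0.0,
        neck_width=0.0, inlet_extension=4e-3,
    )


@pytest.fixture(scope="session")
def side_spec():
    """Side-wall aneurysm: post-coiling flow parallel to the coil plane."""
    return AneurysmSpec(
        parent_radius=2e-3, parent_length=16e-3, dome_radius=3e-3,
        neck_width=3e-3, dome_offset_angle=0.0, inlet_extension=4e-3,
    )


@pytest.fixture(scope="session")
def term_spec():
    """Terminal aneurysm on a bent vessel: inflow jet impinges on the coil plane."""
    return AneurysmSpec(
        parent_radius=2e-3, parent_length=16e-3, dome_radius=3e-3,
        neck_width=3e-3, dome_offset_angle=np.pi / 2, inlet_extension=4e-3,
    )


@pytest.fixture(scope="session")
def tube_steady(tube_spec, props):
    """Plane-Poiseuille steady solve at the default 0.25 mm resolution."""
    geom = build_pre_coiling(tube_spec, 0.25e-3)
    field = solve_steady(geom, props, 0.65, init="profile")
    return geom, field


@pytest.fixture(scope="session")
def poiseuille_errors(tube_spec, props):
    """Centerline-profile error at three refinements (h = R/4, R/8, R/16)."""
    errs = {}
    for h in (0.5e-3, 0.25e-3, 0.125e-3):
        geom = build_pre_coiling(tube_spec, h)
        field = solve_steady(geom, props, 0.65, init="profile")
        x, y = geom.cell_centers()
        i = geom.shape[0] // 2
        col = geom.fluid[i, :]
        uc, _ = field.cell_velocity()
        yy = y[col]
        y0, y1 = yy.min() - h / 2, yy.max() + h / 2  # wall positions
        xi = (yy - (y0 + y1) / 2) / ((y1 - y0) / 2)
        exact = 1.5 * 0.65 * (1 - xi**2)
        errs[h] = float(np.max(np.abs(uc[i, col] - exact)) / (1.5 * 0.65))
    return errs


@pytest.fixture(scope="session")
def case_summaries(side_spec, term_spec, props, wave, sim):
    """Full pulsatile VM/RM summaries for the parallel- and impinging-flow cases."""
    out = {}
    coil = CoilSurfaceSpec(roughness_amplitude=0.15, roughness_correlation_length=1e-3, seed=11)
    for name, spec in (("parallel", side_spec), ("impinging", term_spec)):
        pre = build_pre_coiling(spec, 0.5e-3)
        vm = apply_virtual_coiling(pre, spec)
        rm = apply_real_coiling(pre, spec, coil)
        out[name] = {}
        for tag, geom in (("VM", vm), ("RM", rm)):
            series = solve_transient(geom, props, wave, sim)
            out[name][tag] = {
                "geom": geom,
                "series": series,
                "summary": summarize_at_peak(series, geom, props, sim, model=tag),
            }
    return out
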