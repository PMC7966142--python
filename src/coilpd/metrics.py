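"""Hemodynamic parameters at peak systole: Pmax, Pave, Vin, PD.

The pressure-difference score is

    PD = (Pmax - Pave) / (1/2 * rho * Vin^2)

with Pmax the highest pressure sampled on the coil plane, Pave the
area-weighted mean pressure on the inlet measurement plane (1 mm proximal
to the neck), and Vin the area-weighted mean inlet-normal velocity there.
PD is dimensionless (the pressure rise at the coil surface in units of the
inlet dynamic pressure) and is gauge-invariant by construction.  All
values are taken at peak systole, the instant of maximum inlet velocity
within the analyzed cardiac cycle (ties break to the earliest snapshot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError, PatchError
from .flow import FlowField, FlowSeries, SimulationConfig
from .geometry import DomainGeometry


@dataclass
class PlaneSample:
    """Face-sampled pressures, velocities and areas on one patch."""

    patch: str
    pressures: np.ndarray  # Pa, nearest-fluid-cell pressure per face
    normal_velocity: np.ndarray  # m/s, staggered face value, inlet-normal sense
    areas: np.ndarray  # m^2 per unit depth (= h per face)

    def validate(self) -> None:
        if self.pressures.size == 0:
            raise PatchError(f"patch {self.patch!r} is empty")
        if not (np.all(np.isfinite(self.pressures)) and np.all(np.isfinite(self.normal_velocity))):
            raise InputError(f"non-finite samples on patch {self.patch!r}")
        if np.any(self.areas <= 0):
            raise InputError("face areas must be > 0")


@dataclass
class HemodynamicSummary:
    """Pmax, Pave, Vin and PD for one model at peak systole."""

    pmax: float  # Pa
    pave: float  # Pa
    vin: float  # m/s
    pd: float  # dimensionless
    peak_systole_time: float  # s
    model: str = ""  # {"VM", "RM", ...}


def sample_plane(field: FlowField, geom: DomainGeometry, patch: str) -> PlaneSample:
    """Sample a patch: owning-cell pressure and staggered face velocity.

    First-order sampling by design: each face takes the pressure of the
    fluid cell it belongs to, and the face-normal velocity lives exactly on
    the face in the staggered layout.
    """
    faces = geom.patches.get(patch)
    if faces is None or faces.shape[0] == 0:
        raise PatchError(f"patch {patch!r} is empty or missing")
    i, j, di, dj = faces[:, 0], faces[:, 1], faces[:, 2], faces[:, 3]
    press = field.p[i, j]
    vel = np.zeros(faces.shape[0])
    for k in range(faces.shape[0]):
        if dj[k] == 0:
            # vertical face: u index i for di=-1, i+1 for di=+1; the +x
            # (inlet-normal) sense is positive either way
            vel[k] = field.u[i[k] + (1 if di[k] > 0 else 0), j[k]]
        else:
            vel[k] = field.v[i[k], j[k] + (1 if dj[k] > 0 else 0)]
            if dj[k] < 0:
                vel[k] = -vel[k]
    areas = np.full(faces.shape[0], geom.spacing)
    sample = PlaneSample(patch=patch, pressures=press, normal_velocity=vel, areas=areas)
    sample.validate()
    return sample


def find_peak_systole(series: FlowSeries, cfg: SimulationConfig) -> float:
    """Time of maximum inlet mean velocity within the analyzed cycle."""
    if not series.snapshots:
        raise InputError("flow series holds no snapshots")
    best_t = None
    best_v = -np.inf
    faces = series.geom.patches["inlet_plane"]
    for snap in series.snapshots:
        v = float(np.mean(snap.u[faces[:, 0], faces[:, 1]]))
        if v > best_v:  # strict: ties keep the earliest snapshot
            best_v = v
            best_t = snap.time
    return float(best_t)


def pressure_difference(pmax: float, pave: float, vin: float, rho: float) -> float:
    """PD = (pmax - pave) / (0.5 * rho * vin^2); may be negative."""
    if vin <= 0:
        raise ParameterError("vin must be > 0 for the dynamic-pressure normalization")
    if rho <= 0:
        raise ParameterError("rho must be > 0")
    return (pmax - pave) / (0.5 * rho * vin**2)


def summarize(
    field: FlowField,
    geom: DomainGeometry,
    props,
    t_peak: float,
    model: str = "",
) -> HemodynamicSummary:
    """Extract Pmax (coil plane), Pave and Vin (inlet plane) and PD."""
    coil = sample_plane(field, geom, "coil_plane")
    inlet_name = "inlet_plane" if geom.patches.get("inlet_plane") is not None and geom.patches["inlet_plane"].shape[0] else "inlet"
    inlet = sample_plane(field, geom, inlet_name)

    pmax = float(np.max(coil.pressures))
    w = inlet.areas / inlet.areas.sum()
    pave = float(np.sum(w * inlet.pressures))
    vin = float(np.sum(w * inlet.normal_velocity))
    pd = pressure_difference(pmax, pave, vin, props.density)
    return HemodynamicSummary(
        pmax=pmax, pave=pave, vin=vin, pd=pd, peak_systole_time=float(t_peak), model=model
    )


def summarize_at_peak(
    series: FlowSeries, geom: DomainGeometry, props, cfg: SimulationConfig, model: str = ""
) -> HemodynamicSummary:
    """Convenience: locate peak systole in the series and summarize there."""
    t_peak = find_peak_systole(series, cfg)
    snap = min(series.snapshots, key=lambda s: abs(s.time - t_peak))
    return summarize(snap, geom, props, t_peak, model=model)
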