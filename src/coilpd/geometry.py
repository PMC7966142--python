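"""Idealized post-coiling aneurysm geometries on a uniform Cartesian grid.

The fluid domain is two-dimensional (a planar channel standing in for the
internal carotid artery) and is represented immersed-boundary style: a
boolean cell mask on a uniform grid plus labeled boundary patches.  Two
post-coiling variants are derived from one pre-coiling geometry:

* **VM** (virtual post-coiling model): the dome is removed by a flat cut
  through the neck, the planar interface becomes the ``coil_plane`` patch —
  the idealization of complete coil obliteration judged from pre-treatment
  imaging.
* **RM** (real post-coiling model): the same cut displaced by a seeded,
  spatially correlated elevation field, mimicking the rough, uneven surface
  of an actual coil mass.

Two flow configurations are supported through ``dome_offset_angle``:

* ``0`` — side-wall aneurysm on a straight parent vessel; after coiling the
  flow runs *parallel* to the coil plane.
* ``[pi/4, pi/2]`` — the parent vessel bends by that angle at the neck and
  the dome sits in line with the inflow jet (terminal type); after coiling
  the jet *impinges* on the coil plane.

All lengths are meters; masks are cell-centered, 0-based, with half-open
index ranges.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import Point, Polygon
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from .errors import GeometryError, ResolutionError, SpecError

#: distance from the neck's proximal edge to the interior measurement plane
#: where Pave and Vin are sampled (the ICA section 1 mm proximal to the neck).
INLET_PLANE_OFFSET = 1.0e-3

#: minimum number of cells across the parent-vessel diameter
MIN_CELLS_ACROSS = 8

PATCH_NAMES = ("inlet", "outlet", "wall", "coil_plane", "inlet_plane")


@dataclass(frozen=True)
class BranchSpec:
    """A PcomA-like branch leaving the parent vessel near the neck."""

    radius: float  # m, half-width of the branch channel
    angle: float  # rad from the +x axis (positive: upward)


@dataclass(frozen=True)
class AneurysmSpec:
    """Parametric description of the pre-coiling vessel + dome geometry."""

    parent_radius: float = 2.0e-3  # m (ICA-like half-width)
    parent_length: float = 16.0e-3  # m, mother-vessel segment containing the neck
    dome_radius: float = 3.0e-3  # m; 0 gives the degenerate straight tube
    neck_width: float = 3.0e-3  # m; must be <= 2*dome_radius
    dome_offset_angle: float = 0.0  # rad; 0 side-wall, [pi/4, pi/2] terminal
    branch: Optional[BranchSpec] = None
    inlet_extension: float = 75.0e-3  # m, proximal passage before the neck

    def validate(self) -> None:
        if self.parent_radius <= 0 or self.parent_length <= 0:
            raise SpecError("parent_radius and parent_length must be > 0")
        if self.inlet_extension <= 0:
            raise SpecError("inlet_extension must be > 0")
        if self.dome_radius < 0 or self.neck_width < 0:
            raise SpecError("dome_radius and neck_width must be >= 0")
        if self.dome_radius > 0 and self.neck_width <= 0:
            raise SpecError("a dome requires neck_width > 0")
        if self.neck_width > 2.0 * self.dome_radius:
            raise SpecError("neck_width must not exceed the dome diameter")
        th = self.dome_offset_angle
        if not (th == 0.0 or (np.pi / 4 - 1e-12) <= th <= (np.pi / 2 + 1e-12)):
            raise SpecError(
                "dome_offset_angle must be 0 (side-wall) or in [pi/4, pi/2] (terminal)"
            )
        if th > 0 and self.neck_width > 2.0 * self.parent_radius:
            raise SpecError("terminal configuration requires neck_width <= vessel diameter")
        if self.branch is not None:
            if self.branch.radius <= 0 or self.branch.radius >= self.parent_radius:
                raise SpecError("branch.radius must be in (0, parent_radius)")

    @property
    def has_dome(self) -> bool:
        return self.dome_radius > 0


@dataclass(frozen=True)
class CoilSurfaceSpec:
    """Coil-surface variant: flat virtual plane or seeded rough surrogate."""

    mode: str = "RM_rough"  # {"VM_flat", "RM_rough"}
    roughness_amplitude: float = 0.15  # fraction of neck_width (RM only)
    roughness_correlation_length: float = 1.0e-3  # m (RM only)
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("VM_flat", "RM_rough"):
            raise SpecError(f"unknown coil-surface mode {self.mode!r}")
        if not (0.0 <= self.roughness_amplitude <= 0.5):
            raise SpecError("roughness_amplitude must lie in [0, 0.5]")
        if self.roughness_correlation_length <= 0:
            raise SpecError("roughness_correlation_length must be > 0")


@dataclass
class DomainGeometry:
    """Discretized fluid domain with labeled boundary patches.

    ``fluid`` is indexed ``[i, j]`` for (x, y).  A patch is an ``(N, 4)``
    integer array of faces ``(i, j, di, dj)``: the face of fluid cell
    ``(i, j)`` toward neighbor ``(i+di, j+dj)`` (which is solid, removed
    coil mass, or outside the lattice).
    """

    spacing: float
    origin: tuple[float, float]
    fluid: np.ndarray
    patches: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    # -- convenience ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.fluid.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.fluid.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        return x, y

    def fluid_volume(self) -> float:
        """Fluid area per unit depth (m^2): cell count times h^2."""
        return float(self.fluid.sum()) * self.spacing**2

    def copy(self) -> "DomainGeometry":
        return DomainGeometry(
            spacing=self.spacing,
            origin=self.origin,
            fluid=self.fluid.copy(),
            patches={k: v.copy() for k, v in self.patches.items()},
            meta=dict(self.meta),
        )


def _empty_patch() -> np.ndarray:
    return np.zeros((0, 4), dtype=np.intp)


def _strip(p0: np.ndarray, direction: np.ndarray, half_width: float, length: float) -> Polygon:
    """Rectangle of given half-width from p0 along a unit direction."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    n = np.array([-d[1], d[0]])
    a = p0 + n * half_width
    b = p0 - n * half_width
    return Polygon([a, b, b + d * length, a + d * length])


def _label_components(mask: np.ndarray) -> int:
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n = ndimage.label(mask, structure=structure)
    return n


def _interior_faces(fluid: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Faces of `fluid` cells whose 4-neighbor lies in `other`."""
    rows = []
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = np.zeros_like(fluid)
        if di == 1:
            nb[:-1, :] = other[1:, :]
        elif di == -1:
            nb[1:, :] = other[:-1, :]
        elif dj == 1:
            nb[:, :-1] = other[:, 1:]
        else:
            nb[:, 1:] = other[:, :-1]
        ii, jj = np.nonzero(fluid & nb)
        if ii.size:
            rows.append(
                np.column_stack([ii, jj, np.full_like(ii, di), np.full_like(ii, dj)])
            )
    if not rows:
        return _empty_patch()
    out = np.concatenate(rows).astype(np.intp)
    order = np.lexsort((out[:, 3], out[:, 2], out[:, 1], out[:, 0]))
    return out[order]


def _boundary_patches(fluid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(inlet, outlet) faces on the lattice boundary.

    The inlet is the x=0 edge; every other boundary face of a fluid cell
    is an outlet (pressure reference p = 0).
    """
    nx, ny = fluid.shape
    inlet = []
    outlet = []
    for j in np.nonzero(fluid[0, :])[0]:
        inlet.append((0, j, -1, 0))
    for j in np.nonzero(fluid[nx - 1, :])[0]:
        outlet.append((nx - 1, j, 1, 0))
    for i in np.nonzero(fluid[:, 0])[0]:
        if i != 0:
            outlet.append((i, 0, 0, -1))
    for i in np.nonzero(fluid[:, ny - 1])[0]:
        if i != 0:
            outlet.append((i, ny - 1, 0, 1))
    inlet_arr = np.array(inlet, dtype=np.intp) if inlet else _empty_patch()
    outlet_arr = np.array(outlet, dtype=np.intp) if outlet else _empty_patch()
    return inlet_arr, outlet_arr


def _inlet_plane_patch(fluid: np.ndarray, spacing: float, origin_x: float, x_m: float) -> np.ndarray:
    """Interior vertical measurement plane nearest x = x_m."""
    i_m = int(round((x_m - origin_x) / spacing))
    nx, _ = fluid.shape
    i_m = max(1, min(nx - 1, i_m))
    faces = []
    for j in np.nonzero(fluid[i_m, :] & fluid[i_m - 1, :])[0]:
        faces.append((i_m, j, -1, 0))
    if not faces:
        raise GeometryError("inlet measurement plane intersects no fluid cells")
    return np.array(faces, dtype=np.intp)


def n_patch_components(geom: DomainGeometry, name: str) -> int:
    """Number of connected face groups in a patch (e.g. distinct outlets)."""
    faces = geom.patches.get(name, _empty_patch())
    if faces.shape[0] == 0:
        return 0
    mask = np.zeros(geom.fluid.shape, dtype=bool)
    mask[faces[:, 0], faces[:, 1]] = True
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return int(n)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _layout(spec: AneurysmSpec, h: float) -> dict:
    """Continuous-geometry layout shared by build and coiling operations."""
    R = spec.parent_radius
    a = spec.dome_radius
    w = spec.neck_width
    th = spec.dome_offset_angle
    ext = spec.inlet_extension
    big = 4.0 * (ext + spec.parent_length + 4 * a + 1.0)

    vessel: list[Polygon] = []
    dome: list[Polygon] = []
    margin = 3.0 * h

    if th == 0.0:  # side-wall configuration
        L = ext + spec.parent_length
        x_n = ext + spec.parent_length / 2.0
        vessel.append(shapely_box(0.0, -R, L, R))
        if spec.has_dome:
            cy = R + float(np.sqrt(max(a**2 - (w / 2.0) ** 2, 0.0)))
            dome.append(Point(x_n, cy).buffer(a, quad_segs=128))
        cut_point = np.array([x_n, R])
        cut_normal = np.array([0.0, 1.0])
        cut_tangent = np.array([1.0, 0.0])
        neck_proximal_x = x_n - w / 2.0
        branch_anchor = np.array([x_n, 0.0])
        xmax = L
        ymax = max(R, (dome[0].bounds[3] if dome else R)) + margin
        ymin = -R - margin
    else:  # terminal configuration on a bent parent vessel
        x_b = ext + spec.parent_length / 2.0
        x_cut = x_b + 2.0 * R
        vessel.append(shapely_box(0.0, -R, x_b, R))
        vessel.append(shapely_box(x_b, -R, x_cut, R))  # bend junction box
        pivot = np.array([x_b + R, 0.0])
        d = np.array([np.cos(th), -np.sin(th)])
        vessel.append(_strip(pivot, d, R, big))
        if spec.has_dome:
            ccx = x_cut + float(np.sqrt(max(a**2 - (w / 2.0) ** 2, 0.0)))
            dip = a - float(np.sqrt(max(a**2 - (w / 2.0) ** 2, 0.0)))
            if dip > 2.0 * R:
                raise SpecError("dome dips past the bend junction; reduce neck_width")
            dome.append(Point(ccx, 0.0).buffer(a, quad_segs=128))
        cut_point = np.array([x_cut, 0.0])
        cut_normal = np.array([1.0, 0.0])
        cut_tangent = np.array([0.0, 1.0])
        neck_proximal_x = x_b
        branch_anchor = pivot
        xmax = (dome[0].bounds[2] if dome else x_cut) + margin
        ymax = max(R, (dome[0].bounds[3] if dome else R)) + margin
        ymin = -R - spec.parent_length / 2.0

    if spec.branch is not None:
        alpha = spec.branch.angle
        bdir = np.array([np.cos(alpha), np.sin(alpha)])
        branch_poly = _strip(branch_anchor, bdir, spec.branch.radius, big)
        if dome and branch_poly.intersection(dome[0]).area > 1e-3 * dome[0].area:
            raise SpecError("branch overlaps the aneurysm dome")
        vessel.append(branch_poly)

    box = shapely_box(0.0, ymin, xmax, ymax)
    vessel_poly = unary_union(vessel).intersection(box)
    full_poly = unary_union(vessel + dome).intersection(box)
    return {
        "vessel_poly": vessel_poly,
        "full_poly": full_poly,
        "box": (0.0, ymin, xmax, ymax),
        "cut_point": cut_point,
        "cut_normal": cut_normal,
        "cut_tangent": cut_tangent,
        "neck_proximal_x": neck_proximal_x,
    }


def build_pre_coiling(spec: AneurysmSpec, grid_spacing: float) -> DomainGeometry:
    """Voxelize the pre-coiling vessel + dome onto a uniform grid.

    Patches ``inlet``/``outlet``/``wall`` (and the interior measurement
    plane ``inlet_plane``) are tagged; ``coil_plane`` is empty until a
    coiling operation is applied.
    """
    spec.validate()
    h = float(grid_spacing)
    if h <= 0:
        raise SpecError("grid_spacing must be > 0")
    if 2.0 * spec.parent_radius / h < MIN_CELLS_ACROSS:
        raise ResolutionError(
            f"grid spacing {h:g} m resolves the vessel diameter with fewer "
            f"than {MIN_CELLS_ACROSS} cells"
        )

    lay = _layout(spec, h)
    x0, y0, x1, y1 = lay["box"]
    nx = int(np.ceil((x1 - x0) / h - 1e-9))
    ny = int(np.ceil((y1 - y0) / h - 1e-9))
    xc = x0 + (np.arange(nx) + 0.5) * h
    yc = y0 + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    fluid = shapely.contains_xy(lay["full_poly"], X.ravel(), Y.ravel()).reshape(nx, ny)
    vessel_mask = shapely.contains_xy(lay["vessel_poly"], X.ravel(), Y.ravel()).reshape(nx, ny)
    if not fluid.any():
        raise GeometryError("empty fluid domain")
    if _label_components(fluid) != 1:
        raise ResolutionError(
            "fluid region is not a single connected component; the grid is "
            "too coarse to resolve the neck or branch"
        )

    inlet, outlet = _boundary_patches(fluid)
    if inlet.shape[0] == 0:
        raise GeometryError("no inlet faces on the x=0 boundary")
    if outlet.shape[0] == 0:
        raise GeometryError("no outlet faces; the vessel does not reach the boundary")
    solid = ~fluid
    wall = _interior_faces(fluid, solid)
    x_m = lay["neck_proximal_x"] - INLET_PLANE_OFFSET
    if x_m < 2 * h:
        raise SpecError("inlet_extension too short for the 1 mm measurement plane")
    inlet_plane = _inlet_plane_patch(fluid, h, x0, x_m)

    dome_region = fluid & ~vessel_mask
    geom = DomainGeometry(
        spacing=h,
        origin=(x0, y0),
        fluid=fluid,
        patches={
            "inlet": inlet,
            "outlet": outlet,
            "wall": wall,
            "coil_plane": _empty_patch(),
            "inlet_plane": inlet_plane,
        },
        meta={
            "spec": spec,
            "stage": "pre_coiling",
            "dome_region": dome_region,
            "cut_point": lay["cut_point"],
            "cut_normal": lay["cut_normal"],
            "cut_tangent": lay["cut_tangent"],
            "neck_proximal_x": lay["neck_proximal_x"],
        },
    )
    return geom


def _apply_cut(geom: DomainGeometry, elevation: Optional[np.ndarray], tag: str) -> DomainGeometry:
    """Remove dome cells above the cut surface and tag the coil plane.

    ``elevation`` maps each dome cell to the local admissible height above
    the flat cut (None means a flat cut: remove the whole dome region).
    """
    fluid = geom.fluid
    dome_region = geom.meta["dome_region"]
    if not dome_region.any():
        out = geom.copy()
        out.meta["stage"] = tag
        return out  # nothing to cut: identity with empty coil_plane

    h = geom.spacing
    x0, y0 = geom.origin
    nx, ny = fluid.shape
    ii, jj = np.nonzero(dome_region)
    cx = x0 + (ii + 0.5) * h
    cy = y0 + (jj + 0.5) * h
    n = geom.meta["cut_normal"]
    p0 = geom.meta["cut_point"]
    s = (cx - p0[0]) * n[0] + (cy - p0[1]) * n[1]  # height above the flat cut

    keep = np.zeros(ii.shape, dtype=bool)
    if elevation is not None:
        keep = (s > 0) & (s < elevation)
    removed = np.zeros_like(fluid)
    removed[ii[~keep], jj[~keep]] = True
    removed &= dome_region
    post = fluid & ~removed

    # cells no longer reachable from the inlet become coil mass as well
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, nlab = ndimage.label(post, structure=structure)
    if nlab > 1:
        inlet = geom.patches["inlet"]
        lab_in = labels[inlet[0, 0], inlet[0, 1]]
        orphan = post & (labels != lab_in)
        removed |= orphan
        post &= labels == lab_in

    inlet, outlet = _boundary_patches(post)
    for patch, name in ((inlet, "inlet"), (outlet, "outlet")):
        pre = geom.patches[name]
        if patch.shape[0] != pre.shape[0]:
            raise GeometryError(f"coil cut intersects the {name} patch")

    coil_plane = _interior_faces(post, removed)
    wall = _interior_faces(post, ~post)
    x_m = geom.meta["neck_proximal_x"] - INLET_PLANE_OFFSET
    inlet_plane = _inlet_plane_patch(post, h, x0, x_m)

    out = DomainGeometry(
        spacing=h,
        origin=geom.origin,
        fluid=post,
        patches={
            "inlet": inlet,
            "outlet": outlet,
            "wall": wall,
            "coil_plane": coil_plane,
            "inlet_plane": inlet_plane,
        },
        meta=dict(geom.meta),
    )
    out.meta["stage"] = tag
    out.meta["removed"] = removed
    return out


def apply_virtual_coiling(geom: DomainGeometry, spec: AneurysmSpec) -> DomainGeometry:
    """Flat planar cut through the neck: the virtual post-coiling model.

    The cut plane is parallel to the local parent-vessel axis and separates
    the dome from the vessel (and from any branch ostium, which stays
    patent because only dome cells are removed).
    """
    if geom.meta.get("stage") == "pre_coiling" and geom.meta.get("spec") != spec:
        raise SpecError("geometry was not built from the given spec")
    return _apply_cut(geom, elevation=None, tag="VM")


def apply_real_coiling(
    geom: DomainGeometry, spec: AneurysmSpec, coil: CoilSurfaceSpec
) -> DomainGeometry:
    """Rough coil-surface surrogate: the real post-coiling model.

    The flat cut is displaced into the dome by a seeded, spatially
    correlated elevation field with maximum displacement
    ``roughness_amplitude * neck_width``; a zero amplitude reproduces the
    VM cut exactly and the construction is a pure function of
    ``(spec, coil, seed)``.
    """
    coil.validate()
    if coil.mode != "RM_rough":
        raise SpecError("apply_real_coiling requires mode='RM_rough'")
    if geom.meta.get("stage") == "pre_coiling" and geom.meta.get("spec") != spec:
        raise SpecError("geometry was not built from the given spec")

    amp = coil.roughness_amplitude * spec.neck_width
    if amp > spec.dome_radius:
        raise GeometryError("roughness amplitude exceeds the dome: surface would breach the wall")

    dome_region = geom.meta["dome_region"]
    if not dome_region.any() or amp == 0.0:
        return _apply_cut(geom, elevation=None if amp == 0.0 else None, tag="RM")

    h = geom.spacing
    x0, y0 = geom.origin
    ii, jj = np.nonzero(dome_region)
    cx = x0 + (ii + 0.5) * h
    cy = y0 + (jj + 0.5) * h
    tvec = geom.meta["cut_tangent"]
    p0 = geom.meta["cut_point"]
    t = (cx - p0[0]) * tvec[0] + (cy - p0[1]) * tvec[1]

    # correlated elevation profile along the cut, rescaled to [0, amp]
    ds = h / 2.0
    t_lo, t_hi = float(t.min()) - h, float(t.max()) + h
    ns = max(int(np.ceil((t_hi - t_lo) / ds)) + 1, 8)
    sgrid = np.linspace(t_lo, t_hi, ns)
    rng = np.random.default_rng(coil.seed)
    noise = rng.standard_normal(ns)
    sigma = coil.roughness_correlation_length / (sgrid[1] - sgrid[0])
    smooth = gaussian_filter1d(noise, sigma=sigma, mode="nearest")
    smooth -= smooth.min()
    peak = smooth.max()
    eta = amp * smooth / peak if peak > 0 else np.zeros_like(smooth)

    elevation = np.interp(t, sgrid, eta)
    return _apply_cut(geom, elevation=elevation, tag="RM")
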