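"""Slicing-based cylindrical parameterization of a vascular surface.

The surface is cut at each centerline station's axial level z_k; each closed
cross-section contour is resampled uniformly in arclength, translated to the
local centerline origin (c_x,k, c_y,k) and mapped to polar samples (r, θ).
Interpolating the samples onto a fixed angle axis θ_i = −π + 2πi/N (with
periodic ±2π augmentation, so the seam at ±π is continuous) yields a regular
K×N radius grid: the *unwrapped* representation.  Because all follow-up scans
of one patient share the same (z_k, θ_i) lattice, temporal shape change is
carried entirely by the radii, with one-to-one node correspondence over time.

The inverse map re-projects a radius grid about a centerline into a Cartesian
point cloud, closing the loop for quality control and for turning forecasted
grids back into 3D geometry.

Each cross-section is assumed star-shaped about its centerline point (the
radius single-valued in θ); violations are resolved conservatively by keeping
the outermost sample per angle, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

from ._slicing import polygon_centroid, polygon_perimeter, section_loops
from .centerline import Centerline
from .exceptions import (
    DegenerateSamplesError,
    EmptySliceError,
    GeometryError,
    LatticeError,
    ParameterizationError,
)
from .mesh_io import Layer, SurfaceMesh

__all__ = [
    "Contour",
    "CylindricalGrid",
    "make_theta_axis",
    "slice_at_level",
    "resample_contour",
    "to_cylindrical",
    "grid_row_interpolate",
    "parameterize_surface",
    "inverse_map",
]


@dataclass
class Contour:
    """A closed planar cross-section at constant z, ordered CCW from +z."""

    points: np.ndarray  # (M, 3), cm; all z equal
    z: float
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise GeometryError(
                f"contour at z={self.z:.6g} has {len(self.points)} points"
            )
        if np.any(np.abs(self.points[:, 2] - self.z) > 1e-9):
            raise GeometryError(f"contour points not coplanar at z={self.z:.6g}")

    @property
    def perimeter(self) -> float:
        return polygon_perimeter(self.points)

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid (x, y)."""
        return polygon_centroid(self.points)


@dataclass
class CylindricalGrid:
    """K×N radius field on the fixed (z_k, θ_i) lattice."""

    radii: np.ndarray  # (K, N), cm
    z_axis: np.ndarray  # (K,), cm
    theta_axis: np.ndarray  # (N,), radians in [-pi, pi)
    layer: Layer

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        self.theta_axis = np.asarray(self.theta_axis, dtype=float)
        self.layer = Layer(self.layer)
        K, N = self.radii.shape
        if self.z_axis.shape != (K,) or self.theta_axis.shape != (N,):
            raise LatticeError(
                f"axes ({self.z_axis.shape}, {self.theta_axis.shape}) do not "
                f"match radii shape {self.radii.shape}"
            )
        if not np.all(np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise GeometryError("grid radii must be finite and positive")

    @property
    def K(self) -> int:
        return self.radii.shape[0]

    @property
    def N(self) -> int:
        return self.radii.shape[1]

    def unwrapped_cloud(self) -> np.ndarray:
        """(K·N, 3) array of (r, θ, z) points — the deployed representation."""
        th = np.broadcast_to(self.theta_axis, self.radii.shape)
        zz = np.broadcast_to(self.z_axis[:, None], self.radii.shape)
        return np.column_stack([self.radii.ravel(), th.ravel(), zz.ravel()])

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV: k, i, z_k, theta_i, r."""
        K, N = self.radii.shape
        kk, ii = np.meshgrid(np.arange(K), np.arange(N), indexing="ij")
        rows = np.column_stack([
            kk.ravel(), ii.ravel(),
            self.z_axis[kk.ravel()], self.theta_axis[ii.ravel()],
            self.radii.ravel(),
        ])
        np.savetxt(path, rows, delimiter=",",
                   header=f"# layer={self.layer.value}\nk,i,z_k,theta_i,r",
                   comments="", fmt=["%d", "%d", "%.17g", "%.17g", "%.17g"])


def make_theta_axis(N: int) -> np.ndarray:
    """The fixed angle lattice θ_i = −π + 2πi/N, i = 0..N−1."""
    if N < 4:
        raise ValueError("N must be >= 4")
    return -np.pi + 2.0 * np.pi * np.arange(N) / N


def slice_at_level(
    mesh: SurfaceMesh, z: float, center: np.ndarray | tuple[float, float]
) -> Contour:
    """Planar intersection of the surface at height z, as one closed contour.

    When the plane cuts several loops (e.g. slicing below an iliac
    bifurcation) the loop whose area centroid lies nearest to ``center`` is
    kept.  Orientation is counter-clockwise viewed from +z.
    """
    lo, hi = mesh.z_extent
    if not (lo < z < hi):
        raise EmptySliceError(
            f"z={z:.6g} not strictly inside mesh z-extent [{lo:.6g}, {hi:.6g}]"
        )
    loops = section_loops(mesh.trimesh, z)
    c = np.asarray(center, dtype=float)[:2]
    loop = min(loops, key=lambda lp: float(np.linalg.norm(polygon_centroid(lp) - c)))
    return Contour(points=loop, z=float(z))


def resample_contour(contour: Contour, N: int) -> Contour:
    """Resample a closed contour to N points uniformly spaced in arclength.

    The walk starts at the original vertex with the smallest polar angle
    about the contour's area centroid, making the output reproducible.
    """
    if N < 3:
        raise ValueError("N must be >= 3")
    pts = contour.points
    P = contour.perimeter
    if P <= 0:
        raise GeometryError(f"zero-perimeter contour at z={contour.z:.6g}")
    cx, cy = contour.centroid
    theta = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
    start = int(np.argmin(theta))
    pts = np.roll(pts, -start, axis=0)

    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed[:, :2], axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = arclen[-1] * np.arange(N) / N
    x = np.interp(targets, arclen, closed[:, 0])
    y = np.interp(targets, arclen, closed[:, 1])
    out = np.column_stack([x, y, np.full(N, contour.z)])
    return Contour(points=out, z=contour.z)


def to_cylindrical(
    contour: Contour, center: np.ndarray | tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Polar samples (r, θ) of a contour about the local centerline origin.

    The center must lie strictly inside the contour (star-shape assumption);
    θ is in [−π, π) and r strictly positive.
    """
    c = np.asarray(center, dtype=float)[:2]
    poly = Polygon(contour.points[:, :2])
    if not poly.contains(Point(c)):
        raise ParameterizationError(
            f"centerline point ({c[0]:.6g}, {c[1]:.6g}) not strictly inside "
            f"the contour at z={contour.z:.6g}"
        )
    dx = contour.points[:, 0] - c[0]
    dy = contour.points[:, 1] - c[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    theta[theta >= np.pi] = -np.pi  # fold the half-open boundary
    return r, theta


def _dedupe_sorted(theta: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average radii at exactly-tied angles (already sorted by theta)."""
    if len(theta) == 0:
        return theta, r
    uniq, inverse = np.unique(theta, return_inverse=True)
    if len(uniq) == len(theta):
        return theta, r
    sums = np.bincount(inverse, weights=r)
    counts = np.bincount(inverse)
    return uniq, sums / counts


def grid_row_interpolate(
    r: np.ndarray, theta: np.ndarray, theta_axis: np.ndarray
) -> np.ndarray:
    """Periodic interpolation of polar samples onto the fixed angle axis.

    Samples are sorted by θ, replicated at θ±2π, and linearly interpolated at
    each θ_i.  On a single slice the paper's natural-neighbour interpolation
    degenerates to 1-D interpolation in θ; periodic linear interpolation with
    the same ±2π augmentation is used, which is seam-free at ±π by
    construction.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if len(r) < 3:
        raise DegenerateSamplesError("need >= 3 (r, θ) samples")
    order = np.argsort(theta, kind="stable")
    theta, r = theta[order], r[order]
    theta, r = _dedupe_sorted(theta, r)
    if len(theta) < 2 or theta[-1] - theta[0] < 1e-12:
        raise DegenerateSamplesError("angular samples collapse to one angle")
    theta_aug = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_aug = np.concatenate([r, r, r])
    out = np.interp(theta_axis, theta_aug, r_aug)
    if not np.all(np.isfinite(out)) or np.any(out <= 0):
        raise GeometryError("interpolated radii must be finite and positive")
    return out


def _star_shape_envelope(
    r: np.ndarray, theta: np.ndarray, theta_axis: np.ndarray
) -> np.ndarray:
    """Outer-envelope fallback for non-star-shaped sections.

    Bins samples to the nearest lattice angle keeping the largest radius,
    then interpolates the envelope periodically.
    """
    N = len(theta_axis)
    idx = np.round((theta + np.pi) * N / (2 * np.pi)).astype(int) % N
    env = np.full(N, -np.inf)
    np.maximum.at(env, idx, r)
    good = np.isfinite(env)
    return grid_row_interpolate(env[good], theta_axis[good], theta_axis)


def _is_star_shaped(theta: np.ndarray) -> bool:
    """True when θ along the CCW-resampled contour winds monotonically.

    Small local backtracks are tolerated; more than one full wrap of
    accumulated backtracking counts as a violation.
    """
    d = np.diff(np.unwrap(theta))
    backtrack = -d[d < 0].sum()
    return backtrack <= 2 * np.pi


def parameterize_surface(
    mesh: SurfaceMesh, cl: Centerline, N: int
) -> tuple[CylindricalGrid, list[Contour]]:
    """Forward cylindrical parameterization of one surface.

    Per station k: slice at z_k about (c_x,k, c_y,k), resample the contour
    uniformly to N points (these Cartesian slices S_k are returned for
    evaluation), convert to polar samples about the station, and interpolate
    onto the fixed θ lattice.  The grid interpolation uses the polar samples
    of the *full* chained contour rather than the N arclength-resampled
    points: it is strictly more information, identical in the limit of fine
    meshes, and avoids aliasing sub-lattice radial detail through the
    arclength reparameterization.  The resulting K×N radius grid shares its
    axes with every other scan of the patient parameterized on the same
    centerline lattice.
    """
    theta_axis = make_theta_axis(N)
    K = cl.K
    radii = np.empty((K, N))
    slices: list[Contour] = []
    for k in range(K):
        cx, cy, zk = cl.stations[k]
        try:
            raw = slice_at_level(mesh, zk, (cx, cy))
            contour = resample_contour(raw, N)
            r, theta = to_cylindrical(raw, (cx, cy))
            if _is_star_shaped(theta):
                radii[k] = grid_row_interpolate(r, theta, theta_axis)
            else:
                warnings.warn(
                    f"station {k} (z={zk:.6g}): cross-section not star-shaped "
                    f"about the centerline; keeping the outer envelope",
                    stacklevel=2,
                )
                radii[k] = _star_shape_envelope(r, theta, theta_axis)
        except Exception as exc:
            raise type(exc)(f"station {k} (z={zk:.6g}): {exc}") from exc
        slices.append(contour)
    grid = CylindricalGrid(radii=radii, z_axis=cl.z.copy(),
                           theta_axis=theta_axis, layer=mesh.layer)
    return grid, slices


@dataclass
class LayerParameterization:
    """All scans of one layer on the patient-common lattice."""

    layer: Layer
    centerlines: list[Centerline]  # one per scan, shared z lattice
    grids: list[CylindricalGrid]  # one per scan, shared axes
    slices: list[list[Contour]]  # raw Cartesian slices S_k per scan


@dataclass
class SeriesParameterization:
    """Per-layer parameterizations of a patient series on one lattice."""

    z_axis: dict[Layer, np.ndarray]  # per-layer K station levels
    theta_axis: np.ndarray  # N angles, shared
    layers: dict[Layer, LayerParameterization]


def parameterize_series(
    series,
    K: int = 100,
    N: int = 100,
    n_harmonics: int = 5,
    z_margin: float = 0.02,
) -> SeriesParameterization:
    """Parameterize every scan of a patient on a common per-layer lattice.

    Per layer: a slice-centroid centerline is extracted for each scan over
    the z range common to all of that layer's meshes (shrunk by ``z_margin``
    of the range at each end so slicing planes stay strictly interior),
    Fourier-smoothed, and resampled onto the K-station z lattice defined
    over that common range.  Each mesh is then parameterized about its own
    scan's centerline on that lattice, so all scans share axes and node
    correspondence.
    """
    from .centerline import extract_raw_centerline, fourier_smooth, resample_stations

    theta_axis = make_theta_axis(N)
    out_z: dict[Layer, np.ndarray] = {}
    out_layers: dict[Layer, LayerParameterization] = {}
    for layer in (Layer.OUTER_WALL, Layer.LUMEN):
        meshes = series.meshes(layer)
        lo = max(m.z_extent[0] for m in meshes)
        hi = min(m.z_extent[1] for m in meshes)
        if hi <= lo:
            raise LatticeError(
                f"{layer.value}: scans share no common z range"
            )
        pad = z_margin * (hi - lo)
        z_grid = np.linspace(lo + pad, hi - pad, K)
        cls_, grids, slices = [], [], []
        for mesh in meshes:
            raw = extract_raw_centerline(mesh, z_grid[0], z_grid[-1], K)
            smooth = fourier_smooth(raw, n_harmonics)
            cl = resample_stations(smooth, K, z_grid=z_grid)
            grid, sl = parameterize_surface(mesh, cl, N)
            # one shared axes object per patient: node correspondence is
            # structural, not merely numerical
            grid.z_axis = z_grid
            grid.theta_axis = theta_axis
            cls_.append(cl)
            grids.append(grid)
            slices.append(sl)
        out_z[layer] = z_grid
        out_layers[layer] = LayerParameterization(
            layer=layer, centerlines=cls_, grids=grids, slices=slices
        )
    return SeriesParameterization(z_axis=out_z, theta_axis=theta_axis,
                                  layers=out_layers)


def inverse_map(grid: CylindricalGrid, cl: Centerline) -> np.ndarray:
    """Back-project a radius grid about a centerline to Cartesian points.

    Node (k, i) maps to (c_x,k + r_{k,i} cos θ_i, c_y,k + r_{k,i} sin θ_i,
    z_k); returns the K·N points in row-major (k, i) order.
    """
    if grid.K != cl.K or not np.allclose(grid.z_axis, cl.z, atol=1e-9):
        raise LatticeError(
            f"grid lattice (K={grid.K}) inconsistent with centerline (K={cl.K})"
        )
    cos_t = np.cos(grid.theta_axis)
    sin_t = np.sin(grid.theta_axis)
    x = cl.stations[:, 0][:, None] + grid.radii * cos_t
    y = cl.stations[:, 1][:, None] + grid.radii * sin_t
    z = np.broadcast_to(grid.z_axis[:, None], grid.radii.shape)
    return np.column_stack([x.ravel(), y.ravel(), z.ravel()])
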