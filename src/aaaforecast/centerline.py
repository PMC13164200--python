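"""Vessel centerlines: slice-centroid extraction, Fourier smoothing, resampling.

A centerline is an ordered sequence of K stations (c_x, c_y, c_z) running
proximal (renal arteries) to distal (iliac bifurcation), with strictly
increasing z.  Raw centerlines come from the area centroids of constant-z
cross-sections of the surface; they are then smoothed with a truncated
Fourier series in the normalised axial parameter and resampled onto K evenly
spaced stations (or onto a supplied patient-common z lattice so that all
follow-up scans share one station axis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._slicing import polygon_area, polygon_centroid, section_loops
from .exceptions import (
    CoverageError,
    EmptySliceError,
    ExtrapolationError,
    IdentifiabilityError,
)
from .mesh_io import Layer, SurfaceMesh

__all__ = [
    "Centerline",
    "extract_raw_centerline",
    "fourier_smooth",
    "resample_stations",
]


@dataclass
class Centerline:
    """K ordered stations along the vessel axis, z strictly increasing."""

    stations: np.ndarray  # (K, 3), cm
    layer: Layer

    def __post_init__(self):
        self.stations = np.atleast_2d(np.asarray(self.stations, dtype=float))
        self.layer = Layer(self.layer)
        z = self.stations[:, 2]
        if len(z) < 2 or np.any(np.diff(z) <= 0):
            raise ValueError("centerline z must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.stations)

    @property
    def z(self) -> np.ndarray:
        return self.stations[:, 2]

    def to_csv(self, path: str | Path) -> None:
        header = (f"# layer={self.layer.value} K={self.K}\n"
                  "station_index,c_x,c_y,c_z")
        rows = np.column_stack([np.arange(self.K), self.stations])
        np.savetxt(path, rows, delimiter=",", header=header, comments="",
                   fmt=["%d", "%.17g", "%.17g", "%.17g"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "Centerline":
        with open(path) as fh:
            meta = fh.readline().strip()
        layer = Layer.OUTER_WALL
        if meta.startswith("#"):
            for tok in meta[1:].split():
                if tok.startswith("layer="):
                    layer = Layer(tok.split("=", 1)[1])
        data = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2)
        return cls(stations=data[:, 1:4], layer=layer)


def extract_raw_centerline(
    mesh: SurfaceMesh,
    z_min: float,
    z_max: float,
    n_levels: int,
) -> Centerline:
    """Slice-centroid centerline at ``n_levels`` evenly spaced z levels.

    At each level the area centroid of the planar cross-section contour (the
    largest-area loop if the plane cuts several) becomes one station.
    """
    if n_levels < 3:
        raise ValueError(f"n_levels must be >= 3, got {n_levels}")
    lo, hi = mesh.z_extent
    if z_min < lo - 1e-12 or z_max > hi + 1e-12 or z_min >= z_max:
        raise ValueError(
            f"[z_min, z_max]=[{z_min:.6g}, {z_max:.6g}] outside mesh z-extent "
            f"[{lo:.6g}, {hi:.6g}]"
        )
    levels = np.linspace(z_min, z_max, n_levels)
    stations = np.empty((n_levels, 3))
    for k, z in enumerate(levels):
        try:
            loops = section_loops(mesh.trimesh, z)
        except EmptySliceError as exc:
            raise CoverageError(
                f"no cross-section at level {k} (z={z:.6g})", level=k
            ) from exc
        loop = max(loops, key=lambda lp: abs(polygon_area(lp)))
        cx, cy = polygon_centroid(loop)
        stations[k] = (cx, cy, z)
    return Centerline(stations=stations, layer=mesh.layer)


def _fourier_design(s: np.ndarray, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(s)]
    for m in range(1, n_harmonics + 1):
        cols.append(np.cos(2 * np.pi * m * s))
        cols.append(np.sin(2 * np.pi * m * s))
    return np.column_stack(cols)


def fourier_smooth(cl: Centerline, n_harmonics: int) -> Centerline:
    """Least-squares truncated Fourier smoothing of c_x(s) and c_y(s).

    The axial coordinate is mapped to s in [0, 1]; each transverse coordinate
    is replaced by its projection onto {1, cos 2πms, sin 2πms : m <= H}.
    z is untouched (it is the parameter, not a response).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if cl.K < 2 * n_harmonics + 1:
        raise IdentifiabilityError(
            f"K={cl.K} stations cannot identify {2 * n_harmonics + 1} "
            f"Fourier coefficients"
        )
    z = cl.z
    s = (z - z[0]) / (z[-1] - z[0])
    X = _fourier_design(s, n_harmonics)
    coef, *_ = np.linalg.lstsq(X, cl.stations[:, :2], rcond=None)
    smoothed = cl.stations.copy()
    smoothed[:, :2] = X @ coef
    return Centerline(stations=smoothed, layer=cl.layer)


def resample_stations(
    cl: Centerline,
    K: int,
    z_grid: np.ndarray | None = None,
) -> Centerline:
    """Linear resampling onto K evenly spaced z stations (or a given lattice).

    Passing ``z_grid`` forces a patient-common station axis: the baseline
    scan's lattice is reused for every follow-up so all scans share node
    correspondence.
    """
    z = cl.z
    if z_grid is not None:
        z_new = np.asarray(z_grid, dtype=float)
        if z_new.min() < z.min() - 1e-12 or z_new.max() > z.max() + 1e-12:
            raise ExtrapolationError(
                f"z_grid [{z_new.min():.6g}, {z_new.max():.6g}] outside "
                f"centerline extent [{z.min():.6g}, {z.max():.6g}]"
            )
    else:
        if K < 2:
            raise ValueError("K must be >= 2")
        z_new = np.linspace(z[0], z[-1], K)
    x_new = np.interp(z_new, z, cl.stations[:, 0])
    y_new = np.interp(z_new, z, cl.stations[:, 1])
    return Centerline(stations=np.column_stack([x_new, y_new, z_new]),
                      layer=cl.layer)
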