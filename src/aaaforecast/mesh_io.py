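"""Surface-mesh and patient-manifest I/O.

The pipeline consumes already-segmented, co-registered triangulated surfaces of
the aneurysm outer wall and lumen, one pair per imaging session, in a common
patient frame with coordinates in centimetres.  This module reads and
validates those meshes (STL or PLY), loads the per-patient scan manifest, and
writes point clouds produced downstream.

Registration of follow-up scans to the patient frame is a *precondition*: the
loader only checks that consecutive scans overlap substantially and warns
otherwise.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .exceptions import (
    InsufficientDataError,
    MeshFormatError,
    MeshValidationError,
)

__all__ = [
    "Layer",
    "SurfaceMesh",
    "Scan",
    "PatientSeries",
    "read_mesh",
    "load_patient_series",
    "write_point_cloud",
]


class Layer(str, enum.Enum):
    """Anatomical surface layer."""

    LUMEN = "lumen"
    OUTER_WALL = "outer_wall"


@dataclass
class SurfaceMesh:
    """A closed, consistently oriented triangulated surface in cm.

    Invariants (enforced by :func:`read_mesh` / :meth:`validate`): watertight
    (every edge shared by exactly two faces), positive signed volume, at least
    four vertices.
    """

    vertices: np.ndarray  # (V, 3) float64, cm
    faces: np.ndarray  # (F, 3) int
    layer: Layer

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.layer = Layer(self.layer)
        self._trimesh: trimesh.Trimesh | None = None

    @property
    def trimesh(self) -> trimesh.Trimesh:
        """The underlying :class:`trimesh.Trimesh` (cached, not processed)."""
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @property
    def signed_volume(self) -> float:
        return float(self.trimesh.volume)

    @property
    def z_extent(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    def validate(self) -> None:
        """Raise :class:`MeshValidationError` on any invariant violation."""
        if len(self.vertices) < 4:
            raise MeshValidationError(
                f"mesh has {len(self.vertices)} vertices; need >= 4"
            )
        tm = self.trimesh
        if not tm.is_watertight:
            n_open = _count_open_edges(tm)
            raise MeshValidationError(
                f"mesh is not watertight: {n_open} open edges", open_edges=n_open
            )
        if tm.volume <= 0:
            raise MeshValidationError(
                f"mesh has non-positive signed volume {tm.volume:.6g}"
            )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, layer: Layer) -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
                   layer=layer)


def _count_open_edges(tm: trimesh.Trimesh) -> int:
    """Number of edges referenced by exactly one face."""
    edges = np.sort(tm.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


@dataclass
class Scan:
    """One imaging session: acquisition time and both layer surfaces."""

    time_days: int
    wall: SurfaceMesh
    lumen: SurfaceMesh


@dataclass
class PatientSeries:
    """Time-ordered co-registered scans of one patient.

    ``z_axis``/``theta_axis`` are attached by the parameterization step and
    are shared by every scan of the patient (one-to-one node correspondence).
    """

    patient_id: str
    scans: list[Scan]
    z_axis: np.ndarray | None = None  # K station levels, cm
    theta_axis: np.ndarray | None = None  # N angles, radians, [-pi, pi)

    def __post_init__(self):
        times = [s.time_days for s in self.scans]
        if len(times) < 2:
            raise InsufficientDataError(
                f"patient {self.patient_id!r}: {len(times)} scan(s); need >= 2"
            )
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise MeshValidationError(
                f"patient {self.patient_id!r}: scan times must be strictly "
                f"increasing, got {times}"
            )
        if times[0] != 0:
            raise MeshValidationError(
                f"patient {self.patient_id!r}: first scan must be at day 0, "
                f"got {times[0]}"
            )

    @property
    def times_days(self) -> np.ndarray:
        return np.array([s.time_days for s in self.scans], dtype=float)

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def meshes(self, layer: Layer) -> list[SurfaceMesh]:
        layer = Layer(layer)
        return [s.wall if layer is Layer.OUTER_WALL else s.lumen
                for s in self.scans]


def read_mesh(path: str | Path, layer: Layer | str) -> SurfaceMesh:
    """Read and validate a surface mesh (STL, binary or ASCII, or PLY).

    Degenerate (zero-area) triangles are dropped, duplicate vertices merged
    and the orientation fixed so the signed volume is positive.  A mesh that
    is not watertight after this light repair raises
    :class:`MeshValidationError` naming the open-edge count.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load_mesh(str(path))
    except Exception as exc:  # trimesh raises a zoo of types
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"no geometry in {path}")
        tm = trimesh.util.concatenate(geoms)
    if tm.faces.shape[0] == 0:
        raise MeshFormatError(f"no faces in {path}")

    tm.merge_vertices()
    tm.update_faces(tm.nondegenerate_faces())
    tm.update_faces(tm.unique_faces())
    tm.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(tm)
    if tm.is_watertight and tm.volume < 0:
        tm.invert()

    mesh = SurfaceMesh.from_trimesh(tm, Layer(layer))
    mesh.validate()
    return mesh


def _scan_day(entry: dict, base_date: _dt.date | None) -> int:
    if "day" in entry:
        return int(entry["day"])
    if "date" in entry:
        d = _dt.date.fromisoformat(entry["date"])
        assert base_date is not None
        return (d - base_date).days
    raise MeshValidationError(f"manifest scan entry needs 'day' or 'date': {entry}")


def load_patient_series(manifest_path: str | Path) -> PatientSeries:
    """Load a patient's scan series from a JSON manifest.

    Manifest schema::

        {"patient_id": "AAA001",
         "scans": [{"date": "2020-01-01" | "day": 0,
                    "wall_mesh": "fu1_wall.stl",
                    "lumen_mesh": "fu1_lumen.stl"}, ...]}

    Mesh paths are resolved relative to the manifest.  Times are converted to
    integer days since the earliest scan and scans sorted by time.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    entries = manifest.get("scans", [])
    if len(entries) < 2:
        raise InsufficientDataError(
            f"manifest {manifest_path} lists {len(entries)} scan(s); need >= 2"
        )

    base_date = None
    if any("date" in e for e in entries):
        base_date = min(_dt.date.fromisoformat(e["date"]) for e in entries
                        if "date" in e)
    days = [_scan_day(e, base_date) for e in entries]
    day0 = min(days)
    days = [d - day0 for d in days]
    if len(set(days)) != len(days):
        raise MeshValidationError(
            f"manifest {manifest_path}: duplicate scan times {sorted(days)}"
        )

    root = manifest_path.parent
    scans = []
    for day, entry in sorted(zip(days, entries), key=lambda p: p[0]):
        wall = read_mesh(root / entry["wall_mesh"], Layer.OUTER_WALL)
        lumen = read_mesh(root / entry["lumen_mesh"], Layer.LUMEN)
        scans.append(Scan(time_days=day, wall=wall, lumen=lumen))

    series = PatientSeries(patient_id=str(manifest.get("patient_id", manifest_path.stem)),
                           scans=scans)
    _check_registration(series)
    return series


def _bbox_overlap_fraction(a: SurfaceMesh, b: SurfaceMesh) -> float:
    lo = np.maximum(a.vertices.min(axis=0), b.vertices.min(axis=0))
    hi = np.minimum(a.vertices.max(axis=0), b.vertices.max(axis=0))
    inter = np.prod(np.clip(hi - lo, 0, None))
    vol_a = np.prod(a.vertices.max(axis=0) - a.vertices.min(axis=0))
    vol_b = np.prod(b.vertices.max(axis=0) - b.vertices.min(axis=0))
    denom = min(vol_a, vol_b)
    return float(inter / denom) if denom > 0 else 0.0


def _check_registration(series: PatientSeries) -> None:
    # co-registration is a precondition; only sanity-check overlap
    for s1, s2 in zip(series.scans, series.scans[1:]):
        frac = _bbox_overlap_fraction(s1.wall, s2.wall)
        if frac < 0.5:
            warnings.warn(
                f"patient {series.patient_id!r}: wall bounding boxes of scans "
                f"at day {s1.time_days} and {s2.time_days} overlap only "
                f"{100 * frac:.0f}% — are the scans co-registered?",
                stacklevel=2,
            )


_CYL_HEADER = "r_cm,theta_rad,z_cm"
_CART_HEADER = "x_cm,y_cm,z_cm"


def write_point_cloud(
    points: Sequence[Sequence[float]] | np.ndarray,
    path: str | Path,
    format: str = "csv",
    coordinates: str = "cartesian",
) -> None:
    """Write a point cloud losslessly.

    CSV files carry a header naming the coordinate convention
    (``x_cm,y_cm,z_cm`` or ``r_cm,theta_rad,z_cm``); values round-trip at full
    float64 precision.  PLY output is Cartesian only.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot write an empty point cloud")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {pts.shape}")
    path = Path(path)
    if format == "csv":
        header = _CYL_HEADER if coordinates == "cylindrical" else _CART_HEADER
        np.savetxt(path, pts, delimiter=",", header=header, comments="",
                   fmt="%.17g")
    elif format == "ply":
        if coordinates != "cartesian":
            raise ValueError("PLY output supports Cartesian coordinates only")
        trimesh.PointCloud(pts).export(str(path), file_type="ply")
    else:
        raise ValueError(f"unknown point-cloud format {format!r}")


def read_point_cloud(path: str | Path) -> tuple[np.ndarray, str]:
    """Read a CSV point cloud written by :func:`write_point_cloud`.

    Returns the points and the coordinate convention
    (``"cartesian"`` or ``"cylindrical"``).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    coords = "cylindrical" if header == _CYL_HEADER else "cartesian"
    return pts, coords
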