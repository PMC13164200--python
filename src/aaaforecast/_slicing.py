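"""Low-level constant-z plane sections of a triangulated surface.

Shared by centerline extraction and cylindrical parameterization.  Sections
are taken with horizontal planes z = const; trimesh performs the
triangle-plane intersection and segment chaining, and this module normalises
the result into closed, counter-clockwise loops.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .exceptions import EmptySliceError, TopologyError

_Z = np.array([0.0, 0.0, 1.0])


def section_loops(tm: trimesh.Trimesh, z: float) -> list[np.ndarray]:
    """All closed loops of the section of ``tm`` at height ``z``.

    Each loop is an (M, 3) array of distinct points (not repeated at the
    end), ordered counter-clockwise when viewed from +z, all at height ``z``.

    Raises :class:`EmptySliceError` when the plane misses the mesh and
    :class:`TopologyError` when intersection segments cannot be chained into
    closed loops (within trimesh's merge tolerance).
    """
    path = tm.section(plane_origin=[0.0, 0.0, float(z)], plane_normal=_Z)
    if path is None:
        raise EmptySliceError(f"plane z={z:.6g} does not intersect the mesh")
    tol = 1e-6 * float(np.linalg.norm(tm.bounds[1] - tm.bounds[0]))
    loops = []
    for curve in path.discrete:
        curve = np.asarray(curve, dtype=float)
        if len(curve) < 4:
            continue
        if np.linalg.norm(curve[0] - curve[-1]) > tol:
            raise TopologyError(
                f"open intersection curve at z={z:.6g}: endpoint gap "
                f"{np.linalg.norm(curve[0] - curve[-1]):.3g} exceeds "
                f"tolerance {tol:.3g}"
            )
        loop = curve[:-1]
        # drop consecutive duplicates left by chaining
        keep = np.ones(len(loop), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(loop, axis=0), axis=1) > 1e-14
        loop = loop[keep]
        if len(loop) < 3:
            continue
        loop = loop.copy()
        loop[:, 2] = z  # pin exactly onto the slicing plane
        if polygon_area(loop) < 0:
            loop = loop[::-1]
        loops.append(loop)
    if not loops:
        raise EmptySliceError(
            f"plane z={z:.6g} produced no usable closed loop"
        )
    return loops


def polygon_area(loop: np.ndarray) -> float:
    """Signed shoelace area of a planar loop's (x, y) projection."""
    x, y = loop[:, 0], loop[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(loop: np.ndarray) -> np.ndarray:
    """Area centroid (x, y) of a planar loop."""
    x, y = loop[:, 0], loop[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return np.array([x.mean(), y.mean()])
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def polygon_perimeter(loop: np.ndarray) -> float:
    """Perimeter of a closed planar loop (xy projection)."""
    d = np.diff(np.vstack([loop, loop[:1]])[:, :2], axis=0)
    return float(np.linalg.norm(d, axis=1).sum())
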