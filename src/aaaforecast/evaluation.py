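"""Forecast evaluation: HD95 spatial similarity and geometric scalars.

Spatial agreement between a forecast and the observed anatomy is measured
with the 95th percentile of the combined bidirectional nearest-neighbour
distance distribution (HD95), in three complementary spaces: the 3D
centerline path (x, y, z), the unwrapped (r, θ, z) point cloud, and the
reconstructed Cartesian surface.  HD95 discounts isolated outliers while
still bounding meaningful local discrepancies.

Clinically interpretable scalars are compared as relative percentage errors:
the maximum *hydraulic* diameter D_h = 4A/P over cross-sections (robust to
asymmetric sections, unlike a single caliper distance) and the slice-
integrated sac volume.  Both sides of every scalar comparison pass through
the same slice representation so the error isolates the growth model rather
than the parameterization.

Cohort summaries are macro-averages of per-patient means over follow-ups
(each patient weighs equally regardless of scan count), plus R^2 and MAE of
predicted versus true scalars across patient-follow-up pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._slicing import polygon_area, polygon_perimeter
from .cyl_param import Contour, CylindricalGrid, inverse_map
from .exceptions import GeometryError
from .mesh_io import Layer

__all__ = [
    "hd95",
    "hydraulic_dmax",
    "volume_from_slices",
    "grid_slices",
    "EvalReport",
    "CohortSummary",
    "evaluate_forecast",
    "summarize_cohort",
]


def hd95(A: np.ndarray, B: np.ndarray) -> float:
    """95th percentile of the combined bidirectional NN distances.

    For every point of A the distance to its nearest neighbour in B is
    computed, and vice versa; the two lists are concatenated and the 95th
    percentile (linear interpolation between order statistics) returned.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("point sets must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    d_ab = cKDTree(B).query(A, k=1)[0]
    d_ba = cKDTree(A).query(B, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def _contour_area_perimeter(contour: Contour) -> tuple[float, float]:
    pts = contour.points
    area = abs(polygon_area(pts))
    perim = polygon_perimeter(pts)
    if area <= 0 or perim <= 0:
        raise GeometryError(
            f"degenerate contour at z={contour.z:.6g} "
            f"(area={area:.3g}, perimeter={perim:.3g})"
        )
    return area, perim


def hydraulic_dmax(slices: list[Contour]) -> float:
    """Maximum hydraulic diameter D_h = 4A/P over cross-section slices."""
    if not slices:
        raise ValueError("need at least one slice")
    best = 0.0
    for c in slices:
        area, perim = _contour_area_perimeter(c)
        best = max(best, 4.0 * area / perim)
    return best


def volume_from_slices(slices: list[Contour], z_axis: np.ndarray) -> float:
    """Trapezoidal integration of per-slice polygon area over z (cm^3)."""
    z = np.asarray(z_axis, dtype=float)
    if len(slices) < 2 or len(slices) != len(z):
        raise ValueError("need >= 2 slices matching z_axis")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z_axis must be strictly increasing")
    areas = np.array([_contour_area_perimeter(c)[0] for c in slices])
    return float(np.trapezoid(areas, z))


def grid_slices(grid: CylindricalGrid, cl) -> list[Contour]:
    """Constant-z contours of a radius grid about its centerline.

    Used so forecast scalars and ground-truth scalars come from the same
    slice representation.
    """
    pts = inverse_map(grid, cl).reshape(grid.K, grid.N, 3)
    return [Contour(points=pts[k], z=float(grid.z_axis[k]))
            for k in range(grid.K)]


_METRICS = ["hd95_centerline", "hd95_unwrapped", "hd95_reconstruction",
            "dmax_err_pct", "volume_err_pct",
            # mean predicted scalars reported alongside the error metrics
            "dmax_pred", "volume_pred"]
_SCALARS = ["dmax", "volume"]


@dataclass
class EvalReport:
    """Per-follow-up, per-layer evaluation rows for one patient."""

    patient_id: str
    regime: str
    table: pd.DataFrame  # columns: time_days, layer, held_out, metrics...

    def to_json(self, path) -> None:
        payload = {"patient_id": self.patient_id, "regime": self.regime,
                   "rows": self.table.to_dict(orient="records")}
        import json
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _normalized_unwrapped(cloud: np.ndarray, r_scale: float) -> np.ndarray:
    # optional variant: put θ (radians) on the radial length scale
    out = cloud.copy()
    out[:, 1] *= r_scale
    return out


def evaluate_forecast(results, normalize_unwrapped: bool = False) -> EvalReport:
    """Evaluate a fitted patient model against every follow-up scan.

    For each follow-up time and layer the model is forecast at that time and
    compared with the scan's parameterized ground truth: HD95 of centerline
    stations, of unwrapped (r, θ, z) clouds, and of reconstructed Cartesian
    clouds, plus relative percentage errors of max hydraulic diameter and
    slice-integrated volume.  Follow-ups excluded from training (the
    ``exclude_last`` regime) are flagged ``held_out``.

    By default the unwrapped space mixes units (r, z in cm; θ in radians),
    matching how the representation is defined; ``normalize_unwrapped``
    rescales θ by the mean radius to put all coordinates on a length scale.
    """
    series = results.series
    param = results.param
    times = series.times_days
    rows = []
    for j in range(1, series.n_scans):
        t = float(times[j])
        fc = results.forecast(t)
        for layer in (Layer.OUTER_WALL, Layer.LUMEN):
            lp = param.layers[layer]
            cl_true = lp.centerlines[j]
            grid_true = lp.grids[j]
            cl_pred, grid_pred, cloud_pred = fc[layer]

            unw_pred = grid_pred.unwrapped_cloud()
            unw_true = grid_true.unwrapped_cloud()
            if normalize_unwrapped:
                r_scale = float(grid_true.radii.mean())
                unw_pred = _normalized_unwrapped(unw_pred, r_scale)
                unw_true = _normalized_unwrapped(unw_true, r_scale)

            cloud_true = inverse_map(grid_true, cl_true)
            slices_pred = grid_slices(grid_pred, cl_pred)
            slices_true = grid_slices(grid_true, cl_true)
            dmax_pred = hydraulic_dmax(slices_pred)
            dmax_true = hydraulic_dmax(slices_true)
            vol_pred = volume_from_slices(slices_pred, grid_pred.z_axis)
            vol_true = volume_from_slices(slices_true, grid_true.z_axis)

            rows.append({
                "time_days": t,
                "layer": layer.value,
                "held_out": t in results.held_out_times,
                "hd95_centerline": hd95(cl_pred.stations, cl_true.stations),
                "hd95_unwrapped": hd95(unw_pred, unw_true),
                "hd95_reconstruction": hd95(cloud_pred, cloud_true),
                "dmax_pred": dmax_pred,
                "dmax_true": dmax_true,
                "dmax_err_pct": 100.0 * abs(dmax_pred - dmax_true) / dmax_true,
                "volume_pred": vol_pred,
                "volume_true": vol_true,
                "volume_err_pct": 100.0 * abs(vol_pred - vol_true) / vol_true,
            })
    return EvalReport(patient_id=series.patient_id,
                      regime=results.regime.value,
                      table=pd.DataFrame(rows))


@dataclass
class CohortSummary:
    """Macro-averaged cohort metrics (patient-first weighting)."""

    macro_means: pd.DataFrame  # index (layer), columns metrics
    scalar_stats: pd.DataFrame  # index (layer, scalar), columns [r2, mae]
    n_patients: int

    def summary(self) -> str:
        lines = [f"Cohort summary over {self.n_patients} patient(s)",
                 "Macro-means (per-patient means first):",
                 self.macro_means.to_string(float_format="%.4f"),
                 "Scalar agreement (pred vs true, all patient-follow-ups):",
                 self.scalar_stats.to_string(float_format="%.4f")]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """One row per layer: macro-mean metrics plus scalar R^2/MAE."""
        wide = self.scalar_stats.unstack("scalar")
        wide.columns = [f"{stat}_{scalar}" for stat, scalar in wide.columns]
        self.macro_means.join(wide).to_csv(path, float_format="%.6g")


def _r2(true: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((true - pred) ** 2))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def summarize_cohort(reports: list[EvalReport]) -> CohortSummary:
    """Macro-average of per-patient means plus R^2/MAE of the scalars.

    Per-patient means over follow-ups are taken first, then averaged across
    patients, so every patient contributes equally no matter how many
    follow-ups it has.
    """
    if not reports:
        raise ValueError("need at least one report")
    frames = []
    for rep in reports:
        df = rep.table.copy()
        df["patient_id"] = rep.patient_id
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)

    per_patient = (pooled.groupby(["patient_id", "layer"])[_METRICS].mean())
    macro = per_patient.groupby("layer").mean()

    stats = []
    for layer, sub in pooled.groupby("layer"):
        for scalar in _SCALARS:
            true = sub[f"{scalar}_true"].to_numpy()
            pred = sub[f"{scalar}_pred"].to_numpy()
            stats.append({"layer": layer, "scalar": scalar,
                          "r2": _r2(true, pred),
                          "mae": float(np.mean(np.abs(true - pred)))})
    scalar_stats = pd.DataFrame(stats).set_index(["layer", "scalar"])
    return CohortSummary(macro_means=macro, scalar_stats=scalar_stats,
                         n_patients=len(reports))
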