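"""Synthetic longitudinal aneurysm geometry with known node-wise growth.

The generator emulates what the pipeline consumes from clinical imaging:
co-registered fusiform tubular surfaces (outer wall and lumen) at several
acquisition times, with node-wise *linear* radial growth, a slowly drifting
centerline and Gaussian observation noise.  Because every random draw is
stored, downstream oracles can be exact rather than statistical.

The wall radius field on the generator's (z, θ) lattice is

    r(z, θ, t) = r0 + (A0 + g t) · exp(−(z − z0)² / 2w²) · (1 + e cos(θ − θ0))
                 + η_n + b_n t + ε_nt,

a Gaussian axial bulge with cosine cross-sectional asymmetry: growth
concentrates near the maximum diameter and fades toward the proximal and
distal necks, the hallmark pattern of sac remodeling.  η_n ~ N(0, σ_node²)
are node intercept deviations, b_n ~ N(0, σ_slope²) node slope deviations
and ε ~ N(0, σ_obs²) per-observation noise — exactly the random-effects
structure the growth model assumes.  The lumen is the wall field minus a
constant offset (floored at 0.3·r0), with its own noise draws.  The
centerline drifts as x_c(z, t) = δ sin(πz/L) · t / t_last.

Surfaces are swept and triangulated into watertight meshes whose rings are
deliberately offset from the lattice station levels, so slicing planes never
pass through vertex rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .cyl_param import make_theta_axis
from .exceptions import ConfigError
from .growth_lme import Response, ResponseMatrix
from .mesh_io import Layer, PatientSeries, Scan, SurfaceMesh

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_patient",
    "generate_cohort",
    "ground_truth_response",
    "simulate_response_matrix",
    "save_patient",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic patient.

    Defaults describe a surveillance-typical fusiform aneurysm: a 2 cm
    diameter healthy aorta with a sac reaching ~4.5 cm maximum diameter at
    baseline, growing ~2 mm/yr in diameter at the apex over four scans
    spanning 1540 days.
    """

    K: int = 100  #: axial stations
    N: int = 100  #: angular nodes
    times: tuple[int, ...] = (0, 510, 1025, 1540)  #: scan days since baseline
    length: float = 10.0  #: axial extent L, cm
    r0: float = 1.0  #: healthy aorta radius, cm
    A0: float = 1.25  #: baseline bulge amplitude, cm
    g: float = 2.74e-4  #: bulge growth rate, cm/day (~0.1 cm/yr radius)
    z0: float = 5.0  #: bulge center, cm
    w: float = 1.5  #: bulge axial width, cm
    e: float = 0.25  #: cross-sectional asymmetry fraction
    theta0: float = 0.0  #: asymmetry phase, radians
    delta: float = 0.15  #: centerline drift amplitude, cm
    sigma_node: float = 0.05  #: node intercept SD, cm
    sigma_slope: float = 2.5e-5  #: node slope SD, cm/day
    sigma_obs: float = 0.02  #: observation noise SD, cm
    lumen_offset: float = 0.3  #: wall-to-lumen radial offset, cm
    seed: int = 0
    mesh_axial_factor: int = 3  #: mesh rings per station interval
    mesh_angular_factor: int = 2  #: mesh vertices per lattice angle

    def validate(self) -> None:
        if self.K < 4 or self.N < 4:
            raise ConfigError(f"K={self.K}, N={self.N}: lattice must be >= 4")
        if len(self.times) < 2 or self.times[0] != 0 or \
                any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ConfigError(
                f"times must start at 0 and increase strictly: {self.times}"
            )
        if not (self.r0 > self.A0 * self.e >= 0):
            raise ConfigError(
                f"need r0 > A0*e >= 0, got r0={self.r0}, A0*e={self.A0 * self.e}"
            )
        for name in ("sigma_node", "sigma_slope", "sigma_obs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.lumen_offset <= 0 or self.lumen_offset >= self.r0:
            raise ConfigError("lumen_offset must be in (0, r0)")


@dataclass
class GroundTruth:
    """Exact generating quantities for one synthetic patient."""

    config: SynthConfig
    z_axis: np.ndarray  # (K,)
    theta_axis: np.ndarray  # (N,)
    #: per layer: exact node intercept field (K, N), cm
    alpha: dict[Layer, np.ndarray] = field(default_factory=dict)
    #: per layer: exact node slope field (K, N), cm/day
    beta: dict[Layer, np.ndarray] = field(default_factory=dict)
    #: per layer: observation noise draws (T, K, N), cm
    eps: dict[Layer, np.ndarray] = field(default_factory=dict)
    #: per-station centerline-x slope, cm/day (intercept is 0)
    cl_beta_x: np.ndarray | None = None


def _bulge_profile(z: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    return np.exp(-((z - cfg.z0) ** 2) / (2.0 * cfg.w ** 2))


def _asym_profile(theta: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    return 1.0 + cfg.e * np.cos(theta - cfg.theta0)


def _centerline_x(z: np.ndarray, t: float, cfg: SynthConfig) -> np.ndarray:
    t_last = cfg.times[-1]
    return cfg.delta * np.sin(np.pi * z / cfg.length) * (t / t_last)


def _wall_analytic(z: np.ndarray, theta: np.ndarray, t: float,
                   cfg: SynthConfig) -> np.ndarray:
    """Analytic wall radius on an outer-product (z, θ) grid."""
    fz = _bulge_profile(z, cfg)[:, None]
    at = _asym_profile(theta, cfg)[None, :]
    return cfg.r0 + (cfg.A0 + cfg.g * t) * fz * at


def _layer_analytic(z, theta, t, cfg: SynthConfig, layer: Layer) -> np.ndarray:
    r = _wall_analytic(z, theta, t, cfg)
    if layer is Layer.LUMEN:
        r = np.maximum(r - cfg.lumen_offset, 0.3 * cfg.r0)
    return r


def _interp_lattice_field(field_kn: np.ndarray, z_axis: np.ndarray,
                          theta_axis: np.ndarray, z_q: np.ndarray,
                          theta_q: np.ndarray) -> np.ndarray:
    """Nearest-node (piecewise-constant) extension of a lattice field.

    The node-effect fields are white noise on the lattice, so they carry no
    sub-lattice structure; extending each draw over its whole (z, θ) lattice
    cell makes the parameterization of the swept mesh recover the *exact*
    per-node draws, keeping downstream oracles exact rather than
    statistical.  θ is treated periodically; z is clamped at the ends.
    """
    dz = z_axis[1] - z_axis[0]
    dth = theta_axis[1] - theta_axis[0]
    ki = np.clip(np.round((np.asarray(z_q) - z_axis[0]) / dz).astype(int),
                 0, len(z_axis) - 1)
    ii = np.round((np.asarray(theta_q) - theta_axis[0]) / dth).astype(int) \
        % len(theta_axis)
    return field_kn[np.ix_(ki, ii)]


def _sweep_mesh(z_rings: np.ndarray, theta_f: np.ndarray,
                radii: np.ndarray, xc: np.ndarray, layer: Layer
                ) -> SurfaceMesh:
    """Triangulate a swept tube with flat end caps into a watertight mesh."""
    nz, nt = radii.shape
    x = xc[:, None] + radii * np.cos(theta_f)[None, :]
    y = radii * np.sin(theta_f)[None, :]
    z = np.broadcast_to(z_rings[:, None], radii.shape)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    jj, ii = np.meshgrid(np.arange(nz - 1), np.arange(nt), indexing="ij")
    v00 = jj * nt + ii
    v01 = jj * nt + (ii + 1) % nt
    v10 = (jj + 1) * nt + ii
    v11 = (jj + 1) * nt + (ii + 1) % nt
    side = np.concatenate([
        np.stack([v00, v01, v10], axis=-1).reshape(-1, 3),
        np.stack([v10, v01, v11], axis=-1).reshape(-1, 3),
    ])

    apex_lo = len(verts)
    apex_hi = len(verts) + 1
    verts = np.vstack([verts,
                       [xc[0], 0.0, z_rings[0]],
                       [xc[-1], 0.0, z_rings[-1]]])
    i_arr = np.arange(nt)
    cap_lo = np.stack([np.full(nt, apex_lo), (i_arr + 1) % nt, i_arr],
                      axis=-1)
    top0 = (nz - 1) * nt
    cap_hi = np.stack([np.full(nt, apex_hi), top0 + i_arr,
                       top0 + (i_arr + 1) % nt], axis=-1)
    faces = np.vstack([side, cap_lo, cap_hi])

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh.from_trimesh(tm, layer)


def generate_patient(cfg: SynthConfig, patient_id: str = "SYN000"
                     ) -> tuple[PatientSeries, GroundTruth]:
    """Generate one patient's longitudinal mesh series plus exact truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    z_axis = np.linspace(0.0, cfg.length, cfg.K)
    theta_axis = make_theta_axis(cfg.N)
    times = np.array(cfg.times, dtype=float)
    T = len(times)

    gt = GroundTruth(config=cfg, z_axis=z_axis, theta_axis=theta_axis)
    gt.cl_beta_x = (cfg.delta * np.sin(np.pi * z_axis / cfg.length)
                    / cfg.times[-1])

    noise = {}
    for layer in (Layer.OUTER_WALL, Layer.LUMEN):
        eta = rng.normal(0.0, cfg.sigma_node, size=(cfg.K, cfg.N))
        slope = rng.normal(0.0, cfg.sigma_slope, size=(cfg.K, cfg.N))
        eps = rng.normal(0.0, cfg.sigma_obs, size=(T, cfg.K, cfg.N))
        base = _layer_analytic(z_axis, theta_axis, 0.0, cfg, layer)
        at_last = _layer_analytic(z_axis, theta_axis, float(times[-1]), cfg,
                                  layer)
        beta_analytic = (at_last - base) / float(times[-1])
        gt.alpha[layer] = base + eta
        gt.beta[layer] = beta_analytic + slope
        gt.eps[layer] = eps
        noise[layer] = (eta, slope, eps)

    # mesh sampling: rings offset from station levels, finer in z and theta
    dz = z_axis[1] - z_axis[0]
    mz = cfg.mesh_axial_factor
    n_rings = mz * cfg.K + 1
    z_rings = z_axis[0] - dz / 2 + np.arange(n_rings) * dz / mz
    nt = cfg.mesh_angular_factor * cfg.N
    theta_f = -np.pi + 2 * np.pi * (np.arange(nt) + 0.5) / nt

    scans = []
    for j, t in enumerate(times):
        meshes = {}
        for layer in (Layer.OUTER_WALL, Layer.LUMEN):
            eta, slope, eps = noise[layer]
            lattice_dev = eta + slope * t + eps[j]
            dev_f = _interp_lattice_field(lattice_dev, z_axis, theta_axis,
                                          z_rings, theta_f)
            r_f = _layer_analytic(z_rings, theta_f, float(t), cfg, layer) + dev_f
            xc = _centerline_x(z_rings, float(t), cfg)
            meshes[layer] = _sweep_mesh(z_rings, theta_f, r_f, xc, layer)
        scans.append(Scan(time_days=int(t),
                          wall=meshes[Layer.OUTER_WALL],
                          lumen=meshes[Layer.LUMEN]))

    series = PatientSeries(patient_id=patient_id, scans=scans,
                           z_axis=z_axis, theta_axis=theta_axis)
    return series, gt


def generate_cohort(n_patients: int, cfg: SynthConfig
                    ) -> list[tuple[PatientSeries, GroundTruth]]:
    """Independent patients seeded deterministically from ``cfg.seed``."""
    out = []
    for p in range(n_patients):
        cfg_p = replace(cfg, seed=(cfg.seed + 7919 * p) % (2**31 - 1))
        out.append(generate_patient(cfg_p, patient_id=f"SYN{p:03d}"))
    return out


def ground_truth_response(gt: GroundTruth, response: Response | str,
                          layer: Layer | str) -> ResponseMatrix:
    """Exact noiseless node trajectories (for parameter-recovery checks)."""
    response = Response(response)
    layer = Layer(layer)
    times = np.array(gt.config.times, dtype=float)
    if response is Response.RADIUS:
        a = gt.alpha[layer].ravel()
        b = gt.beta[layer].ravel()
    elif response is Response.CENTERLINE_X:
        a = np.zeros(gt.config.K)
        b = gt.cl_beta_x
    else:  # CENTERLINE_Y: no drift component generated
        a = np.zeros(gt.config.K)
        b = np.zeros(gt.config.K)
    values = a[:, None] + np.outer(b, times)
    return ResponseMatrix(values=values, times=times, response=response,
                          layer=layer)


def simulate_response_matrix(
    G: int,
    times: np.ndarray,
    alpha: float,
    beta: float,
    sigma0: float,
    sigma1: float,
    sigma_eps: float,
    rng: np.random.Generator,
) -> tuple[ResponseMatrix, dict]:
    """Draw a balanced panel directly from the growth-model equations.

    Bypasses mesh generation; used to study estimator behaviour under known
    (alpha, beta, sigma0, sigma1, sigma_eps).
    """
    times = np.asarray(times, dtype=float)
    b0 = rng.normal(0.0, sigma0, size=G)
    b1 = rng.normal(0.0, sigma1, size=G)
    eps = rng.normal(0.0, sigma_eps, size=(G, len(times)))
    values = (alpha + b0)[:, None] + np.outer(beta + b1, times) + eps
    Y = ResponseMatrix(values=values, times=times, response=Response.RADIUS,
                       layer=Layer.OUTER_WALL)
    truth = {"alpha": alpha, "beta": beta, "b0": b0, "b1": b1, "eps": eps}
    return Y, truth


def save_patient(series: PatientSeries, out_dir: str | Path) -> Path:
    """Write STL meshes plus the JSON manifest the loader consumes."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for scan in series.scans:
        names = {}
        for layer, mesh in (("wall", scan.wall), ("lumen", scan.lumen)):
            fname = f"day{scan.time_days:05d}_{layer}.stl"
            mesh.trimesh.export(str(out_dir / fname))
            names[layer] = fname
        entries.append({"day": scan.time_days,
                        "wall_mesh": names["wall"],
                        "lumen_mesh": names["lumen"]})
    manifest = {"patient_id": series.patient_id, "scans": entries}
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
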