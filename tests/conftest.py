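import numpy as np
import pytest
import trimesh

from aaaforecast import (
    AneurysmGrowthModel,
    Layer,
    SurfaceMesh,
    SynthConfig,
    generate_patient,
    parameterize_series,
)


def make_cylinder_mesh(radius=1.0, height=2.0, sections=512,
                       layer=Layer.OUTER_WALL, transform=None) -> SurfaceMesh:
    tm = trimesh.creation.cylinder(radius=radius, height=height,
                                   sections=sections)
    if transform is not None:
        tm.apply_transform(transform)
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh.from_trimesh(tm, layer)


def make_tube(radius_fn, z_lo=0.0, z_hi=6.0, n_rings=120, n_theta=128,
              xc_fn=None, layer=Layer.OUTER_WALL) -> SurfaceMesh:
    """Closed watertight tube with rings r = radius_fn(z, theta) at constant z.

    ``radius_fn`` maps (z array (K,), theta array (M,)) -> (K, M) radii;
    ``xc_fn`` optionally shifts ring centers along x.
    """
    z = np.linspace(z_lo, z_hi, n_rings)
    theta = -np.pi + 2 * np.pi * np.arange(n_theta) / n_theta
    r = radius_fn(z, theta)
    xc = xc_fn(z) if xc_fn is not None else np.zeros(n_rings)
    x = xc[:, None] + r * np.cos(theta)[None, :]
    y = r * np.sin(theta)[None, :]
    zz = np.broadcast_to(z[:, None], x.shape)
    verts = np.column_stack([x.ravel(), y.ravel(), zz.ravel()])
    jj, ii = np.meshgrid(np.arange(n_rings - 1), np.arange(n_theta),
                         indexing="ij")
    v00 = jj * n_theta + ii
    v01 = jj * n_theta + (ii + 1) % n_theta
    v10 = (jj + 1) * n_theta + ii
    v11 = (jj + 1) * n_theta + (ii + 1) % n_theta
    faces = np.concatenate([
        np.stack([v00, v01, v10], axis=-1).reshape(-1, 3),
        np.stack([v10, v01, v11], axis=-1).reshape(-1, 3),
    ])
    lo_apex, hi_apex = len(verts), len(verts) + 1
    verts = np.vstack([verts, [xc[0], 0, z_lo], [xc[-1], 0, z_hi]])
    i_arr = np.arange(n_theta)
    caps = np.vstack([
        np.stack([np.full(n_theta, lo_apex), (i_arr + 1) % n_theta, i_arr],
                 axis=-1),
        np.stack([np.full(n_theta, hi_apex),
                  (n_rings - 1) * n_theta + i_arr,
                  (n_rings - 1) * n_theta + (i_arr + 1) % n_theta], axis=-1),
    ])
    tm = trimesh.Trimesh(vertices=verts, faces=np.vstack([faces, caps]),
                         process=False)
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh.from_trimesh(tm, layer)


def make_sphere_mesh(radius=2.0, subdivisions=5) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh.from_trimesh(tm, Layer.OUTER_WALL)


@pytest.fixture(scope="session")
def unit_cube_trimesh():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture
def cube_stl(tmp_path, unit_cube_trimesh):
    path = tmp_path / "cube.stl"
    unit_cube_trimesh.export(str(path))
    return path


@pytest.fixture(scope="session")
def small_config():
    # scaled-down lattice keeps the mesh pipeline fast while exercising
    # every stage; growth/noise levels are the generator defaults
    return SynthConfig(K=24, N=24, seed=11)


@pytest.fixture(scope="session")
def small_patient(small_config):
    return generate_patient(small_config, patient_id="SYNTEST")


@pytest.fixture(scope="session")
def small_param(small_patient):
    series, _ = small_patient
    return parameterize_series(series, K=24, N=24, n_harmonics=4)


@pytest.fixture(scope="session")
def small_results(small_patient, small_param):
    series, _ = small_patient
    return AneurysmGrowthModel(series, small_param).fit("all_fu")


@pytest.fixture(scope="session")
def noise_free_patient():
    # circular sections (e=0) and a static centerline (delta=0) keep the
    # parameterized responses exactly linear in time, so the model class
    # contains the truth to machine precision
    cfg = SynthConfig(K=24, N=24, sigma_node=0.0, sigma_slope=0.0,
                      sigma_obs=0.0, e=0.0, delta=0.0, seed=5)
    return generate_patient(cfg, patient_id="SYNCLEAN")


@pytest.fixture(scope="session")
def noise_free_results(noise_free_patient):
    series, _ = noise_free_patient
    param = parameterize_series(series, K=24, N=24, n_harmonics=4)
    return AneurysmGrowthModel(series, param).fit("all_fu")
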