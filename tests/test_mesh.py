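"""Meshing: marching-cubes oracles, healing, Taubin smoothing, pruning."""

import numpy as np
import pytest
import trimesh

from sheath3d.interpolate import ScalarVolume
from sheath3d.mesh import (
    SurfaceMesh,
    diagonal_fraction_um,
    enclosed_volume_um3,
    heal_mesh,
    isolate_component,
    laplacian_smooth,
    marching_cubes,
    remove_small_components,
    taubin_smooth,
)
from sheath3d.separate import Channel
from tests.conftest import sphere_volume


def test_empty_volume_gives_empty_mesh():
    vol = ScalarVolume(np.zeros((8, 8, 8), np.uint8), (1, 1, 1), Channel.CYAN)
    assert marching_cubes(vol, 30.0).is_empty


def test_sphere_volume_within_three_percent():
    r = 50.0
    mesh = marching_cubes(sphere_volume(r, spacing_um=1.0), 120.0)
    vol = enclosed_volume_um3(mesh)
    expected = 4.0 / 3.0 * np.pi * r**3
    assert abs(vol - expected) / expected < 0.03


def test_sphere_volume_error_decreases_with_spacing():
    r = 20.0
    expected = 4.0 / 3.0 * np.pi * r**3
    errs = []
    for spacing in (2.0, 1.0, 0.5):
        mesh = marching_cubes(sphere_volume(r, spacing_um=spacing), 120.0)
        errs.append(abs(enclosed_volume_um3(mesh) - expected) / expected)
    assert errs[0] > errs[1] > errs[2]


def test_iso_crossing_linearly_interpolated():
    """0→255 step between adjacent voxels: crossing at 120/255 of the gap."""
    vox = np.zeros((2, 2, 2), np.uint8)
    vox[:, :, 1] = 255
    vol = ScalarVolume(vox, (1.0, 1.0, 1.0), Channel.BLACK)
    mesh = marching_cubes(vol, 120.0)
    xs = np.unique(np.round(mesh.vertices[:, 0], 6))
    assert xs == pytest.approx([120.0 / 255.0])


def test_heal_preserves_clean_sphere_volume(sphere_mesh):
    healed = heal_mesh(sphere_mesh, depth=9)
    tm = healed.to_trimesh()
    assert tm.is_watertight
    v0 = enclosed_volume_um3(sphere_mesh)
    assert abs(enclosed_volume_um3(healed) - v0) / v0 < 0.02


def test_heal_closes_holes_and_is_watertight(sphere_mesh, rng):
    faces = sphere_mesh.faces
    keep = np.ones(len(faces), bool)
    keep[rng.choice(len(faces), size=len(faces) // 20, replace=False)] = False
    holey = SurfaceMesh(sphere_mesh.vertices.copy(), faces[keep])
    assert not holey.to_trimesh().is_watertight
    healed = heal_mesh(holey, depth=9)
    tm = healed.to_trimesh()
    assert tm.is_watertight
    # every edge of the healed mesh borders exactly 2 faces
    edges = tm.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    assert (counts == 2).all()
    v0 = enclosed_volume_um3(sphere_mesh)
    assert abs(enclosed_volume_um3(healed) - v0) / v0 < 0.05


def noisy_sphere(rng, radius=100.0, noise=0.02):
    tm = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    radial = tm.vertices / np.linalg.norm(tm.vertices, axis=1, keepdims=True)
    verts = tm.vertices + radial * rng.normal(0, noise * radius, (len(tm.vertices), 1))
    return SurfaceMesh(verts, tm.faces.copy())


def test_taubin_preserves_volume_better_than_laplacian(rng):
    mesh = noisy_sphere(rng)
    v0 = enclosed_volume_um3(mesh)
    v_taubin = enclosed_volume_um3(taubin_smooth(mesh, 10, 0.5, -0.53))
    v_lap = enclosed_volume_um3(laplacian_smooth(mesh, 10, 0.5))
    assert abs(v_taubin - v0) < abs(v_lap - v0) / 3.0


def test_taubin_zero_iterations_is_identity(sphere_mesh):
    out = taubin_smooth(sphere_mesh, 0)
    assert np.array_equal(out.vertices, sphere_mesh.vertices)
    assert np.array_equal(out.faces, sphere_mesh.faces)


def test_taubin_reduces_roughness_keeps_topology(rng):
    mesh = noisy_sphere(rng)

    def roughness(m):
        e = m.edges()
        from scipy.sparse import coo_matrix

        n = len(m.vertices)
        a = coo_matrix(
            (np.ones(2 * len(e)),
             (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        ).tocsr()
        deg = np.asarray(a.sum(axis=1)).ravel()
        mean_nb = a @ m.vertices / deg[:, None]
        return float(np.linalg.norm(m.vertices - mean_nb, axis=1).mean())

    out = taubin_smooth(mesh, 10, 0.5, -0.53)
    assert len(out.vertices) == len(mesh.vertices)
    assert np.array_equal(out.faces, mesh.faces)
    assert roughness(out) < roughness(mesh)


def test_taubin_requires_shrink_inflate_pair(sphere_mesh):
    with pytest.raises(ValueError):
        taubin_smooth(sphere_mesh, 10, -0.5, -0.53)
    with pytest.raises(ValueError):
        taubin_smooth(sphere_mesh, 10, 0.5, 0.53)


@pytest.mark.parametrize(
    "extents, fraction, expected",
    [
        ((1000.0, 1000.0, 168.0), 0.05, 71.0),  # cyan threshold, printed 71 µm
        ((1000.0, 1000.0, 168.0), 0.02, 28.0),  # black threshold, printed 28 µm
        ((1000.0, 1000.0, 1000.0), 0.05, 86.6),
    ],
)
def test_diagonal_fraction_thresholds(extents, fraction, expected):
    assert diagonal_fraction_um(extents, fraction) == pytest.approx(expected, abs=0.5)


def test_iso_config_per_roi_overrides():
    from sheath3d.mesh import IsoConfig

    cfg = IsoConfig(overrides={"R3": {"iso_cyan": 35.0}})
    assert cfg.iso_for(Channel.CYAN) == 30.0
    assert cfg.iso_for(Channel.CYAN, roi="R3") == 35.0
    assert cfg.iso_for(Channel.BLACK, roi="R3") == 120.0
    with pytest.raises(ValueError):
        IsoConfig(iso_black=0.0)


def two_spheres(d1=100.0, d2=30.0):
    a = trimesh.creation.icosphere(2, radius=d1 / (2 * np.sqrt(3)))
    b = trimesh.creation.icosphere(2, radius=d2 / (2 * np.sqrt(3)))
    b = b.apply_translation([200.0, 0, 0])
    m = trimesh.util.concatenate([a, b])
    return SurfaceMesh(m.vertices.copy(), m.faces.copy())


def test_prune_removes_only_small_components():
    mesh = two_spheres()
    out = remove_small_components(mesh, 71.0)
    n_comp, _ = out.vertex_components()
    assert n_comp == 1
    assert out.vertices[:, 0].max() < 100.0  # the far small sphere is gone
    assert np.array_equal(remove_small_components(mesh, 0.0).vertices, mesh.vertices)


def test_prune_monotone_in_threshold(rng):
    spheres = []
    for i in range(6):
        r = rng.uniform(5, 60)
        s = trimesh.creation.icosphere(1, radius=r).apply_translation(
            rng.uniform(-500, 500, 3)
        )
        spheres.append(s)
    m = trimesh.util.concatenate(spheres)
    mesh = SurfaceMesh(m.vertices.copy(), m.faces.copy())
    counts = []
    for thr in (0.0, 30.0, 71.0, 120.0):
        kept = remove_small_components(mesh, thr)
        counts.append(kept.vertex_components()[0] if len(kept.vertices) else 0)
    assert counts == sorted(counts, reverse=True)


def test_prune_matches_exhaustive_component_scan(rng):
    spheres, diags = [], []
    for i in range(5):
        r = rng.uniform(5, 50)
        s = trimesh.creation.icosphere(1, radius=r).apply_translation(
            [300.0 * i, 0, 0]
        )
        spheres.append(s)
        lo, hi = s.bounds
        diags.append(float(np.linalg.norm(hi - lo)))
    m = trimesh.util.concatenate(spheres)
    mesh = SurfaceMesh(m.vertices.copy(), m.faces.copy())
    thr = 60.0
    out = remove_small_components(mesh, thr)
    assert out.vertex_components()[0] == sum(d >= thr for d in diags)


def test_isolate_component_returns_nearest(rng):
    mesh = two_spheres()
    near_b = isolate_component(mesh, (200.0, 0.0, 0.0))
    assert near_b.vertex_components()[0] == 1
    assert near_b.vertices[:, 0].min() > 100.0
    only = isolate_component(near_b, (200.0, 0.0, 0.0))
    assert len(only.vertices) == len(near_b.vertices)
    with pytest.raises(ValueError):
        isolate_component(SurfaceMesh(np.empty((0, 3)), np.empty((0, 3))), (0, 0, 0))
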