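"""Geodesic painting, sheath classification and ROI morphometry."""

import numpy as np
import pytest
import trimesh

from sheath3d.annotate import (
    AnnotationSeed,
    ROIGeometry,
    SheathRecord,
    classify_sheaths,
    geodesic_paint,
    roi_volume_mm3,
    summarise,
    summarise_rois,
)
from sheath3d.mesh import LABEL_BLUE, LABEL_GREEN, LABEL_RED, SurfaceMesh
from sheath3d.separate import Channel


def sphere(radius=100.0, subdivisions=3, translate=(0, 0, 0), channel=Channel.BLACK):
    tm = trimesh.creation.icosphere(subdivisions, radius=radius)
    tm = tm.apply_translation(translate)
    return SurfaceMesh(tm.vertices.copy(), tm.faces.copy(), channel=channel)


def tube(p0, p1, radius=5.0, channel=Channel.CYAN, max_edge=4.0):
    tm = trimesh.creation.cylinder(
        radius=radius, segment=np.array([p0, p1]), sections=24
    )
    v, f = trimesh.remesh.subdivide_to_size(tm.vertices, tm.faces, max_edge=max_edge)
    return SurfaceMesh(v, f, channel=channel)


def test_tiny_radius_labels_only_seed_vertex(sphere_mesh):
    mesh = SurfaceMesh(sphere_mesh.vertices.copy(), sphere_mesh.faces.copy())
    seed_v = mesh.vertices[0]
    geodesic_paint(mesh, AnnotationSeed(tuple(seed_v), 1e-9))
    assert mesh.vertex_labels.sum() == LABEL_RED
    assert mesh.vertex_labels[0] == LABEL_RED


def test_geodesic_paint_matches_arc_length_on_sphere():
    """On a sphere, geodesic distance from the pole is R * polar angle."""
    mesh = sphere(radius=100.0, subdivisions=4)
    pole = (0.0, 0.0, 100.0)
    geodesic_paint(mesh, AnnotationSeed(pole, 50.0))
    arc = 100.0 * np.arccos(np.clip(mesh.vertices[:, 2] / 100.0, -1, 1))
    edges = mesh.edges()
    mean_edge = float(
        np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1).mean()
    )
    painted = mesh.vertex_labels == LABEL_RED
    # painted set sits between the inner and outer arc bands, one mean
    # edge length of slack for graph-path vs great-circle discrepancy
    assert painted[arc <= 50.0 - 2 * mean_edge].all()
    assert not painted[arc >= 50.0 + 2 * mean_edge].any()
    # graph geodesic >= true geodesic: painted set is a subset of the
    # Euclidean ball of the same radius
    eu = np.linalg.norm(mesh.vertices - np.array(pole), axis=1)
    assert (eu[painted] <= 50.0 + 1e-6).all()


def test_paint_does_not_leak_to_disconnected_tube():
    """Two parallel tubes 3 µm apart: red stays on the seeded tube."""
    a = tube((0, 0, 0), (100, 0, 0), radius=5.0)
    b_tm = trimesh.creation.cylinder(
        radius=5.0, segment=np.array([(0, 13.0, 0), (100, 13.0, 0)]), sections=24
    )
    n_a = len(a.vertices)
    merged = SurfaceMesh(
        np.vstack([a.vertices, b_tm.vertices]),
        np.vstack([a.faces, b_tm.faces + n_a]),
    )
    geodesic_paint(merged, AnnotationSeed((50.0, 0.0, -5.0), 50.0))
    assert (merged.vertex_labels[:n_a] == LABEL_RED).any()
    assert not (merged.vertex_labels[n_a:] == LABEL_RED).any()


def test_seed_far_from_mesh_rejected(sphere_mesh):
    mesh = SurfaceMesh(sphere_mesh.vertices.copy(), sphere_mesh.faces.copy())
    with pytest.raises(ValueError, match="snap"):
        geodesic_paint(mesh, AnnotationSeed((500.0, 0.0, 0.0), 10.0))


def test_classification_contact_rule():
    """Sheath tubes near/far from red arterial surface split green/blue."""
    artery = tube((0, 0, 0), (80, 0, 0), radius=8.0, channel=Channel.BLACK)
    geodesic_paint(artery, AnnotationSeed((40.0, 0.0, -8.0), 200.0))
    near = trimesh.creation.cylinder(
        radius=5.0, segment=np.array([(80.0, 0.0, 0.0), (130.0, 0.0, 0.0)])
    )
    far = trimesh.creation.cylinder(
        radius=5.0, segment=np.array([(0.0, 100.0, 0.0), (50.0, 100.0, 0.0)])
    )
    cyan = SurfaceMesh(
        np.vstack([near.vertices, far.vertices]),
        np.vstack([near.faces, far.faces + len(near.vertices)]),
        channel=Channel.CYAN,
    )
    records = classify_sheaths(cyan, artery, contact_epsilon_um=5.0)
    classes = sorted(r.sheath_class for r in records)
    assert classes == ["post_arteriolar", "undefined"]
    # vertex labels painted green/blue accordingly
    assert (cyan.vertex_labels == LABEL_GREEN).any()
    assert (cyan.vertex_labels == LABEL_BLUE).any()


def test_no_red_means_all_undefined():
    artery = tube((0, 0, 0), (80, 0, 0), radius=8.0, channel=Channel.BLACK)
    cyan = tube((90, 0, 0), (130, 0, 0), radius=5.0)
    records = classify_sheaths(cyan, artery, contact_epsilon_um=5.0)
    assert all(r.sheath_class == "undefined" for r in records)
    assert all(np.isinf(r.min_dist_to_red_um) for r in records)


def test_epsilon_monotonicity():
    artery = tube((0, 0, 0), (80, 0, 0), radius=8.0, channel=Channel.BLACK)
    geodesic_paint(artery, AnnotationSeed((40.0, 0.0, -8.0), 200.0))
    cyan = tube((95.0, 0.0, 0.0), (140.0, 0.0, 0.0), radius=5.0)
    green = []
    for eps in (1.0, 5.0, 10.0, 50.0):
        c = SurfaceMesh(cyan.vertices.copy(), cyan.faces.copy(), channel=Channel.CYAN)
        recs = classify_sheaths(c, artery, contact_epsilon_um=eps)
        green.append(sum(r.sheath_class == "post_arteriolar" for r in recs))
    assert green == sorted(green)


def test_phantom_classification_recovers_truth():
    """With red painted on all arterioles, exactly the truly attached
    sheaths come out green (contact epsilon 5 µm)."""
    from sheath3d.phantom import PhantomSpec
    from sheath3d.pipeline import PipelineConfig, run_pipeline
    from sheath3d.study import phantom_iso_config

    spec = PhantomSpec(
        width_px=192, height_px=192, n_sections=12, n_sheaths=3,
        n_arterioles=1, frac_post_arteriolar=0.34,
        sheath_length_range_um=(22, 40), misalignment_px=0.0, noise_sd=0.0,
        dropout_rate=0.0, include_fdc_blobs=False, rng_seed=1,
    )
    cfg = PipelineConfig(
        phantom=spec, skip_registration=True, heal=False,
        iso=phantom_iso_config(),
        cyan_operations=(("closing", (4, 4, 1)), ("blur", 1.0)),
    )
    result = run_pipeline(cfg)
    truth_green = sum(
        t.sheath_class == "post_arteriolar" for t in result.truth.sheath_components
    )
    got_green = sum(r.sheath_class == "post_arteriolar" for r in result.records)
    assert got_green == truth_green


@pytest.mark.parametrize(
    "geom, expected",
    [
        (ROIGeometry(2000, 2000, 0.5, 24, 7.0), 0.168),  # prints as 0.17
        (ROIGeometry(1, 1, 1.0, 1, 1.0), 1e-9),
    ],
)
def test_roi_volume(geom, expected):
    assert roi_volume_mm3(geom) == pytest.approx(expected, rel=1e-9)


def test_eleven_rois_total_volume():
    v = roi_volume_mm3(ROIGeometry(2000, 2000, 0.5, 24, 7.0))
    assert 11 * v == pytest.approx(1.848)  # prints as 1.85 mm^3


def rec(cls, vol=1e-5, boundary=False):
    return SheathRecord(0, vol, (10, 10, 10), cls, boundary, 1.0)


def test_summarise_fraction_and_empty():
    geom = ROIGeometry(2000, 2000, 0.5, 24, 7.0)
    records = [rec("post_arteriolar")] * 9 + [rec("undefined")] * 11
    s = summarise(records, geom)
    assert s["n_sheaths"] == 20
    assert s["green_fraction_pct"] == pytest.approx(45.0)
    empty = summarise([], geom)
    assert empty["n_sheaths"] == 0 and empty["green_fraction_pct"] is None


def test_summarise_rois_pooled_partition():
    geom = ROIGeometry(2000, 2000, 0.5, 24, 7.0)
    t1 = summarise([rec("post_arteriolar"), rec("undefined")], geom, "R1")
    t2 = summarise([rec("post_arteriolar")] * 3, geom, "R2")
    table = summarise_rois([t1, t2])
    pooled = table.iloc[-1]
    assert pooled["n_sheaths"] == 5
    assert pooled["n_post_arteriolar"] + pooled["n_undefined"] == 5
    assert pooled["green_fraction_pct"] == pytest.approx(80.0)
    assert pooled["roi_volume_mm3"] == pytest.approx(2 * 0.168)
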