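"""Virtual-specimen generator: determinism, truth consistency, rendering."""

import numpy as np
import pytest
from dataclasses import replace

from sheath3d.phantom import (
    PALETTE,
    PhantomSpec,
    build_phantom,
    paint_tube,
    render_sections,
)


def small_spec(**kw):
    base = dict(
        width_px=128, height_px=128, n_sections=8, n_sheaths=6, n_arterioles=2,
        frac_post_arteriolar=0.5, sheath_length_range_um=(20, 40),
        misalignment_px=0.0, noise_sd=0.0, dropout_rate=0.0,
        include_fdc_blobs=False, rng_seed=7,
    )
    base.update(kw)
    return PhantomSpec(**base)


def test_post_arteriolar_count_matches_rounded_fraction():
    spec = small_spec(n_sheaths=20, frac_post_arteriolar=0.45,
                      width_px=192, height_px=192)
    truth = build_phantom(spec)
    n_post = sum(s.sheath_class == "post_arteriolar" for s in truth.sheath_components)
    assert n_post == round(20 * 0.45) == 9
    assert len(truth.sheath_components) == 20


def test_empty_sheath_case():
    truth = build_phantom(small_spec(n_sheaths=0, n_arterioles=0))
    assert truth.sheath_components == []
    assert not (truth.label_volume == 2).any()


def test_determinism_bit_identical():
    spec = small_spec(misalignment_px=4.0, noise_sd=3.0, dropout_rate=0.2)
    t1, t2 = build_phantom(spec), build_phantom(spec)
    assert np.array_equal(t1.label_volume, t2.label_volume)
    s1, s2 = render_sections(t1, spec), render_sections(t2, spec)
    for a, b in zip(s1, s2):
        assert np.array_equal(a.pixels, b.pixels)
    for ta, tb in zip(t1.applied_transforms, t2.applied_transforms):
        assert ta == tb


def test_rejects_oversized_vessels():
    with pytest.raises(ValueError, match="radius"):
        build_phantom(small_spec(arteriole_radius_um=50.0))


def test_post_arteriolar_sheaths_start_at_arteriole_ends():
    spec = small_spec(width_px=192, height_px=192)
    truth = build_phantom(spec)
    nodes = truth.vessel_graph.nodes
    arteriole_ends = {
        e.b for e in truth.vessel_graph.edges if e.vessel_type == "arteriole"
    }
    for s in truth.sheath_components:
        if s.sheath_class != "post_arteriolar":
            continue
        assert s.start_node in arteriole_ends
        assert np.allclose(s.centerline[0], nodes[s.start_node], atol=1e-6)


def test_section_count_and_noiseless_identity():
    spec = small_spec(background_texture_amp=0.0)
    truth = build_phantom(spec)
    sections = render_sections(truth, spec)
    assert len(sections) == spec.n_sections
    # noiseless, unmisaligned render equals the palette slab projection
    lut = np.zeros((256, 3))
    for k, rgb in PALETTE.items():
        lut[k] = rgb
    nsub = spec.n_subplanes
    slab = truth.label_volume[:nsub]
    expected = np.clip(np.rint(lut[slab].mean(axis=0)), 0, 255).astype(np.uint8)
    assert np.array_equal(sections[0].pixels, expected)


def test_straight_cylinder_renders_constant_disc():
    """A z-axis cylinder of radius 10 µm shows a 20 px disc per section."""
    spec = small_spec(n_sheaths=0, n_arterioles=0, background_texture_amp=0.0)
    truth = build_phantom(spec)
    centre_um = (32.0, 32.0, 0.0)
    top_um = (32.0, 32.0, 56.0)
    paint_tube(truth.label_volume, spec.label_spacing_um, centre_um, top_um,
               -1.0, 10.0, 1)
    sections = render_sections(truth, spec)
    for sec in sections:
        brown = sec.pixels[..., 2] < 200  # brown has low blue, bg high
        ys, xs = np.nonzero(brown)
        assert len(ys) > 0
        cy, cx = ys.mean(), xs.mean()
        assert abs(cy - 64.0) < 1.0 and abs(cx - 64.0) < 1.0
        radius_px = np.sqrt(len(ys) / np.pi)
        assert abs(radius_px - 20.0) <= 1.0


def test_dropout_monotone_in_rate():
    spec = small_spec(n_sheaths=8, width_px=192, height_px=192)
    areas = []
    for rate in (0.0, 0.2, 0.5, 0.9):
        sp = replace(spec, dropout_rate=rate)
        truth = build_phantom(sp)
        secs = render_sections(truth, sp)
        # total stained (blue) area across sections
        area = sum(int((s.pixels[..., 0] < 150).sum()) for s in secs)
        areas.append(area)
    assert areas == sorted(areas, reverse=True)
    assert areas[-1] < areas[0]  # heavy dropout visibly erases stain


def test_isolated_cuff_volume_matches_analytic_shell():
    """An undisturbed annular cuff rasterises to the analytic tube-shell
    volume pi*(r_out^2 - r_in^2)*L within a one-voxel surface shell."""
    spacing = (0.5, 0.5, 1.0)
    label = np.zeros((60, 160, 160), np.uint8)
    p0, p1 = (15.0, 40.0, 10.0), (65.0, 45.0, 50.0)
    r_in, r_out = 3.5, 9.5
    n = paint_tube(label, spacing, p0, p1, r_in, r_out, 2, flat_caps=True)
    length = float(np.linalg.norm(np.subtract(p1, p0)))
    analytic = np.pi * (r_out**2 - r_in**2) * length
    voxel = n * spacing[0] * spacing[1] * spacing[2]
    shell_area = 2 * np.pi * (r_in + r_out) * length + 2 * np.pi * (
        r_out**2 - r_in**2
    )
    assert abs(voxel - analytic) <= shell_area * max(spacing)


def test_truth_volume_equals_painted_voxels(small_phantom_truth):
    """Each sheath's recorded volume is exactly its painted voxel volume."""
    spec, truth = small_phantom_truth
    sx, sy, sz = spec.label_spacing_um
    voxel_vol = sx * sy * sz * 1e-9
    for s in truth.sheath_components:
        n_vox = int((truth.sheath_id_volume == s.id).sum())
        assert n_vox * voxel_vol == pytest.approx(s.true_volume_mm3, rel=1e-9)


def test_label_volume_grid_matches_spec():
    spec = small_spec()
    truth = build_phantom(spec)
    nz, ny, nx = truth.label_volume.shape
    assert (ny, nx) == (spec.height_px, spec.width_px)
    assert nz == spec.n_sections * spec.n_subplanes
    assert truth.sheath_id_volume.shape == truth.label_volume.shape
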