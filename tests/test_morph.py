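"""3D grayscale morphology: brute-force oracles, extensivity, profiles."""

import numpy as np
import pytest

from sheath3d.interpolate import ScalarVolume
from sheath3d.morph import (
    BLACK_PROFILE,
    CYAN_PROFILE,
    KernelSpec,
    gaussian_blur,
    gray_closing,
    gray_dilation,
    gray_erosion,
    process_channel,
)
from sheath3d.separate import Channel


def vol_of(arr, channel=Channel.CYAN):
    return ScalarVolume(np.asarray(arr, np.uint8), (1.0, 1.0, 1.0), channel)


def brute_dilation(vox: np.ndarray, radii_xyz) -> np.ndarray:
    """Direct max-over-window reference, O(n * kernel) on tiny grids."""
    rx, ry, rz = radii_xyz
    out = np.zeros_like(vox)
    nz, ny, nx = vox.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                block = vox[
                    max(0, k - rz) : k + rz + 1,
                    max(0, j - ry) : j + ry + 1,
                    max(0, i - rx) : i + rx + 1,
                ]
                out[k, j, i] = block.max()
    return out


def test_dilation_matches_brute_force_oracle(rng):
    vox = rng.integers(0, 256, size=(10, 12, 11), dtype=np.uint8)
    for radii in [(1, 1, 1), (2, 1, 0), (3, 2, 1)]:
        got = gray_dilation(vol_of(vox), KernelSpec(radii)).voxels
        assert np.array_equal(got, brute_dilation(vox, radii))


def test_closing_equals_dilation_then_erosion(rng):
    vox = rng.integers(0, 256, size=(9, 9, 9), dtype=np.uint8)
    k = KernelSpec((2, 2, 1))
    direct = gray_closing(vol_of(vox), k).voxels
    composed = gray_erosion(gray_dilation(vol_of(vox), k), k).voxels
    assert np.array_equal(direct, composed)


def test_closing_bridges_a_one_voxel_tube_gap():
    vox = np.zeros((7, 7, 21), np.uint8)
    vox[3, 3, :] = 255
    vox[3, 3, 10] = 0  # interrupted stain
    closed = gray_closing(vol_of(vox), KernelSpec((2, 2, 1))).voxels
    assert closed[3, 3, 10] == 255


def test_single_voxel_dilates_to_full_box():
    vox = np.zeros((5, 5, 5), np.uint8)
    vox[2, 2, 2] = 200
    out = gray_dilation(vol_of(vox), KernelSpec((1, 1, 1))).voxels
    assert (out[1:4, 1:4, 1:4] == 200).all()
    assert out.sum() == 200 * 27


def test_extensivity_and_closing_idempotence(rng):
    vox = rng.integers(0, 256, size=(12, 12, 12), dtype=np.uint8)
    k = KernelSpec((2, 2, 2))
    v = vol_of(vox)
    for op in (gray_dilation, gray_closing):
        assert (op(v, k).voxels >= vox).all()
    once = gray_closing(v, k)
    twice = gray_closing(once, k)
    assert np.array_equal(once.voxels, twice.voxels)


def test_constant_volume_unchanged_by_closing():
    vox = np.full((8, 8, 8), 77, np.uint8)
    assert np.array_equal(gray_closing(vol_of(vox), KernelSpec((2, 2, 1))).voxels, vox)


def test_gaussian_blur_identity_and_mass_preservation(rng):
    from scipy.ndimage import gaussian_filter

    raw = rng.integers(0, 256, size=(16, 16, 16)).astype(float)
    vox = np.clip(gaussian_filter(raw, 2.0), 0, 255).astype(np.uint8)
    v = vol_of(vox)
    assert np.array_equal(gaussian_blur(v, 0.0).voxels, vox)
    blurred = gaussian_blur(v, 1.0).voxels
    interior = (slice(4, 12),) * 3
    assert abs(float(blurred[interior].mean()) - float(vox[interior].mean())) < 0.5
    with pytest.raises(ValueError):
        gaussian_blur(v, -1.0)


def test_point_source_blur_matches_gaussian_kernel():
    vox = np.zeros((15, 15, 15), np.uint8)
    vox[7, 7, 7] = 255
    out = gaussian_blur(vol_of(vox), 1.0).voxels.astype(float)
    ax = np.arange(15) - 7.0
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    g = np.exp(-(x**2 + y**2 + z**2) / 2.0)
    g = 255.0 * g / g.sum()
    sig = g > 2.0  # compare where rounding noise is negligible
    ratio = out[sig] / g[sig]
    assert np.abs(ratio - 1.0).max() < 0.01 + 0.5 / g[sig].min()


def test_kernel_larger_than_volume_rejected():
    with pytest.raises(ValueError):
        gray_closing(vol_of(np.zeros((3, 3, 3))), KernelSpec((5, 5, 5)))


def test_profile_channel_mismatch_rejected():
    v = vol_of(np.zeros((40, 40, 12)), Channel.BLACK)
    with pytest.raises(ValueError):
        process_channel(v, "cyan_default")


def test_anti_fragmentation_monotone_in_kernel(rng):
    """Dropout-riddled tube: fragment count non-increasing in kernel size."""
    from scipy import ndimage as ndi

    vox = np.zeros((12, 40, 40), np.uint8)
    vox[4:8, 18:22, :] = 255
    for i in rng.choice(40, size=10, replace=False):
        vox[:, :, i] = 0  # stain interruptions
    counts = []
    for radii in [(2, 2, 1), (7, 7, 2), (14, 14, 4)]:
        closed = gray_closing(vol_of(vox), KernelSpec(radii)).voxels
        counts.append(ndi.label(closed >= 128)[1])
    assert counts[0] >= counts[1] >= counts[2]
    assert counts[2] <= 1 + 0  # fully restored by the largest kernel


def test_ellipsoid_footprint_inside_box():
    from sheath3d.morph import KernelShape

    ell = KernelSpec((3, 2, 1), KernelShape.ELLIPSOID)
    fp = ell.footprint()
    assert fp.shape == (3, 5, 7)  # (2rz+1, 2ry+1, 2rx+1)
    assert fp[1, 2, 3]  # centre
    assert not fp[0, 0, 0]  # corners trimmed relative to the box kernel
    assert fp.sum() < np.prod(fp.shape)
    # dilation with the ellipsoid never exceeds the box dilation
    vox = np.zeros((9, 9, 9), np.uint8)
    vox[4, 4, 4] = 200
    box = gray_dilation(vol_of(vox), KernelSpec((3, 2, 1))).voxels
    ello = gray_dilation(vol_of(vox), ell).voxels
    assert (ello <= box).all() and ello[4, 4, 4] == 200


def test_default_profiles_as_printed():
    assert CYAN_PROFILE[1] == ("dilation", (11, 11, 3))
    assert CYAN_PROFILE[2] == ("closing", (14, 14, 4))
    assert BLACK_PROFILE[0] == ("closing", (7, 7, 2))
    assert CYAN_PROFILE[-1] == BLACK_PROFILE[-1] == ("blur", 1.0)
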