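import numpy as np
import pytest

from sheath3d.interpolate import ScalarVolume
from sheath3d.register import SectionImage
from sheath3d.separate import Channel, ChannelImage


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_section(rng):
    """RGB section with enough blob texture to register against."""
    img = np.full((200, 200, 3), 255, np.uint8)
    for _ in range(40):
        y, x = rng.integers(20, 180, 2)
        img[y - 5 : y + 5, x - 5 : x + 5] = rng.integers(0, 200, 3)
    return SectionImage(img, index=0)


def make_channel(pixels: np.ndarray, channel=Channel.CYAN, **kw) -> ChannelImage:
    return ChannelImage(np.asarray(pixels, dtype=np.uint8), channel, **kw)


def sphere_volume(
    radius_um: float,
    spacing_um: float = 1.0,
    margin_um: float = 5.0,
    value: int = 255,
) -> ScalarVolume:
    """Binary solid sphere centred in an isotropic grid."""
    half = radius_um + margin_um
    n = int(2 * half / spacing_um) + 1
    ax = (np.arange(n) - (n - 1) / 2) * spacing_um
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    vox = np.where(x**2 + y**2 + z**2 <= radius_um**2, value, 0).astype(np.uint8)
    return ScalarVolume(vox, (spacing_um,) * 3, Channel.BLACK)


@pytest.fixture(scope="session")
def sphere_mesh():
    """Watertight icosphere of radius 100 µm (trimesh primitive)."""
    import trimesh

    from sheath3d.mesh import SurfaceMesh

    tm = trimesh.creation.icosphere(subdivisions=4, radius=100.0)
    return SurfaceMesh(tm.vertices.copy(), tm.faces.copy())


@pytest.fixture(scope="session")
def small_phantom_truth():
    """A small but non-trivial phantom, shared across tests."""
    from sheath3d.phantom import PhantomSpec, build_phantom

    spec = PhantomSpec(
        width_px=160,
        height_px=160,
        n_sections=10,
        n_sheaths=4,
        n_arterioles=2,
        frac_post_arteriolar=0.5,
        sheath_length_range_um=(20, 40),
        misalignment_px=0.0,
        noise_sd=0.0,
        dropout_rate=0.0,
        include_fdc_blobs=False,
        rng_seed=42,
    )
    return spec, build_phantom(spec)
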