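"""Dual-chromogen channel separation via naive CMYK.

Brightfield sections double-stained with DAB (brown: SMA + CD34) and Fast
Blue (violet-blue: CD271) are split into two single-channel "stain
intensity" images by converting RGB to the CMYK colour space and keeping

* channel **C** (cyan) for the blue chromogen, and
* channel **K** (black) for the brown chromogen.

The conversion is the device-independent textbook transform (no ICC
profile): with R, G, B scaled to [0, 1],

    K' = 1 - max(R, G, B)
    C' = (1 - R - K') / (1 - K')   if K' < 1 else 0

both rescaled to 0-255.  Higher values mean more stain, so downstream
iso-surface extraction can threshold the channels directly.  Colour
deconvolution with measured absorbance vectors is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .register import RegisteredStack, SectionImage

__all__ = ["Channel", "ChannelImage", "rgb_to_cmyk_channels", "split_stack"]


class Channel(str, Enum):
    CYAN = "cyan"
    BLACK = "black"


@dataclass(frozen=True)
class ChannelImage:
    """Single-channel 8-bit stain-intensity raster.

    ``pixels`` is (H, W) uint8; ``channel`` tags the chromogen of origin;
    physical calibration is inherited from the source section.
    """

    pixels: np.ndarray
    channel: Channel
    index: int = 0
    pixel_size_um: float = 0.5
    thickness_um: float = 7.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("ChannelImage expects a 2D single-channel raster")
        if px.dtype != np.uint8:
            raise ValueError("ChannelImage pixels must be uint8 (0-255)")


def cmyk_ck(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return float (C, K) planes in [0, 255] for an (..., 3) RGB array."""
    rgb01 = np.asarray(rgb, dtype=np.float64) / 255.0
    k = 1.0 - rgb01.max(axis=-1)
    denom = 1.0 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (1.0 - rgb01[..., 0] - k) / denom
    c = np.where(denom > 0, c, 0.0)  # K'=1 (pure black) -> C'=0 by convention
    return 255.0 * np.clip(c, 0.0, 1.0), 255.0 * np.clip(k, 0.0, 1.0)


def rgb_to_cmyk_channels(section: SectionImage) -> tuple[ChannelImage, ChannelImage]:
    """Split one RGB section into (cyan, black) stain-intensity images."""
    rgb = np.asarray(section.pixels)
    if rgb.ndim != 3 or rgb.shape[-1] != 3 or rgb.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB input of shape (H, W, 3)")
    c, k = cmyk_ck(rgb)
    meta = dict(
        index=section.index,
        pixel_size_um=section.pixel_size_um,
        thickness_um=section.thickness_um,
    )
    cyan = ChannelImage(np.rint(c).astype(np.uint8), Channel.CYAN, **meta)
    black = ChannelImage(np.rint(k).astype(np.uint8), Channel.BLACK, **meta)
    return cyan, black


def split_stack(stack: RegisteredStack) -> tuple[list[ChannelImage], list[ChannelImage]]:
    """Order-preserving per-section channel separation of a registered stack."""
    cyans: list[ChannelImage] = []
    blacks: list[ChannelImage] = []
    for section in stack.sections:
        c, k = rgb_to_cmyk_channels(section)
        cyans.append(c)
        blacks.append(k)
    return cyans, blacks
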