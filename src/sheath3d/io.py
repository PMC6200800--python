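"""File formats: numbered TIFF stacks, JSON sidecars, labelled PLY meshes."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from .interpolate import ScalarVolume
from .mesh import LABEL_COLOURS, SurfaceMesh
from .phantom import GroundTruth
from .register import RigidTransform, SectionImage
from .separate import Channel, ChannelImage

__all__ = [
    "write_section_stack",
    "read_section_stack",
    "write_channel_stack",
    "write_volume",
    "read_volume",
    "write_mesh_ply",
    "write_truth_json",
]


def write_section_stack(sections: list[SectionImage], out_dir: str | Path) -> list[Path]:
    """Write numbered 8-bit RGB TIFFs (`section_000.tif`, ...) + sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sections:
        p = out / f"section_{s.index:03d}.tif"
        tifffile.imwrite(p, s.pixels)
        paths.append(p)
    meta = {
        "pixel_size_um": sections[0].pixel_size_um,
        "thickness_um": sections[0].thickness_um,
        "n_sections": len(sections),
    }
    (out / "stack.json").write_text(json.dumps(meta, indent=2))
    return paths


def read_section_stack(in_dir: str | Path) -> list[SectionImage]:
    ind = Path(in_dir)
    meta = json.loads((ind / "stack.json").read_text())
    sections = []
    for i, p in enumerate(sorted(ind.glob("section_*.tif"))):
        sections.append(
            SectionImage(
                pixels=tifffile.imread(p),
                index=i,
                pixel_size_um=meta["pixel_size_um"],
                thickness_um=meta["thickness_um"],
            )
        )
    if not sections:
        raise FileNotFoundError(f"no section_*.tif files in {ind}")
    return sections


def write_channel_stack(images: list[ChannelImage], out_dir: str | Path) -> list[Path]:
    """Per-channel 8-bit grayscale TIFFs (`cyan_000.tif` / `black_000.tif`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, im in enumerate(images):
        p = out / f"{im.channel.value}_{k:03d}.tif"
        tifffile.imwrite(p, im.pixels)
        paths.append(p)
    return paths


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Multi-page grayscale TIFF with spacing metadata in a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.voxels)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"spacing_um": list(vol.spacing_um), "channel": vol.channel.value}, indent=2
    ))


def read_volume(path: str | Path) -> ScalarVolume:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ScalarVolume(
        voxels=tifffile.imread(path),
        spacing_um=tuple(meta["spacing_um"]),
        channel=Channel(meta["channel"]),
    )


def write_mesh_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    """Binary little-endian PLY with per-vertex RGBA colours from labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = mesh.to_trimesh()
    colours = np.array([LABEL_COLOURS[int(l)] for l in mesh.vertex_labels],
                       dtype=np.uint8).reshape(-1, 4)
    if len(colours):
        tm.visual.vertex_colors = colours
    tm.export(path, file_type="ply", encoding="binary")


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """Vessel graph, transforms and per-sheath truth rows (no voxel data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "spec": asdict(truth.spec),
        "nodes": [list(p) for p in truth.vessel_graph.nodes],
        "edges": [
            {"a": e.a, "b": e.b, "type": e.vessel_type, "radius_um": e.radius_um}
            for e in truth.vessel_graph.edges
        ],
        "sheaths": [
            {
                "id": s.id,
                "class": s.sheath_class,
                "true_volume_mm3": s.true_volume_mm3,
                "touches_boundary": s.touches_boundary,
                "start_node": s.start_node,
                "centerline": s.centerline.tolist(),
            }
            for s in truth.sheath_components
        ],
        "applied_transforms": [asdict(t) for t in truth.applied_transforms],
    }
    path.write_text(json.dumps(payload, indent=2, default=float))


def write_label_volume(truth: GroundTruth, path: str | Path) -> None:
    """Truth label volume as multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, truth.label_volume)


def load_rigid_transforms(path: str | Path) -> list[RigidTransform]:
    data = json.loads(Path(path).read_text())
    return [RigidTransform(**t) for t in data]
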