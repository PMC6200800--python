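"""Synthetic dual-chromogen serial-section specimens with known truth.

The generator emulates the imaging situation of a 24-section block of
human splenic red pulp scanned in brightfield: a branching arterial tree
(SMA+ walls, CD34+ endothelium) rendered as brown DAB-like tubes, thin
brown capillaries, CD271+ capillary sheaths as blue periendothelial cuffs
on a configurable fraction of post-arteriolar capillaries, optional blue
FDC blobs as confounders, per-section rigid misalignment, additive
intensity noise, stain dropout mimicking unstained stromal-cell nuclei and
intercalated macrophages, and the 14:1 xy:z anisotropy of 0.5 µm pixels
over 7 µm sections.

Arterial vessels divide in a sequential dichotomous manner; side branches
terminate in sheathed capillaries, so every post-arteriolar sheath cuff in
the truth begins exactly where an arteriole-type edge ends.  "Detached"
sheaths stand for sheaths whose feeding vessel lies outside the block.

The truth container records the vessel graph (µm coordinates), one row per
sheath component (class, centreline, analytic volume), an integer label
volume (0 background, 1 brown vessel, 2 blue sheath, 3 blue FDC) at
sub-section axial resolution (~1 µm sub-planes, 7 per section) so that
sections can be rendered as slab projections, and the per-section rigid
transforms actually applied.

Randomness: a single ``SeedSequence(rng_seed)`` is split into a build
stream (tree geometry, sheath placement, dropout candidates) and a render
stream (misalignment, noise), in that documented order, so the same
(spec, seed) reproduces sections bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .register import RigidTransform, SectionImage, apply_transform

__all__ = [
    "PhantomSpec",
    "VesselEdge",
    "VesselGraph",
    "SheathTruth",
    "DropoutPatch",
    "GroundTruth",
    "PALETTE",
    "build_phantom",
    "render_sections",
    "paint_tube",
]

# Brightfield palette: DAB-like brown, Fast-Blue-like blue, warm white
# background; chosen so the naive CMYK C/K split separates them cleanly.
# Minimum surface-to-surface clearance kept between distinct sheath cuffs
# at placement time (µm): red-pulp cords separate real sheaths, and the
# downstream cyan dilation (±5.5 µm each) plus the large closing (±7 µm)
# would otherwise fuse neighbouring cuffs into one component: two dilated
# surfaces must stay > 14 µm apart to survive the closing.
SHEATH_CLEARANCE_UM = 40.0

PALETTE: dict[int, tuple[int, int, int]] = {
    0: (245, 243, 240),
    1: (110, 70, 40),
    2: (60, 70, 150),
    3: (70, 78, 155),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a virtual specimen.

    Defaults mirror the real study conditions: 0.5 µm/px, 7 µm sections,
    24 sections, a 1 × 1 mm ROI, ~48 sheaths per ROI of which 44.5% are
    post-arteriolar.  Sheath wall thickness and capillary calibre are free
    parameters of the generator (set to plausible microanatomy), not
    measurements.
    """

    width_px: int = 2000
    height_px: int = 2000
    n_sections: int = 24
    pixel_size_um: float = 0.5
    section_thickness_um: float = 7.0
    n_arterioles: int = 4
    n_sheaths: int = 48
    frac_post_arteriolar: float = 0.445
    sheath_length_range_um: tuple[float, float] = (30.0, 150.0)
    sheath_wall_thickness_um: float = 6.0
    capillary_radius_um: float = 3.5
    arteriole_radius_um: float = 10.0
    include_fdc_blobs: bool = True
    dropout_rate: float = 0.15
    misalignment_px: float = 8.0
    noise_sd: float = 4.0
    # faint brownish mottling of the red-pulp cords (ubiquitous weakly
    # SMA+/CD271+ fibroblasts); continuous across sections, well below the
    # meshing iso-values, and what registration anchors on in real tissue
    background_texture_amp: float = 40.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_sections) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("physical sizes must be positive")
        if not 0.0 <= self.frac_post_arteriolar <= 1.0:
            raise ValueError("frac_post_arteriolar must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        for v in (
            self.sheath_wall_thickness_um,
            self.capillary_radius_um,
            self.arteriole_radius_um,
        ):
            if v <= 0:
                raise ValueError("physical sizes must be positive")
        if self.n_sheaths < 0 or self.n_arterioles < 0:
            raise ValueError("counts must be non-negative")

    @property
    def extents_um(self) -> tuple[float, float, float]:
        return (
            self.width_px * self.pixel_size_um,
            self.height_px * self.pixel_size_um,
            self.n_sections * self.section_thickness_um,
        )

    @property
    def n_subplanes(self) -> int:
        """Sub-planes per section in the truth label volume (~1 µm each)."""
        return max(1, round(self.section_thickness_um))

    @property
    def label_spacing_um(self) -> tuple[float, float, float]:
        return (
            self.pixel_size_um,
            self.pixel_size_um,
            self.section_thickness_um / self.n_subplanes,
        )

    @property
    def n_post_arteriolar(self) -> int:
        return round(self.n_sheaths * self.frac_post_arteriolar)


@dataclass(frozen=True)
class VesselEdge:
    a: int
    b: int
    vessel_type: str  # artery | arteriole | capillary
    radius_um: float


@dataclass
class VesselGraph:
    nodes: list[tuple[float, float, float]] = field(default_factory=list)
    edges: list[VesselEdge] = field(default_factory=list)

    def add_node(self, p: tuple[float, float, float]) -> int:
        self.nodes.append(tuple(float(v) for v in p))
        return len(self.nodes) - 1

    def add_edge(self, a: int, b: int, vessel_type: str, radius_um: float) -> None:
        self.edges.append(VesselEdge(a, b, vessel_type, radius_um))


@dataclass
class SheathTruth:
    id: int
    centerline: np.ndarray  # (n, 3) µm points
    sheath_class: str  # post_arteriolar | detached
    true_volume_mm3: float
    touches_boundary: bool
    start_node: int | None  # arteriole end node for post-arteriolar sheaths


@dataclass(frozen=True)
class DropoutPatch:
    """Candidate stain interruption: applied when ``u < dropout_rate``, so
    the erased set grows monotonically with the rate at a fixed seed."""

    center_um: tuple[float, float, float]
    radius_um: float
    u: float


@dataclass
class GroundTruth:
    spec: PhantomSpec
    vessel_graph: VesselGraph
    sheath_components: list[SheathTruth]
    label_volume: np.ndarray  # (nz_sub, ny, nx) uint8 labels
    sheath_id_volume: np.ndarray  # (nz_sub, ny, nx) int16, -1 = none
    dropout_patches: list[DropoutPatch]
    texture: np.ndarray | None = None  # (nz_sub, ny, nx) float32, ~N(0,1)
    applied_transforms: list[RigidTransform] = field(default_factory=list)


def _segment_clip(
    p0: np.ndarray, p1: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool] | None:
    """Clip segment to the box [lo, hi]; returns (q0, q1, clipped) or None."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                return None
            continue
        ta = (lo[ax] - p0[ax]) / d[ax]
        tb = (hi[ax] - p0[ax]) / d[ax]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return p0 + t0 * d, p0 + t1 * d, (t0 > 0.0 or t1 < 1.0)


def paint_tube(
    label: np.ndarray,
    spacing_um: tuple[float, float, float],
    p0: tuple[float, float, float],
    p1: tuple[float, float, float],
    r_inner_um: float,
    r_outer_um: float,
    value: int,
    id_volume: np.ndarray | None = None,
    id_value: int = -1,
    overwrite: bool = True,
    flat_caps: bool = False,
) -> int:
    """Rasterise a tube (or annular cuff) around segment p0→p1 into ``label``.

    Voxels with distance d to the segment satisfying
    ``r_inner_um < d <= r_outer_um`` receive ``value`` (``r_inner_um < 0``
    paints a solid rod).  ``flat_caps`` restricts to the cylindrical part
    (no rounded end caps), making the painted volume of an annular cuff
    exactly pi*(r_out^2 - r_in^2)*L up to voxelisation.  With
    ``overwrite=False`` only background voxels are painted, so cuffs never
    eat into vessel lumina.  Returns the number of voxels painted.
    """
    sx, sy, sz = spacing_um
    nz, ny, nx = label.shape
    a = np.asarray(p0, dtype=np.float64)
    b = np.asarray(p1, dtype=np.float64)
    margin = r_outer_um + max(sx, sy, sz)
    lo = np.minimum(a, b) - margin
    hi = np.maximum(a, b) + margin
    i0 = max(0, int(math.floor(lo[0] / sx)))
    i1 = min(nx, int(math.ceil(hi[0] / sx)) + 1)
    j0 = max(0, int(math.floor(lo[1] / sy)))
    j1 = min(ny, int(math.ceil(hi[1] / sy)) + 1)
    k0 = max(0, int(math.floor(lo[2] / sz)))
    k1 = min(nz, int(math.ceil(hi[2] / sz)) + 1)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return 0
    # voxel (i, j, k) centre at (i*sx, j*sy, k*sz)
    xs = np.arange(i0, i1) * sx
    ys = np.arange(j0, j1) * sy
    zs = np.arange(k0, k1) * sz
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    d = b - a
    L2 = float(d @ d)
    if L2 < 1e-12:
        dist = np.linalg.norm(P - a, axis=-1)
        inside_span = np.ones(dist.shape, dtype=bool)
    else:
        t_raw = ((P - a) @ d) / L2
        t = np.clip(t_raw, 0.0, 1.0)
        proj = a + t[..., None] * d
        dist = np.linalg.norm(P - proj, axis=-1)
        inside_span = (t_raw >= 0.0) & (t_raw <= 1.0)
    mask = (dist <= r_outer_um) & (dist > r_inner_um)
    if flat_caps:
        mask &= inside_span
    sub = label[k0:k1, j0:j1, i0:i1]
    if not overwrite:
        mask &= sub == 0
    sub[mask] = value
    if id_volume is not None:
        id_sub = id_volume[k0:k1, j0:j1, i0:i1]
        id_sub[mask] = id_value
    return int(mask.sum())


def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def _seg_seg_dist(
    p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray
) -> float:
    """Minimum distance between two 3D segments (sampled, adequate for
    placement clearance checks)."""
    ts = np.linspace(0.0, 1.0, 24)
    a = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    b = q0[None, :] + ts[:, None] * (q1 - q0)[None, :]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def _jittered_direction(rng: np.random.Generator, d: np.ndarray, angle_sd: float) -> np.ndarray:
    """Perturb direction d by a random small rotation (z-component damped
    to keep vessels mostly in-plane in a thin block)."""
    out = d + rng.normal(0.0, angle_sd, size=3) * np.array([1.0, 1.0, 0.35])
    return _unit(out)


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Construct the voxel/graph-level truth of a virtual specimen."""
    ext = np.array(spec.extents_um)
    max_radius = max(
        spec.arteriole_radius_um * 1.4,
        spec.capillary_radius_um + spec.sheath_wall_thickness_um,
    )
    if max_radius > min(ext) / 2:
        raise ValueError(
            f"vessel radius {max_radius:.1f} µm exceeds half the smallest "
            f"grid dimension ({min(ext) / 2:.1f} µm)"
        )

    ss = np.random.SeedSequence(spec.rng_seed)
    build_ss, _render_ss = ss.spawn(2)
    rng = np.random.default_rng(build_ss)

    nz = spec.n_sections * spec.n_subplanes
    label = np.zeros((nz, spec.height_px, spec.width_px), dtype=np.uint8)
    sheath_ids = np.full_like(label, -1, dtype=np.int16)
    spacing = spec.label_spacing_um
    lo = np.zeros(3)
    hi = ext - 1e-9
    graph = VesselGraph()
    sheaths: list[SheathTruth] = []
    arterial_segments: list[tuple[np.ndarray, np.ndarray, float]] = []

    def _paint_vessel(a: np.ndarray, b: np.ndarray, radius: float) -> None:
        paint_tube(label, spacing, tuple(a), tuple(b), -1.0, radius, 1)
        arterial_segments.append((np.asarray(a, float), np.asarray(b, float), radius))

    n_attached = spec.n_post_arteriolar
    n_detached = spec.n_sheaths - n_attached

    # --- arterial trees: sequential dichotomous branching -----------------
    arteriole_tips: list[tuple[int, np.ndarray]] = []  # (node id, direction)
    # branch lengths scale with the block so small test phantoms still fit
    # a full dichotomous tree; tips are kept off the boundary so that
    # post-arteriolar cuffs have room to start inside the volume
    scale = min(1.0, float(min(ext)) / 400.0)
    tip_margin = lo + max(
        spec.capillary_radius_um + spec.sheath_wall_thickness_um + 2.0,
        0.06 * float(min(ext)),
    )
    centre = (lo + hi) / 2.0
    def _clip_inside(q: np.ndarray) -> np.ndarray:
        return np.clip(q, tip_margin, hi - (tip_margin - lo))

    def _side_direction(d: np.ndarray, sign: float) -> np.ndarray:
        """Rotate d by ~60-75 degrees in the xy plane (side branch)."""
        phi = sign * rng.uniform(math.radians(65), math.radians(90))
        c, s = math.cos(phi), math.sin(phi)
        rotated = np.array(
            [d[0] * c - d[1] * s, d[0] * s + d[1] * c, 0.4 * d[2]]
        )
        return _jittered_direction(rng, rotated, 0.1)

    if spec.n_sheaths > 0 or spec.n_arterioles > 0:
        # Sequential dichotomous divisions: the main vessel stays
        # unsheathed while each side branch ends in a sheath candidate,
        # until the main vessel itself terminates in one.
        tips_needed = max(n_attached, spec.n_arterioles)
        tips_per_tree = -(-tips_needed // max(spec.n_arterioles, 1))  # ceil
        root_points: list[np.ndarray] = []
        for _ in range(spec.n_arterioles):
            margin = 0.15 * ext
            # spread roots apart so trees (and hence their sheathed tips)
            # occupy different territories of the block
            p = rng.uniform(lo + margin, hi - margin)
            for _try in range(30):
                if all(
                    np.linalg.norm((p - r)[:2]) >= 0.35 * float(min(ext[:2]))
                    for r in root_points
                ):
                    break
                p = rng.uniform(lo + margin, hi - margin)
            root_points.append(p)
            # grow in a random, mostly in-plane direction; wall avoidance
            # is handled per-step during growth
            d = _unit(rng.normal(size=3) * np.array([1.0, 1.0, 0.25]))
            root = graph.add_node(p)
            # feeding artery stub
            q = _clip_inside(p + d * rng.uniform(40.0, 70.0) * scale)
            head = graph.add_node(q)
            graph.add_edge(root, head, "artery", spec.arteriole_radius_um * 1.4)
            _paint_vessel(p, q, spec.arteriole_radius_um * 1.4)
            node, dd = head, _unit(q - p)
            side_sign = 1.0 if rng.uniform() < 0.5 else -1.0
            for step in range(max(tips_per_tree - 1, 0)):
                base = np.asarray(graph.nodes[node])
                radius = spec.arteriole_radius_um * (0.9**step)
                # pull the main vessel back toward the interior near walls
                pull = 0.6 * _unit(centre - base) if (
                    np.any(base - lo < 0.12 * ext) or np.any(hi - base < 0.12 * ext)
                ) else 0.0
                nd = _jittered_direction(rng, dd + pull, 0.12)
                q2 = _clip_inside(base + nd * rng.uniform(45.0, 70.0) * max(scale, 0.75))
                child = graph.add_node(q2)
                graph.add_edge(node, child, "arteriole", radius)
                _paint_vessel(base, q2, radius)
                # side branch at the division, alternating sides
                sd = _side_direction(nd, side_sign)
                side_sign = -side_sign
                sq = _clip_inside(q2 + sd * rng.uniform(55.0, 75.0) * max(scale, 0.85))
                side = graph.add_node(sq)
                graph.add_edge(child, side, "arteriole", radius * 0.8)
                _paint_vessel(q2, sq, radius * 0.8)
                arteriole_tips.append((side, _unit(sq - q2)))
                node, dd = child, _unit(q2 - base)
            # the main vessel finally also ends in a sheath candidate
            base = np.asarray(graph.nodes[node])
            nd = _jittered_direction(rng, dd, 0.12)
            q2 = _clip_inside(base + nd * rng.uniform(35.0, 55.0) * scale)
            tip = graph.add_node(q2)
            graph.add_edge(node, tip, "arteriole",
                           spec.arteriole_radius_um * (0.9 ** max(tips_per_tree - 1, 0)))
            _paint_vessel(base, q2, spec.arteriole_radius_um * 0.8)
            arteriole_tips.append((tip, _unit(q2 - base)))

    rng.shuffle(arteriole_tips)

    # --- post-arteriolar sheaths: cuffs starting at arteriole end nodes ---
    # Sheaths are discrete structures separated by red pulp cords; keep a
    # clearance between cuffs so distinct sheaths stay distinct even after
    # the aggressive cyan closing/dilation downstream.
    placed_cuffs: list[tuple[np.ndarray, np.ndarray, float]] = []
    r_out_all = spec.capillary_radius_um + spec.sheath_wall_thickness_um

    def _clear_of_cuffs(a: np.ndarray, b: np.ndarray) -> bool:
        for c0, c1, cr in placed_cuffs:
            if _seg_seg_dist(a, b, c0, c1) < cr + r_out_all + SHEATH_CLEARANCE_UM:
                return False
        return True

    def _clear_of_vessels(
        a: np.ndarray, b: np.ndarray, exclude_near: np.ndarray | None = None
    ) -> bool:
        """No foreign arterial segment may cross the cuff (it would erase
        part of the sheath stain); the cuff's own feeder is excluded."""
        for v0, v1, vr in arterial_segments:
            if exclude_near is not None and (
                np.linalg.norm(v1 - exclude_near) < 1.0
                or np.linalg.norm(v0 - exclude_near) < 1.0
            ):
                continue
            if _seg_seg_dist(a, b, v0, v1) < vr + r_out_all + 6.0:
                return False
        return True

    sheath_id = 0
    for tip_node, tip_dir in arteriole_tips[:n_attached]:
        start = np.asarray(graph.nodes[tip_node])

        def _inside_len(dd: np.ndarray, ll: float) -> float:
            c = _segment_clip(start, start + dd * ll, lo, hi)
            return 0.0 if c is None else float(np.linalg.norm(c[1] - c[0]))

        # prefer a direction whose cuff both clears other sheaths and stays
        # mostly inside the block (pull toward the centre near the walls)
        best: tuple[float, np.ndarray, float] | None = None
        for _try in range(18):
            jitter = 0.25 if _try == 0 else 0.45
            base_dir = tip_dir if _try % 2 == 0 else tip_dir + 0.8 * _unit(centre - start)
            d = _jittered_direction(rng, base_dir, jitter)
            length = rng.uniform(*spec.sheath_length_range_um)
            if _try >= 12:  # a shorter cuff is easier to keep clear
                length = max(spec.sheath_length_range_um[0], 0.6 * length)
            inside = _inside_len(d, length)
            cuff_end_pt = start + d * length
            clear = _clear_of_cuffs(start, cuff_end_pt) and _clear_of_vessels(
                start, cuff_end_pt, exclude_near=start
            )
            score = inside * (1.0 if clear else 0.25)
            if best is None or score > best[0]:
                best = (score, d, length)
            if clear and inside >= 0.7 * length:
                break
        _, d, length = best
        end = start + d * (length + 20.0)  # capillary continues past the cuff
        clip = _segment_clip(start, end, lo, hi)
        cap_end = clip[1] if clip else start
        cap_node = graph.add_node(tuple(cap_end))
        graph.add_edge(tip_node, cap_node, "capillary", spec.capillary_radius_um)
        paint_tube(label, spacing, tuple(start), tuple(cap_end), -1.0,
                   spec.capillary_radius_um, 1)
        # the bare capillary continuation can cut a later cuff too
        arterial_segments.append(
            (start + d * length, cap_end, spec.capillary_radius_um)
        )
        cuff_end = start + d * length
        cclip = _segment_clip(start, cuff_end, lo, hi)
        if cclip is None:
            continue
        q0, q1, was_clipped = cclip
        r_in = spec.capillary_radius_um
        r_out = r_in + spec.sheath_wall_thickness_um
        n_painted = paint_tube(
            label, spacing, tuple(q0), tuple(q1), r_in, r_out, 2,
            id_volume=sheath_ids, id_value=sheath_id, overwrite=False,
            flat_caps=True)
        # the cuff volume that actually exists in the specimen (crossing
        # vessels and the feeder's wall locally displace sheath stain)
        vol_um3 = n_painted * spacing[0] * spacing[1] * spacing[2]
        sheaths.append(SheathTruth(
            id=sheath_id,
            centerline=np.stack([q0, q1]),
            sheath_class="post_arteriolar",
            true_volume_mm3=vol_um3 * 1e-9,
            touches_boundary=was_clipped or _near_boundary(q0, q1, lo, hi, r_out),
            start_node=tip_node,
        ))
        placed_cuffs.append((q0, q1, r_out))
        sheath_id += 1

    # unsheathed arteriole tips continue as short open-ended capillaries
    for tip_node, tip_dir in arteriole_tips[n_attached:]:
        start = np.asarray(graph.nodes[tip_node])
        d = _jittered_direction(rng, tip_dir, 0.25)
        end = np.clip(start + d * rng.uniform(25.0, 60.0), lo, hi)
        cap_node = graph.add_node(tuple(end))
        graph.add_edge(tip_node, cap_node, "capillary", spec.capillary_radius_um)
        paint_tube(label, spacing, tuple(start), tuple(end), -1.0,
                   spec.capillary_radius_um, 1)

    # --- detached sheaths: feeding vessel outside the block ---------------
    for _ in range(n_detached):
        margin = 0.05 * ext
        clip = None
        for _try in range(60):
            p = rng.uniform(lo + margin, hi - margin)
            d = _unit(rng.normal(size=3) * np.array([1.0, 1.0, 0.3]))
            length = rng.uniform(*spec.sheath_length_range_um)
            end = p + d * length
            cand = _segment_clip(p, end, lo, hi)
            if cand is not None and _clear_of_cuffs(cand[0], cand[1]) \
                    and _clear_of_vessels(cand[0], cand[1]):
                clip = cand
                break
            if cand is not None and clip is None:
                clip = cand  # fallback if no clear spot is found
        if clip is None:
            continue
        q0, q1, was_clipped = clip
        paint_tube(label, spacing, tuple(q0), tuple(q1), -1.0,
                   spec.capillary_radius_um, 1)
        r_in = spec.capillary_radius_um
        r_out = r_in + spec.sheath_wall_thickness_um
        n_painted = paint_tube(
            label, spacing, tuple(q0), tuple(q1), r_in, r_out, 2,
            id_volume=sheath_ids, id_value=sheath_id, overwrite=False,
            flat_caps=True)
        # the cuff volume that actually exists in the specimen (crossing
        # vessels and the feeder's wall locally displace sheath stain)
        vol_um3 = n_painted * spacing[0] * spacing[1] * spacing[2]
        sheaths.append(SheathTruth(
            id=sheath_id,
            centerline=np.stack([q0, q1]),
            sheath_class="detached",
            true_volume_mm3=vol_um3 * 1e-9,
            touches_boundary=was_clipped or _near_boundary(q0, q1, lo, hi, r_out),
            start_node=None,
        ))
        placed_cuffs.append((q0, q1, r_out))
        sheath_id += 1

    # --- FDC blobs: CD271+ confounders in follicles -----------------------
    if spec.include_fdc_blobs:
        n_blobs = max(1, spec.n_arterioles // 2)
        for _ in range(n_blobs):
            for _try in range(20):
                c = rng.uniform(lo + 0.1 * ext, hi - 0.1 * ext)
                r = rng.uniform(15.0, 30.0)
                if all(
                    _seg_seg_dist(c, c, c0, c1) > cr + r + SHEATH_CLEARANCE_UM
                    for c0, c1, cr in placed_cuffs
                ) and all(
                    # follicles sit away from the red-pulp vasculature
                    _seg_seg_dist(c, c, v0, v1) > vr + r + 25.0
                    for v0, v1, vr in arterial_segments
                ):
                    break
            paint_tube(label, spacing, tuple(c), tuple(c), -1.0, r, 3,
                       overwrite=False)

    # --- dropout candidates (applied at render time) ----------------------
    patches: list[DropoutPatch] = []
    n_sheath_vox = int((label == 2).sum())
    n_candidates = n_sheath_vox // 400
    if n_candidates > 0:
        kk, jj, ii = np.nonzero(label == 2)
        picks = rng.integers(0, len(kk), size=n_candidates)
        radii = rng.uniform(3.0, 8.0, size=n_candidates)
        us = rng.uniform(0.0, 1.0, size=n_candidates)
        sx, sy, sz = spacing
        for p, r, u in zip(picks, radii, us):
            c = (ii[p] * sx, jj[p] * sy, kk[p] * sz)
            patches.append(DropoutPatch(center_um=c, radius_um=float(r), u=float(u)))

    # --- faint red-pulp cord texture (smooth, continuous in z) ------------
    texture = None
    if spec.background_texture_amp > 0:
        from scipy import ndimage as ndi

        # z cells span ~2 sections so consecutive sections see correlated
        # cord texture, as consecutive real sections do
        coarse_shape = (
            max(2, spec.n_sections // 2),
            max(2, spec.height_px // 5),
            max(2, spec.width_px // 5),
        )
        coarse = rng.normal(size=coarse_shape)
        coarse = ndi.gaussian_filter(coarse, (1.0, 0.8, 0.8))
        zoom = [t / c for t, c in zip(label.shape, coarse_shape)]
        texture = ndi.zoom(coarse, zoom, order=1, grid_mode=True, mode="nearest")
        texture = (texture / max(texture.std(), 1e-9)).astype(np.float32)

    return GroundTruth(
        spec=spec,
        vessel_graph=graph,
        sheath_components=sheaths,
        label_volume=label,
        sheath_id_volume=sheath_ids,
        dropout_patches=patches,
        texture=texture,
    )


def _near_boundary(
    q0: np.ndarray, q1: np.ndarray, lo: np.ndarray, hi: np.ndarray, r: float
) -> bool:
    for q in (q0, q1):
        if np.any(q - lo < r) or np.any(hi - q < r):
            return True
    return False


def _dropout_label(truth: GroundTruth) -> np.ndarray:
    """Label volume with active dropout patches erased from sheath stain."""
    rate = truth.spec.dropout_rate
    active = [p for p in truth.dropout_patches if p.u < rate]
    if not active:
        return truth.label_volume
    label = truth.label_volume.copy()
    sx, sy, sz = truth.spec.label_spacing_um
    nz, ny, nx = label.shape
    for p in active:
        cx, cy, cz = p.center_um
        r = p.radius_um
        i0, i1 = max(0, int((cx - r) / sx)), min(nx, int((cx + r) / sx) + 2)
        j0, j1 = max(0, int((cy - r) / sy)), min(ny, int((cy + r) / sy) + 2)
        k0, k1 = max(0, int((cz - r) / sz)), min(nz, int((cz + r) / sz) + 2)
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        Z, Y, X = np.meshgrid(
            np.arange(k0, k1) * sz,
            np.arange(j0, j1) * sy,
            np.arange(i0, i1) * sx,
            indexing="ij",
        )
        inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2
        sub = label[k0:k1, j0:j1, i0:i1]
        sub[inside & (sub == 2)] = 0
    return label


def render_sections(truth: GroundTruth, spec: PhantomSpec) -> list[SectionImage]:
    """Render brightfield section scans from the truth label volume.

    Each section integrates (averages) the palette projection of its
    sub-planes over the 7 µm slab, then receives its rigid misalignment,
    then additive Gaussian noise.  The applied transforms are recorded in
    ``truth.applied_transforms``.
    """
    if spec is not truth.spec and spec != truth.spec:
        raise ValueError("spec must match the one used to build the truth")
    ss = np.random.SeedSequence(spec.rng_seed)
    _build_ss, render_ss = ss.spawn(2)
    rng = np.random.default_rng(render_ss)

    label = _dropout_label(truth)
    lut = np.zeros((256, 3), dtype=np.float64)
    for k, rgb in PALETTE.items():
        lut[k] = rgb

    nsub = spec.n_subplanes
    truth.applied_transforms = []
    sections: list[SectionImage] = []
    # faint brown absorption weights per RGB channel (DAB-like hue)
    tex_w = np.array([0.20, 0.32, 0.42]) * spec.background_texture_amp
    for k in range(spec.n_sections):
        slab = label[k * nsub : (k + 1) * nsub]
        rgb = lut[slab].mean(axis=0)  # slab projection
        if truth.texture is not None:
            # cord-like faint patches: thresholded random field, crisp
            # in-plane edges, correlated over ~2 sections in z
            field = truth.texture[k * nsub : (k + 1) * nsub].mean(axis=0)
            patches_ = 1.0 / (1.0 + np.exp(-(field - 0.5) / 0.18))
            bg = (slab == 0).all(axis=0)  # stain overrides the faint cords
            rgb[bg] = rgb[bg] - patches_[bg][:, None] * tex_w[None, :]
        if spec.misalignment_px > 0:
            mag = rng.uniform(0.0, spec.misalignment_px)
            ang = rng.uniform(0.0, 2 * math.pi)
            theta = rng.uniform(-math.radians(0.5), math.radians(0.5))
            t = RigidTransform(mag * math.cos(ang), mag * math.sin(ang), theta)
            # the slide extends beyond the stored field of view: misalign a
            # reflect-padded canvas and crop, so no frame-pinned fill
            # border appears (a real scan crop has tissue to its edge)
            pad = int(math.ceil(spec.misalignment_px)) + 6
            img8 = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
            padded = np.pad(img8, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
            moved = np.empty_like(padded, dtype=np.float64)
            for c in range(3):
                moved[..., c] = apply_transform(
                    padded[..., c], t, cval=PALETTE[0][c]
                )
            rgb = moved[pad:-pad, pad:-pad]
        else:
            t = RigidTransform()
        truth.applied_transforms.append(t)
        if spec.noise_sd > 0:
            rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
        px = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
        sections.append(
            SectionImage(
                pixels=px,
                index=k,
                pixel_size_um=spec.pixel_size_um,
                thickness_um=spec.section_thickness_um,
            )
        )
    return sections
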