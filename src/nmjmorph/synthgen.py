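"""Synthetic two-channel NMJ stacks with complete ground truth.

The generator emulates what the pipeline sees in real data: a branched
tubular terminal with bouton swellings in the scaffold channel
(Dlg1-like: continuous tube with constrictions between boutons;
Syt-like: disjoint bright boutons with fully dark interbouton gaps),
punctate active-zone spots inside the terminal footprint in the second
channel, a smooth non-uniform background, optional out-of-focus blur
and Gaussian sensor noise.  Everything is deterministic given the seed,
and every planted quantity (topology, bouton count, spot coordinates)
is recorded as ground truth.

Default acquisition geometry follows a 63x wide-field setup: 42 planes,
0.3 um z-step, 6.932 px/um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from .io_stack import Calibration, NmjStackPair
from .roi import RoiPolygon, write_roi_file, roi_file_path

__all__ = ["SynthSpec", "GroundTruth", "Tree", "random_tree", "generate_nmj", "write_fixture_directory"]


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Planar polyline tree: nodes are (y, x) points, edges straight arms."""

    graph: nx.Graph  # node -> point (y, x); edge attr 'length' in px

    @property
    def segments(self) -> list:
        pts = nx.get_node_attributes(self.graph, "point")
        return [(pts[u], pts[v]) for u, v in self.graph.edges]

    @property
    def n_branches(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_branching_points(self) -> int:
        return sum(1 for n in self.graph if self.graph.degree(n) >= 3)

    def total_length_px(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def longest_leaf_path_px(self) -> float:
        leaves = [n for n in self.graph if self.graph.degree(n) == 1]
        best = 0.0
        for i, a in enumerate(leaves):
            dist = nx.single_source_dijkstra_path_length(self.graph, a, weight="length")
            for b in leaves[i + 1 :]:
                best = max(best, dist[b])
        return best


def _seg_points(p0, p1, step=1.0):
    n = max(int(math.hypot(p1[0] - p0[0], p1[1] - p0[1]) / step), 1)
    t = np.linspace(0, 1, n + 1)
    return np.stack([p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1])], axis=1)


class _Occupancy:
    """Sampled points of already-placed arms, for self-avoidance checks."""

    def __init__(self):
        self.points = np.empty((0, 2))

    def clearance_ok(self, samples: np.ndarray, ignore_near, min_dist: float) -> bool:
        if self.points.shape[0] == 0:
            return True
        keep = np.ones(samples.shape[0], dtype=bool)
        for p in ignore_near:
            d = np.hypot(samples[:, 0] - p[0], samples[:, 1] - p[1])
            keep &= d > 2.0 * min_dist
        samples = samples[keep]
        if samples.size == 0:
            return True
        d2 = (
            (samples[:, None, 0] - self.points[None, :, 0]) ** 2
            + (samples[:, None, 1] - self.points[None, :, 1]) ** 2
        )
        return bool(d2.min() >= min_dist**2)

    def add(self, samples: np.ndarray):
        self.points = np.vstack([self.points, samples])


def _branch_partition(k_branches: int, k_islands: int) -> list[int]:
    """Split a branch budget over islands; each island gets 1 or >= 3 arms."""
    if k_islands < 1 or k_branches < k_islands:
        raise ValueError("need k_branches >= k_islands >= 1")
    parts = [1] * k_islands
    remaining = k_branches - k_islands
    while remaining > 0:
        if remaining == 1:
            grown = [i for i, b in enumerate(parts) if b >= 3]
            if not grown:
                raise ValueError(
                    f"cannot realize {k_branches} branches over {k_islands} islands "
                    "(an island cannot have exactly 2 branches)"
                )
            parts[grown[0]] += 1
            remaining -= 1
        else:
            target = next((i for i, b in enumerate(parts) if b == 1), 0)
            parts[target] += 2
            remaining -= 2
    return parts


def random_tree(
    rng: np.random.Generator,
    n_branches: int,
    shape: tuple[int, int],
    margin: int = 25,
    min_angle_deg: float = 30.0,
    arm_len: tuple[float, float] = (25.0, 70.0),
    clearance: float = 12.0,
    occupancy: _Occupancy | None = None,
    node_offset: int = 0,
) -> Tree:
    """Grow one random polyline tree inside the frame.

    Arms are added by splitting leaf tips into 2 or 3 child arms whose
    directions are at least ``min_angle_deg`` apart (and from the parent
    arm), which keeps rasterized topology identical to the planted one.
    Arms keep ``clearance`` pixels away from all previously placed arms.
    A geometrically stuck layout is discarded and regrown (the generator
    stays deterministic: all draws come from ``rng``).
    """
    if n_branches != 1 and n_branches < 3:
        raise ValueError("a single tree supports 1 or >= 3 branches")
    occ = occupancy or _Occupancy()
    last_err = None
    for _ in range(25):
        snapshot = occ.points.copy()
        try:
            return _grow_tree(
                rng, n_branches, shape, margin, min_angle_deg, arm_len, clearance, occ, node_offset
            )
        except RuntimeError as err:
            occ.points = snapshot
            last_err = err
    raise RuntimeError(f"tree layout failed repeatedly: {last_err}")


def _grow_tree(rng, n_branches, shape, margin, min_angle_deg, arm_len, clearance, occ, node_offset):
    h, w = shape
    g = nx.Graph()
    nid = node_offset

    def in_bounds(p):
        return margin <= p[0] <= h - 1 - margin and margin <= p[1] <= w - 1 - margin

    def try_arm(origin, theta_choices, lengths, staged=None, shared_origin=True):
        # arms sharing a junction may approach each other near that origin;
        # a fresh root arm has no such license
        ignore = [origin] if shared_origin else []
        for theta in theta_choices:
            for length in lengths:
                end = (origin[0] + length * math.sin(theta), origin[1] + length * math.cos(theta))
                if not in_bounds(end):
                    continue
                samples = _seg_points(origin, end, step=2.0)
                if not occ.clearance_ok(samples, ignore_near=ignore, min_dist=clearance):
                    continue
                if staged:
                    far = samples[
                        np.hypot(samples[:, 0] - origin[0], samples[:, 1] - origin[1])
                        > 2.0 * clearance
                    ]
                    if far.size and any(
                        ((far[:, None, :] - s[None, :, :]) ** 2).sum(-1).min() < clearance**2
                        for s in staged
                    ):
                        continue
                return end, theta, samples
        return None, None, None

    # root arm
    for _ in range(200):
        root = (
            float(rng.uniform(margin, h - 1 - margin)),
            float(rng.uniform(margin, w - 1 - margin)),
        )
        theta0 = float(rng.uniform(0, 2 * math.pi))
        lengths = sorted(rng.uniform(*arm_len, size=6), reverse=True)
        thetas = theta0 + np.linspace(0, 2 * math.pi, 12, endpoint=False)
        end, theta, samples = try_arm(root, thetas, lengths, shared_origin=False)
        if end is not None:
            break
    else:
        raise RuntimeError("could not place root arm")
    g.add_node(nid, point=root)
    g.add_node(nid + 1, point=end)
    g.add_edge(nid, nid + 1, length=math.hypot(end[0] - root[0], end[1] - root[1]))
    occ.add(samples)
    tips = [(nid + 1, theta)]
    nid += 2
    remaining = n_branches - 1

    min_angle = math.radians(min_angle_deg)
    stalls = 0
    while remaining > 0:
        m = 3 if remaining == 3 else 2
        placed = False
        order = rng.permutation(len(tips))
        for idx in order:
            tip_node, tip_theta = tips[idx]
            origin = g.nodes[tip_node]["point"]
            # child direction offsets, pairwise >= min_angle apart and
            # >= min_angle away from the reversed parent direction
            if m == 2:
                offs = [
                    -float(rng.uniform(min_angle * 0.8, math.radians(70))),
                    float(rng.uniform(min_angle * 0.8, math.radians(70))),
                ]
                if abs(offs[1] - offs[0]) < min_angle:
                    offs[1] = offs[0] + min_angle * 1.1
            else:
                spread = float(rng.uniform(max(min_angle, math.radians(35)), math.radians(60)))
                offs = [-spread, 0.0, spread]
            children = []
            staged = []
            ok = True
            for off in offs:
                lengths = sorted(rng.uniform(*arm_len, size=6), reverse=True)
                jitter = [0.0, 0.08, -0.08]
                end, theta, samples = try_arm(
                    origin, [tip_theta + off + j for j in jitter], lengths, staged=staged
                )
                if end is None:
                    ok = False
                    break
                children.append((end, theta, samples))
                staged.append(samples)
            if not ok or len(children) < m:
                continue
            for samples in staged:
                occ.add(samples)
            for end, theta, _ in children:
                g.add_node(nid, point=end)
                g.add_edge(
                    tip_node, nid, length=math.hypot(end[0] - origin[0], end[1] - origin[1])
                )
                tips.append((nid, theta))
                nid += 1
            tips.pop(idx)
            remaining -= m
            placed = True
            break
        if not placed:
            stalls += 1  # re-draw angles and lengths; geometry is often salvageable
            if stalls > 40:
                raise RuntimeError("tree growth stalled; widen the frame or shorten arms")
    return Tree(g)


# ---------------------------------------------------------------------------
# Spec and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic specimen.

    ``marker_style`` 'dlg1' renders a continuous tube with bouton
    swellings (shallow constrictions); 'syt' renders disjoint bright
    boutons with dark interbouton gaps.  ``neck_ratio`` is the tube
    width relative to the bouton diameter and controls how pronounced
    the constrictions are (only meaningful for dlg1).
    """

    seed: int = 0
    k_branches: int = 6
    k_islands: int = 2
    n_spots: int = 250
    spot_min_separation_px: float = 8.0
    tube_width_px: int = 9
    bouton_radius_px: int = 12
    bouton_spacing_px: float = 30.0
    arm_len: tuple = (35.0, 80.0)
    amplitude: float = 3000.0
    spot_amplitude: float = 2000.0
    background: str = "constant"  # constant | ramp | blobs
    background_level: float = 200.0
    noise_sd: float = 0.0
    psf_sigma_px: float = 0.0
    shape: tuple = (512, 512)
    n_planes: int = 42
    calibration: Calibration = field(default_factory=Calibration)
    marker_style: str = "dlg1"
    neck_ratio: float | None = None  # dlg1 tube width / bouton diameter

    def __post_init__(self):
        if self.marker_style not in ("dlg1", "syt"):
            raise ValueError("marker_style must be 'dlg1' or 'syt'")
        if self.background not in ("constant", "ramp", "blobs"):
            raise ValueError("unknown background model")

    def with_overrides(self, **kwargs) -> "SynthSpec":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    nmj_id: str
    n_islands: int
    n_branches: int
    n_branching_points: int
    polyline_total_length_um: float
    longest_path_um: float
    n_boutons: int
    spot_coordinates: list  # (z, y, x)
    footprint: np.ndarray | None = None  # 2D terminal footprint used for ROI


def _place_boutons(trees: list[Tree], spec: SynthSpec, min_center_dist: float) -> list:
    """Bouton centers along arms, kept clear of foreign arms and of each other.

    Candidates sit at regular arclength intervals on each arm; one is
    accepted only if it keeps ``min_center_dist`` from accepted centers
    and its disc cannot touch the tube of any *other* arm (which would
    silently create a cycle in the rasterized topology).
    """
    all_segments = []
    for tree in trees:
        pts = nx.get_node_attributes(tree.graph, "point")
        all_segments.extend((pts[u], pts[v]) for u, v in tree.graph.edges)
    seg_samples = [_seg_points(p0, p1, step=1.5) for p0, p1 in all_segments]
    safety = spec.bouton_radius_px + spec.tube_width_px / 2 + 4

    centers = []
    for j, (p0, p1) in enumerate(all_segments):
        length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
        n = int(length // spec.bouton_spacing_px)
        for k in range(n):
            s = (k + 0.5) * spec.bouton_spacing_px + (length - n * spec.bouton_spacing_px) / 2
            t = s / length
            c = (p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1]))
            if any(math.hypot(c[0] - o[0], c[1] - o[1]) < min_center_dist for o in centers):
                continue
            clear = True
            for i, samples in enumerate(seg_samples):
                if i == j:
                    continue
                d2 = (samples[:, 0] - c[0]) ** 2 + (samples[:, 1] - c[1]) ** 2
                if d2.min() < safety**2:
                    clear = False
                    break
            if clear:
                centers.append(c)
    return centers


def _disc_mask(shape, center, radius):
    y0 = max(int(center[0] - radius - 1), 0)
    y1 = min(int(center[0] + radius + 2), shape[0])
    x0 = max(int(center[1] - radius - 1), 0)
    x1 = min(int(center[1] + radius + 2), shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (slice(y0, y1), slice(x0, x1)), (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _background(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    level = spec.background_level
    if spec.background == "constant":
        return np.full((h, w), level)
    if spec.background == "ramp":
        yy, xx = np.mgrid[0:h, 0:w]
        return level * (0.7 + 0.6 * (yy + xx) / (h + w - 2))
    coarse = rng.uniform(0.5, 1.5, size=(8, 8))
    blobs = ndi.zoom(coarse, (h / 8, w / 8), order=3)[:h, :w]
    return level * blobs


def generate_nmj(spec: SynthSpec, nmj_id: str = "NMJ001") -> tuple[NmjStackPair, GroundTruth]:
    """Render one two-channel stack and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    parts = _branch_partition(spec.k_branches, spec.k_islands)
    # arms only need tube-level separation; bouton placement enforces its own
    clearance = spec.tube_width_px + 4
    occ = _Occupancy()
    trees = []
    offset = 0
    for b in parts:
        for attempt in range(12):
            snapshot = occ.points.copy()
            try:
                tree = random_tree(
                    rng,
                    b,
                    spec.shape,
                    margin=spec.bouton_radius_px + 12,
                    arm_len=spec.arm_len,
                    clearance=clearance,
                    occupancy=occ,
                    node_offset=offset,
                )
                break
            except RuntimeError:
                occ.points = snapshot
        else:
            raise RuntimeError("could not lay out islands; enlarge the frame")
        offset += tree.graph.number_of_nodes()
        trees.append(tree)

    # rasterize the centerlines
    centerline = np.zeros((h, w), dtype=bool)
    for tree in trees:
        for p0, p1 in tree.segments:
            for y, x in _seg_points(p0, p1, step=0.5):
                centerline[int(round(y)), int(round(x))] = True

    if spec.marker_style == "dlg1":
        tube_r = spec.tube_width_px
        if spec.neck_ratio is not None:
            tube_r = max(int(round(spec.neck_ratio * 2 * spec.bouton_radius_px)), 1)
        half = max(tube_r // 2, 1)
        footprint = ndi.binary_dilation(centerline, structure=_disk(half))
        bouton_centers = _place_boutons(
            trees, spec, min_center_dist=2.0 * spec.bouton_radius_px + 4
        )
        for c in bouton_centers:
            sl, disc = _disc_mask((h, w), c, spec.bouton_radius_px)
            footprint[sl] |= disc
        marker_img = footprint.astype(np.float64)
    else:  # syt: disjoint boutons, dark interbouton gaps
        bouton_centers = _place_boutons(
            trees, spec, min_center_dist=2.0 * spec.bouton_radius_px + 4
        )
        marker_img = np.zeros((h, w))
        footprint = np.zeros((h, w), dtype=bool)
        for c in bouton_centers:
            sl, disc = _disc_mask((h, w), c, spec.bouton_radius_px)
            footprint[sl] |= disc
        marker_img = footprint.astype(np.float64)

    n_islands_planted = len(trees)
    labeled, n_found = ndi.label(footprint, np.ones((3, 3)))
    if spec.marker_style == "dlg1" and n_found != n_islands_planted:
        raise RuntimeError(
            f"rasterization changed island count ({n_found} != {n_islands_planted}); "
            "increase clearance or frame size"
        )

    # spot coordinates: inside the eroded footprint, min 3D separation
    erode_r = 2
    allowed = ndi.binary_erosion(footprint, structure=_disk(erode_r))
    if not allowed.any():
        allowed = footprint
    ys, xs = np.nonzero(allowed)
    z_lo, z_hi = max(1, spec.n_planes // 6), max(spec.n_planes - 2, 1)
    spot_coords: list[tuple[int, int, int]] = []
    max_tries = 200 * max(spec.n_spots, 1)
    tries = 0
    while len(spot_coords) < spec.n_spots:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"cannot place {spec.n_spots} spots at separation "
                f"{spec.spot_min_separation_px}; footprint too small"
            )
        k = int(rng.integers(0, ys.size))
        z = int(rng.integers(z_lo, z_hi + 1))
        cand = (z, int(ys[k]), int(xs[k]))
        if all(
            (cand[0] - s[0]) ** 2 + (cand[1] - s[1]) ** 2 + (cand[2] - s[2]) ** 2
            >= spec.spot_min_separation_px**2
            for s in spot_coords
        ):
            spot_coords.append(cand)

    # --- render the stacks -------------------------------------------------
    z = np.arange(spec.n_planes)
    zc = (spec.n_planes - 1) / 2.0
    zprof = np.exp(-0.5 * ((z - zc) / max(spec.n_planes / 5.0, 1.0)) ** 2)

    bg = _background(spec, rng)
    marker_stack = np.empty((spec.n_planes, h, w))
    for iz in range(spec.n_planes):
        marker_stack[iz] = spec.amplitude * zprof[iz] * marker_img + bg

    spot_stack = np.tile(bg, (spec.n_planes, 1, 1))
    sig_xy, sig_z = 1.5, 1.0
    rad_xy, rad_z = 5, 3
    for sz, sy, sx in spot_coords:
        z0, z1 = max(sz - rad_z, 0), min(sz + rad_z + 1, spec.n_planes)
        y0, y1 = max(sy - rad_xy, 0), min(sy + rad_xy + 1, h)
        x0, x1 = max(sx - rad_xy, 0), min(sx + rad_xy + 1, w)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        spot_stack[z0:z1, y0:y1, x0:x1] += spec.spot_amplitude * np.exp(
            -0.5 * (((zz - sz) / sig_z) ** 2 + ((yy - sy) / sig_xy) ** 2 + ((xx - sx) / sig_xy) ** 2)
        )

    if spec.psf_sigma_px > 0:
        for stack in (marker_stack, spot_stack):
            for iz in range(spec.n_planes):
                stack[iz] = ndi.gaussian_filter(stack[iz], spec.psf_sigma_px)
    if spec.noise_sd > 0:
        marker_stack = marker_stack + rng.normal(0, spec.noise_sd, marker_stack.shape)
        spot_stack = spot_stack + rng.normal(0, spec.noise_sd, spot_stack.shape)

    marker_stack = np.clip(marker_stack, 0, 65535).astype(np.uint16)
    spot_stack = np.clip(spot_stack, 0, 65535).astype(np.uint16)

    cal = replace(spec.calibration, n_planes=spec.n_planes)
    pair = NmjStackPair(
        nmj_id=nmj_id, marker_stack=marker_stack, spot_stack=spot_stack, calibration=cal
    )
    total_px = sum(t.total_length_px() for t in trees)
    longest_px = max(t.longest_leaf_path_px() for t in trees)
    truth = GroundTruth(
        nmj_id=nmj_id,
        n_islands=len(trees),
        n_branches=sum(t.n_branches for t in trees),
        n_branching_points=sum(t.n_branching_points for t in trees),
        polyline_total_length_um=total_px / cal.px_per_um_xy,
        longest_path_um=longest_px / cal.px_per_um_xy,
        n_boutons=len(bouton_centers),
        spot_coordinates=spot_coords,
        footprint=footprint,
    )
    return pair, truth


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def roi_polygon_for_footprint(footprint: np.ndarray, nmj_id: str, pad: float = 6.0) -> RoiPolygon:
    """Padded convex hull of the terminal footprint, as an ROI polygon."""
    ys, xs = np.nonzero(footprint)
    pts = np.stack([xs, ys], axis=1).astype(float)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    c = verts.mean(axis=0)
    out = []
    for v in verts:
        d = np.hypot(*(v - c))
        out.append(tuple(c + (v - c) * (1 + pad / max(d, 1e-9))))
    return RoiPolygon(nmj_id, out)


def write_fixture_directory(items, directory) -> list[GroundTruth]:
    """Write (pair, truth) items as per-plane TIFFs + ROI files + manifest.

    Plane files follow the default io_stack naming
    (``<id>_z<zz>_ch<k>.tif``, 1-based z); the ROI is the padded convex
    hull of the planted footprint; ground truth goes to
    ``ground_truth.tsv`` plus per-id spot coordinate files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truths = []
    rows = []
    for pair, truth in items:
        for ch, stack in ((1, pair.spot_stack), (2, pair.marker_stack)):
            for iz in range(stack.shape[0]):
                tifffile.imwrite(
                    str(directory / f"{pair.nmj_id}_z{iz + 1:02d}_ch{ch}.tif"), stack[iz]
                )
        if truth.footprint is not None:
            poly = roi_polygon_for_footprint(truth.footprint, pair.nmj_id)
            write_roi_file(roi_file_path(directory, pair.nmj_id), poly)
        spot_file = directory / f"{pair.nmj_id}_spots.txt"
        spot_file.write_text(
            "".join(f"{z}\t{y}\t{x}\n" for z, y, x in truth.spot_coordinates)
        )
        rows.append(
            f"{truth.nmj_id}\t{truth.n_islands}\t{truth.n_branches}\t"
            f"{truth.n_branching_points}\t{truth.polyline_total_length_um:.4f}\t"
            f"{truth.longest_path_um:.4f}\t{truth.n_boutons}\t{len(truth.spot_coordinates)}"
        )
        truths.append(truth)
    header = (
        "nmj_id\tn_islands\tn_branches\tn_branching_points\t"
        "polyline_total_length_um\tlongest_path_um\tn_boutons\tn_spots"
    )
    (directory / "ground_truth.tsv").write_text("\n".join([header, *rows]) + "\n")
    return truths
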