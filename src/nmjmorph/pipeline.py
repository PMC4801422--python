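"""Batch orchestration: convert -> (ROIs from files) -> analyze.

Mirrors the three-step workflow of semi-automated NMJ morphometry:
stack assembly, region-of-interest consumption, and per-NMJ analysis
producing nine features (or the eight-feature vesicle-marker variant),
one row per NMJ in a tab-separated results file, plus an annotated
overlay image per NMJ (outline yellow, skeleton blue, spots white).

Stage failures set quality flags on the row; they never abort a batch.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import io_stack, roi as roi_mod
from .boutons_vesicle import bouton_features, segment_boutons_vesicle
from .io_stack import Calibration, NmjStackPair
from .outline import count_boutons_watershed, measure_area, measure_perimeter, segment_outline
from .skeleton import (
    DEFAULT_SPUR_PRUNE_UM,
    build_skeleton_graph,
    segment_for_skeleton,
    skeleton_features,
    skeletonize,
)
from .spots import SpotParams, count_active_zones

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "MorphometryResult", "run_convert", "run_analyze", "run_bouton_variant"]

MAIN_COLUMNS = [
    "nmj_id",
    "area_um2",
    "perimeter_um",
    "n_boutons",
    "total_length_um",
    "longest_branch_length_um",
    "n_islands",
    "n_branches",
    "n_branching_points",
    "n_active_zones",
    "flags",
]

BOUTON_COLUMNS = [
    "nmj_id",
    "n_boutons",
    "bouton_area_um2",
    "total_length_um",
    "longest_branch_length_um",
    "n_islands",
    "n_branches",
    "n_branching_points",
    "n_active_zones",
    "flags",
]


@dataclass(frozen=True)
class RunConfig:
    calibration: Calibration = field(default_factory=Calibration)
    marker_kind: str = "dlg1"
    preset: str = "widefield"  # widefield | confocal
    min_particle: int = 100
    filter_on: bool = True
    min_bouton_area: int = 100
    vesicle_min_area: int = 10
    dilation_radius_px: int = 2
    ball_radius: int = 20
    spur_prune_um: float = DEFAULT_SPUR_PRUNE_UM
    noise_tolerance: float | None = None  # override; None = preset default
    min_intensity: float | str | None = None
    exclude: tuple = ()
    pattern: str = io_stack.DEFAULT_PATTERN

    def spot_params(self) -> SpotParams:
        params = SpotParams.confocal() if self.preset == "confocal" else SpotParams.widefield()
        if self.noise_tolerance is not None:
            params = params.with_overrides(noise_tolerance=self.noise_tolerance)
        if self.min_intensity is not None:
            params = params.with_overrides(min_intensity=self.min_intensity)
        return params


@dataclass
class MorphometryResult:
    nmj_id: str
    area_um2: float = 0.0
    perimeter_um: float = 0.0
    n_boutons: int = 0
    bouton_area_um2: float = 0.0
    total_length_um: float = 0.0
    longest_branch_length_um: float = 0.0
    n_islands: int = 0
    n_branches: int = 0
    n_branching_points: int = 0
    n_active_zones: int = 0
    flags: set = field(default_factory=set)

    def row(self, columns) -> str:
        values = []
        for col in columns:
            if col == "flags":
                values.append(",".join(sorted(self.flags)) or "-")
            else:
                v = getattr(self, col)
                values.append(f"{v:.4f}" if isinstance(v, float) else str(v))
        return "\t".join(values)


def run_convert(input_dir, config: RunConfig | None = None) -> list[str]:
    """Assemble per-plane TIFFs into hyperstacks + flats; returns assembled ids."""
    config = config or RunConfig()
    pairs = io_stack.assemble_stacks(
        input_dir, pattern=config.pattern, calibration=config.calibration
    )
    return [p.nmj_id for p in pairs]


def _discover_ids(workspace: Path) -> list[str]:
    ids = set()
    for path in workspace.glob("*_ch2_stack.tif"):
        ids.add(path.name.removesuffix("_ch2_stack.tif"))
    return sorted(ids)


def _load_pair(workspace: Path, nmj_id: str, cal: Calibration) -> NmjStackPair:
    marker = io_stack.read_hyperstack(io_stack.stack_path(workspace, nmj_id, 2))
    spot = io_stack.read_hyperstack(io_stack.stack_path(workspace, nmj_id, 1))
    return NmjStackPair(nmj_id=nmj_id, marker_stack=marker, spot_stack=spot, calibration=cal)


def _overlay(flat: np.ndarray, outline_mask, skel_mask, spot_coords) -> np.ndarray:
    """RGB composite: yellow outline contour, blue skeleton, white spots."""
    lo, hi = float(flat.min()), float(flat.max())
    norm = (flat - lo) / (hi - lo) if hi > lo else np.zeros_like(flat, dtype=float)
    rgb = np.stack([norm] * 3, axis=-1)
    if outline_mask is not None and outline_mask.any():
        from scipy import ndimage as ndi

        contour = outline_mask & ~ndi.binary_erosion(outline_mask)
        rgb[contour] = (1.0, 1.0, 0.0)
    if skel_mask is not None and skel_mask.any():
        rgb[skel_mask] = (0.2, 0.4, 1.0)
    for _, y, x in spot_coords:
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < rgb.shape[0] and 0 <= ix < rgb.shape[1]:
            rgb[iy, ix] = (1.0, 1.0, 1.0)
    return (rgb * 255).astype(np.uint8)


def _write_results(path: Path, columns, results: list[MorphometryResult]) -> None:
    lines = ["\t".join(columns)]
    lines += [r.row(columns) for r in results]
    path.write_text("\n".join(lines) + "\n")


def _analyze_one(
    workspace: Path, nmj_id: str, config: RunConfig, variant: str
) -> MorphometryResult:
    res = MorphometryResult(nmj_id=nmj_id)
    cal = config.calibration
    t0 = time.perf_counter()

    roi_path = roi_mod.roi_file_path(workspace, nmj_id)
    if not roi_path.exists():
        res.flags.add("no_roi")
        return res
    pair = _load_pair(workspace, nmj_id, cal)
    flat_marker = io_stack.max_projection(pair.marker_stack)
    polygon = roi_mod.read_roi_file(roi_path, nmj_id)
    roi = roi_mod.rasterize_polygon(polygon, flat_marker.shape)

    # --- outline / bouton stage -------------------------------------------
    if variant == "main":
        out = segment_outline(
            flat_marker,
            roi,
            min_particle=config.min_particle,
            filter_on=config.filter_on,
            ball_radius=config.ball_radius,
        )
        if out.no_terminal:
            res.flags.add("no_terminal")
        else:
            res.area_um2 = measure_area(out, cal)
            res.perimeter_um = measure_perimeter(out, cal)
            res.n_boutons = count_boutons_watershed(out, config.min_bouton_area).count
        skel_input, empty = segment_for_skeleton(flat_marker, roi, config.marker_kind)
        footprint_mask = out.mask
    else:  # vesicle-marker bouton variant
        bset = segment_boutons_vesicle(
            flat_marker,
            roi,
            min_area=config.vesicle_min_area,
            dilation_radius_px=config.dilation_radius_px,
        )
        if bset.count == 0 and not (bset.labels != 0).any():
            res.flags.add("no_terminal")
        res.n_boutons, res.bouton_area_um2 = bouton_features(bset, cal)
        # skeleton runs on the dilated bouton footprint
        from scipy import ndimage as _ndi
        from skimage import morphology as _morph

        skel_input = bset.labels > 0
        if config.dilation_radius_px > 0:
            skel_input = _ndi.binary_dilation(
                skel_input, structure=_morph.disk(config.dilation_radius_px)
            )
        empty = not skel_input.any()
        footprint_mask = skel_input
        from .outline import OutlineMask as _OM

        out = _OM(footprint_mask, no_terminal=empty)

    # --- skeleton stage ----------------------------------------------------
    skel_mask = None
    if empty:
        res.flags.add("empty_skeleton")
    else:
        skel_mask = skeletonize(skel_input)
        graph = build_skeleton_graph(skel_mask, cal, config.spur_prune_um)
        feats = skeleton_features(graph)
        res.total_length_um = feats.total_length_um
        res.longest_branch_length_um = feats.longest_branch_length_um
        res.n_islands = feats.n_islands
        res.n_branches = feats.n_branches
        res.n_branching_points = feats.n_branching_points
        res.flags |= feats.flags

    # --- spot stage ---------------------------------------------------------
    spot_coords = []
    if footprint_mask is not None and footprint_mask.any():
        spots = count_active_zones(pair, out, roi, config.spot_params())
        res.n_active_zones = spots.count
        res.flags |= spots.flags
        spot_coords = spots.coordinates
    else:
        res.flags.add("no_terminal")

    overlay = _overlay(flat_marker, out.mask if out is not None else None, skel_mask, spot_coords)
    iio.imwrite(workspace / f"{nmj_id}_annotated.png", overlay)
    logger.info("%s analyzed in %.2fs flags=%s", nmj_id, time.perf_counter() - t0, res.flags)
    return res


def _run_batch(workspace_dir, config: RunConfig, variant: str) -> list[MorphometryResult]:
    workspace = Path(workspace_dir)
    config = config or RunConfig()
    columns = MAIN_COLUMNS if variant == "main" else BOUTON_COLUMNS
    results = []
    for nmj_id in _discover_ids(workspace):
        if nmj_id in set(config.exclude):
            logger.info("%s excluded by exclusion list", nmj_id)
            continue
        try:
            results.append(_analyze_one(workspace, nmj_id, config, variant))
        except Exception:
            logger.exception("%s: stage failure", nmj_id)
            res = MorphometryResult(nmj_id=nmj_id)
            res.flags.add("incomplete_stack")
            results.append(res)
    name = "results.txt" if variant == "main" else "results_boutons.txt"
    _write_results(workspace / name, columns, results)
    return results


def run_analyze(workspace_dir, config: RunConfig | None = None) -> list[MorphometryResult]:
    """Nine-feature analysis of every id with a hyperstack and an ROI file."""
    return _run_batch(workspace_dir, config or RunConfig(), "main")


def run_bouton_variant(workspace_dir, config: RunConfig | None = None) -> list[MorphometryResult]:
    """Eight-feature vesicle-marker (Syt/Csp) bouton analysis."""
    cfg = config or RunConfig(marker_kind="syt")
    return _run_batch(workspace_dir, cfg, "bouton")
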