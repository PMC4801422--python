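"""Per-plane TIFF discovery, hyperstack assembly and projections.

Specimens arrive as directories of single-plane grayscale TIFFs, one
file per (NMJ, z-plane, channel), with the identity encoded in the
filename.  The default pattern expects names like ``NMJ007_z03_ch2.tif``
but any regular expression with named groups ``nmj_id``, ``z`` and
``channel`` can be supplied.

Channel convention: channel 1 is the active-zone (spot) marker, e.g.
Brp; channel 2 is the terminal (scaffold) marker, e.g. Dlg1 or Hrp.

Filenames carry 1-based z indices; internal arrays are 0-based with
axis order (z, y, x).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_PATTERN = r"^(?P<nmj_id>.+)_z(?P<z>\d+)_ch(?P<channel>\d+)\.tiff?$"

SPOT_CHANNEL = 1
MARKER_CHANNEL = 2

__all__ = [
    "DEFAULT_PATTERN",
    "SPOT_CHANNEL",
    "MARKER_CHANNEL",
    "UnrecognizedFileError",
    "PlaneKey",
    "Calibration",
    "NmjStackPair",
    "parse_filename",
    "assemble_stacks",
    "max_projection",
    "write_hyperstack",
    "read_hyperstack",
]


class UnrecognizedFileError(ValueError):
    """A filename that does not match the plane-naming pattern."""


@dataclass(frozen=True)
class PlaneKey:
    """Identity of one image plane: which NMJ, which z-slice, which channel."""

    nmj_id: str
    z_index: int  # 1-based, as encoded in the filename
    channel: int  # 1 = spot marker (Brp), 2 = terminal marker

    def __post_init__(self):
        if self.z_index < 1:
            raise ValueError(f"z_index must be >= 1, got {self.z_index}")
        if self.channel not in (1, 2):
            raise ValueError(f"channel out of range: {self.channel} (expected 1 or 2)")


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of a stack.

    Defaults follow a 63x wide-field acquisition: 6.932 px/um in x/y and
    42 planes at 0.3 um z-step.  ``n_planes`` is advisory; the actual
    depth is taken from the files.
    """

    px_per_um_xy: float = 6.932
    z_step_um: float = 0.3
    n_planes: int = 42

    def __post_init__(self):
        if self.px_per_um_xy <= 0:
            raise ValueError("px_per_um_xy must be > 0")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")


@dataclass
class NmjStackPair:
    """The two registered z-stacks of one specimen plus calibration."""

    nmj_id: str
    marker_stack: np.ndarray  # terminal marker (channel 2), shape (z, y, x)
    spot_stack: np.ndarray  # active-zone marker (channel 1), same shape
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self):
        if self.marker_stack.shape != self.spot_stack.shape:
            raise ValueError(
                f"channel stacks differ in shape: {self.marker_stack.shape} "
                f"vs {self.spot_stack.shape}"
            )
        if self.marker_stack.ndim != 3:
            raise ValueError("stacks must be 3D (z, y, x)")


def parse_filename(filename, pattern: str = DEFAULT_PATTERN) -> PlaneKey:
    """Decode (nmj_id, z, channel) from a plane filename.

    Raises :class:`UnrecognizedFileError` when the name does not match;
    an out-of-range z or channel raises :class:`ValueError`.
    """
    name = Path(filename).name
    m = re.match(pattern, name)
    if m is None:
        raise UnrecognizedFileError(f"unrecognized file: {name!r}")
    return PlaneKey(
        nmj_id=m.group("nmj_id"),
        z_index=int(m.group("z")),
        channel=int(m.group("channel")),
    )


def max_projection(stack) -> np.ndarray:
    """Maximum-intensity z-projection (the 'flat stack')."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("expected a non-empty 3D stack")
    return stack.max(axis=0)


def write_hyperstack(path, stack) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def read_hyperstack(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, ...]
    return data


def stack_path(directory, nmj_id: str, channel: int) -> Path:
    return Path(directory) / f"{nmj_id}_ch{channel}_stack.tif"


def flat_path(directory, nmj_id: str, channel: int) -> Path:
    return Path(directory) / f"{nmj_id}_ch{channel}_flat.tif"


def _scan_planes(directory: Path, pattern: str) -> dict[str, dict[int, dict[int, Path]]]:
    """Map nmj_id -> channel -> z_index -> file path, skipping foreign files."""
    planes: dict[str, dict[int, dict[int, Path]]] = {}
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        if path.suffix.lower() not in (".tif", ".tiff"):
            continue
        name = path.name
        # products of a previous run are not input planes
        if name.endswith("_stack.tif") or name.endswith("_flat.tif"):
            continue
        try:
            key = parse_filename(name, pattern)
        except UnrecognizedFileError:
            logger.warning("skipping unrecognized file %s", name)
            continue
        by_channel = planes.setdefault(key.nmj_id, {})
        by_z = by_channel.setdefault(key.channel, {})
        if key.z_index in by_z:
            raise ValueError(f"duplicate plane {key} in {directory}")
        by_z[key.z_index] = path
    return planes


def _complete_depth(by_channel: dict[int, dict[int, Path]]) -> int | None:
    """Common contiguous 1..n depth across both channels, or None."""
    if set(by_channel) != {1, 2}:
        return None
    depths = []
    for ch in (1, 2):
        zs = sorted(by_channel[ch])
        if not zs or zs != list(range(1, zs[-1] + 1)):
            return None
        depths.append(zs[-1])
    if depths[0] != depths[1]:
        return None
    return depths[0]


def assemble_stacks(
    directory,
    pattern: str = DEFAULT_PATTERN,
    calibration: Calibration | None = None,
    write: bool = True,
) -> list[NmjStackPair]:
    """Assemble per-plane TIFFs into two-channel stack pairs.

    One :class:`NmjStackPair` per NMJ id found with complete plane sets
    (planes 1..n present for both channels).  Ids with missing planes
    are excluded with a warning.  When ``write`` is true each channel is
    also persisted as a multi-page hyperstack plus a maximum-intensity
    flat projection; ids whose hyperstacks already exist are re-read
    rather than re-assembled, so re-running is idempotent.
    """
    directory = Path(directory)
    calibration = calibration or Calibration()
    planes = _scan_planes(directory, pattern)

    pairs: list[NmjStackPair] = []
    for nmj_id in sorted(planes):
        spath_m = stack_path(directory, nmj_id, MARKER_CHANNEL)
        spath_s = stack_path(directory, nmj_id, SPOT_CHANNEL)
        if write and spath_m.exists() and spath_s.exists():
            logger.info("%s: already assembled, reusing", nmj_id)
            pairs.append(
                NmjStackPair(
                    nmj_id=nmj_id,
                    marker_stack=read_hyperstack(spath_m),
                    spot_stack=read_hyperstack(spath_s),
                    calibration=calibration,
                )
            )
            continue
        depth = _complete_depth(planes[nmj_id])
        if depth is None:
            logger.warning("%s: incomplete plane set, excluded", nmj_id)
            continue
        stacks = {}
        for ch in (1, 2):
            stacks[ch] = np.stack(
                [tifffile.imread(str(planes[nmj_id][ch][z])) for z in range(1, depth + 1)]
            )
        pair = NmjStackPair(
            nmj_id=nmj_id,
            marker_stack=stacks[MARKER_CHANNEL],
            spot_stack=stacks[SPOT_CHANNEL],
            calibration=calibration,
        )
        if write:
            for ch, stack in ((MARKER_CHANNEL, pair.marker_stack), (SPOT_CHANNEL, pair.spot_stack)):
                write_hyperstack(stack_path(directory, nmj_id, ch), stack)
                tifffile.imwrite(str(flat_path(directory, nmj_id, ch)), max_projection(stack))
        pairs.append(pair)
    return pairs
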