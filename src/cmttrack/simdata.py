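"""Synthetic cell microscopy scenes with controllable density, photometric
domain shift, motion, and division, plus Cell Tracking Challenge (CTC)
layout I/O.

The generator emulates the dataset properties that matter to the adaptation
problem: blob-like cells of tunable size and eccentricity on a textured
background, a tunable cell count per frame (hence imaging density), additive
Gaussian noise, an illumination plane, Gaussian frame-to-frame motion, and
optional division events with CTC parent semantics.  Masks use 16-bit
instance labels with 0 = background.
"""

from __future__ import annotations

import dataclasses
import os
import re
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "SceneConfig", "ShiftSpec", "SyntheticSequence", "PlacementOverflowError",
    "InconsistentSequenceError", "generate_frame", "generate_sequence",
    "apply_domain_shift", "write_ctc_dataset", "read_ctc_dataset",
]

MAX_PLACEMENT_ATTEMPTS = 200


class PlacementOverflowError(RuntimeError):
    """Raised when cells cannot be placed within the attempt budget."""


class InconsistentSequenceError(RuntimeError):
    """Raised when a CTC directory has missing or inconsistent frames."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene; identical config + seed is
    bit-reproducible."""

    frame_size: tuple[int, int] = (96, 96)
    n_cells: int = 8
    cell_radius_range: tuple[float, float] = (5.0, 8.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    intensity_fg: float = 0.75
    intensity_bg: float = 0.25
    noise_sigma: float = 0.03
    illumination_gradient: float = 0.0
    motion_sigma: float = 1.0
    division_prob: float = 0.0
    division_refractory: int = 1   # frames a newborn matures before dividing
    n_frames: int = 1
    min_separation: float = 0.0   # extra centre-to-centre spacing demanded
    seed: int = 0

    def __post_init__(self):
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise ValueError("frame_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class ShiftSpec:
    """Photometric domain shift: gamma remap, contrast/brightness affine,
    an additive illumination plane, and a fresh noise draw.  The identity
    spec leaves the image untouched; masks are never altered."""

    gamma: float = 1.0
    contrast: float = 1.0        # multiplicative, about the 0.5 midpoint
    brightness: float = 0.0      # additive offset
    invert: bool = False
    illumination_gradient: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def is_identity(self) -> bool:
        return (self.gamma == 1.0 and self.contrast == 1.0
                and self.brightness == 0.0 and not self.invert
                and self.illumination_gradient == 0.0 and self.noise_sigma == 0.0)


@dataclass
class SyntheticSequence:
    """Frames, instance masks and a CTC-style track table
    (label, begin frame, end frame, parent label)."""

    frames: list[np.ndarray]
    instance_masks: list[np.ndarray]
    track_table: list[tuple[int, int, int, int]]
    config: SceneConfig | None = None

    def __eq__(self, other):
        if not isinstance(other, SyntheticSequence):
            return NotImplemented
        # masks and the track table are exact; images are compared to the
        # 16-bit quantization step used by the TIFF round trip
        return (len(self.frames) == len(other.frames)
                and all(np.allclose(a, b, atol=1.0 / 65535)
                        for a, b in zip(self.frames, other.frames))
                and all(np.array_equal(a, b)
                        for a, b in zip(self.instance_masks, other.instance_masks))
                and sorted(self.track_table) == sorted(other.track_table))


# ----------------------------------------------------------------- rendering
@dataclass
class _Cell:
    label: int
    row: float
    col: float
    a: float          # semi-major axis, px
    b: float          # semi-minor axis, px
    theta: float      # orientation, rad
    parent: int = 0
    born: int = 0


def _cell_footprint(cell: _Cell, shape) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - cell.row
    dc = cc - cell.col
    ct, st = np.cos(cell.theta), np.sin(cell.theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / cell.a) ** 2 + (v / cell.b) ** 2 <= 1.0


def _sample_cells(cfg: SceneConfig, rng: np.random.Generator) -> list[_Cell]:
    h, w = cfg.frame_size
    rmin, rmax = cfg.cell_radius_range
    if cfg.n_cells > 0 and (h - rmax <= rmax or w - rmax <= rmax):
        raise PlacementOverflowError("frame too small for the cell radius range")
    cells: list[_Cell] = []
    for label in range(1, cfg.n_cells + 1):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            r = rng.uniform(rmin, rmax)
            ecc = rng.uniform(*cfg.eccentricity_range)
            a = r / np.sqrt(np.sqrt(1 - ecc ** 2)) if ecc < 1 else r
            b = r * np.sqrt(np.sqrt(1 - ecc ** 2))
            row = rng.uniform(rmax, h - rmax)
            col = rng.uniform(rmax, w - rmax)
            theta = rng.uniform(0, np.pi)
            if cfg.min_separation > 0:
                too_close = any(
                    np.hypot(c.row - row, c.col - col) < cfg.min_separation
                    for c in cells)
                if too_close:
                    continue
            cells.append(_Cell(label, row, col, a, b, theta))
            break
        else:
            raise PlacementOverflowError(
                f"could not place cell {label} of {cfg.n_cells} within "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts")
    return cells


def _render(cfg: SceneConfig, cells: list[_Cell],
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    h, w = cfg.frame_size
    mask = np.zeros((h, w), dtype=np.uint16)
    # later-drawn cell wins overlapping pixels (deterministic tie-break)
    for cell in cells:
        mask[_cell_footprint(cell, (h, w))] = cell.label
    image = np.full((h, w), cfg.intensity_bg, dtype=np.float64)
    # mild background texture so the background is not a constant plateau
    image += 0.02 * np.sin(np.arange(w) / 7.0)[None, :]
    image[mask > 0] = cfg.intensity_fg
    if cfg.illumination_gradient:
        ramp = np.linspace(-0.5, 0.5, w)[None, :] * cfg.illumination_gradient
        image = image + ramp
    if cfg.noise_sigma:
        image = image + rng.normal(0.0, cfg.noise_sigma, size=(h, w))
    return np.clip(image, 0.0, 1.0), mask


def generate_frame(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame: a grayscale image in [0, 1] and its instance mask."""
    rng = np.random.default_rng(config.seed)
    cells = _sample_cells(config, rng)
    return _render(config, cells, rng)


def generate_sequence(config: SceneConfig) -> SyntheticSequence:
    """Render a video: cells drift with Gaussian displacements, keep their
    labels, and may divide (child tracks record the parent label)."""
    rng = np.random.default_rng(config.seed)
    cells = _sample_cells(config, rng)
    h, w = config.frame_size
    rmax = config.cell_radius_range[1]
    next_label = config.n_cells + 1
    born = {c.label: 0 for c in cells}
    parent_of = {c.label: 0 for c in cells}
    ended: dict[int, int] = {}
    frames, masks = [], []
    for f in range(config.n_frames):
        if f > 0:
            moved: list[_Cell] = []
            for cell in cells:
                mature = (f - cell.born) > config.division_refractory \
                    or cell.parent == 0 and cell.born == 0
                if config.division_prob > 0 and mature \
                        and rng.uniform() < config.division_prob:
                    # terminate the parent; two children start this frame at
                    # offset centroids (CTC parent semantics)
                    ended[cell.label] = f - 1
                    off = max(cell.b, 2.0)
                    ang = rng.uniform(0, np.pi)
                    for sgn in (1.0, -1.0):
                        child = _Cell(
                            next_label,
                            float(np.clip(cell.row + sgn * off * np.sin(ang),
                                          rmax, h - rmax)),
                            float(np.clip(cell.col + sgn * off * np.cos(ang),
                                          rmax, w - rmax)),
                            cell.a / 1.3, cell.b / 1.3, cell.theta,
                            parent=cell.label, born=f)
                        moved.append(child)
                        born[next_label] = f
                        parent_of[next_label] = cell.label
                        next_label += 1
                else:
                    dr, dc = rng.normal(0.0, config.motion_sigma, size=2) \
                        if config.motion_sigma > 0 else (0.0, 0.0)
                    moved.append(dataclasses.replace(
                        cell,
                        row=float(np.clip(cell.row + dr, rmax, h - rmax)),
                        col=float(np.clip(cell.col + dc, rmax, w - rmax))))
            cells = moved
        image, mask = _render(config, cells, rng)
        frames.append(image)
        masks.append(mask)
    for cell in cells:
        ended.setdefault(cell.label, config.n_frames - 1)
    table = [(lab, born[lab], ended[lab], parent_of[lab]) for lab in sorted(born)]
    return SyntheticSequence(frames, masks, table, config)


def apply_domain_shift(image: np.ndarray, shift: ShiftSpec) -> np.ndarray:
    """Photometric remap of an image in [0, 1]; the instance mask is by
    design untouched by any shift."""
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("image must be normalized to [0, 1]")
    if shift.is_identity():
        return image.copy()
    out = np.clip(image, 0.0, 1.0) ** shift.gamma
    if shift.invert:
        out = 1.0 - out
    out = (out - 0.5) * shift.contrast + 0.5 + shift.brightness
    if shift.illumination_gradient:
        h, w = out.shape
        ramp = np.linspace(-0.5, 0.5, w)[None, :] * shift.illumination_gradient
        out = out + ramp
    if shift.noise_sigma:
        rng = np.random.default_rng(shift.seed)
        out = out + rng.normal(0.0, shift.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)


# ------------------------------------------------------------------- CTC I/O
def write_ctc_dataset(seq: SyntheticSequence, directory: str,
                      index_width: int = 3) -> None:
    """Write frames as ``tNNN.tif``, masks as ``man_trackNNN.tif`` and the
    track table as ``man_track.txt`` (rows: label begin end parent)."""
    os.makedirs(directory, exist_ok=True)
    for f, (img, mask) in enumerate(zip(seq.frames, seq.instance_masks)):
        idx = str(f).zfill(index_width)
        tifffile.imwrite(os.path.join(directory, f"t{idx}.tif"),
                         np.round(img * 65535).astype(np.uint16))
        tifffile.imwrite(os.path.join(directory, f"man_track{idx}.tif"),
                         mask.astype(np.uint16))
    with open(os.path.join(directory, "man_track.txt"), "w") as fh:
        for label, begin, end, parent in sorted(seq.track_table):
            fh.write(f"{label} {begin} {end} {parent}\n")


def read_ctc_dataset(directory: str) -> SyntheticSequence:
    """Read a CTC-layout directory back; raises on missing frame indices."""
    frame_files = sorted(f for f in os.listdir(directory)
                         if re.fullmatch(r"t\d+\.tif", f))
    if not frame_files:
        raise InconsistentSequenceError(f"no frames found in {directory}")
    indices = [int(re.findall(r"\d+", f)[0]) for f in frame_files]
    if indices != list(range(len(indices))):
        raise InconsistentSequenceError(
            f"frame indices {indices} are not contiguous from 0")
    frames, masks = [], []
    for f, fname in zip(indices, frame_files):
        width = len(re.findall(r"\d+", fname)[0])
        frames.append(tifffile.imread(os.path.join(directory, fname))
                      .astype(np.float64) / 65535.0)
        mpath = os.path.join(directory, f"man_track{str(f).zfill(width)}.tif")
        if not os.path.exists(mpath):
            raise InconsistentSequenceError(f"missing mask for frame {f}")
        masks.append(tifffile.imread(mpath).astype(np.uint16))
    table = []
    tpath = os.path.join(directory, "man_track.txt")
    if os.path.exists(tpath):
        with open(tpath) as fh:
            for line in fh:
                if line.strip():
                    label, begin, end, parent = map(int, line.split())
                    table.append((label, begin, end, parent))
    return SyntheticSequence(frames, masks, table)
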