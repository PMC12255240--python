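"""Ultrasound tile stitching and calibrated intercondylar measurement.

The ultrasound probe is narrower than the distance between the femoral
condyles, so a sweep is recorded, frames extracted, and the frames stitched
into one panorama on which the distance between the medial and lateral
condyle centres is measured and calibrated from pixels to centimetres.

Registration is translation-only normalized cross-correlation (NCC): the
probe slides laterally in contact with the skin, so perspective warps are
minimal and a deterministic, testable translation model suffices.
Landmarks (condyle centres) are supplied via an annotation JSON — the
measurement protocol is manual clicking by trained raters, not
auto-segmentation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.feature import match_template

logger = logging.getLogger(__name__)


class StitchError(RuntimeError):
    """Raised when a tile pair cannot be registered confidently."""


@dataclass(frozen=True)
class CalibratedMeasurement:
    """One calibrated distance measurement on a (stitched) image."""

    pixel_distance: float
    px_per_cm: float
    distance_cm: float
    rater: str = "r1"
    session: int = 1
    repeat: int = 1

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        expected = self.pixel_distance / self.px_per_cm
        if abs(self.distance_cm - expected) > 1e-9:
            raise ValueError("distance_cm inconsistent with pixel distance / calibration")


def extract_frames(
    source: str | Path | list,
    source_fps: float = 30.0,
    rate_fps: float = 10.0,
) -> list:
    """Ordered grayscale frames subsampled to the target frame rate.

    ``source`` is a directory of image files (sorted by name, the sweep
    order) or an in-memory list of 2-D arrays.  Every ``source_fps /
    rate_fps``-th frame is kept.
    """
    if rate_fps <= 0 or source_fps <= 0:
        raise ValueError("frame rates must be positive")
    if isinstance(source, (str, Path)):
        paths = sorted(
            p
            for p in Path(source).iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not paths:
            raise FileNotFoundError(f"no image frames found in {source}")
        frames = [np.asarray(iio.imread(p), dtype=float) for p in paths]
    else:
        frames = [np.asarray(f, dtype=float) for f in source]
        if not frames:
            raise ValueError("no frames supplied")
    step = max(1, int(round(source_fps / rate_fps)))
    frames = frames[::step]
    out = []
    for f in frames:
        if f.ndim == 3:  # RGB(A) -> luminance
            f = f[..., :3].mean(axis=2)
        out.append(f)
    return out


def _register_pair(left: np.ndarray, right: np.ndarray, min_overlap_frac: float) -> tuple:
    """Horizontal offset of ``right`` relative to ``left`` by NCC.

    A left-edge strip of ``right`` is matched against ``left``; returns
    (offset_px, ncc_peak).
    """
    w = left.shape[1]
    strip_w = max(8, int(min_overlap_frac * w))
    template = right[:, :strip_w]
    corr = match_template(left, template, pad_input=False)
    row = corr[0] if corr.shape[0] == 1 else corr.max(axis=0)
    dx = int(np.argmax(row))
    return dx, float(row[dx])


def stitch(
    tiles: list,
    min_correlation: float = 0.7,
    min_overlap_frac: float = 0.15,
) -> tuple[np.ndarray, list]:
    """Stitch an ordered medial-to-lateral tile sequence into a panorama.

    Consecutive tiles are registered by translation-only NCC; overlapping
    pixels are averaged.  Returns (panorama, per-tile offsets); offsets are
    relative to the first tile.  A correlation peak below
    ``min_correlation`` aborts with a :class:`StitchError` naming the pair.
    """
    tiles = [np.asarray(t, dtype=float) for t in tiles]
    if not tiles:
        raise ValueError("no tiles to stitch")
    if len({t.shape for t in tiles}) != 1:
        raise ValueError("all tiles must share one shape")
    offsets = [0]
    for k in range(1, len(tiles)):
        dx, ncc = _register_pair(tiles[k - 1], tiles[k], min_overlap_frac)
        if ncc < min_correlation:
            raise StitchError(
                f"stitch failure between tiles {k - 1} and {k}: "
                f"NCC peak {ncc:.3f} < {min_correlation}"
            )
        offsets.append(offsets[-1] + dx)
    h, w = tiles[0].shape
    width = offsets[-1] + w
    acc = np.zeros((h, width))
    counts = np.zeros((h, width))
    for off, tile in zip(offsets, tiles):
        acc[:, off : off + w] += tile
        counts[:, off : off + w] += 1.0
    return acc / np.maximum(counts, 1.0), offsets


def measure_distance(
    panorama: np.ndarray,
    landmarks: dict | tuple,
    px_per_cm: float,
    rater: str = "r1",
    session: int = 1,
    repeat: int = 1,
) -> CalibratedMeasurement:
    """Euclidean distance between two annotated points, in centimetres.

    ``landmarks`` is either ``{"medial": [x, y], "lateral": [x, y]}`` or a
    pair of (x, y) tuples in panorama pixel coordinates.
    """
    if isinstance(landmarks, dict):
        p1, p2 = landmarks["medial"], landmarks["lateral"]
    else:
        p1, p2 = landmarks
    h, w = panorama.shape[:2]
    for (x, y) in (p1, p2):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"landmark ({x}, {y}) outside panorama {w}x{h}")
    px = float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))
    return CalibratedMeasurement(
        pixel_distance=px,
        px_per_cm=px_per_cm,
        distance_cm=px / px_per_cm,
        rater=rater,
        session=session,
        repeat=repeat,
    )


def load_landmarks(path: str | Path) -> dict:
    """Read a ``{"medial": [x, y], "lateral": [x, y]}`` annotation file."""
    payload = json.loads(Path(path).read_text())
    for key in ("medial", "lateral"):
        if key not in payload:
            raise ValueError(f"landmark annotation missing {key!r}")
    return payload


def to_midcondylar(distance_cm: float, gender: str, condylar_ratio: dict) -> float:
    """Scale a measured intercondylar distance to the midcondylar estimate.

    The sweep images the condyles superior to the patella with the knee
    flexed, underestimating the contact-point span; gender-specific cadaver
    ratios rescale it.
    """
    if distance_cm <= 0:
        raise ValueError("measured distance must be positive")
    if gender not in condylar_ratio:
        raise ValueError(f"no condylar ratio configured for gender {gender!r}")
    return distance_cm * condylar_ratio[gender]


def aggregate_measurements(measurements: pd.DataFrame) -> float:
    """Per-subject value: grand mean over raters × sessions × repeats.

    Expects a frame with at least a ``distance_cm`` column (and optionally
    rater/session/repeat identifiers).  Logs a warning when fewer than two
    raters contributed.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements to aggregate")
    if "rater" in measurements.columns and measurements["rater"].nunique() < 2:
        logger.warning(
            "aggregating over a single rater (%s); protocol expects two",
            measurements["rater"].iloc[0] if len(measurements) else "none",
        )
    return float(measurements["distance_cm"].mean())


def write_tiles_png(tiles: list, out_dir: str | Path, prefix: str = "tile") -> list:
    """Write tiles as 8-bit PNGs; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, tile in enumerate(tiles):
        arr = np.clip(np.asarray(tile, float), 0.0, 1.0)
        path = out_dir / f"{prefix}_{k:03d}.png"
        iio.imwrite(path, (arr * 255).astype(np.uint8))
        paths.append(path)
    return paths
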