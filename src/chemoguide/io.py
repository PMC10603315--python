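"""Shared data types and I/O for the alignment/motility pipeline.

Coordinate conventions used throughout the package
--------------------------------------------------
* Pixel (0, 0) is the top-left corner; x increases rightward (columns),
  y increases downward (rows), matching raster image order.
* Angles are measured counter-clockwise from the +x axis in a y-up
  mathematical frame, i.e. the image y axis is negated before any
  trigonometry.  Orientation values are axial (defined modulo pi) and
  reported in (-pi/2, pi/2].
* All lengths are micrometers and all times hours past the I/O boundary;
  pixel units never leak into the analysis modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("chemoguide")

#: micrometers per pixel for a 1.1 x 1.1 mm field of view at 1024 x 1024 px
DEFAULT_PIXEL_SIZE_UM = 1.1e3 / 1024

VALID_CHANNELS = ("fibers", "cells", "dye")


@dataclass(frozen=True)
class ImageFrame:
    """One grayscale frame of one channel at one time point.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Nonnegative intensity grid.
    pixel_size_um : float
        Micrometers per pixel (> 0).
    channel : str
        One of ``"fibers"``, ``"cells"``, ``"dye"``.
    time_h : float
        Acquisition time in hours.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "fibers"
    time_h: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.min() < 0:
            raise ValueError("pixels must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometers."""
        h, w = self.pixels.shape
        return w * self.pixel_size_um, h * self.pixel_size_um


@dataclass(frozen=True)
class ImageStack:
    """Time-ordered single-channel stack with a constant frame interval."""

    frames: tuple[ImageFrame, ...]
    frame_interval_h: float = 1.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("ImageStack requires at least one frame")
        f0 = frames[0]
        for f in frames[1:]:
            if f.shape != f0.shape:
                raise ValueError("all frames must share dimensions")
            if f.channel != f0.channel:
                raise ValueError("all frames must share channel")
            if f.pixel_size_um != f0.pixel_size_um:
                raise ValueError("all frames must share pixel_size_um")
        times = [f.time_h for f in frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]

    @property
    def channel(self) -> str:
        return self.frames[0].channel

    @property
    def pixel_size_um(self) -> float:
        return self.frames[0].pixel_size_um

    @property
    def times_h(self) -> np.ndarray:
        return np.array([f.time_h for f in self.frames])


@dataclass(frozen=True)
class DeviceGeometry:
    """Device geometry: inner-reservoir center, radius and pixel scale.

    The radial unit vector r-hat at any point p != center is
    (p - center) / |p - center|; the chemotactic gradient points along
    -r-hat (toward the center, where the attractant source sits).
    """

    center_px: tuple[float, float]
    inner_radius_um: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.inner_radius_um < 0:
            raise ValueError("inner_radius_um must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def center_um(self) -> np.ndarray:
        return np.asarray(self.center_px, dtype=float) * self.pixel_size_um

    def radius_um(self, points_um: np.ndarray) -> np.ndarray:
        """Distance from the device center, micrometers."""
        d = np.atleast_2d(points_um) - self.center_um
        r = np.hypot(d[..., 0], d[..., 1])
        return r if np.ndim(points_um) > 1 else float(r[0])

    def radial_unit(self, points_um: np.ndarray) -> np.ndarray:
        """Outward radial unit vector(s) r-hat at the given point(s).

        Zero vector where a point coincides with the center.
        """
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        d = p - self.center_um
        r = np.hypot(d[:, 0], d[:, 1])
        out = np.zeros_like(d)
        ok = r > 0
        out[ok] = d[ok] / r[ok, None]
        return out if np.ndim(points_um) > 1 else out[0]

    def azimuth_rad(self, points_um: np.ndarray) -> np.ndarray:
        """Azimuth of point(s) about the center, y-up convention.

        theta = atan2(-(y - cy), x - cx) so that a point displaced along
        image +y (downward) has theta = -pi/2.
        """
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        d = p - self.center_um
        th = np.arctan2(-d[:, 1], d[:, 0])
        return th if np.ndim(points_um) > 1 else float(th[0])


def fold_axial(angle_rad: np.ndarray | float) -> np.ndarray | float:
    """Fold angle(s) to the axial range (-pi/2, pi/2] (nematic convention)."""
    a = np.asarray(angle_rad, dtype=float)
    b = (a + np.pi / 2) % np.pi - np.pi / 2
    b = np.where(b == -np.pi / 2, np.pi / 2, b)
    return b if a.ndim else float(b)


def axial_difference_rad(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    """Smallest angle between two axial (headless) directions, in [0, pi/2]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % np.pi
    out = np.minimum(d, np.pi - d)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# readers / writers


def read_stack(
    path: str | Path,
    channel: str,
    pixel_size_um: float | None = None,
    frame_interval_h: float = 1.0,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Page *k* is stamped at time ``k * frame_interval_h``.  Intensities are
    preserved bit-exactly as read.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            axes = tif.series[0].axes
            arr = tif.asarray()
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    if "S" in axes or arr.ndim not in (2, 3):
        raise ValueError(
            f"{path}: expected grayscale pages, got axes {axes!r} shape {arr.shape}; "
            "extract a single channel upstream"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if pixel_size_um is None:
        pixel_size_um = DEFAULT_PIXEL_SIZE_UM
        logger.warning(
            "pixel size not specified for %s; using default %.4f um/px",
            path,
            pixel_size_um,
        )
    frames = tuple(
        ImageFrame(page, pixel_size_um, channel, k * frame_interval_h)
        for k, page in enumerate(arr)
    )
    return ImageStack(frames, frame_interval_h)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), np.stack([f.pixels for f in stack]))


def write_table(records: Sequence[dict], path: str | Path) -> None:
    """Write keyed rows as CSV with a header; floats keep >= 6 significant digits."""
    df = pd.DataFrame.from_records(list(records))
    try:
        df.to_csv(Path(path), index=False, float_format="%.8g")
    except OSError as exc:
        raise IOError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "geometry": {
        "center_px": [512, 512],
        "inner_radius_um": 500.0,
        "pixel_size_um": DEFAULT_PIXEL_SIZE_UM,
    },
    "orientation": {
        "gradient_sigma_px": 1.0,
        "window_sigma_px": 8.0,
        "energy_quantile": 0.5,
    },
    "segmentation": {
        "threshold_method": "otsu",
        "min_area_um2": 100.0,
        "max_area_um2": 10000.0,
        "min_solidity": 0.3,
    },
    "tracking": {
        "max_step_um": 30.0,
        "min_displacement_um": 0.5 * DEFAULT_PIXEL_SIZE_UM,
    },
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, merged over :data:`DEFAULT_CONFIG`."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict):
                cfg.setdefault(section, {}).update(values)
            else:
                cfg[section] = values
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def geometry_from_config(cfg: dict) -> DeviceGeometry:
    g = cfg["geometry"]
    return DeviceGeometry(
        center_px=tuple(g["center_px"]),
        inner_radius_um=float(g["inner_radius_um"]),
        pixel_size_um=float(g["pixel_size_um"]),
    )
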