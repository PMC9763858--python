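"""Image-stack and table I/O.

Image sequences travel as OME-TIFF; the physical pixel size is read from the
OME ``PhysicalSizeX`` element when present and must otherwise be supplied
explicitly — it is never silently defaulted.  Tabular artifacts are plain CSV
with physical units in the column names.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError, ParameterError


class _ListHandler(logging.Handler):
    def __init__(self, sink: list) -> None:
        super().__init__()
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(record)


@dataclass
class ImageStack:
    """Time-ordered 2D intensity frames with physical metadata.

    frames are camera counts, shape (T, H, W); ``pixel_size_nm`` is the lateral
    sampling; ``frame_interval_s`` the time between frames; ``t0_frame`` the
    index of the first laser-exposed frame.
    """

    frames: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float = 1.0 / 77.0
    t0_frame: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ParameterError("frames must be a (T, H, W) array with T >= 1")
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")
        if not 0 <= self.t0_frame < self.frames.shape[0]:
            raise ParameterError("t0_frame outside stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an OME-TIFF carrying the pixel size (µm) in its metadata."""
    px_um = stack.pixel_size_nm / 1000.0
    tifffile.imwrite(
        str(path),
        np.asarray(stack.frames, dtype=np.float32),
        ome=True,
        metadata={
            "axes": "TYX",
            "PhysicalSizeX": px_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": px_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": stack.frame_interval_s,
            "TimeIncrementUnit": "s",
        },
    )


def _ome_pixel_size_nm(tif: tifffile.TiffFile) -> float | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    try:
        d = tifffile.xml2dict(meta)
        pixels = d["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
        size = float(pixels["PhysicalSizeX"])
        unit = pixels.get("PhysicalSizeXUnit", "µm")
    except (KeyError, TypeError, ValueError):
        return None
    scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "mm": 1e6}.get(unit)
    return size * scale if scale else None


def _ome_frame_interval_s(tif: tifffile.TiffFile) -> float | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    try:
        d = tifffile.xml2dict(meta)
        pixels = d["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        return float(pixels["Pixels"]["TimeIncrement"])
    except (KeyError, TypeError, ValueError):
        return None


def _ome_size_t(tif: tifffile.TiffFile) -> int | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    try:
        d = tifffile.xml2dict(meta)
        pixels = d["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        return int(pixels["Pixels"]["SizeT"])
    except (KeyError, TypeError, ValueError):
        return None


def read_image_stack(
    path: str | Path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
    t0_frame: int = 0,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack in acquisition order.

    Explicit arguments override file metadata.  A missing pixel size with no
    override raises :class:`ConfigurationError`; unreadable or truncated files
    raise :class:`FormatError` and never yield a partial stack.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    # tifffile reports structural damage (truncated pages, bad tag offsets)
    # through its logger while still returning the salvageable pages; a
    # partial stack must never be silently accepted
    tiff_log: list[logging.LogRecord] = []
    capture = _ListHandler(tiff_log)
    tiff_logger = logging.getLogger("tifffile")
    tiff_logger.addHandler(capture)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray()
            declared_t = _ome_size_t(tif)
            if pixel_size_nm is None:
                pixel_size_nm = _ome_pixel_size_nm(tif)
            if frame_interval_s is None:
                frame_interval_s = _ome_frame_interval_s(tif)
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises a zoo of error types
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    finally:
        tiff_logger.removeHandler(capture)
    damage = [r for r in tiff_log if r.levelno >= logging.WARNING]
    if damage:
        raise FormatError(
            f"{path} is damaged or truncated: {damage[0].getMessage()}")
    if declared_t is not None and frames.ndim >= 1 and len(frames) != declared_t:
        raise FormatError(
            f"{path} is truncated: metadata declares {declared_t} frames, "
            f"file holds {len(frames)}")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path} is not a T x H x W stack (shape {frames.shape})")
    if pixel_size_nm is None:
        raise ConfigurationError(
            f"{path} carries no pixel size; pass pixel_size_nm explicitly"
        )
    return ImageStack(
        frames=np.asarray(frames, dtype=np.float64),
        pixel_size_nm=float(pixel_size_nm),
        frame_interval_s=float(frame_interval_s) if frame_interval_s else 1.0 / 77.0,
        t0_frame=t0_frame,
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(records: Sequence, path: str | Path,
                config_hash: str | None = None) -> pd.DataFrame:
    """Write dataclass records (or dicts) as a CSV with a header row.

    Ordering is exactly the input ordering, so identical inputs produce
    byte-identical files.  If ``config_hash`` is given it is stamped into a
    ``config_hash`` column so every table records the configuration that
    produced it.
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            row = dataclasses.asdict(rec)
        elif isinstance(rec, dict):
            row = dict(rec)
        else:
            raise ParameterError(f"cannot tabulate record of type {type(rec)!r}")
        rows.append(row)
    if rows:
        keys = list(rows[0])
        for row in rows:
            if list(row) != keys:
                raise ParameterError("records do not share a schema")
    df = pd.DataFrame(rows)
    if config_hash is not None:
        df["config_hash"] = config_hash
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# region-of-interest masks
# ---------------------------------------------------------------------------

def read_roi_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a cell-boundary ROI.

    Accepts a single-plane TIFF (nonzero = inside the cell) or a CSV of
    polygon vertices with columns ``x_px, y_px``, rasterized onto ``shape``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if shape is None:
            raise ParameterError("rasterizing a polygon ROI needs a target shape")
        df = pd.read_csv(path)
        if not {"x_px", "y_px"} <= set(df.columns):
            raise FormatError(f"{path}: polygon ROI needs x_px,y_px columns")
        from skimage.draw import polygon

        rr, cc = polygon(df["y_px"].to_numpy(), df["x_px"].to_numpy(), shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read ROI {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"ROI {path} must be a single plane")
    return arr != 0
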