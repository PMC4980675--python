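"""Readers and writers: numbered image stacks and unit-annotated CSV tables.

Stacks are numbered single-image files (``ir_000001.tif`` /
``gfp_000001.tif``; PNG works the same way), one file per frame and
channel.  Intensities are stored as 16-bit (or 8-bit) grayscale and mapped
back to [0, 1] floats on read.  CSV tables carry a leading ``#`` comment
line stating the units of each column; ``read_table`` skips it.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .segmentation import FramePair


def _to_stored(img: np.ndarray, dtype: str) -> np.ndarray:
    if dtype == "uint8":
        return (np.clip(img, 0, 1) * 255).astype(np.uint8)
    if dtype == "uint16":
        return (np.clip(img, 0, 1) * 65535).astype(np.uint16)
    return img.astype(np.float32)


def _to_float(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float32) / 65535.0
    return img.astype(np.float32)


def write_stacks(frames, outdir: str | Path, dtype: str = "uint16",
                 fmt: str = "tif") -> int:
    """Write a frame sequence as numbered IR/GFP image files; returns the
    number of frames written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = 0
    for frame in frames:
        for name, img in (("ir", frame.ir), ("gfp", frame.gfp)):
            path = outdir / f"{name}_{frame.frame_index + 1:06d}.{fmt}"
            data = _to_stored(img, dtype)
            if fmt in ("tif", "tiff"):
                tifffile.imwrite(path, data)
            else:
                iio.imwrite(path, data)
        n += 1
    return n


class StackReader:
    """Lazy FramePair reader over two numbered image stacks."""

    def __init__(self, ir_files: list[Path], gfp_files: list[Path], fps: float):
        if len(ir_files) != len(gfp_files):
            raise ValueError(
                f"IR and GFP stacks differ in length ({len(ir_files)} vs {len(gfp_files)})")
        if not ir_files:
            raise ValueError("empty image stacks")
        self.ir_files = ir_files
        self.gfp_files = gfp_files
        self.fps = fps

    def __len__(self) -> int:
        return len(self.ir_files)

    def __getitem__(self, i: int) -> FramePair:
        ir = _to_float(_read_image(self.ir_files[i]))
        gfp = _to_float(_read_image(self.gfp_files[i]))
        return FramePair(ir=ir, gfp=gfp, frame_index=i, time=i / self.fps)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def open_stacks(directory: str | Path, fps: float,
                ir_prefix: str = "ir_", gfp_prefix: str = "gfp_") -> StackReader:
    """Open the IR and GFP stacks found under ``directory`` (by prefix)."""
    directory = Path(directory)
    ir = sorted(p for p in directory.iterdir()
                if p.name.startswith(ir_prefix) and p.suffix.lower() in
                (".tif", ".tiff", ".png"))
    gfp = sorted(p for p in directory.iterdir()
                 if p.name.startswith(gfp_prefix) and p.suffix.lower() in
                 (".tif", ".tiff", ".png"))
    return StackReader(ir, gfp, fps)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

FEATURE_UNITS = ("frame [-], time_s [s], id [-], x_mm [mm], y_mm [mm], "
                 "bending_deg [deg], velocity_mm_s [mm/s], is_bend30 [-], "
                 "is_bend40 [-], b_gfp [-], in_collision [-], axis_x [-], axis_y [-]")


def write_table(df: pd.DataFrame, path: str | Path, units: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if units:
            fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
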