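"""TIFF stack I/O, waveform extraction, and ROI selection.

Recordings are stored as multi-page grayscale TIFF (lossless), one page per
frame, with an optional YAML sidecar carrying the frame rate, pixel pitch,
cohort label and seed. Waveforms export to CSV with ``time_s, luminance``
columns.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FrameStack, Waveform
from .smoothing import moving_average
from .spectral import THRILL_BAND

__all__ = [
    "read_stack",
    "write_stack",
    "extract_waveform",
    "auto_select_roi",
    "waveform_to_csv",
    "waveform_from_csv",
]

_SIDE_KEYS = ("fps", "pixel_pitch_mm", "cohort_label", "seed")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page grayscale TIFF plus a YAML sidecar.

    The array is written with its native dtype, so a read-back reproduces the
    pixel values exactly.
    """
    path = Path(path)
    data = stack.data
    if not (np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.floating)):
        raise ValueError(f"unsupported dtype {data.dtype}")
    tifffile.imwrite(path, data, photometric="minisblack")
    side = {
        "fps": float(stack.fps),
        "pixel_pitch_mm": float(stack.pixel_pitch_mm),
    }
    for key in ("cohort_label", "seed", "quant_offset", "quant_gain", "config_hash"):
        if key in stack.meta:
            side[key] = stack.meta[key]
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=True)
    return path


def read_stack(
    path: str | Path, fps: float | None = None, pixel_pitch_mm: float | None = None
) -> FrameStack:
    """Read a multi-page grayscale TIFF into a :class:`FrameStack`.

    Sampling metadata comes from an explicit argument, else the YAML sidecar,
    else the defaults (40 fps, 0.08 mm pitch).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.series) != 1:
            raise ValueError(f"{path.name}: pages of unequal shape (multiple series)")
        series = tf.series[0]
        if "S" in series.axes:
            raise ValueError(f"{path.name}: non-grayscale pages (sample axis present)")
        data = series.asarray()
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected grayscale pages, got array of ndim {data.ndim}"
        )
    meta: dict = {"source": str(path)}
    side = _sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            loaded = yaml.safe_load(fh) or {}
        meta.update({k: v for k, v in loaded.items() if k not in ("fps", "pixel_pitch_mm")})
        if fps is None:
            fps = loaded.get("fps")
        if pixel_pitch_mm is None:
            pixel_pitch_mm = loaded.get("pixel_pitch_mm")
    return FrameStack(
        data,
        fps=float(fps) if fps is not None else 40.0,
        pixel_pitch_mm=float(pixel_pitch_mm) if pixel_pitch_mm is not None else 0.08,
        meta=meta,
    )


def extract_waveform(stack: FrameStack, roi_center: tuple[int, int]) -> Waveform:
    """Time series of the single pixel at ``roi_center`` (row, col).

    Spatial context enters only through prior moving-average smoothing; this
    operation is a pure projection.
    """
    row, col = roi_center
    return Waveform(stack.pixel_series(row, col).astype(float), fs=stack.fps)


def _band_power_map(stack: FrameStack, band: tuple[float, float]) -> np.ndarray:
    """Per-pixel power in ``band`` from a full-length DFT (mean removed)."""
    data = stack.data.astype(float)
    data = data - data.mean(axis=0, keepdims=True)
    spec = np.fft.rfft(data, axis=0)
    freqs = np.fft.rfftfreq(stack.n_frames, d=1.0 / stack.fps)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return (np.abs(spec[mask]) ** 2).sum(axis=0)


def auto_select_roi(stack: FrameStack, kernel_n: int = 21) -> tuple[int, int]:
    """Pick the analysis pixel: maximal thrill-band power after smoothing.

    The stack is smoothed with a default 21 x 21 moving average (clipped to
    the image if smaller), then the pixel with the largest 5-10 Hz band power
    is returned; ties break in row-major order. Deterministic.
    """
    if stack.n_frames < 256:
        raise ValueError(
            f"need at least 256 frames for spectral ROI selection, got {stack.n_frames}"
        )
    n = min(kernel_n, min(stack.rows, stack.cols))
    if n % 2 == 0:
        n -= 1
    smoothed = moving_average(stack, n)
    power = _band_power_map(smoothed, THRILL_BAND)
    flat = int(np.argmax(power))
    return (flat // stack.cols, flat % stack.cols)


def waveform_to_csv(w: Waveform, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": w.times, "luminance": w.samples}).to_csv(path, index=False)
    return path


def waveform_from_csv(path: str | Path) -> Waveform:
    df = pd.read_csv(path)
    if len(df) < 2:
        raise ValueError("waveform CSV needs at least two samples")
    dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    return Waveform(df["luminance"].to_numpy(), fs=1.0 / dt)
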