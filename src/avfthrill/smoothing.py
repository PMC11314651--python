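"""Spatial moving-average filtering of frame stacks.

Non-contact luminance recordings are dominated by per-pixel diffuse-reflection
noise. Smoothing every frame with a uniform N x N kernel (N odd) suppresses
spatially incoherent noise by ~N^2 in power while the spatially smooth
vascular signal survives, which is the basis of the kernel-size sweep used by
the SNR analysis.

Edges are handled by replicate padding so the output has the input's shape and
constant images are preserved exactly; borders are a documented convention, as
any choice there is.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import FrameStack

__all__ = [
    "Kernel",
    "moving_average",
    "sweep_kernels",
    "default_kernel_grid",
    "smoothed_pixel_series",
]


def _check_size(size_n: int, rows: int | None = None, cols: int | None = None) -> None:
    if size_n < 1 or size_n % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {size_n}")
    if rows is not None and size_n > min(rows, cols):
        raise ValueError(
            f"kernel size {size_n} exceeds image extent {rows}x{cols}"
        )


@dataclass(frozen=True)
class Kernel:
    """Uniform N x N averaging kernel; every coefficient is 1/N^2."""

    size_n: int

    def __post_init__(self) -> None:
        _check_size(self.size_n)

    @property
    def weights(self) -> np.ndarray:
        n = self.size_n
        return np.full((n, n), 1.0 / (n * n))


def default_kernel_grid(n_min: int = 1, n_max: int = 201, step: int = 2) -> list[int]:
    """Odd kernel sizes swept by default: 1, 3, ..., 201 (101 values)."""
    grid = [n for n in range(n_min, n_max + 1, step) if n % 2 == 1]
    if not grid:
        raise ValueError("empty kernel grid")
    return grid


def moving_average(stack: FrameStack, size_n: int) -> FrameStack:
    """Smooth every frame with a centered uniform ``size_n`` x ``size_n`` mean.

    Returns a new :class:`FrameStack` of identical shape; ``size_n = 1`` is the
    identity. Replicate padding at the borders.
    """
    _check_size(size_n, stack.rows, stack.cols)
    if size_n == 1:
        out = stack.data.astype(float, copy=True)
    else:
        out = ndimage.uniform_filter(
            stack.data.astype(float), size=(1, size_n, size_n), mode="nearest"
        )
    meta = dict(stack.meta)
    meta["kernel_n"] = size_n
    return FrameStack(out, fps=stack.fps, pixel_pitch_mm=stack.pixel_pitch_mm, meta=meta)


def sweep_kernels(
    stack: FrameStack, n_values: list[int] | None = None
) -> dict[int, FrameStack]:
    """Apply :func:`moving_average` for every kernel size in ``n_values``.

    Defaults to the odd grid 1..201, i.e. 101 smoothed versions of the
    recording.
    """
    if n_values is None:
        n_values = default_kernel_grid()
    return {n: moving_average(stack, n) for n in n_values}


def smoothed_pixel_series(
    stack: FrameStack,
    roi: tuple[int, int],
    size_n: int,
    _padded: np.ndarray | None = None,
    _pad: int = 0,
) -> np.ndarray:
    """Time series of one pixel after N x N smoothing, computed directly.

    Equivalent to ``moving_average(stack, size_n).data[:, row, col]`` but only
    evaluates the window around the requested pixel, which makes kernel sweeps
    cheap. ``_padded``/``_pad`` let callers reuse a replicate-padded copy of
    the stack across kernel sizes.
    """
    _check_size(size_n, stack.rows, stack.cols)
    row, col = roi
    if not (0 <= row < stack.rows and 0 <= col < stack.cols):
        raise IndexError(f"roi {roi} outside {stack.rows}x{stack.cols} image")
    hw = (size_n - 1) // 2
    if _padded is None:
        _pad = hw
        _padded = np.pad(
            stack.data.astype(float), ((0, 0), (hw, hw), (hw, hw)), mode="edge"
        )
    if _pad < hw:
        raise ValueError("padded stack too small for requested kernel")
    r0 = row + _pad - hw
    c0 = col + _pad - hw
    window = _padded[:, r0 : r0 + size_n, c0 : c0 + size_n]
    return window.mean(axis=(1, 2))
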