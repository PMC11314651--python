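"""Core in-memory containers for luminance recordings.

A non-contact recording of an arteriovenous fistula (AVF) is a stack of
grayscale frames sampled at a fixed frame rate; every pixel carries a
luminance time series whose spectral content encodes the pulse and the
thrill vibration of the vessel wall.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameStack", "Waveform", "DegenerateInputError"]


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but makes the requested
    quantity undefined (zero noise power, constant waveform, ...)."""


@dataclass
class FrameStack:
    """Time-ordered stack of grayscale frames.

    Parameters
    ----------
    data
        3-D luminance array indexed ``(frame, row, col)``. Arbitrary
        luminance units; any real dtype.
    fps
        Frame rate in Hz (frames per second).
    pixel_pitch_mm
        Physical pixel size in mm (square pixels assumed).
    meta
        Free-form provenance mapping (seed, cohort label, source path, ...).
    """

    data: np.ndarray
    fps: float = 40.0
    pixel_pitch_mm: float = 0.08
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"FrameStack.data must be 3-D (frame, row, col); got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("FrameStack needs at least one frame")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def rows(self) -> int:
        return self.data.shape[1]

    @property
    def cols(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        """Luminance time series of one pixel (bounds-checked)."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(
                f"pixel ({row}, {col}) outside {self.rows}x{self.cols} image"
            )
        return self.data[:, row, col]


@dataclass
class Waveform:
    """1-D luminance time series at a fixed sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ValueError("Waveform needs at least one sample")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs
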