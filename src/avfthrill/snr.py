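"""Thrill-band SNR across the kernel-size sweep.

For one recording and one kernel size N, the statistic is

    SNR_thr(N) = Peak_thrill(N) / Peak_noise(N)

where Peak_thrill(N) is the median, across overlapping Hann-windowed FFT
segments, of the per-segment peak power inside the 5-10 Hz thrill band after
band-pass filtering the smoothed pixel waveform to that band, and
Peak_noise(N) is computed identically for the 15-20 Hz noise reference band.
The ratio is dimensionless and invariant to global luminance scaling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DegenerateInputError, FrameStack, Waveform
from .smoothing import default_kernel_grid, smoothed_pixel_series
from .spectral import NOISE_BAND, THRILL_BAND, band_peak, bandpass, segment_spectra

__all__ = [
    "BandPeaks",
    "SnrCurve",
    "band_peaks_for_kernel",
    "snr_thr",
    "snr_curve",
    "curves_to_frame",
    "curves_to_csv",
    "curves_from_csv",
]


@dataclass(frozen=True)
class BandPeaks:
    """Median band-peak powers for one recording at one kernel size."""

    kernel_n: int
    peak_thrill: float
    peak_noise: float

    def __post_init__(self) -> None:
        if self.peak_thrill < 0 or self.peak_noise < 0:
            raise ValueError("band peak powers must be nonnegative")


@dataclass
class SnrCurve:
    """SNR_thr(N) over a kernel-size grid for one recording."""

    kernel_n: np.ndarray
    snr: np.ndarray
    peak_thrill: np.ndarray
    peak_noise: np.ndarray
    recording_id: str = ""
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.kernel_n = np.asarray(self.kernel_n, dtype=int)
        self.snr = np.asarray(self.snr, dtype=float)
        self.peak_thrill = np.asarray(self.peak_thrill, dtype=float)
        self.peak_noise = np.asarray(self.peak_noise, dtype=float)
        if not (
            len(self.kernel_n) == len(self.snr) == len(self.peak_thrill) == len(self.peak_noise)
        ):
            raise ValueError("curve arrays must share length")
        if np.any(np.diff(self.kernel_n) <= 0) or np.any(self.kernel_n % 2 == 0):
            raise ValueError("kernel sizes must be strictly increasing odd integers")
        if np.any(self.snr < 0):
            raise ValueError("snr must be nonnegative")

    def snr_at(self, n: int) -> float:
        idx = np.flatnonzero(self.kernel_n == n)
        if idx.size == 0:
            raise KeyError(f"kernel size {n} not in curve")
        return float(self.snr[idx[0]])


def _median_band_peak(
    w: Waveform, band: tuple[float, float], nfft: int, overlap: float
) -> float:
    filtered = bandpass(w, band[0], band[1])
    spectra = segment_spectra(filtered, nfft=nfft, overlap=overlap)
    return float(np.median([band_peak(s, band[0], band[1]) for s in spectra]))


def band_peaks_for_kernel(
    stack: FrameStack,
    roi: tuple[int, int],
    kernel_n: int,
    nfft: int = 256,
    overlap: float = 0.75,
    thrill_band: tuple[float, float] = THRILL_BAND,
    noise_band: tuple[float, float] = NOISE_BAND,
    _padded: np.ndarray | None = None,
    _pad: int = 0,
) -> BandPeaks:
    """Median thrill-band and noise-band peak powers at one kernel size.

    Pipeline: N x N moving average -> ROI pixel waveform -> band-pass ->
    segmented Hann/FFT power spectra -> per-segment in-band peak -> median.
    The smoothing is evaluated directly at the ROI (identical to filtering
    the whole frame), so kernel sweeps stay cheap.
    """
    if stack.n_frames < nfft:
        raise ValueError(f"recording must contain at least {nfft} frames")
    series = smoothed_pixel_series(stack, roi, kernel_n, _padded=_padded, _pad=_pad)
    w = Waveform(series, fs=stack.fps)
    return BandPeaks(
        kernel_n=kernel_n,
        peak_thrill=_median_band_peak(w, thrill_band, nfft, overlap),
        peak_noise=_median_band_peak(w, noise_band, nfft, overlap),
    )


def snr_thr(bp: BandPeaks) -> float:
    """SNR_thr = Peak_thrill / Peak_noise; undefined for zero noise power."""
    if bp.peak_noise == 0:
        raise DegenerateInputError(
            "noise-band peak power is zero (noiseless input); SNR undefined"
        )
    return bp.peak_thrill / bp.peak_noise


def snr_curve(
    stack: FrameStack,
    roi: tuple[int, int],
    n_values: list[int] | None = None,
    nfft: int = 256,
    overlap: float = 0.75,
    recording_id: str = "",
    cohort_label: str = "",
) -> SnrCurve:
    """SNR_thr(N) over a kernel grid (default: odd 1..201, 101 values).

    The same ROI pixel is used for every kernel size.
    """
    if n_values is None:
        n_values = default_kernel_grid()
    n_values = sorted(int(n) for n in n_values)
    hw_max = (max(n_values) - 1) // 2
    padded = np.pad(
        stack.data.astype(float), ((0, 0), (hw_max, hw_max), (hw_max, hw_max)), mode="edge"
    )
    peaks = [
        band_peaks_for_kernel(
            stack, roi, n, nfft=nfft, overlap=overlap, _padded=padded, _pad=hw_max
        )
        for n in n_values
    ]
    return SnrCurve(
        kernel_n=np.array(n_values),
        snr=np.array([snr_thr(bp) for bp in peaks]),
        peak_thrill=np.array([bp.peak_thrill for bp in peaks]),
        peak_noise=np.array([bp.peak_noise for bp in peaks]),
        recording_id=recording_id or stack.meta.get("recording_id", ""),
        cohort_label=cohort_label or stack.meta.get("cohort_label", ""),
    )


def curves_to_frame(curves: list[SnrCurve]) -> pd.DataFrame:
    """Long-format interchange table for the optimizer and group statistics."""
    rows = []
    for c in curves:
        for k in range(len(c.kernel_n)):
            rows.append(
                {
                    "recording_id": c.recording_id,
                    "cohort_label": c.cohort_label,
                    "kernel_n": int(c.kernel_n[k]),
                    "peak_thrill": float(c.peak_thrill[k]),
                    "peak_noise": float(c.peak_noise[k]),
                    "snr": float(c.snr[k]),
                }
            )
    return pd.DataFrame(rows)


def curves_to_csv(curves: list[SnrCurve], path: str | Path, header_comment: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        curves_to_frame(curves).to_csv(fh, index=False)
    return path


def curves_from_csv(path: str | Path) -> list[SnrCurve]:
    df = pd.read_csv(path, comment="#")
    out = []
    for rid, grp in df.groupby("recording_id", sort=True):
        grp = grp.sort_values("kernel_n")
        out.append(
            SnrCurve(
                kernel_n=grp["kernel_n"].to_numpy(),
                snr=grp["snr"].to_numpy(),
                peak_thrill=grp["peak_thrill"].to_numpy(),
                peak_noise=grp["peak_noise"].to_numpy(),
                recording_id=str(rid),
                cohort_label=str(grp["cohort_label"].iloc[0]),
            )
        )
    return out
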