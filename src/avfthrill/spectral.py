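"""Band filtering, windowed FFT power spectra, and harmonic analysis.

The pulse waveform measured over an arteriovenous fistula is a composite of
the arterial pulse (a fundamental near 1-2 Hz with integer harmonics of
decaying amplitude) and the thrill vibration, a quasi-periodic component
confined to 5-10 Hz. Wide-band sensor/skin noise extends to the Nyquist
frequency; 15-20 Hz serves as a pure-noise reference band at a 40 Hz frame
rate.

Conventions
-----------
* Filters are 4th-order Butterworth applied forward-backward (zero phase).
  A requested band edge at or above 0.99 x Nyquist is clamped to
  0.99 x Nyquist, so the 15-20 Hz band at 40 Hz sampling is realisable.
* Power spectra come from 256-sample segments with 75% overlap, per-segment
  mean removal, and a Hann taper. One-sided power is scaled so that its sum
  equals the energy of the tapered segment (Parseval).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import DegenerateInputError, Waveform

__all__ = [
    "PowerSpectrum",
    "HarmonicReport",
    "bandpass",
    "lowpass",
    "segment_spectra",
    "band_peak",
    "harmonic_analysis",
    "lpf_correlation_curve",
    "THRILL_BAND",
    "NOISE_BAND",
]

THRILL_BAND = (5.0, 10.0)
NOISE_BAND = (15.0, 20.0)

_FILTER_ORDER = 4
_NYQUIST_MARGIN = 0.99


@dataclass
class PowerSpectrum:
    """One-sided power spectrum of a single windowed FFT segment."""

    freqs: np.ndarray
    power: np.ndarray
    window: str = "hann"
    nfft: int = 256

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have identical shape")
        if np.any(np.diff(self.freqs) < 0):
            raise ValueError("freqs must be nondecreasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be nonnegative")


@dataclass
class HarmonicReport:
    """Fundamental plus harmonic peaks read off one power spectrum."""

    fundamental_hz: float
    harmonic_freqs: list[float]
    harmonic_powers: list[float]
    max_order: int


def _sos(btype: str, freqs, fs: float) -> np.ndarray:
    return sps.butter(_FILTER_ORDER, freqs, btype=btype, fs=fs, output="sos")


def _apply_sos(sos: np.ndarray, w: Waveform) -> Waveform:
    # sosfiltfilt's default padlen is the warm-up length; shorter inputs
    # cannot be filtered meaningfully.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(w) <= padlen:
        raise ValueError(
            f"waveform of {len(w)} samples shorter than filter warm-up ({padlen})"
        )
    return Waveform(sps.sosfiltfilt(sos, w.samples), fs=w.fs)


def bandpass(w: Waveform, f_lo: float, f_hi: float) -> Waveform:
    """Zero-phase Butterworth band-pass over [f_lo, f_hi] Hz.

    An upper edge at or above 0.99 x Nyquist (e.g. 20 Hz at fs = 40) is
    clamped just below Nyquist, where a literal corner is ill-posed.
    """
    nyq = w.fs / 2.0
    if not (0 < f_lo < f_hi <= nyq):
        raise ValueError(f"invalid band [{f_lo}, {f_hi}] for fs={w.fs}")
    f_hi = min(f_hi, _NYQUIST_MARGIN * nyq)
    if f_hi <= f_lo:
        raise ValueError(f"band [{f_lo}, {f_hi}] collapsed after Nyquist clamp")
    return _apply_sos(_sos("bandpass", [f_lo, f_hi], w.fs), w)


def lowpass(w: Waveform, f_cut: float) -> Waveform:
    """Zero-phase Butterworth low-pass with cutoff ``f_cut`` Hz."""
    nyq = w.fs / 2.0
    if not (0 < f_cut < nyq):
        raise ValueError(f"invalid cutoff {f_cut} for fs={w.fs}")
    return _apply_sos(_sos("lowpass", f_cut, w.fs), w)


def segment_spectra(
    w: Waveform, nfft: int = 256, overlap: float = 0.75
) -> list[PowerSpectrum]:
    """Per-segment one-sided power spectra (Hann taper, 75% overlap).

    Each ``nfft``-sample segment is mean-subtracted, Hann-tapered and
    transformed; one-sided power is scaled so its sum equals the tapered
    segment's energy. A 400-sample recording at the defaults yields
    floor((400-256)/64)+1 = 3 segments.
    """
    if len(w) < nfft:
        raise ValueError(f"waveform of {len(w)} samples shorter than nfft={nfft}")
    step = int(round(nfft * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large")
    taper = np.hanning(nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / w.fs)
    out: list[PowerSpectrum] = []
    n_seg = (len(w) - nfft) // step + 1
    for k in range(n_seg):
        seg = w.samples[k * step : k * step + nfft]
        seg = (seg - seg.mean()) * taper
        x = np.fft.rfft(seg)
        power = np.abs(x) ** 2 / nfft
        # fold negative frequencies; DC and Nyquist are unpaired
        power[1:] *= 2.0
        if nfft % 2 == 0:
            power[-1] /= 2.0
        out.append(PowerSpectrum(freqs, power, window="hann", nfft=nfft))
    return out


def band_peak(s: PowerSpectrum, f_lo: float, f_hi: float) -> float:
    """Maximum power over bins with f_lo <= freq <= f_hi."""
    mask = (s.freqs >= f_lo) & (s.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] contains no spectral bin")
    return float(s.power[mask].max())


def harmonic_analysis(
    s: PowerSpectrum,
    max_order: int = 6,
    search_range: tuple[float, float] = (0.5, 3.0),
) -> HarmonicReport:
    """Locate the pulse fundamental and its first ``max_order`` harmonics.

    The fundamental is the argmax bin in ``search_range`` (physiologic heart
    rates). Each harmonic n is read at the strongest of the bins within one
    bin of n x fundamental, which absorbs bin-quantisation drift.
    """
    lo, hi = search_range
    mask = (s.freqs > lo) & (s.freqs < hi)
    if not mask.any() or not np.any(s.power[mask] > 0):
        raise DegenerateInputError("no spectral power in the fundamental search range")
    idx = np.flatnonzero(mask)
    k0 = idx[np.argmax(s.power[idx])]
    fundamental = float(s.freqs[k0])
    dfreq = s.freqs[1] - s.freqs[0] if s.freqs.size > 1 else 1.0
    hfreqs: list[float] = []
    hpowers: list[float] = []
    for n in range(1, max_order + 1):
        target = n * fundamental
        k = int(round(target / dfreq))
        cand = [c for c in (k - 1, k, k + 1) if 0 <= c < s.freqs.size]
        kbest = max(cand, key=lambda c: s.power[c])
        hfreqs.append(float(s.freqs[kbest]))
        hpowers.append(float(s.power[kbest]))
    return HarmonicReport(fundamental, hfreqs, hpowers, max_order)


def lpf_correlation_curve(
    w: Waveform, cutoffs: list[float]
) -> list[tuple[float, float]]:
    """Pearson correlation of ``w`` with its low-passed versions.

    Used to judge how many pulse harmonics materially shape the waveform:
    correlation climbs toward 1 as the cutoff admits more of them.
    """
    if np.ptp(w.samples) == 0:
        raise DegenerateInputError("correlation undefined for a constant waveform")
    out = []
    x = w.samples - w.samples.mean()
    for fc in cutoffs:
        y = lowpass(w, fc).samples
        y = y - y.mean()
        denom = np.sqrt((x**2).sum() * (y**2).sum())
        r = float((x * y).sum() / denom) if denom > 0 else 0.0
        out.append((float(fc), r))
    return out
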