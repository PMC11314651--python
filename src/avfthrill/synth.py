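"""Synthetic arteriovenous-fistula recordings.

Generates 1-D luminance waveforms and full image stacks with the statistical
structure the analysis pipeline assumes:

* an arterial pulse: fundamental in the physiologic heart-rate range plus
  integer harmonics whose amplitudes decay with order,
* a thrill component: a quasi-periodic, amplitude-modulated oscillation whose
  spectral support is projected exactly into the 5-10 Hz thrill band; its
  amplitude is multiplied by ``stenosis_factor`` for the stenosis cohort
  (a narrowed anastomosis weakens the wall vibration),
* wide-band Gaussian noise covering the 15-20 Hz reference band,
* spatial structure: a Gaussian vessel-ridge reflectance profile, static
  halation (specular-glare) patches, and independent per-pixel
  diffuse-reflection noise.

The generator is deterministic for a fixed parameter set and seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import FrameStack, Waveform
from .spectral import THRILL_BAND

__all__ = ["SynthParams", "generate_waveform", "generate_stack", "generate_cohort"]

NORMAL = "normal"
STENOSIS = "stenosis"


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic AVF recording.

    Amplitudes are relative luminance units; the pulse fundamental has
    amplitude ``harmonic_amps[0]``. ``thrill_amp`` is the RMS of the thrill
    component relative to that scale, before the cohort's
    ``stenosis_factor`` is applied.
    """

    fundamental_hz: float = 1.2            # ~72 bpm
    harmonic_amps: tuple[float, ...] = (1.0, 1 / 2, 1 / 3, 1 / 4, 1 / 5, 1 / 6)
    thrill_amp: float = 0.3
    thrill_center_hz: float = 7.5
    noise_sd: float = 1.0                  # per-pixel diffuse-reflection noise SD
    halation_count: int = 3
    stenosis_factor: float = 1.0
    fps: float = 40.0
    duration_s: float = 10.0
    rows: int = 32
    cols: int = 32
    seed: int = 0
    # spatial reflectance model: base + ridge_amp * exp(-(dcol^2)/(2 w^2))
    ridge_width_px: float = 5.0
    ridge_amp: float = 0.85
    base_reflectance: float = 0.15
    # fraction of noise_sd that is spatially coherent (shared sensor noise);
    # diffuse per-pixel noise averages out under spatial smoothing, this does not
    shared_noise_frac: float = 0.2
    halation_value: float = 5.0

    def __post_init__(self) -> None:
        if not (0.5 < self.fundamental_hz < 3.0):
            raise ValueError(
                f"fundamental_hz must lie in (0.5, 3.0), got {self.fundamental_hz}"
            )
        amps = np.asarray(self.harmonic_amps, dtype=float)
        if amps.size < 1 or np.any(np.diff(amps) >= 0):
            raise ValueError("harmonic_amps must be strictly decreasing with order")
        nyq = self.fps / 2.0
        if amps.size * self.fundamental_hz >= nyq:
            raise ValueError(
                f"highest harmonic {amps.size * self.fundamental_hz:.2f} Hz at or "
                f"above Nyquist {nyq:.2f} Hz (aliasing)"
            )
        if not (THRILL_BAND[0] <= self.thrill_center_hz <= THRILL_BAND[1]):
            raise ValueError(
                f"thrill_center_hz must lie in {list(THRILL_BAND)}, got {self.thrill_center_hz}"
            )
        if THRILL_BAND[1] >= nyq:
            raise ValueError("thrill band reaches Nyquist; raise fps")
        if not (0 < self.stenosis_factor <= 1):
            raise ValueError(
                f"stenosis_factor must lie in (0, 1], got {self.stenosis_factor}"
            )
        if self.thrill_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")
        if self.duration_s * self.fps < 256:
            raise ValueError("recording must contain at least 256 samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fps))


def _thrill_component(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS quasi-periodic thrill confined to the 5-10 Hz band.

    An amplitude-modulated carrier at ``thrill_center_hz`` with slow random
    phase drift, then projected onto the thrill band by DFT masking so its
    spectral support is exact.
    """
    n = params.n_samples
    t = np.arange(n) / params.fps
    # slow phase drift: white noise smoothed to < ~1 Hz bandwidth
    drift = rng.standard_normal(n)
    from scipy.ndimage import gaussian_filter1d

    drift = gaussian_filter1d(drift, sigma=params.fps / 2.0, mode="nearest")
    sd = drift.std()
    drift = drift / sd * 0.8 if sd > 0 else drift
    am = 1.0 + 0.5 * np.cos(2 * np.pi * params.fundamental_hz * t)
    raw = am * np.cos(2 * np.pi * params.thrill_center_hz * t + drift)
    # exact band limitation
    spec = np.fft.rfft(raw)
    freqs = np.fft.rfftfreq(n, d=1.0 / params.fps)
    spec[(freqs < THRILL_BAND[0]) | (freqs > THRILL_BAND[1])] = 0.0
    th = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(th**2))
    return th / rms if rms > 0 else th


def generate_waveform(params: SynthParams) -> Waveform:
    """Synthesize one AVF luminance waveform.

    Sum of the harmonic pulse train (uniform random phases per seed), the
    band-limited thrill scaled by ``thrill_amp * stenosis_factor``, and white
    Gaussian noise of SD ``noise_sd``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    t = np.arange(n) / params.fps
    amps = np.asarray(params.harmonic_amps, dtype=float)
    phases = rng.uniform(0, 2 * np.pi, amps.size)
    pulse = np.zeros(n)
    for k, (a, phi) in enumerate(zip(amps, phases), start=1):
        pulse += a * np.sin(2 * np.pi * k * params.fundamental_hz * t + phi)
    thrill = np.zeros(n)
    if params.thrill_amp > 0:
        thrill = (
            params.thrill_amp
            * params.stenosis_factor
            * _thrill_component(params, rng)
        )
    else:
        # keep the RNG stream aligned so noise draws do not depend on thrill_amp
        _thrill_component(params, rng)
    noise = rng.standard_normal(n) * params.noise_sd if params.noise_sd > 0 else 0.0
    return Waveform(pulse + thrill + noise, fs=params.fps)


def _spatial_profile(params: SynthParams) -> np.ndarray:
    """Reflectance map: a Gaussian vessel ridge along the center column."""
    cols = np.arange(params.cols)
    ridge_col = params.cols // 2
    gauss = np.exp(-((cols - ridge_col) ** 2) / (2.0 * params.ridge_width_px**2))
    profile_1d = params.base_reflectance + params.ridge_amp * gauss
    return np.tile(profile_1d, (params.rows, 1))


def generate_stack(params: SynthParams) -> FrameStack:
    """Synthesize a full image stack.

    Every pixel's series is ``profile(i, j) * waveform`` plus independent
    per-pixel Gaussian noise of SD ``noise_sd``; the shared waveform carries
    only ``shared_noise_frac * noise_sd`` of coherent noise. Static saturated
    halation patches are added last.
    """
    shared = dataclasses.replace(
        params, noise_sd=params.noise_sd * params.shared_noise_frac
    )
    wf = generate_waveform(shared)
    rng = np.random.default_rng([params.seed, 1])
    profile = _spatial_profile(params)
    data = profile[None, :, :] * wf.samples[:, None, None]
    if params.noise_sd > 0:
        data = data + rng.normal(
            0.0, params.noise_sd, size=(params.n_samples, params.rows, params.cols)
        )
    else:
        rng.normal(0.0, 1.0, size=1)  # keep stream aligned
    for _ in range(params.halation_count):
        r = int(rng.integers(params.rows))
        c = int(rng.integers(params.cols))
        rr, cc = np.ogrid[: params.rows, : params.cols]
        patch = (rr - r) ** 2 + (cc - c) ** 2 <= 2.0**2
        data[:, patch] += params.halation_value
    meta = {"seed": params.seed, "synthetic": True}
    return FrameStack(data, fps=params.fps, pixel_pitch_mm=0.08, meta=meta)


def generate_cohort(
    n_normal: int,
    n_stenosis: int,
    base: SynthParams | None = None,
    seed: int = 0,
    stenosis_factor: float | None = None,
) -> list[tuple[FrameStack, str]]:
    """Generate a labeled cohort of recordings with per-recording jitter.

    Jitter emulates between-session physiological and optical variation:
    fundamental +- 0.2 Hz (uniform), thrill amplitude x exp(N(0, 0.3)),
    noise SD x U(0.8, 1.2), thrill center U(6, 9) Hz. Stenosis recordings
    additionally scale the thrill by ``stenosis_factor`` (default 0.5, or
    ``base.stenosis_factor`` when that is below 1).
    """
    if n_normal < 1 or n_stenosis < 1:
        raise ValueError("each cohort needs at least one recording")
    if base is None:
        base = SynthParams()
    if stenosis_factor is None:
        stenosis_factor = base.stenosis_factor if base.stenosis_factor < 1 else 0.5
    rng = np.random.default_rng(seed)
    out: list[tuple[FrameStack, str]] = []
    labels = [NORMAL] * n_normal + [STENOSIS] * n_stenosis
    for k, label in enumerate(labels):
        fund = float(
            np.clip(base.fundamental_hz + rng.uniform(-0.2, 0.2), 0.6, 2.9)
        )
        params = dataclasses.replace(
            base,
            fundamental_hz=fund,
            thrill_amp=base.thrill_amp * float(np.exp(rng.normal(0.0, 0.3))),
            noise_sd=base.noise_sd * float(rng.uniform(0.8, 1.2)),
            thrill_center_hz=float(rng.uniform(6.0, 9.0)),
            stenosis_factor=1.0 if label == NORMAL else stenosis_factor,
            seed=int(rng.integers(2**31)),
        )
        stack = generate_stack(params)
        stack.meta.update({"cohort_label": label, "recording_id": f"rec_{k:03d}"})
        out.append((stack, label))
    return out
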