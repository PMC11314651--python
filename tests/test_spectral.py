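"""Band filters, segmented power spectra, harmonic structure, LPF correlation."""
import numpy as np
import pytest

from avfthrill.core import DegenerateInputError, Waveform
from avfthrill.spectral import (
    band_peak,
    bandpass,
    harmonic_analysis,
    lowpass,
    lpf_correlation_curve,
    segment_spectra,
)

FS = 40.0
T = np.arange(400) / FS


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestFilters:
    def test_inband_tone_preserved(self):
        w = Waveform(np.sin(2 * np.pi * 7.0 * T), FS)
        out = bandpass(w, 5, 10)
        # interior samples, away from the filtfilt edge transients
        assert rms(out.samples[50:-50]) == pytest.approx(
            rms(w.samples[50:-50]), rel=0.01
        )

    def test_pulse_fundamental_rejected_by_thrill_band(self):
        w = Waveform(np.sin(2 * np.pi * 1.2 * T), FS)
        out = bandpass(w, 5, 10)
        assert 20 * np.log10(rms(out.samples) / rms(w.samples)) <= -20

    def test_zero_in_zero_out(self):
        w = Waveform(np.zeros(400), FS)
        assert np.allclose(bandpass(w, 5, 10).samples, 0.0)
        assert np.allclose(lowpass(w, 5).samples, 0.0)

    def test_lowpass_separates_mixture(self):
        low = np.sin(2 * np.pi * 1.2 * T)
        high = np.sin(2 * np.pi * 7.0 * T)
        out = lowpass(Waveform(low + high, FS), 4.6)
        # 7 Hz gone, 1.2 Hz intact
        resid_high = out.samples - low
        assert 20 * np.log10(rms(resid_high[50:-50]) / rms(high)) <= -20
        out_low_only = lowpass(Waveform(low, FS), 4.6)
        assert rms(out_low_only.samples[50:-50]) == pytest.approx(
            rms(low[50:-50]), rel=0.01
        )

    def test_passband_identity_correlation(self):
        w = Waveform(
            np.sin(2 * np.pi * 2.0 * T) + 0.3 * np.sin(2 * np.pi * 6.0 * T), FS
        )
        out = lowpass(w, 15.0)
        r = np.corrcoef(w.samples, out.samples)[0, 1]
        assert r >= 0.999

    def test_invalid_bands_rejected(self):
        w = Waveform(np.zeros(400), FS)
        with pytest.raises(ValueError):
            bandpass(w, 10, 5)
        with pytest.raises(ValueError):
            bandpass(w, 0, 5)
        with pytest.raises(ValueError):
            lowpass(w, 25)

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass(Waveform(np.zeros(20), FS), 5, 10)

    def test_zero_phase_preserves_pulse_peak(self):
        pulse = np.exp(-((T - 5.0) ** 2) / (2 * 0.3**2))
        out = lowpass(Waveform(pulse, FS), 5.0)
        assert abs(int(np.argmax(out.samples)) - int(np.argmax(pulse))) <= 1


class TestSegmentSpectra:
    def test_400_samples_yield_3_segments(self):
        spectra = segment_spectra(Waveform(np.random.default_rng(1).normal(size=400), FS))
        assert len(spectra) == 3  # floor((400-256)/64)+1

    @pytest.mark.parametrize("n,expected", [(256, 1), (320, 2), (448, 4), (1024, 13)])
    def test_segment_count_formula(self, n, expected):
        spectra = segment_spectra(Waveform(np.ones(n) + np.sin(np.arange(n)), FS))
        assert len(spectra) == expected

    def test_parseval_per_segment(self, rng):
        w = Waveform(rng.normal(size=400), FS)
        taper = np.hanning(256)
        for k, s in enumerate(segment_spectra(w)):
            seg = w.samples[k * 64 : k * 64 + 256]
            tapered = (seg - seg.mean()) * taper
            energy = float((tapered**2).sum())
            assert s.power.sum() == pytest.approx(energy, rel=1e-8)

    def test_bin_centered_sinusoid_recovered_at_exact_bin(self):
        # 5.0 Hz = bin 32 exactly (40/256 = 0.15625 Hz per bin)
        w = Waveform(np.sin(2 * np.pi * 5.0 * T), FS)
        for s in segment_spectra(w):
            assert int(np.argmax(s.power)) == 32

    def test_zero_waveform_gives_zero_spectra(self):
        for s in segment_spectra(Waveform(np.zeros(400), FS)):
            assert np.all(s.power == 0)

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ValueError, match="nfft"):
            segment_spectra(Waveform(np.zeros(100), FS))


class TestBandPeak:
    def test_single_nonzero_bin(self):
        spectra = segment_spectra(Waveform(np.sin(2 * np.pi * 7.03125 * T), FS))
        s = spectra[0]
        assert band_peak(s, 5, 10) == s.power[45]  # 7.03125 Hz = bin 45

    def test_quiet_band_is_near_zero(self):
        s = segment_spectra(Waveform(np.sin(2 * np.pi * 7.0 * T), FS))[0]
        assert band_peak(s, 15, 20) < 1e-6 * band_peak(s, 5, 10)

    def test_matches_linear_scan_oracle(self, rng):
        s = segment_spectra(Waveform(rng.normal(size=400), FS))[0]
        expected = max(
            p for f, p in zip(s.freqs, s.power) if 5 <= f <= 10
        )
        assert band_peak(s, 5, 10) == expected

    def test_empty_band_rejected(self):
        s = segment_spectra(Waveform(np.ones(256) + np.sin(np.arange(256.0)), FS))[0]
        with pytest.raises(ValueError):
            band_peak(s, 5.01, 5.02)


class TestHarmonics:
    @staticmethod
    def harmonic_wave(f0, amps, n=400):
        t = np.arange(n) / FS
        return sum(a * np.sin(2 * np.pi * (k + 1) * f0 * t) for k, a in enumerate(amps))

    def test_fundamental_and_six_harmonics_located(self):
        # 1.25 Hz is bin-centered at nfft=256, so no quantization drift
        w = Waveform(self.harmonic_wave(1.25, [1 / n for n in range(1, 7)]), FS)
        rep = harmonic_analysis(segment_spectra(w)[0])
        assert rep.fundamental_hz == pytest.approx(1.25, abs=FS / 256)
        assert len(rep.harmonic_freqs) == 6
        for k, f in enumerate(rep.harmonic_freqs, start=1):
            assert f == pytest.approx(k * 1.25, abs=2 * FS / 256)

    def test_decaying_amplitudes_give_decreasing_powers(self):
        w = Waveform(self.harmonic_wave(1.25, [1 / n for n in range(1, 7)]), FS)
        rep = harmonic_analysis(segment_spectra(w)[0])
        assert np.all(np.diff(rep.harmonic_powers) < 0)

    def test_single_sinusoid_higher_orders_at_noise_floor(self):
        w = Waveform(np.sin(2 * np.pi * 1.0 * T), FS)
        rep = harmonic_analysis(segment_spectra(w)[0])
        assert rep.fundamental_hz == pytest.approx(1.0, abs=FS / 256)
        assert all(p < 1e-3 * rep.harmonic_powers[0] for p in rep.harmonic_powers[2:])

    def test_empty_search_range_rejected(self):
        w = Waveform(np.sin(2 * np.pi * 10.0 * T), FS)
        with pytest.raises(DegenerateInputError):
            harmonic_analysis(segment_spectra(w)[0], search_range=(0.5, 0.51))


class TestLpfCorrelation:
    def test_cutoff_above_all_content_gives_correlation_near_one(self):
        # content strictly below the cutoff
        w = Waveform(
            np.sin(2 * np.pi * 2.0 * T)
            + 0.3 * np.sin(2 * np.pi * 5.0 * T)
            + 0.2 * np.sin(2 * np.pi * 8.0 * T),
            FS,
        )
        (_, r), = lpf_correlation_curve(w, [15.0])
        assert r >= 0.999

    def test_nondecreasing_in_cutoff_for_harmonic_waveform(self):
        w = Waveform(
            TestHarmonics.harmonic_wave(1.25, [1 / n for n in range(1, 7)]), FS
        )
        cutoffs = [1.8, 3.1, 4.4, 5.6, 6.9, 8.1, 12.0]
        rs = [r for _, r in lpf_correlation_curve(w, cutoffs)]
        # brute-force recomputation of each point
        for fc, r in zip(cutoffs, rs):
            y = lowpass(w, fc).samples
            assert r == pytest.approx(np.corrcoef(w.samples, y)[0, 1], abs=1e-12)
        assert np.all(np.diff(rs) >= -1e-6)

    def test_stopband_output_decorrelates(self):
        w = Waveform(np.sin(2 * np.pi * 1.0 * T), FS)
        (_, r), = lpf_correlation_curve(w, [0.5])
        assert abs(r) < 0.2

    def test_constant_waveform_signaled(self):
        with pytest.raises(DegenerateInputError):
            lpf_correlation_curve(Waveform(np.full(400, 2.0), FS), [5.0])
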