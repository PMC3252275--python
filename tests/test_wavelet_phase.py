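"""Unit and property tests for the phase-synchronization estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plicrit import wavelet_phase as wp


def _tone(freq, fs, n, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestHilbertWaveletTransform:
    def test_dyadic_bands(self):
        assert wp.scale_band(200.0, 2) == (25.0, 50.0)
        assert wp.scale_band(200.0, 3) == (12.5, 25.0)
        assert wp.scale_band(256.0, 1) == (64.0, 128.0)

    def test_band_energy_concentration(self):
        # a 30 Hz tone at fs=200 lies in the scale-2 band (25-50 Hz)
        w = wp.hilbert_wavelet_transform(_tone(30, 200.0, 8192), 200.0, [2, 3, 4])
        e = {j: np.sum(np.abs(w.coeffs[j]) ** 2) for j in (2, 3, 4)}
        assert e[2] > 10 * e[4]
        assert e[2] > 10 * e[3]

    def test_zero_signal_gives_zero_coefficients(self):
        w = wp.hilbert_wavelet_transform(np.zeros(1024), 200.0, [1, 2, 3])
        for j in (1, 2, 3):
            assert np.allclose(w.coeffs[j], 0)

    def test_too_short_signal_names_minimum(self):
        with pytest.raises(ValueError, match=str(wp.min_signal_length(5))):
            wp.hilbert_wavelet_transform(np.ones(30), 200.0, [5])

    def test_analyticity(self, rng):
        # imaginary part is the Hilbert transform: negative-frequency content
        # of the coefficients is (numerically) zero
        x = rng.standard_normal(4096)
        w = wp.hilbert_wavelet_transform(x, 200.0, [2])
        spec = np.fft.fft(w.coeffs[2])
        neg = np.fft.fftfreq(4096) < 0
        assert np.max(np.abs(spec[neg])) < 1e-8 * np.max(np.abs(spec))


class TestPhasePairSeries:
    def test_self_pair_is_perfectly_locked(self):
        w = wp.hilbert_wavelet_transform(_tone(30, 200.0, 4096), 200.0, [2])
        pps = wp.phase_pair_series(w, w, 2)
        i = slice(wp.edge_margin(2), -wp.edge_margin(2))
        assert np.allclose(pps.dphi[i], 0, atol=1e-12)
        assert np.allclose(pps.coherence[i], 1, atol=1e-12)
        assert pps.sig_mask[i].all()

    def test_unit_modulus_and_coherence_bounds(self, rng):
        wa = wp.hilbert_wavelet_transform(rng.standard_normal(4096), 200.0, [2])
        wb = wp.hilbert_wavelet_transform(rng.standard_normal(4096), 200.0, [2])
        pps = wp.phase_pair_series(wa, wb, 2)
        mod = np.abs(pps.C)
        assert np.allclose(mod[mod > 0], 1.0)
        assert (pps.coherence >= 0).all() and (pps.coherence <= 1).all()
        assert (pps.dphi > -np.pi - 1e-12).all() and (pps.dphi <= np.pi + 1e-12).all()

    def test_antisymmetry_under_swap(self, rng):
        wa = wp.hilbert_wavelet_transform(rng.standard_normal(4096), 200.0, [3])
        wb = wp.hilbert_wavelet_transform(rng.standard_normal(4096), 200.0, [3])
        ab = wp.phase_pair_series(wa, wb, 3)
        ba = wp.phase_pair_series(wb, wa, 3)
        assert np.allclose(ab.C_smooth, np.conj(ba.C_smooth))
        interior = ab.sig_mask & ba.sig_mask
        assert np.allclose(ab.dphi[interior], -ba.dphi[interior])

    def test_white_noise_null_coherence(self):
        # with a smoothing window much longer than one cycle, independent
        # signals fall below the 0.5 significance gate at most samples
        med, frac = [], []
        for s in range(3):
            r = np.random.default_rng(s)
            wa = wp.hilbert_wavelet_transform(r.standard_normal(30000), 200.0, [2])
            wb = wp.hilbert_wavelet_transform(r.standard_normal(30000), 200.0, [2])
            pps = wp.phase_pair_series(wa, wb, 2, avg_window=32 * 2**2)
            i = slice(wp.edge_margin(2), -wp.edge_margin(2))
            med.append(np.median(pps.coherence[i]))
            frac.append(pps.sig_mask[i].mean())
        assert np.mean(med) < 0.5
        assert np.mean(frac) < 0.2

    def test_missing_scale_and_grid_mismatch(self, rng):
        wa = wp.hilbert_wavelet_transform(rng.standard_normal(1024), 200.0, [2])
        wb = wp.hilbert_wavelet_transform(rng.standard_normal(1024), 200.0, [3])
        with pytest.raises(ValueError, match="scale 3 not present"):
            wp.phase_pair_series(wa, wb, 3)
        wc = wp.hilbert_wavelet_transform(rng.standard_normal(512), 200.0, [2])
        with pytest.raises(ValueError, match="time grid"):
            wp.phase_pair_series(wa, wc, 2)


def _pps_from_blocks(dphi, mask, scale=2, fs=200.0):
    n = len(dphi)
    c = np.exp(1j * np.asarray(dphi, dtype=float))
    return wp.PhasePairSeries(
        scale=scale, fs=fs, C=c, C_smooth=c, dphi=np.asarray(dphi, float),
        coherence=np.ones(n), sig_mask=np.asarray(mask, bool),
        avg_window=1, min_coherence=0.5,
    )


class TestExtractPli:
    def test_constant_lock_single_interval(self):
        pps = _pps_from_blocks(np.zeros(500), np.ones(500, bool))
        pli = wp.extract_pli(pps, np.pi / 4)
        assert list(pli.durations) == [500]

    def test_constant_offset_above_threshold(self):
        pps = _pps_from_blocks(np.full(500, np.pi / 2), np.ones(500, bool))
        assert wp.extract_pli(pps, np.pi / 4).n == 0

    def test_block_pattern_oracle(self, rng):
        # alternating locked/unlocked blocks of known lengths are recovered
        lengths = rng.integers(1, 50, size=40)
        dphi, expected = [], []
        for k, L in enumerate(lengths):
            locked = k % 2 == 0
            dphi.extend([0.0 if locked else 3.0] * L)
            if locked:
                expected.append(int(L))
        pps = _pps_from_blocks(dphi, np.ones(len(dphi), bool))
        assert sorted(wp.extract_pli(pps, np.pi / 4).durations) == sorted(expected)

    def test_run_lengths_match_naive_scan(self, rng):
        for _ in range(25):
            mask = rng.random(rng.integers(1, 10_000)) < 0.6
            runs = []
            count = 0
            for b in mask:
                if b:
                    count += 1
                elif count:
                    runs.append(count)
                    count = 0
            if count:
                runs.append(count)
            assert list(wp.run_lengths(mask)) == runs

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.booleans(), max_size=300))
    def test_run_lengths_property(self, bits):
        """Run lengths partition the True samples and never exceed the
        longest literal run."""
        mask = np.array(bits, dtype=bool)
        runs = wp.run_lengths(mask)
        assert runs.sum() == mask.sum()
        assert (runs >= 1).all()
        # reconstruct: number of runs equals number of False->True edges
        edges = np.diff(np.concatenate(([0], mask.astype(int)))) == 1
        assert len(runs) == edges.sum()

    def test_locked_time_monotonic_in_threshold_and_gate(self, rng):
        wa = wp.hilbert_wavelet_transform(rng.standard_normal(8192), 200.0, [2])
        wb = wp.hilbert_wavelet_transform(rng.standard_normal(8192), 200.0, [2])
        totals_thr = []
        for thr in (0.2, 0.5, 1.0, 2.0):
            pps = wp.phase_pair_series(wa, wb, 2)
            totals_thr.append(wp.extract_pli(pps, thr).durations.sum())
        assert totals_thr == sorted(totals_thr)
        totals_coh = []
        for mc in (0.1, 0.4, 0.7):
            pps = wp.phase_pair_series(wa, wb, 2, min_coherence=mc)
            totals_coh.append(wp.extract_pli(pps, np.pi / 4).durations.sum())
        assert totals_coh == sorted(totals_coh, reverse=True)

    def test_invalid_threshold(self):
        pps = _pps_from_blocks(np.zeros(100), np.ones(100, bool))
        for bad in (0.0, -1.0, np.pi):
            with pytest.raises(ValueError):
                wp.extract_pli(pps, bad)

    def test_fixed_offset_sinusoids_lock_whole_record(self):
        # two in-band tones with a phase offset below threshold lock from
        # edge to edge
        n, fs = 8192, 200.0
        wa = wp.hilbert_wavelet_transform(_tone(30, fs, n), fs, [2])
        wb = wp.hilbert_wavelet_transform(_tone(30, fs, n, phase=0.3), fs, [2])
        pps = wp.phase_pair_series(wa, wb, 2)
        pli = wp.extract_pli(pps, np.pi / 4)
        assert pli.n == 1
        assert pli.durations[0] >= n - 2 * wp.edge_margin(2) - 2 * pps.avg_window
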