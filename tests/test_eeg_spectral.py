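import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from rewardlist.core_data import CONDITIONS, EpochedEEG
from rewardlist.eeg_spectral import (
    TFR,
    baseline_subtract,
    bandstop_fir,
    db_baseline,
    erp_average,
    extract_ssvep,
    find_ssvep_peak,
    grand_average_tfr,
    psd_hanning,
    tfr_hanning,
)
from rewardlist.synthetic_data import fibonacci_hemisphere


def make_eeg(data, srate=500.0, t0=-2000.0, conditions=None, subjects=None):
    n_tr, n_ch, _ = data.shape
    return EpochedEEG(
        data=data.astype(np.float32),
        srate=srate,
        t0_offset_ms=t0,
        channel_names=[f"ch{i}" for i in range(n_ch)],
        channel_xyz=fibonacci_hemisphere(n_ch),
        trial_condition=np.array(
            conditions or [CONDITIONS[i % 4] for i in range(n_tr)], dtype=object
        ),
        trial_subject=np.array(subjects or ["s1"] * n_tr, dtype=object),
    )


def tone_eeg(freq=14.0, amp=1.0, n_ch=2, n_tr=4, n_samples=2500, srate=500.0):
    t = (-2000.0 + np.arange(n_samples) * 1000.0 / srate) / 1000.0
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_tr, n_ch, 1))
    return make_eeg(data, srate=srate)


class TestBaselineSubtract:
    def test_constant_offset_removed_exactly(self):
        eeg = make_eeg(np.full((4, 2, 2500), 7.25))
        out = baseline_subtract(eeg, (-500.0, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        eeg = make_eeg(rng.normal(size=(4, 2, 2500)))
        once = baseline_subtract(eeg, (-500.0, 0.0))
        twice = baseline_subtract(once, (-500.0, 0.0))
        assert np.allclose(once.data, twice.data, atol=1e-4)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        eeg = make_eeg(rng.normal(size=(3, 2, 2500)))
        out = baseline_subtract(eeg, (-500.0, 0.0))
        mask = (eeg.times >= -500.0) & (eeg.times < 0.0)
        for tr in range(3):
            for ch in range(2):
                expected = eeg.data[tr, ch] - eeg.data[tr, ch, mask].mean()
                assert np.allclose(out.data[tr, ch], expected, atol=1e-4)


class TestPsdHanning:
    def test_quadratic_amplitude_scaling(self):
        p1 = psd_hanning(tone_eeg(amp=1.0), (1000.0, 2000.0))
        p2 = psd_hanning(tone_eeg(amp=2.0), (1000.0, 2000.0))
        bin14 = np.argmin(np.abs(p1.freqs - 14.0))
        for key in p1.power:
            ratio = p2.power[key][0, bin14] / p1.power[key][0, bin14]
            assert ratio == pytest.approx(4.0, rel=1e-6)

    def test_zero_signal_zero_spectrum(self):
        spec = psd_hanning(make_eeg(np.zeros((4, 2, 2500))), (1000.0, 2000.0))
        for p in spec.power.values():
            assert np.allclose(p, 0.0)

    def test_tone_bin_power_matches_direct_dft_oracle(self):
        """Hann-tapered 14 Hz bin power against an explicit DFT sum."""
        eeg = tone_eeg(freq=14.0, amp=1.3)
        spec = psd_hanning(eeg, (1000.0, 2000.0))
        mask = (eeg.times >= 1000.0) & (eeg.times < 2000.0)
        x = eeg.data[0, 0, mask].astype(float)
        n = x.size
        w = sps.windows.hann(n, sym=False)
        k = 14  # 1 s window -> 1 Hz resolution
        X = np.sum(w * x * np.exp(-2j * np.pi * k * np.arange(n) / n))
        expected = (2 * np.abs(X) / w.sum()) ** 2 / 2
        got = next(iter(spec.power.values()))[0, np.argmin(np.abs(spec.freqs - 14.0))]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_tone_amplitude_recovered(self):
        spec = psd_hanning(tone_eeg(freq=14.0, amp=1.0), (1000.0, 2000.0))
        amp = next(iter(spec.amplitude().values()))
        assert amp[0, np.argmin(np.abs(spec.freqs - 14.0))] == pytest.approx(1.0, rel=1e-6)

    def test_parseval_identity_rectangular_window(self):
        """Untapered single-sided power sums to the signal's mean square."""
        rng = np.random.default_rng(3)
        eeg = make_eeg(rng.normal(size=(1, 1, 2500)))
        spec = psd_hanning(eeg, (-2000.0, 3000.0), taper="boxcar")
        x = eeg.data[0, 0].astype(float)
        total = spec.power[next(iter(spec.power))][0].sum()
        assert total == pytest.approx(np.mean(x**2), rel=1e-8)


class TestExtractSsvep:
    def test_two_bin_mean(self):
        eeg = tone_eeg(freq=14.0, amp=1.0)
        spec = psd_hanning(eeg, (1000.0, 2000.0))
        spec.channel_names[0] = "Oz"
        table = extract_ssvep(spec, (14.0, 15.0), "Oz", scale="power")
        bin14 = np.argmin(np.abs(spec.freqs - 14.0))
        bin15 = np.argmin(np.abs(spec.freqs - 15.0))
        p = next(iter(spec.power.values()))
        expected = (p[0, bin14] + p[0, bin15]) / 2
        assert table.data.iloc[0, 0] == pytest.approx(expected)

    def test_unknown_channel_raises(self):
        spec = psd_hanning(tone_eeg(), (1000.0, 2000.0))
        with pytest.raises(KeyError):
            extract_ssvep(spec, channel="Pz9")


class TestTfrHanning:
    def test_stationary_tone_flat_in_time(self):
        eeg = tone_eeg(freq=14.0, amp=1.0)
        tfr = tfr_hanning(eeg, freqs=[14.0])
        P = next(iter(tfr.power.values()))[0, 0]
        interior = P[~np.isnan(P)]
        assert interior.max() / interior.min() < 1.1

    def test_single_cell_matches_direct_windowed_dft(self):
        rng = np.random.default_rng(4)
        eeg = make_eeg(rng.normal(size=(1, 1, 2500)))
        f = 10.0
        tfr = tfr_hanning(eeg, freqs=[f])
        ti = np.argmin(np.abs(tfr.times - 500.0))
        L = int(round(5 * eeg.srate / f))
        center = int(round((tfr.times[ti] - eeg.times[0]) / 2.0))
        seg = eeg.data[0, 0, center - L // 2 : center - L // 2 + L].astype(float)
        w = sps.windows.hann(L, sym=False)
        X = np.sum(w * seg * np.exp(-2j * np.pi * f * np.arange(L) / eeg.srate))
        expected = (2 * np.abs(X) / w.sum()) ** 2 / 2
        got = next(iter(tfr.power.values()))[0, 0, ti]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_edge_windows_marked_missing(self):
        eeg = tone_eeg(freq=4.0)
        tfr = tfr_hanning(eeg, freqs=[4.0])
        P = next(iter(tfr.power.values()))[0, 0]
        assert np.isnan(P[0]) and np.isnan(P[-1])
        assert not np.isnan(P[len(P) // 2])

    def test_agrees_with_psd_on_stationary_tone(self):
        """TFR and static spectrum agree within 5% at 14 Hz when windows align."""
        eeg = tone_eeg(freq=14.0, amp=1.0)
        spec = psd_hanning(eeg, (1000.0, 2000.0))
        bin14 = np.argmin(np.abs(spec.freqs - 14.0))
        p_static = next(iter(spec.power.values()))[0, bin14]
        tfr = tfr_hanning(eeg, freqs=[14.0], cycles=14.0)  # 1 s window
        P = next(iter(tfr.power.values()))[0, 0]
        ti = np.argmin(np.abs(tfr.times - 1500.0))
        assert P[ti] == pytest.approx(p_static, rel=0.05)

    def test_on_off_tone_contrast_exceeds_10db(self):
        t = np.arange(2500) * 2.0 - 2000.0
        x = np.where((t >= 0) & (t <= 2047), np.sin(2 * np.pi * 14.0 * t / 1000), 0.0)
        eeg = make_eeg(np.tile(x, (2, 2, 1)))
        tfr = tfr_hanning(eeg, freqs=[14.0])
        P = next(iter(tfr.power.values()))[0, 0]
        stim = (tfr.times >= 1000) & (tfr.times < 2000)
        pre = (tfr.times >= -1500) & (tfr.times < -500)
        ratio = np.nanmean(P[stim]) / max(np.nanmean(P[pre]), 1e-300)
        assert 10 * np.log10(ratio) > 10


class TestDbBaseline:
    def _tfr(self, P):
        times = np.arange(-1000.0, 1000.0, 50.0)
        return TFR(
            freqs=np.array([14.0]),
            times=times,
            power={("s1", "mixed_high"): P},
            channel_names=["ch0"],
        )

    def test_flat_power_maps_to_zero_db(self):
        times = np.arange(-1000.0, 1000.0, 50.0)
        P = np.full((1, 1, times.size), 3.7)
        out = db_baseline(self._tfr(P), (-700.0, -200.0))
        assert np.allclose(out.power[("s1", "mixed_high")], 0.0)

    def test_tenfold_power_is_10db(self):
        times = np.arange(-1000.0, 1000.0, 50.0)
        P = np.full((1, 1, times.size), 1.0)
        P[:, :, times >= 0] = 10.0
        out = db_baseline(self._tfr(P), (-700.0, -200.0))
        assert np.allclose(out.power[("s1", "mixed_high")][0, 0, times >= 0], 10.0)

    def test_matches_elementwise_oracle_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        times = np.arange(-1000.0, 1000.0, 50.0)
        P = rng.random((3, 2, times.size)) + 0.5
        out = db_baseline(self._tfr(P), (-700.0, -200.0))
        base = P[:, :, (times >= -700) & (times < -200)].mean(axis=2, keepdims=True)
        assert np.allclose(out.power[("s1", "mixed_high")], 10 * np.log10(P / base))
        scaled = db_baseline(self._tfr(P * 37.0), (-700.0, -200.0))
        assert np.allclose(
            scaled.power[("s1", "mixed_high")], out.power[("s1", "mixed_high")]
        )

    def test_zero_baseline_rejected(self):
        times = np.arange(-1000.0, 1000.0, 50.0)
        P = np.zeros((1, 1, times.size))
        with pytest.raises(ValueError):
            db_baseline(self._tfr(P), (-700.0, -200.0))


class TestBandstopFir:
    def test_flicker_tone_attenuated_20db(self):
        eeg = tone_eeg(freq=85.0 / 6.0, amp=1.0, n_tr=1)
        out = bandstop_fir(eeg)
        m = (eeg.times >= 0) & (eeg.times < 2000)
        att = 20 * np.log10(
            np.sqrt(np.mean(out.data[0, 0, m] ** 2))
            / np.sqrt(np.mean(eeg.data[0, 0, m] ** 2))
        )
        assert att <= -20.0

    @pytest.mark.parametrize("freq", [5.0, 40.0])
    def test_passband_tone_within_1db(self, freq):
        eeg = tone_eeg(freq=freq, amp=1.0, n_tr=1)
        out = bandstop_fir(eeg)
        m = (eeg.times >= -1000) & (eeg.times < 2000)
        att = 20 * np.log10(
            np.sqrt(np.mean(out.data[0, 0, m] ** 2))
            / np.sqrt(np.mean(eeg.data[0, 0, m] ** 2))
        )
        assert abs(att) <= 1.0

    def test_zero_in_zero_out(self):
        eeg = make_eeg(np.zeros((2, 2, 2500)))
        assert np.allclose(bandstop_fir(eeg).data, 0.0)


class TestErpAverage:
    def test_identical_trials_average_to_single_trial(self):
        rng = np.random.default_rng(6)
        trial = rng.normal(size=(1, 2, 2500))
        eeg = make_eeg(
            np.repeat(trial, 4, axis=0),
            conditions=["mixed_high"] * 4,
        )
        erps = erp_average(eeg)
        base = (eeg.times >= -200) & (eeg.times < 0)
        expected = trial[0] - trial[0][:, base].mean(axis=1, keepdims=True)
        assert np.allclose(erps.erp[("s1", "mixed_high")], expected, atol=1e-4)
        assert erps.n_trials[("s1", "mixed_high")] == 4

    def test_offset_invariance(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(4, 2, 2500))
        a = erp_average(make_eeg(data))
        b = erp_average(make_eeg(data + 42.0))
        for key in a.erp:
            assert np.allclose(a.erp[key], b.erp[key], atol=1e-3)


class TestFindSsvepPeak:
    def test_single_channel_returns_it(self):
        times = np.arange(-1000.0, 1000.0, 50.0)
        P = np.ones((1, 1, times.size))
        P[0, 0, times >= 0] = 5.0
        tfr = TFR(np.array([14.0]), times, {("s1", "mixed_high"): P}, ["only"], "dB")
        ch, _win = find_ssvep_peak(tfr)
        assert ch == "only"

    def test_peak_location_and_tie_break(self):
        times = np.arange(-1000.0, 1000.0, 50.0)
        P = np.zeros((3, 1, times.size))
        P[1, 0, (times >= 200) & (times < 400)] = 8.0
        tfr = TFR(np.array([14.0]), times, {("s1", "mixed_high"): P}, ["a", "b", "c"], "dB")
        ch, win = find_ssvep_peak(tfr)
        assert ch == "b"
        assert win[0] == 200.0 and win[1] == 350.0

    def test_all_missing_rejected(self):
        times = np.arange(-1000.0, 1000.0, 50.0)
        P = np.full((2, 1, times.size), np.nan)
        tfr = TFR(np.array([14.0]), times, {("s1", "mixed_high"): P}, ["a", "b"], "dB")
        with pytest.raises(ValueError):
            find_ssvep_peak(tfr)
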