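import numpy as np
import pytest

from megfeedback import (ClusterConfig, DegenerateBaselineError, TFRArray,
                         TFRConfig, morlet_tfr, spectrotemporal_cluster_test,
                         tfoi_power, tfr_baseline_zscore)

SFREQ = 200.0
TIMES = -0.25 + np.arange(171) / SFREQ


def _tone(freq, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * TIMES)


def _tfr(signal, **kw):
    with pytest.warns(RuntimeWarning):  # f/3 gives < 2 cycles at low f
        return morlet_tfr(signal, TIMES, SFREQ, TFRConfig(**kw))


class TestMorlet:
    def test_pure_tone_peaks_at_its_frequency(self):
        tfr = _tfr(_tone(10.0))
        central = (TIMES > -0.05) & (TIMES < 0.4)  # central half of epoch
        profile = tfr.power[:, central].mean(axis=1)
        assert tfr.freqs_hz[np.argmax(profile)] == 10.0

    def test_zero_signal_zero_power(self):
        tfr = _tfr(np.zeros_like(TIMES))
        assert np.allclose(tfr.power, 0.0)

    def test_quadratic_homogeneity(self):
        t1 = _tfr(_tone(12.0))
        t2 = _tfr(_tone(12.0, amp=2.0))
        assert np.allclose(t2.power, 4.0 * t1.power, rtol=1e-9)

    def test_frequency_axis_matches_config(self):
        tfr = _tfr(_tone(8.0))
        assert np.array_equal(tfr.freqs_hz, np.arange(4.0, 46.0))
        assert tfr.power.shape == (42, len(TIMES))

    @pytest.mark.parametrize("f0", [6.0, 10.0, 20.0, 40.0])
    def test_power_weighted_mean_frequency_localized(self, f0):
        tfr = _tfr(_tone(f0))
        central = (TIMES > -0.05) & (TIMES < 0.4)
        profile = tfr.power[:, central].mean(axis=1)
        mean_f = (tfr.freqs_hz * profile).sum() / profile.sum()
        assert abs(mean_f - f0) <= 1.0

    def test_narrowband_additivity_at_separated_frequencies(self):
        x, y = _tone(6.0), _tone(30.0)
        both = _tfr(x + y)
        xs, ys = _tfr(x), _tfr(y)
        f6 = np.flatnonzero(both.freqs_hz == 6.0)[0]
        f30 = np.flatnonzero(both.freqs_hz == 30.0)[0]
        central = (TIMES > 0.0) & (TIMES < 0.4)
        for fi in (f6, f30):
            a = both.power[fi, central].mean()
            b = (xs.power + ys.power)[fi, central].mean()
            assert a == pytest.approx(b, rel=0.15)  # cross-term tolerance

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_tfr(_tone(10.0), TIMES, 80.0, TFRConfig())

    def test_too_short_signal_names_frequency(self):
        t = TIMES[:20]
        with pytest.warns(RuntimeWarning):
            with pytest.raises(ValueError):
                morlet_tfr(np.zeros(20), t, SFREQ, TFRConfig())

    def test_agreement_with_mne_reference(self):
        """Independent cross-check against mne.time_frequency.tfr_array_morlet."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(0)
        sig = _tone(10.0) + 0.5 * rng.standard_normal(TIMES.size)
        cfg = TFRConfig(edge_policy="none")
        with pytest.warns(RuntimeWarning):
            mine = morlet_tfr(sig, TIMES, SFREQ, cfg)
        ref = mne.time_frequency.tfr_array_morlet(
            sig[None, None, :], SFREQ, cfg.freqs_hz, n_cycles=cfg.n_cycles(),
            output="power", zero_mean=False, verbose="error")[0, 0]
        central = (TIMES > -0.1) & (TIMES < 0.45)
        for row_mine, row_ref in zip(mine.power[:, central], ref[:, central]):
            r = np.corrcoef(row_mine, row_ref)[0, 1]
            assert r > 0.99


class TestBaselineZscore:
    def _raw(self, power):
        return TFRArray(power, np.arange(4.0, 46.0), TIMES)

    def test_elevated_post_onset_power(self):
        power = np.ones((42, TIMES.size))
        power += np.random.default_rng(1).random((42, TIMES.size)) * 0.1
        power[:, TIMES > 0.1] += 5.0
        z = tfr_baseline_zscore(self._raw(power))
        base = z.power[:, TIMES <= 0.0]
        assert abs(base.mean()) < 0.2
        assert z.power[:, TIMES > 0.1].mean() > 10

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        power = rng.random((42, TIMES.size)) + 0.1
        z1 = tfr_baseline_zscore(self._raw(power))
        z2 = tfr_baseline_zscore(self._raw(power * 10.0))
        assert np.allclose(z1.power, z2.power, atol=1e-10)

    def test_white_noise_rows_near_zero_mean(self):
        rng = np.random.default_rng(3)
        power = rng.random((42, TIMES.size)) + 0.5
        z = tfr_baseline_zscore(self._raw(power))
        row_means = z.power[:, TIMES <= 0.0].mean(axis=1)
        assert np.allclose(row_means, 0.0, atol=1e-10)

    def test_constant_baseline_row_raises(self):
        power = np.ones((42, TIMES.size))
        with pytest.raises(DegenerateBaselineError, match="Hz"):
            tfr_baseline_zscore(self._raw(power))

    def test_global_mode(self):
        rng = np.random.default_rng(4)
        power = rng.random((42, TIMES.size)) + 0.1
        z = tfr_baseline_zscore(self._raw(power), mode="global")
        assert abs(z.power[:, TIMES <= 0.0].mean()) < 1e-10


class TestSpectroTemporal:
    def test_identical_groups_empty(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((6, 10, 20))
        res, lat = spectrotemporal_cluster_test(
            a, a.copy(), ClusterConfig(t_threshold=2.0, n_permutations=100))
        assert res.clusters == []
        assert lat.shape == (10, 20)

    def test_planted_band_power_recovered(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((12, 42, 60))
        b = rng.standard_normal((12, 42, 60))
        b[:, 2:5, 20:50] += 1.5  # rows 2-4 = 6-8 Hz on a 4..45 axis
        res, lat = spectrotemporal_cluster_test(
            a, b, ClusterConfig(t_threshold=2.0, n_permutations=500, seed=1))
        sig = res.significant()
        assert sig
        top = max(sig, key=lambda c: abs(c.mass))
        f_idx = np.unravel_index(top.element_indices, lat.shape)[0]
        assert f_idx.min() <= 2 <= f_idx.max()

    def test_cluster_report_schema_has_band_and_span(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((8, 5, 12))
        b = rng.standard_normal((8, 5, 12)) + 2.0
        res, lat = spectrotemporal_cluster_test(
            a, b, ClusterConfig(t_threshold=2.0, n_permutations=200, seed=2))
        d = res.to_dict(shape=lat.shape)
        assert d["clusters"]
        coords = np.asarray(d["clusters"][0]["coords"])
        assert coords.shape[1] == 2  # (frequency, time) per element


def test_tfr_hdf5_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    tfr = TFRArray(rng.random((42, 50)), np.arange(4.0, 46.0),
                   np.linspace(-0.25, 0.6, 50))
    path = tmp_path / "tfr.h5"
    tfr.to_hdf5(path)
    back = TFRArray.from_hdf5(path)
    assert np.allclose(back.power, tfr.power)
    assert back.z_scored is False


class TestTFOI:
    def test_constant_power(self):
        plane = np.full((4, 5), 2.2)
        assert tfoi_power(plane, np.arange(6)) == pytest.approx(2.2)

    def test_two_by_two_mean(self):
        plane = np.zeros((4, 4))
        plane[1, 1], plane[1, 2], plane[2, 1], plane[2, 2] = 1, 2, 3, 4
        elements = np.ravel_multi_index(([1, 1, 2, 2], [1, 2, 1, 2]), (4, 4))
        assert tfoi_power(plane, elements) == pytest.approx(2.5)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            tfoi_power(np.zeros((3, 3)), [])
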