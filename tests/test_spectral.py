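"""Welch segmentation, dB band averaging, and pooled z-scoring."""

import numpy as np
import pandas as pd
import pytest

from nfdrift.recording import TrialRecording
from nfdrift.spectral import (BANDS, PSD, SpectralConfig, SpectralError,
                              band_power, band_power_table, to_db, welch_psd,
                              zscore_powers)

FS = 250.0


def _trial(samples, fs=FS):
    samples = np.atleast_2d(samples)
    labels = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return TrialRecording("S01", "Control", 1, 1, labels, fs, samples)


def test_segmentation_rule_on_57s_trial():
    cfg = SpectralConfig()
    n = 14250                      # 57 s at 250 Hz
    assert 7 <= cfg.n_segments(n) <= 8
    # longest segments not exceeding 8 at 50% overlap
    nperseg = cfg.segment_length(n)
    step = nperseg - int(nperseg * 0.5)
    assert 1 + (n - nperseg) // step == 8
    longer = nperseg + 2
    assert 1 + (n - longer) // (longer - longer // 2) <= 8


def test_tone_localized_within_one_bin():
    t = np.arange(14250) / FS
    rec = _trial(np.sin(2 * np.pi * 10.0 * t))
    psd = welch_psd(rec)["ch0"]
    fmax = psd.frequencies[np.argmax(psd.power)]
    df = psd.frequencies[1] - psd.frequencies[0]
    assert abs(fmax - 10.0) <= df


def test_parseval_on_white_noise():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(200 * int(FS))
    psd = welch_psd(_trial(x))["ch0"]
    total = np.trapezoid(psd.power, psd.frequencies)
    assert abs(total - 1.0) < 0.05


def test_too_short_recording_raises():
    with pytest.raises(SpectralError):
        welch_psd(_trial(np.zeros(16)))


def test_db_transform():
    psd = PSD(np.array([1.0, 2.0, 3.0]), np.array([1.0, 100.0, 0.0]))
    out = to_db(psd)
    assert out.power[0] == 0.0
    assert out.power[1] == 20.0
    assert np.isfinite(out.power[2])               # floored, not -inf
    # order preserving
    p = np.array([0.5, 1.5, 2.5])
    assert np.all(np.diff(to_db(PSD(np.arange(3.0), p)).power) > 0)


def test_band_mean_half_open_bins():
    """Toy 5-bin spectrum {4:−1, 5:−2, 6:−3, 7:−4, 8:−5} dB: theta [4,8)
    averages bins 4..7 → −2.5 dB; 8 Hz belongs to alpha."""
    psd = PSD(np.array([4.0, 5.0, 6.0, 7.0, 8.0]),
              np.array([-1.0, -2.0, -3.0, -4.0, -5.0]), in_db=True)
    assert band_power(psd, (4.0, 8.0)) == pytest.approx(-2.5)
    with pytest.raises(SpectralError):
        band_power(psd, (30.0, 40.0))


def test_flat_spectrum_gives_constant_band_power():
    freqs = np.arange(0, 125, 0.25)
    psd = PSD(freqs, np.full_like(freqs, -7.5), in_db=True)
    for edges in BANDS.values():
        assert band_power(psd, edges) == pytest.approx(-7.5)


def test_bands_are_disjoint_half_open():
    freqs = np.arange(0, 125, 0.0305)
    counts = np.zeros_like(freqs)
    for low, high in BANDS.values():
        counts += (freqs >= low) & (freqs < high)
    assert counts.max() <= 1


def test_doubling_band_limited_oscillation_adds_6db():
    """Doubling the amplitude of a band-limited oscillation raises its band's
    dB power by ~20·log10(2) while other bands move < 0.5 dB."""
    rng = np.random.default_rng(5)
    n = 14250
    freqs = np.fft.rfftfreq(n, 1 / FS)
    in_alpha = (freqs >= 8.0) & (freqs < 12.0)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    osc = np.fft.irfft(np.where(in_alpha, spec, 0), n=n)
    osc /= np.sqrt(np.mean(osc**2))
    broadband = 0.5 * rng.standard_normal(n)

    def powers(gain):
        tbl = band_power_table([_trial(broadband + gain * osc)])
        return tbl.set_index("band")["power_db"]

    diff = powers(2.0) - powers(1.0)
    assert abs(diff["alpha"] - 6.02) < 0.3
    for other in ("theta", "smr", "beta"):
        assert abs(diff[other]) < 0.5


def test_alpha_dominant_cohort_has_alpha_max(quiet_trial):
    tbl = band_power_table([quiet_trial])
    by_band = tbl.groupby("band")["power_db"].mean()
    assert by_band.idxmax() == "alpha"


def test_band_powers_reproducible(quiet_trial):
    a = band_power_table([quiet_trial])
    b = band_power_table([quiet_trial])
    pd.testing.assert_frame_equal(a, b)


class TestZscore:
    def _table(self, values, electrode="Fz", band="alpha"):
        return pd.DataFrame({
            "subject": [f"S{i}" for i in range(len(values))],
            "electrode": electrode, "band": band, "power_db": values})

    def test_mean_zero_sd_one_per_group(self, small_band_table):
        g = small_band_table.groupby(["electrode", "band"])["power_z"]
        assert np.all(np.abs(g.mean()) < 1e-10)
        assert np.all(np.abs(g.std(ddof=0) - 1) < 1e-10)

    def test_outlier_is_group_max(self):
        tbl = self._table([0.0, 0.1, -0.1, 0.05, 25.0])
        z = zscore_powers(tbl)
        assert z["power_z"].idxmax() == 4

    def test_affine_invariance(self):
        base = self._table([1.0, 2.0, 4.0, 8.0])
        shifted = self._table([10.0, 20.0, 40.0, 80.0])
        a = zscore_powers(base)["power_z"]
        b = zscore_powers(shifted)["power_z"]
        assert np.allclose(a, b)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(SpectralError):
            zscore_powers(self._table([3.0, 3.0, 3.0]))

    def test_single_record_group_rejected(self):
        with pytest.raises(SpectralError):
            zscore_powers(self._table([3.0]))


def test_invalid_spectral_configs_rejected():
    with pytest.raises(SpectralError):
        SpectralConfig(overlap_fraction=1.0)
    with pytest.raises(SpectralError):
        SpectralConfig(max_segments=0)
    with pytest.raises(SpectralError):
        SpectralConfig(bin_spacing=0.0)
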