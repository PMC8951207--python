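"""Filtering, segmentation, referencing, rejection, and the Laplacian."""

import numpy as np
import pytest
from scipy.signal import periodogram

from plinet.montage import Montage, default_montage
from plinet.preprocess import (
    Band, Recording, bandpass, downsample, laplacian, notch,
    preprocess_recording, reject_amplitude, rereference_average, segment,
)

from conftest import make_recording


def _sine(freq, fs=512.0, dur=10.0, n_ch=1):
    t = np.arange(int(dur * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


class TestMontage:
    def test_default_montage_has_canonical_20_and_symmetric_neighbors(self):
        m = default_montage()
        assert m.n_channels == 20
        for lab in m.labels:
            for nb in m.neighbors[lab]:
                assert lab in m.neighbors[nb]

    def test_asymmetric_neighbor_table_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            Montage(["A", "B", "C"], {"A": ["B"], "B": [], "C": []})

    def test_unknown_neighbor_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            Montage(["A", "B"], {"A": ["Z"], "B": []})


class TestBandpass:
    def test_in_band_sinusoid_amplitude_preserved(self):
        rec = make_recording(_sine(10.0), fs=512.0)
        out = bandpass(rec, 8.0, 13.0)
        mid = out.data[0, 2000:-2000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_notch_removes_mains(self):
        rec = make_recording(_sine(50.0), fs=512.0)
        out = notch(rec, 50.0)
        assert np.abs(out.data[0, 2000:-2000]).max() < 0.05

    def test_band_limited_noise_spectral_mass(self, rng):
        rec = make_recording(rng.standard_normal((1, 512 * 30)), fs=512.0)
        out = bandpass(rec, 13.0, 20.0)
        f, p = periodogram(out.data[0], fs=512.0)
        inside = p[(f >= 12.0) & (f <= 21.0)].sum()
        assert inside / p.sum() >= 0.90

    def test_band_outside_nyquist_rejected(self):
        rec = make_recording(_sine(10.0), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 10.0, 60.0)


class TestSegment:
    def test_61_seconds_gives_30_epochs_of_1024(self, rng):
        rec = make_recording(rng.standard_normal((2, int(61 * 512))), fs=512.0)
        ep = segment(rec, 2.0)
        assert ep.n_epochs == 30
        assert ep.samples_per_epoch == 1024

    def test_exactly_one_epoch(self, rng):
        rec = make_recording(rng.standard_normal((2, 1024)), fs=512.0)
        assert segment(rec, 2.0).n_epochs == 1

    def test_shorter_than_one_epoch_raises(self, rng):
        rec = make_recording(rng.standard_normal((2, int(1.9 * 512))), fs=512.0)
        with pytest.raises(ValueError, match="shorter"):
            segment(rec, 2.0)


class TestAverageReference:
    def test_constant_offset_annihilated(self):
        rec = make_recording(np.full((4, 2048), 7.5), fs=512.0)
        ep = rereference_average(segment(rec, 2.0))
        assert np.abs(ep.epochs).max() < 1e-12

    def test_channel_means_zero_and_idempotent(self, rng):
        rec = make_recording(rng.standard_normal((5, 4096)), fs=512.0)
        ep = rereference_average(segment(rec, 2.0))
        assert np.abs(ep.epochs.sum(axis=1)).max() < 1e-9
        again = rereference_average(ep)
        np.testing.assert_allclose(again.epochs, ep.epochs, atol=1e-12)

    def test_single_channel_rejected(self, rng):
        rec = make_recording(rng.standard_normal((1, 2048)), fs=512.0)
        with pytest.raises(ValueError, match="two channels"):
            rereference_average(segment(rec, 2.0))


class TestDownsample:
    def test_halves_sample_count_from_1024(self, rng):
        rec = make_recording(rng.standard_normal((3, 10240)), fs=1024.0)
        out = downsample(rec, 512.0)
        assert out.n_samples == 5120
        assert out.fs == 512.0

    def test_identity_when_target_equals_fs(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)), fs=512.0)
        assert downsample(rec, 512.0) is rec

    def test_low_frequency_survives(self):
        rec = make_recording(_sine(5.0, fs=1024.0, dur=8.0), fs=1024.0)
        out = downsample(rec, 512.0)
        assert np.abs(out.data[0, 500:-500]).max() == pytest.approx(1.0, rel=0.05)

    def test_upsampling_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)), fs=256.0)
        with pytest.raises(ValueError, match="upsample"):
            downsample(rec, 512.0)


class TestRejectAmplitude:
    def test_all_zero_epochs_kept(self):
        rec = make_recording(np.zeros((2, 4096)), fs=512.0)
        ep = reject_amplitude(segment(rec, 2.0), 80.0)
        assert ep.n_epochs == 4
        assert ep.kept_mask.all()

    def test_epoch_with_81_uv_sample_removed(self, rng):
        data = rng.standard_normal((2, 4096))
        data[1, 1500] = 81.0  # inside epoch 1
        ep = reject_amplitude(segment(make_recording(data, fs=512.0), 2.0), 80.0)
        assert ep.n_epochs == 3
        np.testing.assert_array_equal(ep.kept_mask, [True, False, True, True])

    def test_retained_epochs_unaltered(self, rng):
        data = rng.standard_normal((2, 4096))
        data[0, 3000] = 100.0  # falls in epoch 2
        ep0 = segment(make_recording(data, fs=512.0), 2.0)
        ep = reject_amplitude(ep0, 80.0)
        np.testing.assert_array_equal(ep.epochs, ep0.epochs[[0, 1, 3]])

    def test_infinite_limit_is_identity(self, rng):
        data = 1000 * rng.standard_normal((2, 4096))
        ep = reject_amplitude(segment(make_recording(data, fs=512.0), 2.0), np.inf)
        assert ep.n_epochs == 4


class TestLaplacian:
    def test_common_mode_annihilated(self, rng):
        sig = rng.standard_normal(2048)
        rec = make_recording(
            np.tile(sig, (3, 1)), fs=512.0, labels=["A", "B", "C"],
            neighbors={"A": ["B", "C"], "B": ["A", "C"], "C": ["A", "B"]},
        )
        ep = laplacian(segment(rec, 2.0))
        assert np.abs(ep.epochs).max() < 1e-12

    def test_single_zero_neighbor_leaves_channel_unchanged(self, rng):
        sig = rng.standard_normal(2048)
        rec = make_recording(
            np.vstack([sig, np.zeros(2048)]), fs=512.0, labels=["A", "B"],
            neighbors={"A": ["B"], "B": ["A"]},
        )
        ep = laplacian(segment(rec, 2.0))
        np.testing.assert_allclose(ep.epochs[0, 0], sig[:1024], atol=1e-12)

    def test_three_channel_chain_hand_value(self):
        # A=2, B=1, C=0 constant; B - (A+C)/2 = 0, A - B = 1, C - B = -1
        data = np.vstack([np.full(1024, 2.0), np.full(1024, 1.0), np.zeros(1024)])
        rec = make_recording(data, fs=512.0, labels=["A", "B", "C"],
                             neighbors={"A": ["B"], "B": ["A", "C"], "C": ["B"]})
        ep = laplacian(segment(rec, 2.0))
        np.testing.assert_allclose(ep.epochs[0, 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(ep.epochs[0, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(ep.epochs[0, 2], -1.0, atol=1e-12)

    def test_channel_without_neighbors_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 2048)), fs=512.0,
                             labels=["A", "B"], neighbors={})
        with pytest.raises(ValueError, match="no neighbors"):
            laplacian(segment(rec, 2.0))


def test_pipeline_provenance_records_step_order(montage, rng):
    data = rng.standard_normal((20, int(12 * 512)))
    rec = Recording(data, 512.0, montage)
    ep = preprocess_recording(rec, Band("beta2", 20.0, 30.0))
    steps = [s.split("(")[0] for s in ep.provenance]
    assert steps == ["segment", "rereference_average", "reject_amplitude", "laplacian"]
    assert ep.band.name == "beta2"
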