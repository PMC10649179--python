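"""Filtering and ICA artifact removal."""

import numpy as np
import pytest
from scipy import signal as sps

from mieeg.io import DEFAULT_CHANNELS, RawRecording
from mieeg.preprocess import (
    bandpass_filter,
    fit_ica,
    remove_components,
    remove_ocular_artifacts,
    score_frontal_artifact,
)


def _sine_recording(freq, fs=128.0, seconds=8.0, n_ch=2):
    t = np.arange(int(fs * seconds)) / fs
    x = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return RawRecording(x, [f"CH{i}" for i in range(n_ch)], fs)


class TestBandpass:
    def test_passband_tone_preserved(self):
        # oracle: two-pass Butterworth magnitude response at 15 Hz
        sos = sps.butter(4, [8, 30], btype="bandpass", fs=128, output="sos")
        _, h = sps.sosfreqz(sos, worN=[15.0], fs=128)
        expected_gain = np.abs(h[0]) ** 2          # forward-backward
        rec = bandpass_filter(_sine_recording(15.0))
        mid = rec.samples[0, 256:768]              # avoid edges
        measured = np.sqrt(2) * mid.std()
        assert measured == pytest.approx(expected_gain, rel=0.05)
        assert expected_gain == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated_20db(self):
        rec = bandpass_filter(_sine_recording(2.0))
        rms = np.sqrt(np.mean(rec.samples[0, 256:768] ** 2))
        assert 20 * np.log10(rms / np.sqrt(0.5)) < -20

    def test_zero_input_zero_output(self):
        rec = RawRecording(np.zeros((3, 512)), ["a", "b", "c"], 128.0)
        assert np.all(bandpass_filter(rec).samples == 0)

    def test_high_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_sine_recording(10.0), low=8, high=64)

    def test_interior_epoch_unaffected_by_neighbours(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 128 * 24))
        rec = RawRecording(x, ["a", "b"], 128.0)
        full = bandpass_filter(rec).samples[:, 128 * 8 : 128 * 16]
        # same trial filtered with 4 s of real context on each side
        padded = bandpass_filter(
            RawRecording(x[:, 128 * 4 : 128 * 20], ["a", "b"], 128.0)
        ).samples[:, 128 * 4 : 128 * 12]
        np.testing.assert_allclose(full, padded, atol=1e-6)


class TestIca:
    def _mixture(self, seed=0, n_t=4000):
        rng = np.random.default_rng(seed)
        s1 = np.sign(np.sin(2 * np.pi * 3 * np.arange(n_t) / 128))
        s2 = rng.laplace(size=n_t)
        S = np.vstack([s1, s2])
        A = np.array([[1.0, 0.4], [0.3, 1.0]])
        return RawRecording(A @ S, ["a", "b"], 128.0), S

    def test_recovers_independent_sources(self):
        rec, S = self._mixture()
        d = fit_ica(rec, seed=0)
        corr = np.abs(np.corrcoef(np.vstack([d.sources, S]))[:2, 2:])
        # best assignment up to sign/permutation
        assert max(corr[0, 0] * corr[1, 1], corr[0, 1] * corr[1, 0]) > 0.9
        assert corr.max(axis=1).min() > 0.95

    def test_reconstruction_accuracy(self):
        rec, _ = self._mixture()
        d = fit_ica(rec, seed=0)
        recon = d.reconstruct()
        err = np.linalg.norm(recon - rec.samples) / \
            np.linalg.norm(rec.samples)
        assert err < 1e-6

    def test_too_many_components_rejected(self):
        rec, _ = self._mixture()
        with pytest.raises(ValueError):
            fit_ica(rec, n_components=3)

    def test_deterministic_under_seed(self):
        rec, _ = self._mixture()
        d1 = fit_ica(rec, seed=5)
        d2 = fit_ica(rec, seed=5)
        np.testing.assert_array_equal(d1.mixing, d2.mixing)

    def test_rank_deficient_names_channels(self):
        x = np.zeros((3, 400))
        x[0] = np.random.default_rng(0).normal(size=400)
        x[1] = np.sin(np.arange(400) / 5)
        rec = RawRecording(x, ["good1", "good2", "flatline"], 128.0)
        with pytest.raises(ValueError, match="flatline"):
            fit_ica(rec)

    def test_short_recording_rejected(self):
        rec = RawRecording(np.random.default_rng(0).normal(size=(14, 100)),
                           list(DEFAULT_CHANNELS), 128.0)
        with pytest.raises(ValueError):
            fit_ica(rec)


class TestFrontalScore:
    def _decomp_from_mixing(self, mixing):
        from mieeg.preprocess import ICADecomposition

        mixing = np.asarray(mixing, float)
        return ICADecomposition(
            mixing=mixing,
            sources=np.zeros((mixing.shape[1], 10)),
            mean=np.zeros(mixing.shape[0]),
            channel_names=list(DEFAULT_CHANNELS),
        )

    def test_pure_frontal_component_scores_one(self):
        mixing = np.zeros((14, 2))
        mixing[list(DEFAULT_CHANNELS).index("AF3"), 0] = 2.0
        mixing[:, 1] = 0.1
        d = self._decomp_from_mixing(mixing)
        scores = score_frontal_artifact(d)
        assert scores[0] == pytest.approx(1.0)

    def test_uniform_component_scores_4_of_14(self):
        d = self._decomp_from_mixing(np.ones((14, 1)))
        assert score_frontal_artifact(d)[0] == pytest.approx(4 / 14)

    @pytest.mark.parametrize("factor", [-1.0, 0.3, -7.5])
    def test_invariant_to_sign_and_scale(self, factor):
        rng = np.random.default_rng(2)
        mixing = rng.normal(size=(14, 5))
        base = score_frontal_artifact(self._decomp_from_mixing(mixing))
        scaled = score_frontal_artifact(
            self._decomp_from_mixing(mixing * factor))
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_empty_frontal_set_rejected(self):
        d = self._decomp_from_mixing(np.ones((14, 2)))
        with pytest.raises(ValueError):
            score_frontal_artifact(d, frontal_channels=())


class TestRemoveComponents:
    def test_empty_rejection_is_identity(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(rng.normal(size=(4, 1000)),
                           ["w", "x", "y", "z"], 128.0)
        d = fit_ica(rec, seed=0)
        out = remove_components(rec, d, set())
        err = np.linalg.norm(out.samples - rec.samples) / \
            np.linalg.norm(rec.samples)
        assert err < 1e-6

    def test_reject_all_yields_mean_only(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(rng.normal(size=(4, 1000)),
                           ["w", "x", "y", "z"], 128.0)
        d = fit_ica(rec, seed=0)
        out = remove_components(rec, d, range(d.n_components))
        np.testing.assert_allclose(
            out.samples, np.tile(d.mean[:, None], (1, 1000)), atol=1e-8)

    def test_out_of_range_rejected(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(rng.normal(size=(4, 1000)),
                           ["w", "x", "y", "z"], 128.0)
        d = fit_ica(rec, seed=0)
        with pytest.raises(ValueError):
            remove_components(rec, d, {99})


class TestBlinkRemovalEndToEnd:
    def test_injected_blink_found_and_removed(self, bundle):
        from mieeg.simulate import SimulationConfig, simulate_trial

        cfg = SimulationConfig(snr_db=20.0, blink_rate=40.0)
        # concatenate several trials so ICA has enough data
        xs = []
        blink_spans = []
        offset = 0
        for s in range(8):
            x, truth = simulate_trial(cfg, 2, seed=100 + s,
                                      lead_field=bundle.lead_field,
                                      ves=bundle.ves)
            xs.append(x)
            for onset in truth.blink_onsets:
                a = offset + int(onset * cfg.fs)
                blink_spans.append((a, a + int(0.3 * cfg.fs)))
            offset += x.shape[1]
        rec = RawRecording(np.hstack(xs), list(DEFAULT_CHANNELS), cfg.fs)
        assert blink_spans, "generator produced no blinks at this rate"

        cleaned, decomp, rejected = remove_ocular_artifacts(rec, seed=0)
        scores = decomp.component_scores
        assert len(rejected) >= 1
        # the blink component is the top-scoring one
        assert scores.argmax() in rejected
        af3 = list(DEFAULT_CHANNELS).index("AF3")
        mask = np.zeros(rec.n_times, bool)
        for a, b in blink_spans:
            mask[a:b] = True
        rms_before = np.sqrt(np.mean(rec.samples[af3, mask] ** 2))
        rms_after = np.sqrt(np.mean(cleaned.samples[af3, mask] ** 2))
        assert rms_after <= 0.5 * rms_before
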