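"""Generator contracts: schedules, templates, noise spectrum, determinism."""

import numpy as np
import pytest
from scipy import signal, stats

import ierp
from ierp import (
    ErpComponent,
    SyntheticSessionSpec,
    generate_erp_template,
    generate_marker_schedule,
    generate_onset_envelope,
    generate_session,
)


class TestMarkerSchedule:
    def test_onsets_sorted_and_in_range(self, two_region_spec):
        spec = two_region_spec(seed=7, duration_s=90.0, n_phrase_boundaries=8)
        notes, phrases = generate_marker_schedule(spec)
        assert len(notes) > 200  # ioi 0.33 s over ~90 s
        assert np.all(np.diff(notes.times_s) > 0)
        assert notes.times_s[0] > 0 and notes.times_s[-1] < 90.0 - 0.6

    def test_phrases_subset_of_onsets(self, two_region_spec):
        spec = two_region_spec(seed=3, n_phrase_boundaries=4)
        notes, phrases = generate_marker_schedule(spec)
        assert len(phrases) == 4
        for t in phrases.times_s:
            assert np.any(np.isclose(notes.times_s, t))

    def test_zero_phrases(self, two_region_spec):
        _, phrases = generate_marker_schedule(two_region_spec(n_phrase_boundaries=0))
        assert len(phrases) == 0

    def test_deterministic(self, two_region_spec):
        spec = two_region_spec(seed=11)
        a = generate_marker_schedule(spec)
        b = generate_marker_schedule(spec)
        np.testing.assert_array_equal(a[0].times_s, b[0].times_s)
        np.testing.assert_array_equal(a[0].strengths, b[0].strengths)
        np.testing.assert_array_equal(a[1].times_s, b[1].times_s)

    def test_more_phrases_than_onsets_errors(self, two_region_spec):
        spec = two_region_spec(duration_s=5.0, ioi_mean_s=1.0, n_phrase_boundaries=50)
        with pytest.raises(ValueError, match="phrase"):
            generate_marker_schedule(spec)


class TestErpTemplate:
    def test_zero_amplitudes_all_zero(self):
        params = {"note_onset": (ErpComponent(100.0, 0.0, 60.0),)}
        assert not np.any(generate_erp_template("note_onset", 256.0, params))

    def test_note_onset_extrema_near_n1_p2(self):
        wave = generate_erp_template("note_onset", 256.0)
        assert len(wave) == 205
        t_ms = (np.arange(205) - 51) / 256.0 * 1000.0
        assert abs(t_ms[np.argmin(wave)] - 100.0) < 8.0
        assert abs(t_ms[np.argmax(wave)] - 200.0) < 8.0

    def test_phrase_has_prestimulus_energy_note_does_not(self):
        note = generate_erp_template("note_onset", 256.0)
        phrase = generate_erp_template("phrase_boundary", 256.0)
        pre = slice(0, 51)
        assert np.abs(phrase[pre]).max() > 0.1
        assert np.abs(note[pre]).max() < 1e-3

    def test_latency_out_of_window_errors(self):
        params = {"note_onset": (ErpComponent(700.0, 1.0, 60.0),)}
        with pytest.raises(ValueError, match="latency"):
            generate_erp_template("note_onset", 256.0, params)


class TestSession:
    def test_noiseless_session_is_pure_template(self, marker_track):
        spec = SyntheticSessionSpec(
            duration_s=10.0, region_names=("superior temporal",),
            n_channels_per_region=1, noise_sd=0.0, ied_rate_hz=0.0,
            ioi_mean_s=6.0, ioi_jitter_s=0.01, n_phrase_boundaries=0,
            region_gains={"superior temporal": 1.0}, seed=0,
        )
        rec, notes, phrases, gt = generate_session(spec)
        assert len(notes) == 1
        tpl = generate_erp_template("note_onset", spec.fs, spec.erp_params)
        c = int(round(notes.times_s[0] * spec.fs))
        pre = 102  # floor(200 ms * 512 Hz)
        np.testing.assert_allclose(rec.data[0, c - pre : c - pre + len(tpl)], tpl)
        outside = np.concatenate(
            [rec.data[0, : c - pre], rec.data[0, c - pre + len(tpl) :]]
        )
        assert not np.any(outside)

    def test_bit_identical_given_seed(self, two_region_spec):
        r1 = generate_session(two_region_spec(seed=5))[0]
        r2 = generate_session(two_region_spec(seed=5))[0]
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_amplitude_additivity(self, two_region_spec):
        def with_amp(a):
            params = {
                "note_onset": (ErpComponent(100.0, -a, 60.0),),
                "phrase_boundary": (ErpComponent(200.0, a, 80.0),),
            }
            return generate_session(two_region_spec(seed=4, erp_params=params))[0]

        r0, r1, r2 = with_amp(0.0), with_amp(1.0), with_amp(2.0)
        np.testing.assert_allclose(
            r2.data - r1.data, r1.data - r0.data, rtol=0, atol=1e-9
        )

    @pytest.mark.parametrize("alpha", [1.0, 1.5])
    def test_noise_spectral_slope(self, alpha):
        spec = SyntheticSessionSpec(
            duration_s=60.0, region_names=("superior temporal", "insular"),
            n_channels_per_region=1, noise_exponent=alpha,
            erp_params={"note_onset": (), "phrase_boundary": ()},
            ied_rate_hz=0.0, channel_sd_jitter=0.0, seed=2,
        )
        rec, *_ = generate_session(spec)
        f, p = signal.welch(rec.data[0], fs=spec.fs, nperseg=4096)
        band = (f >= 1.0) & (f <= 100.0)
        slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
        assert abs(slope + alpha) < 0.3

    def test_ied_count_in_poisson_interval(self):
        spec = SyntheticSessionSpec(
            duration_s=90.0, region_names=("superior temporal", "insular"),
            n_channels_per_region=5, ied_rate_hz=0.02, seed=9,
        )
        _, _, _, gt = generate_session(spec)
        total = sum(len(v) for v in gt.ied_times.values())
        lo, hi = stats.poisson.ppf([0.005, 0.995], 0.02 * 90.0 * 10)
        assert lo <= total <= hi

    def test_injected_latencies_recoverable_by_averaging(self):
        spec = SyntheticSessionSpec(
            seed=21, region_names=("superior temporal", "rostral middle frontal"),
            n_channels_per_region=1,
            region_gains={"superior temporal": 1.0, "rostral middle frontal": 1.0},
            ied_rate_hz=0.0,
        )
        rec, notes, _, gt = generate_session(spec)
        assert len(notes) >= 200
        pre, post = 102, 307
        c = np.round(notes.times_s * spec.fs).astype(int)
        idx = c[:, None] + np.arange(-pre, post + 1)[None, :]
        erp = rec.data[0, idx].mean(axis=0)
        tpl = gt.templates["note_onset"]
        assert abs(int(np.argmin(erp)) - int(np.argmin(tpl))) <= 2
        assert abs(int(np.argmax(erp)) - int(np.argmax(tpl))) <= 2


class TestOnsetEnvelope:
    def test_noiseless_peaks_at_onsets(self, marker_track):
        track = marker_track([0.5, 1.0, 2.0], strengths=[2.0, 3.0, 1.5])
        env = generate_onset_envelope(track, fs_env=100.0, noise_sd=0.0)
        peaks = np.flatnonzero(
            (env[1:-1] > env[:-2]) & (env[1:-1] > env[2:])
        ) + 1
        np.testing.assert_array_equal(peaks, [50, 100, 200])
        np.testing.assert_allclose(env[peaks], [2.0, 3.0, 1.5])

    def test_empty_track_all_zero(self, marker_track):
        env = generate_onset_envelope(marker_track([]), fs_env=100.0, duration_s=2.0)
        assert not np.any(env)
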