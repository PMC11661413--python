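"""Generator contracts: beat-train statistics, waveform phenomenology,
artifact bookkeeping, and dataset-level invariants."""
import numpy as np
import pandas as pd
import pytest

import ppgarr as pa
from ppgarr.adjudicate import adjudicate_segment, flag_premature_beats
from ppgarr.records import FS, L, Rhythm
from ppgarr.simulate import (SimulationConfig, generate_dataset, generate_rr_af,
                             generate_rr_nsr, generate_rr_pacpvc,
                             inject_artifact, synthesize_acc, synthesize_ppg,
                             windows_to_mask)


class TestNsrTrains:
    def test_rate_times_duration(self, rng):
        train = generate_rr_nsr(60, rng=rng)
        assert 25 <= train.n_beats <= 35
        assert np.all(np.abs(np.diff(train.instantaneous_hr)) < 10)

    def test_every_train_satisfies_delta_rule(self):
        """No NSR train may contain a >=10 BPM beat-to-beat change."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            hr = rng.uniform(45, 110)
            train = generate_rr_nsr(hr, rng=rng, premature_prob=0.0)
            assert np.all(np.abs(np.diff(train.instantaneous_hr)) < 10)

    def test_tail_premature_stays_nsr(self):
        rng = np.random.default_rng(1)
        n_with = 0
        for _ in range(200):
            train = generate_rr_nsr(70, rng=rng, premature_prob=1.0)
            n_with += int(train.premature_flags.sum() > 0)
            assert flag_premature_beats(train.beat_times).sum() <= 2
            assert adjudicate_segment(train.beat_times, False) == Rhythm.NSR
        assert n_with > 150  # insertion succeeds most of the time

    def test_mean_hr_domain(self, rng):
        with pytest.raises(ValueError):
            generate_rr_nsr(25, rng=rng)
        with pytest.raises(ValueError):
            generate_rr_nsr(250, rng=rng)


class TestAfTrains:
    def test_every_window_has_jump(self, rng):
        train = generate_rr_af(80, 0.2, rng=rng)
        hr = train.instantaneous_hr
        jump_t = train.beat_times[2:][np.abs(np.diff(hr)) >= 10]
        for w in range(6):
            assert np.any((jump_t >= 5 * w) & (jump_t < 5 * (w + 1)))

    def test_zero_dispersion_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_rr_af(80, 0.0, rng=rng)
        with pytest.raises(RuntimeError):
            generate_rr_af(80, 0.01, rng=rng, max_tries=20)

    def test_population_mean_hr(self):
        """Mean instantaneous HR over many AF trains matches the request."""
        rng = np.random.default_rng(3)
        hrs = []
        for _ in range(500):
            train = generate_rr_af(80, 0.2, rng=rng)
            hrs.append(train.instantaneous_hr.mean())
        assert abs(np.mean(hrs) - 80) < 2.0


class TestPacPvcTrains:
    def test_isolated_count_conservation(self, rng):
        train = generate_rr_pacpvc(70, pattern="isolated", n_premature=3, rng=rng)
        assert int(train.premature_flags.sum()) == 3

    def test_coupling_arithmetic(self, rng):
        """Premature IBI ~ coupling x base RR; compensatory pause restores phase."""
        train = generate_rr_pacpvc(70, pattern="isolated", n_premature=4,
                                   coupling=0.6, rng=rng)
        t = train.beat_times
        for k in np.flatnonzero(train.premature_flags):
            prem_ibi = t[k] - t[k - 1]
            prev_ibi = t[k - 1] - t[k - 2]
            # preceding RR drifts a few % beat to beat, hence the slack
            assert prem_ibi / prev_ibi == pytest.approx(0.6, abs=0.08)
            if k + 1 < t.size:
                pause = t[k + 1] - t[k]
                assert pause / prev_ibi == pytest.approx(1.4, abs=0.15)

    def test_every_premature_jumps_at_least_10bpm(self, rng):
        train = generate_rr_pacpvc(70, pattern="mixed", n_premature=5, rng=rng)
        hr = train.instantaneous_hr
        delta = np.abs(np.diff(hr))
        for k in np.flatnonzero(train.premature_flags):
            assert delta[k - 2] >= 10  # delta index of the beat closing IBI k

    def test_bigeminy_zigzag(self, rng):
        """Alternating short/long IBIs give a two-level rectangular HR."""
        train = generate_rr_pacpvc(70, pattern="bigeminy", n_premature=10, rng=rng)
        flagged = np.flatnonzero(train.premature_flags)
        run = train.beat_times[flagged[0] - 1:flagged[-1] + 2]
        ibis = np.diff(run)  # starts with the first premature (short) interval
        short, long_ = ibis[0::2], ibis[1::2]
        assert short.max() < long_.min()

    def test_needs_three_premature(self, rng):
        with pytest.raises(ValueError):
            generate_rr_pacpvc(70, n_premature=2, rng=rng)


class TestSynthesizePpg:
    def test_one_pulse_per_beat(self, rng):
        t = np.arange(0.3, 30, 1.0)
        train = pa.BeatTrain(t, np.zeros(t.size, bool), Rhythm.NSR)
        x = synthesize_ppg(train, rng=rng, noise_sd=0.0, wander_amp=0.0)
        assert x.size == L
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(x, height=0.5, distance=FS // 4)
        assert peaks.size == t.size

    def test_zero_beats_flat_noise(self, rng):
        train = pa.BeatTrain(np.empty(0), np.empty(0, bool), Rhythm.NSR)
        x = synthesize_ppg(train, rng=rng, noise_sd=0.02, wander_amp=0.0)
        assert np.abs(x).max() < 0.15

    def test_spectral_peak_at_pulse_rate(self, rng):
        t = np.arange(0.25, 30, 0.8)  # 75 BPM
        train = pa.BeatTrain(t, np.zeros(t.size, bool), Rhythm.NSR)
        x = synthesize_ppg(train, rng=rng, noise_sd=0.0, wander_amp=0.0)
        spec = np.abs(np.fft.rfft(x - x.mean()))
        freqs = np.fft.rfftfreq(x.size, 1.0 / FS)
        # dominant non-DC component sits at the 1.25 Hz pulse rate (bin width 1/30)
        assert freqs[spec.argmax()] == pytest.approx(1.25, abs=0.05)


class TestSynthesizeAcc:
    def test_rest_statistics(self, rng):
        acc = synthesize_acc([], rng=rng)
        assert acc.mean() == pytest.approx(9.8, abs=0.05)
        assert acc.std() < 0.1

    def test_burst_elevates_window(self, rng):
        acc = synthesize_acc([(10.0, 13.0)], rng=rng)
        mask = windows_to_mask([(10.0, 13.0)])
        assert acc[mask].mean() > acc[~mask].mean() + 1.0
        assert acc.max() <= 20.0

    def test_full_segment_window(self, rng):
        acc = synthesize_acc([(0.0, 30.0)], rng=rng)
        assert acc.min() > 9.0 and acc.mean() > 10.0


class TestInjectArtifact:
    def test_no_windows_is_identity(self, rng):
        x = rng.normal(size=L)
        out, mask = inject_artifact(x, [], rng=rng)
        assert np.array_equal(out, x) and not mask.any()

    def test_mask_bookkeeping(self, rng):
        x = rng.normal(size=L)
        out, mask = inject_artifact(x, [(2.0, 4.5), (10.0, 11.5)], rng=rng)
        assert mask.sum() / FS == pytest.approx(4.0, abs=1.0 / FS)

    def test_corruption_confined_to_windows(self, rng):
        x = rng.normal(size=L)
        out, mask = inject_artifact(x, [(5.0, 8.0)], rng=rng)
        assert np.array_equal(out[~mask], x[~mask])
        assert np.sqrt(np.mean((out[mask] - x[mask]) ** 2)) > 0


class TestGenerateDataset:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_nsr_subjects=2, n_af_subjects=1,
                               n_pacpvc_subjects=1, segments_per_subject=3,
                               rng_seed=5)
        recs1, man1 = generate_dataset(cfg)
        recs2, man2 = generate_dataset(cfg)
        pd.testing.assert_frame_equal(man1, man2)
        for a, b in zip(recs1, recs2):
            assert np.array_equal(a.ppg, b.ppg)
            assert np.array_equal(a.acc, b.acc)
            assert np.array_equal(a.beats.beat_times, b.beats.beat_times)

    def test_nsr_only_subjects_have_no_arrhythmia(self, small_dataset):
        cfg, _, manifest = small_dataset
        nsr_subjects = [f"S{i:03d}" for i in range(cfg.n_nsr_subjects)]
        sub = manifest[manifest["subject_id"].isin(nsr_subjects)]
        assert set(sub["rhythm_label"]) == {"NSR"}

    def test_label_consistency(self, small_dataset):
        """Adjudicating ground-truth beats returns the generating label."""
        _, records, _ = small_dataset
        for rec in records:
            label = adjudicate_segment(rec.beats,
                                       af_span_flag=rec.rhythm_label == Rhythm.AF)
            assert label == rec.rhythm_label

    def test_artifact_conservation(self, small_dataset):
        cfg, records, _ = small_dataset
        for rec in records:
            secs = rec.artifact_seconds
            assert secs == 0.0 or secs == pytest.approx(
                cfg.artifact_total_seconds, abs=1.0 / FS)

    def test_class_mix_near_requested(self):
        """Composition ~10:2:1 NSR:AF:PAC/PVC over ~1,000 segments."""
        cfg = SimulationConfig(n_nsr_subjects=48, n_af_subjects=21,
                               n_pacpvc_subjects=21, segments_per_subject=12,
                               rng_seed=17)
        _, manifest = generate_dataset(cfg)
        counts = manifest["rhythm_label"].value_counts()
        n = len(manifest)
        assert n >= 1000
        assert counts["NSR"] / n > 0.65
        assert 0.08 < counts["AF"] / n < 0.20
        assert 0.04 < counts["PACPVC"] / n < 0.15

    def test_empty_config(self):
        cfg = SimulationConfig(n_nsr_subjects=0, n_af_subjects=0,
                               n_pacpvc_subjects=0)
        records, manifest = generate_dataset(cfg)
        assert records == [] and manifest.empty

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(premature_coupling=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(artifact_total_seconds=40.0)
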