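from dataclasses import replace

import numpy as np
import pytest

from eegrhythm import (
    GeneratorConfig,
    default_task_map,
    generate_band_signal,
    generate_cohort,
    generate_recording,
    headline_preset,
    hemispheric_contrast,
    read_records,
    recordings_to_features,
    task_contrast,
    validate_sampling,
    write_records,
)
from eegrhythm.synthetic import (
    BAND_EDGES_HZ,
    TASK_CHAT,
    TASK_PAYMENT,
    load_config,
    save_config,
)

#: Small cohort used where only directions, not magnitudes, matter.
SMALL = dict(n_subjects=2, n_trained=1, n_events=4, epoch_duration_s=2.0)


def band_energy_fraction(x, low, high, fs):
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    inside = spec[(f >= low) & (f <= high)].sum()
    return inside / spec.sum()


class TestGenerateBandSignal:
    @pytest.mark.parametrize("band", list(BAND_EDGES_HZ))
    def test_spectral_energy_confined_to_band(self, band, rng):
        low, high = BAND_EDGES_HZ[band]
        x = generate_band_signal((low, high), 4.0, 128.0, rng)
        # allow half a DFT bin of leakage on either side
        assert band_energy_fraction(x, low - 0.3, high + 0.3, 128.0) >= 0.95

    def test_delta_content_below_4hz(self, rng):
        x = generate_band_signal((0.5, 3.5), 4.0, 128.0, rng)
        assert band_energy_fraction(x, 0.0, 4.0, 128.0) > 0.95

    def test_amplitude_scaling(self, rng):
        x = generate_band_signal((8.0, 13.0), 4.0, 128.0, rng,
                                 amplitude_uv=(20.0, 200.0))
        rms = np.sqrt(np.mean(x**2))
        assert 20.0 / np.sqrt(2.0) <= rms <= 200.0 / np.sqrt(2.0)

    def test_zero_duration_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_band_signal((8.0, 13.0), 0.0, 128.0, rng)

    def test_invalid_edges_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_band_signal((13.0, 8.0), 1.0, 128.0, rng)
        with pytest.raises(ValueError):
            generate_band_signal((8.0, 70.0), 1.0, 128.0, rng)

    def test_same_seed_same_signal(self):
        a = generate_band_signal((4.0, 7.0), 2.0, 128.0,
                                 np.random.default_rng(7))
        b = generate_band_signal((4.0, 7.0), 2.0, 128.0,
                                 np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestGeneratorConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GeneratorConfig(band_fractions={
                "delta": 0.5, "theta": 0.3, "alpha": 0.1, "beta": 0.2,
            })

    def test_fractions_must_be_positive(self):
        with pytest.raises(ValueError):
            GeneratorConfig(band_fractions={
                "delta": 0.6, "theta": 0.3, "alpha": -0.1, "beta": 0.2,
            })

    def test_edges_must_fit_nyquist(self):
        with pytest.raises(ValueError):
            GeneratorConfig(band_edges={**BAND_EDGES_HZ, "beta": (14.0, 70.0)})

    def test_cohort_bounds(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=0)
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=4, n_trained=5)

    def test_headline_preset_injects_all_effects(self):
        cfg = headline_preset()
        fracs = cfg.band_fractions
        assert min(fracs, key=fracs.get) == "alpha"
        assert cfg.left_beta_boost > 1.0
        assert cfg.task1_beta_boost > 1.0
        assert cfg.trained_beta_boost > 1.0

    def test_sidecar_round_trip(self, tmp_path):
        cfg = headline_preset(seed=42)
        save_config(cfg, tmp_path / "gen.yaml")
        assert load_config(tmp_path / "gen.yaml") == cfg


class TestGenerateRecording:
    def test_default_event_structure(self):
        cfg = replace(GeneratorConfig(seed=1), epoch_duration_s=1.0)
        rec = generate_recording(cfg, 1)
        assert set(rec.event_ids) == set(range(10))  # scenes 1..9 plus gaps
        assert validate_sampling(rec).ok

    def test_gap_lengths_within_isi_range(self):
        cfg = replace(GeneratorConfig(seed=2), epoch_duration_s=1.0, n_events=5)
        rec = generate_recording(cfg, 1)
        ids = rec.event_ids
        runs = np.split(np.arange(len(ids)), np.flatnonzero(np.diff(ids)) + 1)
        gap_lengths = [len(r) for r in runs if ids[r[0]] == 0]
        assert len(gap_lengths) == 5
        for n in gap_lengths:
            assert 1000 <= n / cfg.fs * 1000 <= 2000 + 1000 / cfg.fs

    def test_deterministic_under_seed(self):
        cfg = replace(GeneratorConfig(seed=3), **SMALL)
        a = generate_recording(cfg, 1)
        b = generate_recording(cfg, 1)
        np.testing.assert_array_equal(a.voltages, b.voltages)
        np.testing.assert_array_equal(a.event_ids, b.event_ids)

    def test_seed_changes_output(self):
        a = generate_recording(replace(GeneratorConfig(seed=3), **SMALL), 1)
        b = generate_recording(replace(GeneratorConfig(seed=4), **SMALL), 1)
        assert not np.array_equal(a.voltages, b.voltages)

    def test_baseline_is_channel_average(self):
        cfg = replace(GeneratorConfig(seed=5), **SMALL)
        rec = generate_recording(cfg, 1)
        np.testing.assert_allclose(rec.baseline, rec.voltages.mean(axis=1),
                                   atol=1e-12)

    def test_incomplete_schedule_rejected(self):
        cfg = replace(GeneratorConfig(seed=1), **SMALL)
        with pytest.raises(ValueError, match="events"):
            generate_recording(cfg, 1, task_schedule={1: TASK_PAYMENT})

    def test_write_read_round_trip(self, tmp_path):
        cfg = replace(GeneratorConfig(seed=6), **SMALL)
        rec = generate_recording(cfg, 1)
        write_records([rec], tmp_path / "r.tsv")
        back = read_records(tmp_path / "r.tsv")[0]
        np.testing.assert_array_equal(back.event_ids, rec.event_ids)
        np.testing.assert_allclose(back.voltages, rec.voltages, atol=1e-5)
        assert validate_sampling(back).ok


class TestGenerateCohort:
    def test_default_cohort_composition(self):
        cfg = replace(GeneratorConfig(seed=1), n_events=1,
                      epoch_duration_s=0.5)
        recordings, groups = generate_cohort(cfg)
        assert len(recordings) == 12
        assert sorted(groups) == list(range(1, 13))
        assert sum(g == "trained" for g in groups.values()) == 4

    def test_effect_injection_recovered_by_pipeline(self):
        cfg = replace(headline_preset(seed=9), n_subjects=2, n_trained=1,
                      epoch_duration_s=4.0)
        recordings, groups = generate_cohort(cfg)
        table = recordings_to_features(recordings, default_task_map())
        hemi = hemispheric_contrast(table, "beta")
        assert hemi.group_means["left"] > hemi.group_means["right"]
        task = task_contrast(table, "beta", TASK_PAYMENT, TASK_CHAT)
        assert task.mean_difference > 0

    def test_null_boosts_give_near_zero_contrasts(self):
        cfg = replace(
            headline_preset(seed=12), n_subjects=2, n_trained=1,
            epoch_duration_s=4.0,
            left_beta_boost=1.0, task1_beta_boost=1.0, trained_beta_boost=1.0,
        )
        recordings, _ = generate_cohort(cfg)
        table = recordings_to_features(recordings, default_task_map())
        hemi = hemispheric_contrast(table, "beta")
        assert abs(hemi.mean_difference) < 0.03
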