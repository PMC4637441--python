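import logging

import numpy as np
import pandas as pd
import pytest

from eegrhythm import (
    CHANNELS,
    default_montage,
    epoch_by_event,
    read_features,
    read_records,
    validate_sampling,
    write_features,
    write_records,
)
from eegrhythm.record_io import (
    RecordFormatError,
    RecordParseError,
    StructureError,
)
from eegrhythm.wavelet import InsufficientDataError

from conftest import SAMPLE_ROW1_VOLTAGES, make_recording


class TestMontage:
    def test_partition(self):
        m = default_montage()
        left, right = set(m.side("left")), set(m.side("right"))
        assert left == {"Fp1", "T3", "C3", "O1"}
        assert right == {"Fp2", "T4", "C4", "O2"}
        assert left | right == set(m.channels)
        assert not left & right

    def test_regions(self):
        m = default_montage()
        assert set(m.in_region("frontal")) == {"Fp1", "Fp2"}
        assert set(m.in_region("parietal")) == {"T3", "T4", "C3", "C4"}
        assert set(m.in_region("occipital")) == {"O1", "O2"}

    def test_homologous_pairs_are_mirrored(self):
        pairs = default_montage().homologous_pairs
        assert pairs == (("Fp1", "Fp2"), ("T3", "T4"), ("C3", "C4"), ("O1", "O2"))


class TestReadRecords:
    def test_sample_rows_parse(self, sample_record_file):
        recs = read_records(sample_record_file)
        assert [r.tester_id for r in recs] == [1, 12]
        r1 = recs[0]
        assert r1.time_s[0] == pytest.approx(210.633)
        np.testing.assert_allclose(r1.voltages[0], SAMPLE_ROW1_VOLTAGES)
        assert r1.baseline[0] == pytest.approx(-738.123)
        assert r1.event_ids[0] == 1

    def test_round_trip(self, tmp_path, rng):
        rec = make_recording([1] * 40 + [2] * 40, rng)
        path = tmp_path / "rt.tsv"
        write_records([rec], path)
        back = read_records(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].voltages, rec.voltages, rtol=1e-6)
        np.testing.assert_allclose(back[0].time_s, rec.time_s, atol=1e-6)
        np.testing.assert_array_equal(back[0].event_ids, rec.event_ids)

    def test_comma_dialect(self, tmp_path, rng):
        rec = make_recording([1] * 32, rng)
        path = tmp_path / "rt.csv"
        write_records([rec], path, sep=",")
        np.testing.assert_allclose(
            read_records(path)[0].voltages, rec.voltages, rtol=1e-6
        )

    def test_missing_column_is_named(self, tmp_path, sample_record_file):
        df = pd.read_csv(sample_record_file, sep="\t")
        bad = tmp_path / "bad.tsv"
        df.drop(columns=["Baseline"]).to_csv(bad, sep="\t", index=False)
        with pytest.raises(RecordFormatError, match="Baseline"):
            read_records(bad)

    def test_non_numeric_cell_names_row(self, tmp_path, sample_record_file):
        text = sample_record_file.read_text().replace("25.359", "oops", 1)
        bad = tmp_path / "bad.tsv"
        bad.write_text(text)
        with pytest.raises(RecordParseError, match="row 1"):
            read_records(bad)

    def test_empty_file(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(ValueError):
            read_records(empty)


class TestValidateSampling:
    def test_sample_timestamps_consistent_with_128hz(self, sample_record_file):
        rec = read_records(sample_record_file)[0]
        report = validate_sampling(rec)
        assert report.ok
        assert report.median_interval_s == pytest.approx(1 / 128, rel=0.05)

    def test_flat_time_axis_fails(self, rng):
        rec = make_recording([1] * 20, rng)
        rec.time_s = np.zeros(20)
        report = validate_sampling(rec)
        assert not report.ok
        assert "zero" in report.message

    def test_too_few_samples(self, rng):
        rec = make_recording([1], rng)
        with pytest.raises(InsufficientDataError):
            validate_sampling(rec)

    def test_generator_time_axis_passes(self):
        from dataclasses import replace

        from eegrhythm import GeneratorConfig, generate_recording

        cfg = replace(GeneratorConfig(seed=5), epoch_duration_s=1.0, n_events=2)
        assert validate_sampling(generate_recording(cfg, 1)).ok


class TestEpochByEvent:
    TASKS = {i: f"task {i}" for i in range(1, 10)}

    def test_nine_scenes_give_nine_epochs(self, rng):
        ids = np.repeat(np.arange(1, 10), 32)
        epochs = epoch_by_event(make_recording(ids, rng), self.TASKS)
        assert [e.event_id for e in epochs] == list(range(1, 10))
        assert all(e.n_samples == 32 for e in epochs)

    def test_single_event_returns_whole_recording(self, rng):
        rec = make_recording([3] * 50, rng)
        (epoch,) = epoch_by_event(rec, self.TASKS)
        np.testing.assert_array_equal(epoch.voltages, rec.voltages)
        assert epoch.task_label == "task 3"

    def test_short_run_dropped_with_warning(self, rng, caplog):
        ids = [1] * 32 + [2] * 10 + [3] * 32
        with caplog.at_level(logging.WARNING):
            epochs = epoch_by_event(make_recording(ids, rng), self.TASKS)
        assert [e.event_id for e in epochs] == [1, 3]
        assert any("dropping event 2" in m for m in caplog.messages)

    def test_gap_samples_discarded(self, rng):
        ids = [0] * 20 + [1] * 32 + [0] * 20 + [2] * 32
        epochs = epoch_by_event(make_recording(ids, rng), self.TASKS)
        assert [e.event_id for e in epochs] == [1, 2]

    def test_interleaved_events_rejected(self, rng):
        ids = [1] * 32 + [2] * 32 + [1] * 32
        with pytest.raises(StructureError):
            epoch_by_event(make_recording(ids, rng), self.TASKS)

    def test_sample_count_conserved(self, rng):
        ids = [1] * 32 + [2] * 5 + [3] * 32
        rec = make_recording(ids, rng)
        epochs = epoch_by_event(rec, self.TASKS)
        assert sum(e.n_samples for e in epochs) <= rec.n_samples


class TestFeatureTableIO:
    @staticmethod
    def _table(n_tasks=2):
        from eegrhythm import BANDS

        rows = []
        for c in CHANNELS:
            for b in BANDS:
                for t in range(1, n_tasks + 1):
                    rows.append({
                        "channel": c, "band": b, "task": f"task {t}",
                        "rhythm_energy": 0.1, "energy_ratio": 0.25,
                    })
        return pd.DataFrame(rows)

    def test_two_task_table_has_64_rows(self, tmp_path):
        path = tmp_path / "f.csv"
        write_features(self._table(), path)
        assert len(read_features(path)) == 64

    def test_round_trip(self, tmp_path):
        table = self._table(1)
        table["energy_ratio"] = np.linspace(0.1, 0.9, len(table))
        path = tmp_path / "f.csv"
        write_features(table, path)
        back = read_features(path)
        merged = table.merge(back, on=["channel", "band", "task"])
        np.testing.assert_allclose(
            merged["energy_ratio_x"], merged["energy_ratio_y"], atol=1e-6
        )

    def test_channel_major_band_ordered(self, tmp_path):
        path = tmp_path / "f.csv"
        write_features(self._table(1), path)
        back = read_features(path)
        assert list(back["channel"][:4]) == ["Fp1"] * 4
        assert list(back["band"][:4]) == ["delta", "theta", "alpha", "beta"]

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_features(pd.DataFrame(), tmp_path / "f.csv")
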