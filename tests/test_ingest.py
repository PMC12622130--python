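import numpy as np
import pandas as pd
import pytest

import luxwear as lw
from luxwear.errors import ConfigurationError, DataError

from conftest import make_stream


class TestDeviceCsv:
    def test_roundtrip_is_bit_exact(self, tmp_path, rng):
        n = 200
        stream = make_stream(
            n=n,
            lux=rng.uniform(0, 100_000, n),
            medi=rng.uniform(0, 90_000, n),
            tat=rng.integers(0, 10, n),
            orientation=rng.choice([2, 16, 32, 4], n),
        )
        path = tmp_path / "dev.csv"
        lw.write_device_csv(stream, path)
        back = lw.read_device_csv(path)
        np.testing.assert_array_equal(back.photopic_lux, stream.photopic_lux)
        np.testing.assert_array_equal(back.medi_lux, stream.medi_lux)
        np.testing.assert_array_equal(back.tat_count, stream.tat_count)
        np.testing.assert_array_equal(back.orientation_code, stream.orientation_code)
        assert (back.timestamps == stream.timestamps).all()

    def test_values_preserved_including_range_extremes(self, tmp_path):
        path = tmp_path / "dev.csv"
        path.write_text(
            "timestamp,photopic_lux,medi_lux,tat,orientation\n"
            "2025-01-06T08:00:00,0,0,0,16\n"
            "2025-01-06T08:01:00,50,40,3,2\n"
            "2025-01-06T08:02:00,100000,90000,0,32\n"
        )
        stream = lw.read_device_csv(path)
        assert len(stream) == 3
        np.testing.assert_array_equal(stream.photopic_lux, [0, 50, 100_000])

    def test_duplicated_timestamp_is_data_error(self, tmp_path):
        path = tmp_path / "dev.csv"
        path.write_text(
            "timestamp,photopic_lux,medi_lux,tat,orientation\n"
            "2025-01-06T08:00:00,1,1,0,2\n"
            "2025-01-06T08:00:00,2,2,0,2\n"
        )
        with pytest.raises(DataError, match="non-monotonic.*row 3"):
            lw.read_device_csv(path)

    def test_gap_is_flagged(self, tmp_path):
        path = tmp_path / "dev.csv"
        rows = ["2025-01-06T08:00:00", "2025-01-06T08:01:00", "2025-01-06T08:11:00"]
        path.write_text(
            "timestamp,photopic_lux,medi_lux,tat,orientation\n"
            + "".join(f"{t},1,1,0,2\n" for t in rows)
        )
        stream = lw.read_device_csv(path)
        assert len(stream.gaps) == 1
        assert stream.gaps[0].minutes == 10
        assert stream.gaps[0].index == 2

    def test_unparseable_timestamp_rows_rejected_with_report(self, tmp_path):
        path = tmp_path / "dev.csv"
        path.write_text(
            "timestamp,photopic_lux,medi_lux,tat,orientation\n"
            "2025-01-06T08:00:00,1,1,0,2\n"
            "not-a-time,2,2,0,2\n"
            "2025-01-06T08:02:00,3,3,0,2\n"
        )
        with pytest.warns(UserWarning, match="rejected 1 rows"):
            stream = lw.read_device_csv(path)
        assert len(stream) == 2

    def test_missing_mapped_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "dev.csv"
        path.write_text("timestamp,photopic_lux\n2025-01-06T08:00:00,1\n")
        with pytest.raises(ConfigurationError, match="missing"):
            lw.read_device_csv(path)

    def test_custom_dialect_maps_columns(self, tmp_path):
        path = tmp_path / "dev.csv"
        path.write_text(
            "DATETIME,LIGHT,MEL,MOVE,POS\n"
            "2025-01-06T08:00:00,7,5,1,2\n"
            "2025-01-06T08:01:00,8,6,0,16\n"
        )
        stream = lw.read_device_csv(
            path,
            dialect={
                "timestamp": "DATETIME",
                "photopic_lux": "LIGHT",
                "medi_lux": "MEL",
                "tat": "MOVE",
                "orientation": "POS",
            },
        )
        np.testing.assert_array_equal(stream.photopic_lux, [7, 8])


class TestStreamInvariants:
    def test_negative_lux_rejected(self):
        with pytest.raises(DataError, match="negative"):
            make_stream(n=3, lux=[1, -2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError, match="length"):
            make_stream(n=3, lux=[1, 2])

    def test_non_whole_minute_spacing_rejected(self):
        ts = pd.DatetimeIndex(
            ["2025-01-06 08:00:00", "2025-01-06 08:00:30", "2025-01-06 08:01:30"]
        )
        with pytest.raises(DataError, match="whole-minute"):
            make_stream(timestamps=ts)


class TestDiary:
    def _write(self, tmp_path, rows):
        path = tmp_path / "diary.csv"
        path.write_text("start,end,condition\n" + "".join(rows))
        return path

    def test_adjacent_intervals_read(self, tmp_path):
        path = self._write(tmp_path, [
            "2025-01-06T08:00,2025-01-06T12:00,WEAR_ACTIVE\n",
            "2025-01-06T12:00,2025-01-06T13:00,NONWEAR_STATIONARY_DARK\n",
        ])
        diary = lw.read_diary(path)
        assert len(diary) == 2
        assert diary[0].condition is lw.Condition.WEAR_ACTIVE

    def test_condition_match_is_case_insensitive(self, tmp_path):
        path = self._write(
            tmp_path, ["2025-01-06T08:00,2025-01-06T09:00,wear_indoor\n"]
        )
        assert lw.read_diary(path)[0].condition is lw.Condition.WEAR_INDOOR

    def test_overlap_is_data_error_listing_pair(self, tmp_path):
        path = self._write(tmp_path, [
            "2025-01-06T08:00,2025-01-06T12:00,WEAR_ACTIVE\n",
            "2025-01-06T11:00,2025-01-06T13:00,WEAR_SEDENTARY\n",
        ])
        with pytest.raises(DataError, match="overlapping.*WEAR_ACTIVE.*WEAR_SEDENTARY"):
            lw.read_diary(path)

    def test_unknown_condition_is_data_error(self, tmp_path):
        path = self._write(tmp_path, ["2025-01-06T08:00,2025-01-06T09:00,napping\n"])
        with pytest.raises(DataError, match="unknown condition 'napping'"):
            lw.read_diary(path)

    def test_empty_interval_rejected(self):
        with pytest.raises(DataError):
            lw.DiaryInterval(
                pd.Timestamp("2025-01-06 09:00"),
                pd.Timestamp("2025-01-06 08:00"),
                lw.Condition.WEAR_ACTIVE,
            )


class TestLabelStream:
    @pytest.mark.parametrize(
        "condition,expected",
        [
            (lw.Condition.WEAR_ACTIVE, "WEAR"),
            (lw.Condition.WEAR_OUTDOOR, "WEAR"),
            (lw.Condition.NIGHT_FACE_UP, "NIGHT_OK"),
            (lw.Condition.NIGHT_FACE_DOWN, "NONWEAR"),
            (lw.Condition.NONWEAR_MOBILE_DARK, "NONWEAR"),
            (lw.Condition.NONWEAR_STATIONARY_LIGHT, "NONWEAR"),
        ],
    )
    def test_condition_class_mapping(self, condition, expected):
        stream = make_stream(n=10, start="2025-01-06 00:00")
        diary = [lw.DiaryInterval(
            pd.Timestamp("2025-01-06 00:00"),
            pd.Timestamp("2025-01-06 00:10"),
            condition,
        )]
        labeled = lw.label_stream(stream, diary)
        assert (labeled.labels == expected).all()

    def test_minutes_outside_intervals_are_unknown_and_labeling_is_total(self):
        stream = make_stream(n=30)
        diary = [lw.DiaryInterval(
            pd.Timestamp("2025-01-06 00:05"),
            pd.Timestamp("2025-01-06 00:15"),
            lw.Condition.WEAR_ACTIVE,
        )]
        labeled = lw.label_stream(stream, diary)
        assert len(labeled.labels) == len(stream)
        assert set(labeled.labels) == {"WEAR", "UNKNOWN"}
        assert (labeled.labels[:5] == "UNKNOWN").all()
        assert (labeled.labels[15:] == "UNKNOWN").all()

    def test_half_open_intervals_never_double_label(self):
        stream = make_stream(n=20)
        diary = [
            lw.DiaryInterval(
                pd.Timestamp("2025-01-06 00:00"),
                pd.Timestamp("2025-01-06 00:10"),
                lw.Condition.WEAR_ACTIVE,
            ),
            lw.DiaryInterval(
                pd.Timestamp("2025-01-06 00:10"),
                pd.Timestamp("2025-01-06 00:20"),
                lw.Condition.NONWEAR_STATIONARY_DARK,
            ),
        ]
        labeled = lw.label_stream(stream, diary)
        assert (labeled.labels[:10] == "WEAR").all()
        assert (labeled.labels[10:] == "NONWEAR").all()

    def test_fully_covered_interval_labels_duration_minutes(self):
        stream = make_stream(n=120)
        iv = lw.DiaryInterval(
            pd.Timestamp("2025-01-06 00:30"),
            pd.Timestamp("2025-01-06 01:17"),
            lw.Condition.WEAR_INDOOR,
        )
        labeled = lw.label_stream(stream, [iv])
        assert (labeled.labels == "WEAR").sum() == iv.duration_minutes == 47
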