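"""Parsing, serialization, epoch conversion and snapshot extraction."""

import json
from datetime import datetime, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfigures.data_model import (
    DataValidationError,
    HealthDataset,
    Measurement,
    MeasurementGroup,
    Sample,
    SnapshotMode,
    epoch_to_utc,
    extract_snapshots,
    parse_dataset,
    serialize_dataset,
    utc_to_epoch,
    validate_dataset,
)
from hfigures.fixtures import generate_minimal_example

from conftest import random_dataset

MINIMAL_JSON = """
{"groups": [
  {"label": "Blood Pressure",
   "measurements": [
     {"label": "Systolic", "units": "mmHg",
      "recommended": {"min": 90, "max": 120},
      "warning": {"min": 80, "max": 140},
      "samples": [{"timestamp": 1420798224, "value": 132.0},
                  {"timestamp": 1423742720, "value": 118.0}]},
     {"label": "Diastolic", "units": "mmHg",
      "recommended": {"min": 60, "max": 80},
      "samples": [{"timestamp": 1420798224, "value": 88.0},
                  {"timestamp": 1423742720, "value": 79.0}]}
   ]}
]}
"""


class TestParse:
    def test_document_order_preserved(self):
        ds = parse_dataset(MINIMAL_JSON)
        assert len(ds.groups) == 1
        g = ds.groups[0]
        assert g.label == "Blood Pressure"
        assert [m.label for m in g.measurements] == ["Systolic", "Diastolic"]
        assert all(len(m.samples) == 2 for m in g.measurements)
        assert g.measurements[0].samples[0].timestamp == 1420798224

    def test_optional_warning_absent_stays_absent(self):
        ds = parse_dataset(MINIMAL_JSON)
        systolic, diastolic = ds.groups[0].measurements
        assert systolic.warn_min == 80 and systolic.warn_max == 140
        assert diastolic.warn_min is None and diastolic.warn_max is None

    def test_empty_groups_parse_but_fail_validation(self):
        ds = parse_dataset('{"groups": []}')
        assert ds.groups == ()
        assert validate_dataset(ds) != []

    def test_malformed_json_raises_with_position(self):
        with pytest.raises(json.JSONDecodeError):
            parse_dataset("{")

    @pytest.mark.parametrize(
        "mutate, path_part",
        [
            (lambda d: d["groups"][0].pop("label"), "groups[0].label"),
            (lambda d: d["groups"][0]["measurements"][0].pop("recommended"),
             "groups[0].measurements[0].recommended"),
            (lambda d: d["groups"][0]["measurements"][1]["samples"][1].__setitem__("value", "high"),
             "groups[0].measurements[1].samples[1].value"),
            (lambda d: d["groups"][0]["measurements"][0]["recommended"].__setitem__("max", 90),
             "groups[0].measurements[0].recommended"),
        ],
    )
    def test_validation_errors_name_the_offending_path(self, mutate, path_part):
        doc = json.loads(MINIMAL_JSON)
        mutate(doc)
        with pytest.raises(DataValidationError) as exc:
            parse_dataset(json.dumps(doc))
        assert path_part in str(exc.value)

    def test_unsorted_samples_sorted_with_warning(self):
        doc = json.loads(MINIMAL_JSON)
        m = doc["groups"][0]["measurements"][0]
        m["samples"] = list(reversed(m["samples"]))
        with pytest.warns(UserWarning, match="unsorted"):
            ds = parse_dataset(json.dumps(doc))
        ts = [s.timestamp for s in ds.groups[0].measurements[0].samples]
        assert ts == sorted(ts)

    def test_fractional_timestamp_truncated_with_warning(self):
        doc = json.loads(MINIMAL_JSON)
        doc["groups"][0]["measurements"][0]["samples"][0]["timestamp"] = 1420798224.7
        with pytest.warns(UserWarning, match="fractional"):
            ds = parse_dataset(json.dumps(doc))
        assert ds.groups[0].measurements[0].samples[0].timestamp == 1420798224


class TestRoundTrip:
    def test_minimal_round_trip(self):
        ds = parse_dataset(MINIMAL_JSON)
        assert parse_dataset(serialize_dataset(ds)) == ds

    def test_warning_keys_only_where_present(self):
        ds = parse_dataset(MINIMAL_JSON)
        doc = json.loads(serialize_dataset(ds))
        ms = doc["groups"][0]["measurements"]
        assert "warning" in ms[0] and "warning" not in ms[1]

    def test_random_datasets_round_trip(self, rng):
        for _ in range(25):
            ds = random_dataset(rng)
            assert parse_dataset(serialize_dataset(ds)) == ds


class TestEpoch:
    def test_printed_example_timestamps(self):
        assert epoch_to_utc(1420798224) == datetime(2015, 1, 9, 10, 10, 24, tzinfo=timezone.utc)
        assert epoch_to_utc(1423742720) == datetime(2015, 2, 12, 12, 5, 20, tzinfo=timezone.utc)
        assert epoch_to_utc(0) == datetime(1970, 1, 1, tzinfo=timezone.utc)

    def test_inverse_of_printed_examples(self):
        assert utc_to_epoch(datetime(2015, 1, 9, 10, 10, 24)) == 1420798224
        assert utc_to_epoch(datetime(1970, 1, 1, 0, 0, 1)) == 1

    def test_negative_timestamp_rejected(self):
        with pytest.raises(ValueError):
            epoch_to_utc(-1)
        with pytest.raises(ValueError):
            utc_to_epoch(datetime(1969, 12, 31, 23, 59, 59))

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_identity(self, ts):
        assert utc_to_epoch(epoch_to_utc(ts)) == ts


class TestSnapshots:
    def test_by_index_on_two_sample_dataset(self):
        ds = parse_dataset(MINIMAL_JSON)
        snaps = extract_snapshots(ds, SnapshotMode.BY_INDEX, [0, 1])
        assert len(snaps) == 2
        assert all(len(s.entries) == 2 for s in snaps)
        assert snaps[0].entries[("Blood Pressure", "Systolic")].value == 132.0
        assert snaps[1].entries[("Blood Pressure", "Systolic")].value == 118.0

    def test_single_sample_by_index(self):
        ds = HealthDataset(groups=(
            MeasurementGroup(label="g", measurements=(
                Measurement(label="m", units="", rec_min=0, rec_max=1,
                            samples=(Sample(5, 0.5),)),
            )),
        ))
        snaps = extract_snapshots(ds, "by_index", [0])
        assert snaps[0].entries[("g", "m")] == Sample(5, 0.5)

    def test_nearest_time_picks_brute_force_minimum(self):
        ds = parse_dataset(MINIMAL_JSON)
        target = 1422000000
        snaps = extract_snapshots(ds, SnapshotMode.NEAREST_TIME, [target])
        for (g, m_label), sample in snaps[0].entries.items():
            meas = next(m for m in ds.groups[0].measurements if m.label == m_label)
            best = min(meas.samples, key=lambda s: abs(s.timestamp - target))
            assert sample == best
            assert sample.timestamp == 1420798224  # the nearer of the two

    def test_ragged_counts_error_lists_every_measurement(self):
        doc = json.loads(MINIMAL_JSON)
        doc["groups"][0]["measurements"][0]["samples"].pop()
        ds = parse_dataset(json.dumps(doc))
        with pytest.raises(ValueError, match="Systolic=1.*Diastolic=2"):
            extract_snapshots(ds, "by_index", [0])

    def test_index_out_of_range(self):
        ds = parse_dataset(MINIMAL_JSON)
        with pytest.raises(IndexError):
            extract_snapshots(ds, "by_index", [2])

    def test_snapshot_count_and_completeness_on_random_datasets(self, rng):
        for _ in range(10):
            ds = random_dataset(rng, n_samples=3)
            snaps = extract_snapshots(ds, "by_index", [0, 2])
            assert len(snaps) == 2
            for s in snaps:
                assert set(s.entries) == {
                    (g.label, m.label) for g, m in ds.iter_measurements()
                }


class TestInvariants:
    def test_degenerate_recommended_range_rejected(self):
        with pytest.raises(DataValidationError):
            Measurement(label="m", units="", rec_min=5, rec_max=5, samples=())

    def test_warning_bounds_must_bracket_recommended(self):
        with pytest.raises(DataValidationError):
            Measurement(label="m", units="", rec_min=0, rec_max=1, warn_min=0.5, samples=())
        with pytest.raises(DataValidationError):
            Measurement(label="m", units="", rec_min=0, rec_max=1, warn_max=0.5, samples=())

    def test_duplicate_group_labels_rejected(self):
        m = Measurement(label="m", units="", rec_min=0, rec_max=1, samples=(Sample(0, 0.5),))
        g = MeasurementGroup(label="g", measurements=(m,))
        with pytest.raises(DataValidationError):
            HealthDataset(groups=(g, g))

    def test_minimal_fixture_is_valid(self):
        assert validate_dataset(generate_minimal_example()) == []
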