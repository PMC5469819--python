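"""Burst filtering, departure detection and reliability classification."""

import numpy as np
import pandas as pd
import pytest

from stopover_pace.config import SimulationConfig
from stopover_pace.simulate import (
    default_stations,
    emit_detection_log,
    emit_tag_registry,
    simulate_population,
)
from stopover_pace.telemetry import (
    CLASS_A,
    CLASS_B,
    CLASS_C,
    RELIABLE,
    DetectionRun,
    apparent_stopover,
    build_stopover_records,
    detect_departure,
    filter_bursts,
    records_to_frame,
    runs_to_frame,
)

REGISTRY = {"T1": 10.0}


def _log(times, tag="T1", station="LOCAL-1", antenna=1, strengths=None):
    times = np.asarray(times, dtype=float)
    if strengths is None:
        strengths = np.full(len(times), -60.0)
    return pd.DataFrame(
        {
            "tag_id": tag,
            "station_id": station,
            "antenna_id": antenna,
            "timestamp_iso": pd.to_datetime(times, unit="s").strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "signal_strength": strengths,
        }
    )


def _epoch(iso: str) -> float:
    return pd.Timestamp(iso).value / 1e9


# ---------------------------------------------------------------------------
# burst filter


def test_three_bursts_at_interval_form_one_run():
    t0 = _epoch("2016-05-01T10:00:00")
    runs = filter_bursts(_log([t0, t0 + 10, t0 + 20]), REGISTRY)
    assert len(runs) == 1 and runs[0].n_bursts == 3
    assert runs[0].median_interval == 10.0


def test_two_bursts_are_discarded():
    t0 = _epoch("2016-05-01T10:00:00")
    assert filter_bursts(_log([t0, t0 + 10]), REGISTRY) == []


def test_missed_bursts_tolerated_as_integer_multiples():
    t0 = _epoch("2016-05-01T10:00:00")
    # one missed (gap 20 s) and two missed (gap 30 s) stay inside the run
    runs = filter_bursts(_log([t0, t0 + 10, t0 + 30, t0 + 60, t0 + 70]), REGISTRY)
    assert len(runs) == 1 and runs[0].n_bursts == 5
    # three missed (gap 40 s) splits the run
    runs = filter_bursts(
        _log([t0, t0 + 10, t0 + 20, t0 + 60, t0 + 70, t0 + 80]), REGISTRY
    )
    assert [r.n_bursts for r in runs] == [3, 3]


def test_off_interval_gaps_break_runs():
    t0 = _epoch("2016-05-01T10:00:00")
    runs = filter_bursts(_log([t0, t0 + 10, t0 + 16, t0 + 26, t0 + 36]), REGISTRY)
    assert [r.n_bursts for r in runs] == [3]


def test_unknown_tag_counts_as_noise():
    t0 = _epoch("2016-05-01T10:00:00")
    assert filter_bursts(_log([t0, t0 + 10, t0 + 20], tag="ZZ"), REGISTRY) == []


def test_filter_is_idempotent_on_simulated_data(mid_dataset):
    runs = filter_bursts(mid_dataset.detections, mid_dataset.tags)
    refiltered = filter_bursts(
        pd.concat(
            [
                _log(
                    r.times,
                    tag=r.tag_id,
                    station=r.station_id,
                    antenna=r.antenna_id,
                    strengths=r.strengths,
                )
                for r in runs
            ],
            ignore_index=True,
        ),
        mid_dataset.tags,
    )
    # idempotent at burst level (removing rejected bursts can only merge
    # adjacent runs across a now-clean gap, never drop a validated burst)
    def burst_set(rs):
        return {
            (r.tag_id, r.station_id, r.antenna_id, t) for r in rs for t in r.times
        }

    assert burst_set(refiltered) == burst_set(runs)


def test_no_run_spans_an_oversized_gap(mid_dataset):
    interval = float(mid_dataset.config.burst_interval)
    runs = filter_bursts(mid_dataset.detections, mid_dataset.tags)
    for r in runs[:500]:
        assert np.all(np.diff(r.times) <= 3 * interval * 1.1 + 1e-9)


def test_poisson_noise_is_nearly_all_rejected():
    """>= 99% of false-positive bursts fail the three-consecutive-bursts-at-
    interval rule even when their tag ids are known to the receiver."""
    cfg = SimulationConfig(
        n_birds=10, tag_fraction=0.0, false_positive_rate=5.0, rng_seed=31
    )
    birds = simulate_population(cfg)
    log = emit_detection_log(birds, default_stations(), cfg, with_provenance=True)
    assert (log["source"] == "noise").all()
    registry = {t: 10.0 for t in log["tag_id"].unique()}
    runs = filter_bursts(log, registry)
    kept = sum(r.n_bursts for r in runs)
    assert kept / len(log) < 0.01


# ---------------------------------------------------------------------------
# departure detection


def _trace(end_iso, n=60, peak_frac=0.65, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t_end = _epoch(end_iso)
    times = t_end - 10.0 * np.arange(n - 1, -1, -1)
    tp = times[0] + peak_frac * (times[-1] - times[0])
    s = -85 + 35 * np.exp(-0.5 * ((times - tp) / ((times[-1] - times[0]) / 4)) ** 2)
    return times, s + rng.normal(0, noise, n)


def _run(times, strengths, tag="T1", station="LOCAL-1"):
    return DetectionRun(tag, station, 1, np.asarray(times, float), np.asarray(strengths, float))


def test_departure_found_at_final_burst_in_evening_window():
    times, s = _trace("2016-05-06T19:30:00")
    dep = detect_departure([_run(times, s)])
    assert dep == pd.Timestamp("2016-05-06T19:30:00")


def test_flat_run_ending_midmorning_is_not_a_departure():
    t0 = _epoch("2016-05-06T10:55:00")
    times = t0 + 10.0 * np.arange(30)
    dep = detect_departure([_run(times, np.full(30, -60.0))])
    assert dep is None


def test_monotone_decline_without_peak_is_not_a_departure():
    times = _epoch("2016-05-06T19:00:00") + 10.0 * np.arange(30)
    dep = detect_departure([_run(times, -40.0 - np.arange(30.0))])
    assert dep is None


def test_rise_fall_outside_window_is_not_a_departure():
    times, s = _trace("2016-05-06T11:00:00")
    assert detect_departure([_run(times, s)]) is None


def test_latest_qualifying_run_wins():
    t1, s1 = _trace("2016-05-06T18:30:00")
    t2, s2 = _trace("2016-05-06T20:15:00")
    dep = detect_departure([_run(t1, s1), _run(t2, s2)])
    assert dep == pd.Timestamp("2016-05-06T20:15:00")


def test_only_final_calendar_day_is_considered():
    t1, s1 = _trace("2016-05-05T19:00:00")  # perfect signature, earlier day
    t2 = _epoch("2016-05-06T10:00:00") + 10.0 * np.arange(10)
    dep = detect_departure([_run(t1, s1), _run(t2, np.full(10, -60.0))])
    assert dep is None


# ---------------------------------------------------------------------------
# stopover records and classification


def _tags(deploy="2016-04-23", tag="T1"):
    return pd.DataFrame(
        {
            "tag_id": [tag],
            "burst_interval_s": [10.0],
            "deploy_date": [deploy],
            "bird_id": ["B1"],
            "year": [2016],
        }
    )


def test_apparent_stopover_is_whole_days_from_capture_to_departure():
    # capture April 23, departure May 6 evening -> 13 d
    times, s = _trace("2016-05-06T19:30:00")
    runs = [
        _run(_epoch("2016-04-25T10:00:00") + 10 * np.arange(5), np.full(5, -60.0)),
        _run(times, s),
    ]
    rec = build_stopover_records(runs, _tags("2016-04-23"), {"LOCAL-1"})[0]
    assert rec.reliability == RELIABLE
    assert rec.apparent_stopover_days == 13


def test_same_evening_departure_is_class_A():
    times, s = _trace("2016-04-23T19:30:00")
    rec = build_stopover_records([_run(times, s)], _tags("2016-04-23"), {"LOCAL-1"})[0]
    assert rec.reliability == CLASS_A
    assert rec.apparent_stopover_days is None


def test_disappearance_without_evening_signature_is_class_B():
    runs = [
        _run(_epoch("2016-04-25T10:00:00") + 10 * np.arange(5), np.full(5, -60.0)),
        _run(_epoch("2016-04-28T11:00:00") + 10 * np.arange(5), np.full(5, -60.0)),
    ]
    rec = build_stopover_records(runs, _tags("2016-04-23"), {"LOCAL-1"})[0]
    assert rec.reliability == CLASS_B


def test_presence_at_dismantling_is_class_C():
    runs = [
        _run(_epoch("2015-04-25T10:00:00") + 10 * np.arange(5), np.full(5, -60.0)),
        _run(_epoch("2015-05-15T09:00:00") + 10 * np.arange(5), np.full(5, -60.0)),
    ]
    tags = _tags("2015-04-23")
    tags["year"] = 2015
    rec = build_stopover_records(
        runs, tags, {"LOCAL-1"}, dismantle_dates={2015: "2015-05-15"}
    )[0]
    assert rec.reliability == CLASS_C


def test_every_tagged_bird_gets_exactly_one_class(mid_dataset):
    runs = filter_bursts(mid_dataset.detections, mid_dataset.tags)
    local = set(
        mid_dataset.stations.loc[
            mid_dataset.stations["region"] == "Local", "station_id"
        ]
    )
    records = build_stopover_records(
        runs, mid_dataset.tags, local, dismantle_dates={}
    )
    assert len(records) == len(mid_dataset.tags)
    assert {r.reliability for r in records} <= {RELIABLE, CLASS_A, CLASS_B, CLASS_C}
    frame = records_to_frame(records)
    assert frame["tag_id"].is_unique


def test_clean_data_recovers_every_departure_exactly(clean_dataset):
    """Zero noise and full coverage: all multi-day birds reliable and the
    recovered departure equals the generator's timestamp."""
    ds = clean_dataset
    runs = filter_bursts(ds.detections, ds.tags)
    local = set(ds.stations.loc[ds.stations["region"] == "Local", "station_id"])
    records = build_stopover_records(runs, ds.tags, local, dismantle_dates={})
    truth = ds.truth.set_index("tag_id")
    n_rel = 0
    for rec in records:
        true_dep = pd.Timestamp(truth.loc[rec.tag_id, "departure_datetime"])
        if (true_dep - rec.first_capture_date).total_seconds() <= 48 * 3600:
            assert rec.reliability == CLASS_A
            continue
        assert rec.reliability == RELIABLE
        assert abs((rec.departure_datetime - true_dep).total_seconds()) <= 10.0
        n_rel += 1
    assert n_rel > 0


def test_apparent_stopover_summary_and_recovery(mid_dataset):
    ds = mid_dataset
    runs = filter_bursts(ds.detections, ds.tags)
    local = set(ds.stations.loc[ds.stations["region"] == "Local", "station_id"])
    records = build_stopover_records(runs, ds.tags, local, dismantle_dates={})
    summary = apparent_stopover(records)
    overall = summary[summary["year"] == "all"].iloc[0]
    truth = ds.truth.set_index("tag_id")
    rel_tags = [r.tag_id for r in records if r.reliability == RELIABLE]
    true_mean = truth.loc[rel_tags, "stay_days"].mean()
    assert overall["n"] == len(rel_tags)
    assert abs(overall["mean"] - true_mean) <= 0.8


def test_no_reliable_records_is_an_error():
    with pytest.raises(ValueError):
        apparent_stopover([])


def test_runs_frame_has_minimum_burst_invariant(mid_dataset):
    runs = filter_bursts(mid_dataset.detections, mid_dataset.tags)
    frame = runs_to_frame(runs)
    assert (frame["n_bursts"] >= 3).all()
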