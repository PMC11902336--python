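"""Screening, cleaning and segmentation rules on constructed fixtures."""

import numpy as np
import pytest

from sasbls.preprocess import (
    PreprocessError,
    clip_wake_edges,
    delta_filter,
    flag_outliers,
    preprocess_recording,
    resample_1hz,
    sample_exclude,
    screen_subject,
    segment_and_label,
)
from sasbls.synth import Recording, SynthConfig, generate_subject


def _rec(spo2, hypnogram, events=(), fs=1.0, ahi=0.0):
    return Recording(spo2=np.asarray(spo2, dtype=float), fs=fs,
                     hypnogram=list(hypnogram), events=list(events),
                     demographics=(60.0, 28.0, 0, 0), ahi_label=ahi,
                     subject_id="T")


def _flat_rec(minutes, value=97.0, hyp_cycle=("N1", "N2", "N3", "R")):
    n_ep = minutes * 2
    hyp = [hyp_cycle[i % len(hyp_cycle)] for i in range(n_ep)]
    return _rec(np.full(n_ep * 30, value), hyp)


class TestScreening:
    def test_clean_long_subject_passes(self):
        rep = screen_subject(_flat_rec(420))
        assert not rep.excluded and rep.reasons == set()

    def test_quarter_outliers_excluded(self):
        rec = _flat_rec(420)
        n = len(rec.spo2)
        rec.spo2[: n // 4] = 0.0  # 25 % of the night is dropout
        rep = screen_subject(rec)
        assert rep.excluded and "outlier_fraction" in rep.reasons

    def test_five_hour_boundary_strict(self):
        # 299.5 min of sleep -> excluded; exactly 300 -> retained
        short = _flat_rec(300)
        short.hypnogram[-1] = "W"  # 299.5 min TST
        assert screen_subject(short).excluded
        exact = _flat_rec(300)
        rep = screen_subject(exact)
        assert "total_sleep_time" not in rep.reasons

    def test_two_stage_sleep_excluded(self):
        rep = screen_subject(_flat_rec(420, hyp_cycle=("N1", "N2")))
        assert rep.excluded and "stage_count" in rep.reasons

    def test_missing_hypnogram_raises(self):
        with pytest.raises(PreprocessError):
            screen_subject(_rec(np.full(600, 97.0), []))


class TestClipWakeEdges:
    def test_keeps_interior_only(self):
        rec = _rec(np.arange(150.0), ["W", "W", "N2", "N2", "W"])
        out = clip_wake_edges(rec)
        assert out.hypnogram == ["N2", "N2"]
        assert np.array_equal(out.spo2, np.arange(60.0, 120.0))

    def test_identity_without_edge_wake(self):
        rec = _rec(np.arange(90.0), ["N1", "N2", "N3"])
        out = clip_wake_edges(rec)
        assert np.array_equal(out.spo2, rec.spo2)
        assert out.hypnogram == rec.hypnogram

    def test_event_truncated_at_boundary(self):
        # event 50-80 s straddles the clip at 60 s
        rec = _rec(np.arange(150.0), ["W", "W", "N2", "N2", "W"],
                   events=[(50.0, 30.0, "apnea")])
        out = clip_wake_edges(rec)
        (start, dur, _), = out.events
        assert start == 0.0 and dur == pytest.approx(20.0)

    def test_all_wake_raises(self):
        with pytest.raises(PreprocessError):
            clip_wake_edges(_rec(np.arange(60.0), ["W", "W"]))


class TestResample:
    def test_identity_at_1hz(self):
        x = np.array([95.0, 96.0, 97.0])
        assert np.array_equal(resample_1hz(x, 1), x)

    def test_bin_means_at_2hz(self):
        assert np.array_equal(resample_1hz(np.array([96, 96, 95, 97.0]), 2),
                              np.array([96.0, 96.0]))

    def test_constant_invariance(self):
        assert np.all(resample_1hz(np.full(40, 95.0), 4) == 95.0)

    def test_subhertz_rejected(self):
        with pytest.raises(PreprocessError):
            resample_1hz(np.arange(5.0), 0.5)


class TestOutliersAndDeltaFilter:
    def test_constant_unflagged(self):
        assert not flag_outliers(np.full(30, 97.0)).any()

    def test_dropout_flags_self_and_neighbors(self):
        x = np.full(10, 97.0)
        x[5] = 0.0
        mask = flag_outliers(x)
        assert mask[4] and mask[5] and mask[6]
        assert not mask[[0, 1, 2, 3, 7, 8, 9]].any()

    def test_physiologic_desaturation_unflagged(self):
        x = np.concatenate([np.full(20, 97.0), 97 - np.arange(8.0),
                            np.full(20, 90.0)])
        assert not flag_outliers(x).any()

    def test_short_dropout_interpolated(self):
        x = np.full(40, 97.0)
        x[20] = 0.0
        out, residual = delta_filter(x, flag_outliers(x))
        assert np.all(out == 97.0)
        assert not residual.any()

    def test_three_second_dropout_not_interpolated(self):
        x = np.full(60, 97.0)
        x[20:23] = 0.0  # outlier duration exactly 3 s: rule is strict
        out, residual = delta_filter(x, flag_outliers(x))
        assert residual.any()
        assert np.all(out[20:23] == 0.0)

    def test_unflagged_signal_identity(self):
        x = np.full(50, 96.0)
        out, residual = delta_filter(x, np.zeros(50, dtype=bool))
        assert np.array_equal(out, x) and not residual.any()

    def test_fully_flagged_raises(self):
        with pytest.raises(PreprocessError):
            delta_filter(np.zeros(10), np.ones(10, dtype=bool))


class TestSegmentation:
    def test_hour_gives_120_windows(self):
        rec = _rec(np.full(3600, 97.0), ["N2"] * 120)
        out = segment_and_label(rec, window_s=30)
        assert out.segments.shape == (120, 30)
        assert out.n_total == 120

    def test_label_rule_strictly_exceeds_5s(self):
        hyp = ["N2"] * 2
        five = segment_and_label(_rec(np.full(60, 97.0), hyp,
                                      events=[(25.0, 15.0, "apnea")]), 30)
        assert five.labels[0] == 0      # exactly 5 s inside -> negative
        six = segment_and_label(_rec(np.full(60, 97.0), hyp,
                                     events=[(24.0, 16.0, "apnea")]), 30)
        assert six.labels[0] == 1       # 6 s inside -> positive

    def test_no_events_all_negative(self):
        out = segment_and_label(_rec(np.full(300, 97.0), ["N2"] * 10), 30)
        assert not out.labels.any()

    def test_too_short_raises(self):
        with pytest.raises(PreprocessError):
            segment_and_label(_rec(np.full(20, 97.0), ["N2"]), 30)

    def test_label_conservation(self, clean_subject):
        samples, _ = preprocess_recording(clean_subject)
        max_dur = max(d for _, d, _ in clean_subject.events)
        bound = len(clean_subject.events) * np.ceil(max_dur / 30 + 1)
        assert samples.labels.sum() <= bound


class TestSampleExclusion:
    def test_clean_cohort_loses_nothing(self, clean_subject):
        samples, _ = preprocess_recording(clean_subject)
        assert len(samples.labels) == samples.n_total

    def test_negative_window_with_residual_dropout_removed(self):
        rec = _rec(np.full(3600, 97.0), ["N2"] * 120)
        rec.spo2[100:105] = 0.0  # 5 s dropout in a label-0 window
        samples, _ = preprocess_recording(rec)
        assert samples.n_total == 120
        assert 4 not in samples.positions  # window index 4 (1-based) dropped

    def test_positive_window_with_interpolated_run_retained(self):
        rec = _rec(np.full(3600, 97.0), ["N2"] * 120,
                   events=[(95.0, 20.0, "apnea")])
        rec.spo2[100] = 0.0  # 1 s dropout inside the labeled window
        samples, _ = preprocess_recording(rec)
        idx = np.where(samples.positions == 4)[0]
        assert len(idx) == 1 and samples.labels[idx[0]] == 1


def test_event_xml_reader_keeps_respiratory_events(tmp_path):
    from sasbls.preprocess import read_event_xml

    xml = """<?xml version="1.0"?>
<PSGAnnotation><ScoredEvents>
 <ScoredEvent><EventConcept>Obstructive apnea|Obstructive Apnea</EventConcept>
  <Start>120.5</Start><Duration>18.2</Duration></ScoredEvent>
 <ScoredEvent><EventConcept>Hypopnea|Hypopnea</EventConcept>
  <Start>300.0</Start><Duration>22.0</Duration></ScoredEvent>
 <ScoredEvent><EventConcept>Arousal|Arousal</EventConcept>
  <Start>50</Start><Duration>5</Duration></ScoredEvent>
</ScoredEvents></PSGAnnotation>"""
    p = tmp_path / "events.xml"
    p.write_text(xml)
    events = read_event_xml(p)
    assert events == [(120.5, 18.2, "apnea"), (300.0, 22.0, "hypopnea")]


def test_pipeline_idempotent(clean_subject):
    from sasbls.preprocess import clip_wake_edges, delta_filter, flag_outliers, resample_1hz

    once = clip_wake_edges(clean_subject)
    sig1 = resample_1hz(once.spo2, once.fs)
    clean1, _ = delta_filter(sig1, flag_outliers(sig1))
    twice = clip_wake_edges(once)
    sig2 = resample_1hz(clean1, 1.0)
    clean2, _ = delta_filter(sig2, flag_outliers(sig2))
    assert twice.hypnogram == once.hypnogram
    assert np.array_equal(clean1, clean2)
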