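"""SO detector rules, stimulation-point timing and protocol state machines
checked against hand-simulated schedules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcsleep.stimulation import (
    CueController,
    EventLog,
    Point4Tracker,
    Protocol,
    ProtocolConfig,
    SensoryNeuron,
    SNSchedule,
    SODetector,
    StimPoint,
    cls_controller,
    dst_controller,
    point4_trigger,
)


def spikes(t0, n, isi=1.0):
    return [t0 + k * isi for k in range(n)]


# -- SO detector ------------------------------------------------------------

def test_detection_at_75th_spike_after_silence():
    det = SODetector()
    det.update([10.0], 20.0)                 # establish a last-spike time
    train = spikes(140.0, 75)                # silence 10 -> 140 ms (130 ms)
    out = det.update(train, 300.0)
    assert len(out) == 1
    assert out[0].t == pytest.approx(train[74])
    assert out[0].down_duration_ms == pytest.approx(130.0)


def test_insufficient_silence_blocks_detection():
    det = SODetector()
    assert len(det.update(spikes(150.0, 75), 300.0)) == 1   # consume arming
    # gaps of only 80 ms never re-arm, however many spikes follow
    out = det.update(spikes(304.0, 200, isi=80.0), 20000.0)
    assert out == []


def test_too_few_spikes_then_renewed_silence():
    det = SODetector()
    det.update([0.0], 0.0)
    out = det.update(spikes(160.0, 74), 400.0)   # 150 ms silence, 74 spikes
    assert out == []
    # the renewed silence resets the count: 74 more spikes still no detection
    out = det.update(spikes(400.0, 74), 600.0)
    assert out == []
    # but a full 75 completes
    out = det.update(spikes(700.0, 75), 900.0)
    assert len(out) == 1


def test_rearm_requires_new_silence():
    det = SODetector()
    det.update([0.0], 0.0)
    out = det.update(spikes(150.0, 150), 400.0)
    assert len(out) == 1                     # only one detection per arming


# -- Point 4 ----------------------------------------------------------------

def test_point4_triggers_on_falling_edge_of_trapezoid():
    t = np.arange(0, 1000.0, 1.0)
    rate = np.interp(t, [0, 100, 200, 600, 700, 1000], [0, 0, 40, 40, 0, 0])
    cue = point4_trigger(t, rate, frac=0.5, min_peak=10.0)
    # 50% of the 40 Hz peak crossed on the falling edge (600 -> 700 ms)
    assert cue is not None and 600.0 < cue <= 700.0
    assert abs(np.interp(cue, t, rate) - 20.0) < 1.0


def test_point4_no_cue_for_monotone_rise():
    t = np.arange(0, 500.0)
    assert point4_trigger(t, np.linspace(0, 50, len(t))) is None


def test_point4_no_cue_below_baseline():
    t = np.arange(0, 500.0)
    assert point4_trigger(t, np.full_like(t, 3.0), min_peak=10.0) is None


# -- CLS / sCLS -------------------------------------------------------------

def test_cls_pair_then_pause_schedule():
    cfg = ProtocolConfig(protocol=Protocol.CLS, point=StimPoint.P1, pause_s=2.5)
    dets = [1000.0 * k for k in (1, 2, 3, 4, 5, 6)]
    cues = [e.t_cue for e in cls_controller(dets, cfg)]
    # cues on 1 and 2 s; pause 2..4.5 s swallows 3 and 4; cues on 5 and 6
    assert cues == [1000.0, 2000.0, 5000.0, 6000.0]


def test_cls_empty_stream():
    cfg = ProtocolConfig(protocol=Protocol.CLS)
    assert cls_controller([], cfg) == []


def test_scls_single_cue_then_pause():
    cfg = ProtocolConfig(protocol=Protocol.SCLS, pause_s=2.5)
    cues = [e.t_cue for e in cls_controller([1000.0, 2000.0, 3000.0, 4000.0], cfg)]
    # cue at 1 s, pause until 3.5 s, cue at 4 s
    assert cues == [1000.0, 4000.0]


def test_point_delays_applied_to_cue_times():
    for point, delay in ((StimPoint.P1, 0.0), (StimPoint.P2, 120.0),
                         (StimPoint.P3, 180.0)):
        cfg = ProtocolConfig(protocol=Protocol.SCLS, point=point)
        ev = cls_controller([500.0], cfg)[0]
        assert ev.t_cue - ev.so_detection_t == pytest.approx(delay)


# -- DSt --------------------------------------------------------------------

def test_dst_pauses_after_long_downstate():
    cfg = ProtocolConfig(protocol=Protocol.DST, pause_s=2.5)
    dets = [1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0]
    downs = [300.0, 400.0, 700.0, 300.0, 300.0, 300.0]
    cues = [e.t_cue for e in dst_controller(dets, downs, cfg)]
    # cues on the first two; the 700 ms Down-state triggers the pause
    # (3..5.5 s); driving restarts with a cue at 6 s
    assert cues == [1000.0, 2000.0, 6000.0]


def test_dst_cues_every_so_for_short_downstates():
    cfg = ProtocolConfig(protocol=Protocol.DST)
    dets = [1000.0 * k for k in range(1, 8)]
    downs = [300.0] * 7
    assert len(dst_controller(dets, downs, cfg)) == 7


def test_dst_alternates_when_all_downstates_long():
    cfg = ProtocolConfig(protocol=Protocol.DST, pause_s=2.5)
    dets = [4000.0 * k for k in range(1, 7)]     # well-spaced detections
    downs = [800.0] * 6
    evs = dst_controller(dets, downs, cfg)
    # first detection after each pause is cued, the next starts a pause
    assert [e.t_cue for e in evs] == [4000.0, 12000.0, 20000.0]


@given(st.lists(st.floats(min_value=0, max_value=600), min_size=0,
                max_size=40))
@settings(max_examples=50, deadline=None)
def test_no_cue_ever_falls_inside_a_pause(gaps):
    """Protocol invariant: no cue is emitted during a pause window."""
    dets = list(np.cumsum([500.0 + g for g in gaps]))
    for proto in (Protocol.CLS, Protocol.SCLS, Protocol.DST):
        cfg = ProtocolConfig(protocol=proto)
        ctl = CueController(cfg)
        cues = []
        for t in dets:
            ev = ctl.on_detection(t, 400.0)
            if ev is not None:
                cues.append(ev.t_cue)
        for ps, pe in ctl.pauses:
            assert not any(ps < c < pe for c in cues)


# -- sensory neuron schedule -------------------------------------------------

def test_sn_schedule_spike_train_and_merging():
    sn = SensoryNeuron(rate_hz=200.0, cue_duration_ms=20.0)
    sched = SNSchedule(sn)
    sched.add_cue(100.0)
    sp = sched.spikes_between(0.0, 200.0)
    assert len(sp) == 5                      # 200 Hz for 20 ms: 0,5,10,15,20
    assert sp[0] == pytest.approx(100.0)
    # an overlapping cue merges into a single window
    sched.add_cue(110.0)
    assert len(sched.windows) == 1
    assert sched.windows[0] == [100.0, 130.0]
    # a disjoint cue opens a second window
    sched.add_cue(500.0)
    assert len(sched.windows) == 2


# -- event log ---------------------------------------------------------------

def test_event_log_roundtrip(tmp_path):
    log = EventLog()
    log.add(100.0, "SO_DETECT", "cls", 1, 55.0)
    log.add(100.0, "CUE", "cls", 1)
    log.add(200.0, "PAUSE_START", "cls", 1)
    path = tmp_path / "events.tsv"
    log.write_tsv(path)
    back = EventLog.read_tsv(path)
    assert len(back.rows) == 3
    assert list(back.times("CUE")) == [100.0]
    with pytest.raises(ValueError):
        log.add(1.0, "NOT_A_KIND")
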