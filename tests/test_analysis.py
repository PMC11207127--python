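"""Spectral estimators and event statistics on constructed fixtures."""

import math

import numpy as np
import pytest

from tcsleep.analysis import (
    LFPTrace,
    SpindleEvent,
    compare_conditions,
    compute_lfp,
    count_cues,
    count_sos,
    detect_spindles,
    extract_so_events,
    inter_spindle_intervals,
    psd,
    read_trace,
    spectrogram,
    spindle_density,
)
from tcsleep.stimulation import EventLog

FS = 1000.0


def make_trace(x):
    return LFPTrace(np.arange(len(x)) / FS * 1e3, x, FS)


def tone(freq, dur_s, amp=1.0):
    t = np.arange(int(dur_s * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def pink_noise(n, rng):
    white = rng.normal(size=n)
    f = np.fft.rfftfreq(n, 1 / FS)
    spec = np.fft.rfft(white)
    spec[1:] /= np.sqrt(f[1:])
    return np.fft.irfft(spec, n)


# -- compute_lfp ------------------------------------------------------------

def test_lfp_single_source_equals_flipped_current():
    x = np.sin(np.linspace(0, 10, 500))
    lfp = compute_lfp(x[None, :], sample_rate=FS)
    assert np.allclose(lfp.value, -x)


def test_lfp_zero_and_linearity():
    z = compute_lfp(np.zeros((3, 100)), sample_rate=FS)
    assert np.all(z.value == 0)
    x = np.random.default_rng(0).normal(size=(1, 300))
    one = compute_lfp(x, sample_rate=FS)
    two = compute_lfp(np.vstack([x, x]), sample_rate=FS)
    assert np.allclose(two.value, 2 * one.value)


def test_trace_roundtrip(tmp_path):
    tr = make_trace(tone(13.0, 2.0))
    path = tmp_path / "trace.tsv"
    tr.write_tsv(path)
    back = read_trace(path)
    assert back.sample_rate == pytest.approx(FS)
    assert np.allclose(back.value, tr.value)


# -- PSD --------------------------------------------------------------------

def test_psd_peak_at_tone_frequency():
    f, P = psd(make_trace(tone(13.0, 30.0)))
    assert f[np.argmax(P)] == pytest.approx(13.0, abs=0.3)


def test_psd_power_concentration_around_tone():
    f, P = psd(make_trace(tone(13.0, 60.0)))
    near = (f >= 12.0) & (f <= 14.0)
    assert P[near].sum() / P.sum() >= 0.95


def test_psd_two_tones_ordered_by_amplitude():
    x = tone(1.0, 60.0, amp=2.0) + tone(13.0, 60.0, amp=1.0)
    f, P = psd(make_trace(x))
    p1 = P[np.argmin(np.abs(f - 1.0))]
    p13 = P[np.argmin(np.abs(f - 13.0))]
    assert p1 > p13 > 0


def test_psd_white_noise_roughly_flat(rng):
    x = rng.normal(size=100000)
    f, P = psd(make_trace(x))
    sel = (f > 5) & (f < 450)
    slope = np.polyfit(f[sel], np.log(P[sel]), 1)[0]
    assert abs(slope) < 1e-3


def test_psd_rejects_short_trace():
    with pytest.raises(ValueError):
        psd(make_trace(np.zeros(100)), window_s=4.0)


# -- spectrogram ------------------------------------------------------------

def test_spectrogram_stationary_tone():
    f, t, S = spectrogram(make_trace(tone(10.0, 10.0)))
    assert f.max() <= 18.0 and f.min() >= 0.1
    rows = f[np.argmax(S, axis=0)]
    assert np.all(np.abs(rows - 10.0) < 1.0)


def test_spectrogram_localizes_burst():
    x = np.zeros(5000)
    x[2000:3000] = tone(13.0, 1.0)
    f, t, S = spectrogram(make_trace(x))
    band = (f > 11) & (f < 15)
    power = S[band].sum(axis=0)
    inside = (t > 2.2) & (t < 2.8)
    outside = (t < 1.0) | (t > 4.0)
    assert power[inside].mean() > 50 * max(power[outside].mean(), 1e-12)


def test_spectrogram_zero_signal():
    f, t, S = spectrogram(make_trace(np.zeros(3000)))
    assert np.allclose(S, 0.0)


# -- spindle detection ------------------------------------------------------

def test_detects_exactly_constructed_bursts(rng):
    """Recall and precision 1.0 on constructed bursts standing 10x above a
    steady in-band background (slow pink-like drift outside the band)."""
    from scipy import signal as sg
    dur = 60.0
    n = int(dur * FS)
    drift = sg.sosfiltfilt(sg.butter(4, 5, "lowpass", fs=FS, output="sos"),
                           rng.normal(size=n))
    x = 0.05 * tone(13.0, dur) + 0.3 * drift
    starts = [5.0, 15.0, 25.0, 35.0, 45.0]
    for s in starts:
        i = int(s * FS)
        x[i:i + 500] += tone(13.0, 0.5) * np.hanning(500)
    events = detect_spindles(make_trace(x))
    assert len(events) == len(starts)
    for ev, s in zip(events, starts):
        assert ev.t_start / 1e3 == pytest.approx(s, abs=0.15)
        assert 11.0 <= ev.dominant_freq <= 15.0


def test_no_events_with_absurd_threshold(rng):
    x = pink_noise(20000, rng)
    assert detect_spindles(make_trace(x), k=1e9) == []


def test_merge_gap_rule_joins_nearby_bursts(rng):
    from scipy import signal as sg
    drift = sg.sosfiltfilt(sg.butter(4, 5, "lowpass", fs=FS, output="sos"),
                           rng.normal(size=20000))
    x = 0.05 * tone(13.0, 20.0) + 0.3 * drift
    b = tone(13.0, 0.5) * np.hanning(500)
    x[5000:5500] += b
    x[5550:6050] += b                    # 50 ms signal gap
    merged = detect_spindles(make_trace(x), merge_gap=0.15)
    split = detect_spindles(make_trace(x), merge_gap=0.0)
    assert len(merged) == 1
    assert len(split) == 2
    assert merged[0].duration_ms > 800


# -- event statistics -------------------------------------------------------

def _events(times_s, dur=0.5):
    return [SpindleEvent(t * 1e3, (t + dur) * 1e3, 1.0, 13.0) for t in times_s]


def test_density_and_interval_arithmetic():
    evs = _events([0, 7, 14, 21])
    assert spindle_density(evs, 60.0) == pytest.approx(4.0)
    mean, sd = inter_spindle_intervals(evs)
    assert mean == pytest.approx(7.0) and sd == pytest.approx(0.0)


def test_density_zero_and_undefined_intervals():
    assert spindle_density([], 60.0) == 0.0
    mean, sd = inter_spindle_intervals(_events([3.0]))
    assert math.isnan(mean) and math.isnan(sd)
    with pytest.raises(ValueError):
        spindle_density([], 0.0)


def test_density_times_duration_equals_count(rng):
    evs = _events(sorted(rng.uniform(0, 300, 23)))
    dur = 300.0
    assert spindle_density(evs, dur) * dur / 60.0 == pytest.approx(len(evs))
    assert spindle_density(evs, dur) == pytest.approx(4.6)


def test_so_and_cue_counts_from_event_log():
    log = EventLog()
    for t in (1000.0, 3000.0, 5000.0):
        log.add(t, "SO_DETECT")
    log.add(1000.0, "CUE")
    log.add(3000.0, "CUE")
    assert count_sos(log, 60.0) == pytest.approx(3.0)
    assert count_cues(log) == 2


# -- SO marks ---------------------------------------------------------------

def test_so_event_marks_are_ordered():
    t = np.arange(0, 10000.0)
    x = np.zeros_like(t)
    for c in (2000, 5000, 8000):
        x += 5.0 * np.exp(-0.5 * ((t - c) / 200.0) ** 2)
    events = extract_so_events(make_trace(x))
    assert len(events) == 3
    for ev in events:
        assert ev.down_start <= ev.up_onset < ev.up_peak < ev.down_onset


# -- condition comparison ---------------------------------------------------

def test_identical_samples_give_null_effect():
    r = compare_conditions([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert r.mean_diff == 0.0 and r.p_value == pytest.approx(1.0)


def test_large_shift_is_significant(rng):
    a = rng.normal(0, 1, 50)
    r = compare_conditions(a + 100.0, a)
    assert r.p_value < 1e-6 and r.mean_diff == pytest.approx(100.0)


def test_single_sample_rejected():
    with pytest.raises(ValueError):
        compare_conditions([1.0], [2.0])
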