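"""LFP, spectral and event-level analysis of simulation recordings.

The cortical LFP proxy is the summed AMPA + NMDA + GABA_A postsynaptic
current of all pyramidal cells, with the sign fixed so Up states are
positive deflections.  On top of it this module provides:

* Welch power spectral density and a 1 s moving-window spectrogram
  (reported band 0.1-18 Hz),
* a sigma-band spindle detector: band-pass -> analytic-signal envelope ->
  threshold at k x median envelope, merging events separated by short
  gaps and keeping those longer than a minimum duration,
* SO state marks (Down-state end, Up onset/peak, Down onset) extracted
  offline from the smoothed LFP,
* event statistics (densities per minute, inter-spindle intervals, cue
  counts) and a routine two-sample comparison.

The spindle criteria are an operationalization (there is no unique
standard definition); every parameter is exposed and the sensitivity is
documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .stimulation import EventLog

__all__ = [
    "LFPTrace",
    "SpindleEvent",
    "SOEvent",
    "compute_lfp",
    "read_trace",
    "psd",
    "spectrogram",
    "detect_spindles",
    "spindle_density",
    "inter_spindle_intervals",
    "count_sos",
    "count_cues",
    "extract_so_events",
    "compare_conditions",
    "SIGMA_BAND_FAST",
    "SIGMA_BAND_SLOW",
]

SIGMA_BAND_FAST = (10.0, 16.0)
SIGMA_BAND_SLOW = (8.0, 11.0)


@dataclass
class LFPTrace:
    t_ms: np.ndarray
    value: np.ndarray
    sample_rate: float    # Hz

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t_ms.shape != self.value.shape:
            raise ValueError("t and value must have equal length")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite LFP values")

    @property
    def duration_s(self) -> float:
        return len(self.value) / self.sample_rate

    def write_tsv(self, path) -> None:
        pd.DataFrame({"t_ms": self.t_ms, "lfp": self.value}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SpindleEvent:
    t_start: float            # ms
    t_end: float              # ms
    peak_sigma_power: float   # envelope peak (a.u.)
    dominant_freq: float      # Hz

    @property
    def duration_ms(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SOEvent:
    down_start: float
    up_onset: float
    up_peak: float
    down_onset: float


def compute_lfp(source, sample_rate: float | None = None) -> LFPTrace:
    """Cortical LFP from a Recording, or from a (n_cells, n_samples) array
    of per-cell postsynaptic currents (inward negative, summed and
    sign-flipped so depolarizing input is positive)."""
    if hasattr(source, "lfp"):
        rec = source
        fs = rec.config.sample_rate
        return LFPTrace(rec.t_ms, rec.lfp, fs)
    arr = np.atleast_2d(np.asarray(source, dtype=float))
    if sample_rate is None:
        raise ValueError("sample_rate required for raw current arrays")
    value = -arr.sum(axis=0)
    t = np.arange(arr.shape[1]) / sample_rate * 1e3
    return LFPTrace(t, value, sample_rate)


def read_trace(path, sample_rate: float | None = None) -> LFPTrace:
    """Load a two-column (time_ms, value) delimited-text trace."""
    df = pd.read_csv(path, sep=None, engine="python")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if sample_rate is None:
        dt = np.median(np.diff(t))
        sample_rate = 1e3 / dt
    return LFPTrace(t, v, sample_rate)


def psd(
    trace: LFPTrace,
    window_s: float = 4.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram (Welch) PSD of the detrended trace."""
    fs = trace.sample_rate
    nper = int(round(window_s * fs))
    if len(trace.value) < nper:
        raise ValueError("trace shorter than one PSD window")
    f, P = signal.welch(
        signal.detrend(trace.value), fs=fs, nperseg=nper,
        noverlap=int(nper * overlap),
    )
    return f, P


def spectrogram(
    trace: LFPTrace,
    window_s: float = 1.0,
    hop_s: float = 0.1,
    fmin: float = 0.1,
    fmax: float = 18.0,
):
    """Moving-Fourier-window spectrogram clipped to [fmin, fmax]."""
    fs = trace.sample_rate
    nper = int(round(window_s * fs))
    if len(trace.value) < nper:
        raise ValueError("trace shorter than the spectrogram window")
    f, t, S = signal.spectrogram(
        signal.detrend(trace.value), fs=fs, nperseg=nper,
        noverlap=nper - int(round(hop_s * fs)),
    )
    sel = (f >= fmin) & (f <= fmax)
    return f[sel], t, S[sel]


def _band_envelope(trace: LFPTrace, band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=trace.sample_rate,
                        output="sos")
    xb = signal.sosfiltfilt(sos, signal.detrend(trace.value))
    return np.abs(signal.hilbert(xb)), xb


def detect_spindles(
    trace: LFPTrace,
    band: tuple[float, float] = SIGMA_BAND_FAST,
    k: float = 2.0,
    min_dur: float = 0.3,
    merge_gap: float = 0.1,
) -> list[SpindleEvent]:
    """Envelope-threshold spindle detection on the sigma-band LFP.

    Events are intervals where the analytic-signal envelope exceeds
    ``k`` x median envelope; intervals separated by gaps <= ``merge_gap``
    seconds are merged, and only events >= ``min_dur`` seconds are kept.
    """
    fs = trace.sample_rate
    env, xb = _band_envelope(trace, band)
    thr = k * np.median(env)
    above = env > thr
    if not above.any():
        return []
    # contiguous runs
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    # merge short gaps
    merged: list[list[int]] = []
    gap = int(round(merge_gap * fs))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out: list[SpindleEvent] = []
    min_n = int(round(min_dur * fs))
    for s, e in merged:
        if e - s < min_n:
            continue
        seg = xb[s:e]
        fr, P = signal.periodogram(seg, fs=fs)
        sel = (fr >= band[0] - 2) & (fr <= band[1] + 2)
        fdom = float(fr[sel][np.argmax(P[sel])]) if sel.any() else math.nan
        out.append(SpindleEvent(
            t_start=trace.t_ms[s],
            t_end=trace.t_ms[e - 1],
            peak_sigma_power=float(env[s:e].max()),
            dominant_freq=fdom,
        ))
    return out


def spindle_density(events: list[SpindleEvent], duration_s: float) -> float:
    """Events per minute."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return len(events) * 60.0 / duration_s


def inter_spindle_intervals(events: list[SpindleEvent]) -> tuple[float, float]:
    """(mean, SD) of intervals between consecutive spindle onsets, in
    seconds; (nan, nan) for fewer than two events."""
    if len(events) < 2:
        return (math.nan, math.nan)
    onsets = np.asarray([e.t_start for e in events]) / 1e3
    iv = np.diff(np.sort(onsets))
    return float(iv.mean()), float(iv.std())


def count_sos(event_log: EventLog, duration_s: float) -> float:
    """Detected slow oscillations per minute."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return len(event_log.times("SO_DETECT")) * 60.0 / duration_s


def count_cues(event_log: EventLog) -> int:
    return int(len(event_log.times("CUE")))


def extract_so_events(
    trace: LFPTrace,
    smooth_ms: float = 50.0,
    frac: float = 0.25,
    min_peak_frac: float = 0.3,
) -> list[SOEvent]:
    """Offline SO state marks from the smoothed LFP.

    Cycle peaks above ``min_peak_frac`` x global max define Up states;
    the Up onset / Down onset are the rising / falling crossings of
    ``frac`` x cycle peak, and the Down-state start is the preceding
    envelope minimum.
    """
    fs = trace.sample_rate
    n = max(int(round(smooth_ms * fs / 1e3)), 1)
    kern = np.ones(n) / n
    x = np.convolve(trace.value - np.median(trace.value), kern, mode="same")
    if x.max() <= 0:
        return []
    peaks, _ = signal.find_peaks(
        x, height=min_peak_frac * x.max(),
        distance=int(0.3 * fs),
    )
    out = []
    for p in peaks:
        thr = frac * x[p]
        i = p
        while i > 0 and x[i] > thr:
            i -= 1
        j = p
        while j < len(x) - 1 and x[j] > thr:
            j += 1
        k = i
        while k > 0 and x[k] > 0:
            k -= 1
        out.append(SOEvent(
            down_start=trace.t_ms[k], up_onset=trace.t_ms[i],
            up_peak=trace.t_ms[p], down_onset=trace.t_ms[j],
        ))
    return out


@dataclass
class ConditionComparison:
    mean_a: float
    mean_b: float
    mean_diff: float
    sd_a: float
    sd_b: float
    t_stat: float
    p_value: float


def compare_conditions(a, b) -> ConditionComparison:
    """Two-sample t comparison of a metric between conditions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per condition")
    t, p = stats.ttest_ind(a, b)
    if math.isnan(t):         # degenerate (zero-variance identical) input
        t, p = 0.0, 1.0
    return ConditionComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        mean_diff=float(a.mean() - b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        t_stat=float(t), p_value=float(p),
    )
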