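"""Closed-loop stimulation: SO detection, timing points and protocols.

The online slow-oscillation detector watches the pyramidal population: once
every PY cell has been silent for more than ``silence_ms`` (100 ms) it arms
and starts counting PY spikes; the 75th counted spike marks the end of the
Down-state and the beginning of the Down-to-Up transition ("Point 1").

Cues are 20 ms activations of a sensory neuron (SN) projecting to every TC
cell through AMPA receptors.  Timing points:

* Point 1 — at the detection itself (0 ms delay)
* Point 2 / Point 3 — 120 / 180 ms after detection
* Point 4 — on the Up-to-Down transition, operationalized as the falling
  50 %-of-peak crossing of the smoothed PY population firing rate

Protocols:

* CLS  — cue on two successive detections, then detection pauses 2.5 s
* sCLS — cue on one detection, then the 2.5 s pause
* DSt  — cue on every successive detection while the preceding Down-state
  is shorter than 0.5 s; a longer Down-state triggers the 2.5 s pause
  (driving restarts with a cue on the first detection after the pause)

All controllers are pure event-level state machines, usable online inside
the engine or offline on recorded detection streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "StimPoint",
    "ProtocolConfig",
    "SensoryNeuron",
    "StimulationEvent",
    "SODetector",
    "Point4Tracker",
    "CueController",
    "EventLog",
    "so_detector_update",
    "point4_trigger",
    "cls_controller",
    "dst_controller",
    "SNSchedule",
]


class Protocol(str, Enum):
    CONTROL = "control"
    CLS = "cls"
    SCLS = "scls"
    DST = "dst"


class StimPoint(int, Enum):
    P1 = 1
    P2 = 2
    P3 = 3
    P4 = 4


POINT_DELAYS_MS = {StimPoint.P1: 0.0, StimPoint.P2: 120.0, StimPoint.P3: 180.0}


@dataclass(frozen=True)
class ProtocolConfig:
    protocol: Protocol = Protocol.CONTROL
    point: StimPoint = StimPoint.P1
    pause_s: float = 2.5
    dst_downstate_limit_s: float = 0.5
    cue_duration_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.pause_s <= 0:
            raise ValueError("pause_s must be > 0")

    @property
    def delay_ms(self) -> float:
        return POINT_DELAYS_MS.get(self.point, 0.0)


@dataclass(frozen=True)
class SensoryNeuron:
    """Spike source for the acoustic-like cue onto the TC layer (AMPA)."""

    g_sn_tc: float = 0.01       # uS onto every TC cell (calibration constant)
    rate_hz: float = 200.0      # firing rate during the 20 ms cue
    cue_duration_ms: float = 20.0


@dataclass(frozen=True)
class StimulationEvent:
    t_cue: float                # ms
    so_detection_t: float       # ms (nan for Point 4 cues)
    point: StimPoint
    protocol: Protocol
    seq_index: int = 0          # index within the CLS pair / DSt train
    late: bool = False          # delayed cue scheduled after Up-state end


# ---------------------------------------------------------------------------
# SO detector
# ---------------------------------------------------------------------------

@dataclass
class SODetection:
    t: float                    # ms, time of the 75th counted spike
    down_duration_ms: float     # silence preceding the counted spikes


class SODetector:
    """Online Down-to-Up transition detector on the PY spike stream."""

    def __init__(self, silence_ms: float = 100.0, spike_threshold: int = 75):
        self.silence_ms = silence_ms
        self.spike_threshold = spike_threshold
        self.last_spike_t = -math.inf
        self.armed = False
        self.count = 0
        self.down_start = -math.inf
        self._down_dur = math.nan
        self.last_detection_t = -math.inf

    def _check_arm(self, t: float) -> None:
        if t - self.last_spike_t > self.silence_ms:
            if not self.armed:
                self.armed = True
                self.down_start = self.last_spike_t
            elif self.count > 0:
                # renewed silence while counting: restart the count
                self.count = 0
                self.down_start = self.last_spike_t

    def update(self, spike_times: Sequence[float], t_now: float) -> list[SODetection]:
        """Feed time-ordered PY spike times up to ``t_now``; returns any
        detections that occurred."""
        out: list[SODetection] = []
        for t in spike_times:
            self._check_arm(t)
            if self.armed:
                if self.count == 0:
                    self._down_dur = t - self.down_start
                self.count += 1
                if self.count >= self.spike_threshold:
                    out.append(SODetection(t, self._down_dur))
                    self.armed = False
                    self.count = 0
                    self.last_detection_t = t
            self.last_spike_t = t
        self._check_arm(t_now)
        return out


def so_detector_update(
    state: SODetector, py_spike_events: Sequence[float], t: float, dt: float = 0.0
) -> tuple[SODetector, SODetection | None]:
    """Functional wrapper over :class:`SODetector` (one chunk of spikes)."""
    dets = state.update(py_spike_events, t + dt)
    return state, (dets[0] if dets else None)


# ---------------------------------------------------------------------------
# Point-4 trigger: falling 50%-of-peak crossing of the population rate
# ---------------------------------------------------------------------------

class Point4Tracker:
    """Streaming Up-to-Down transition detector on the smoothed PY rate."""

    def __init__(self, frac: float = 0.5, min_peak: float = 10.0):
        self.frac = frac
        self.min_peak = min_peak
        self.peak = 0.0
        self.armed = False

    def arm(self) -> None:
        self.armed = True
        self.peak = 0.0

    def update(self, t: float, rate: float) -> float | None:
        if not self.armed:
            return None
        if rate > self.peak:
            self.peak = rate
        elif self.peak >= self.min_peak and rate < self.frac * self.peak:
            self.armed = False
            return t
        return None


def point4_trigger(
    t: np.ndarray,
    rate: np.ndarray,
    frac: float = 0.5,
    min_peak: float = 10.0,
) -> float | None:
    """Offline Point-4 cue time on a population-rate trace: the first
    falling crossing of ``frac`` x running peak, provided the peak exceeded
    ``min_peak``.  Returns None when no Up-state falling edge exists."""
    tracker = Point4Tracker(frac=frac, min_peak=min_peak)
    tracker.arm()
    for ti, ri in zip(np.asarray(t, float), np.asarray(rate, float)):
        cue = tracker.update(ti, ri)
        if cue is not None:
            return cue
    return None


# ---------------------------------------------------------------------------
# protocol controllers
# ---------------------------------------------------------------------------

class CueController:
    """Event-level cue scheduler for CLS / sCLS / DSt."""

    def __init__(self, config: ProtocolConfig):
        self.config = config
        self.pause_until = -math.inf
        self.pair_count = 0
        self.seq_index = 0
        self.first_after_pause = True
        self.pauses: list[tuple[float, float]] = []

    def _start_pause(self, t: float) -> None:
        self.pause_until = t + self.config.pause_s * 1e3
        self.pauses.append((t, self.pause_until))
        self.first_after_pause = True

    def on_detection(self, t: float, down_duration_ms: float = math.nan
                     ) -> StimulationEvent | None:
        cfg = self.config
        if cfg.protocol is Protocol.CONTROL:
            return None
        if t < self.pause_until:
            return None
        if cfg.protocol in (Protocol.CLS, Protocol.SCLS):
            per_pause = 2 if cfg.protocol is Protocol.CLS else 1
            ev = StimulationEvent(
                t_cue=t + cfg.delay_ms, so_detection_t=t, point=cfg.point,
                protocol=cfg.protocol, seq_index=self.pair_count,
            )
            self.pair_count += 1
            if self.pair_count >= per_pause:
                self._start_pause(t)
                self.pair_count = 0
            return ev
        # DSt: cue while the preceding Down-state stays short; a long
        # Down-state starts the pause.  Driving restarts with a cue on the
        # first detection after a pause.
        long_down = (
            not math.isnan(down_duration_ms)
            and down_duration_ms >= cfg.dst_downstate_limit_s * 1e3
        )
        if long_down and not self.first_after_pause:
            self._start_pause(t)
            return None
        self.first_after_pause = False
        ev = StimulationEvent(
            t_cue=t + cfg.delay_ms, so_detection_t=t, point=cfg.point,
            protocol=cfg.protocol, seq_index=self.seq_index,
        )
        self.seq_index += 1
        return ev


def cls_controller(
    detections: Iterable[float],
    config: ProtocolConfig,
) -> list[StimulationEvent]:
    """Offline CLS/sCLS schedule from a time-ordered detection stream (ms)."""
    ctl = CueController(config)
    out = []
    for t in detections:
        ev = ctl.on_detection(t)
        if ev is not None:
            out.append(ev)
    return out


def dst_controller(
    detections: Iterable[float],
    downstate_durations_ms: Iterable[float],
    config: ProtocolConfig,
) -> list[StimulationEvent]:
    """Offline DSt schedule from detections annotated with the duration of
    the Down-state that preceded each one."""
    ctl = CueController(config)
    out = []
    for t, dd in zip(detections, downstate_durations_ms):
        ev = ctl.on_detection(t, dd)
        if ev is not None:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# sensory-neuron spike schedule
# ---------------------------------------------------------------------------

class SNSchedule:
    """Merged cue windows -> deterministic SN spike train.

    Overlapping cue windows merge into a single activation window, so two
    coincident cues saturate rather than double the drive."""

    def __init__(self, sn: SensoryNeuron):
        self.sn = sn
        self.windows: list[list[float]] = []   # [t0, t1] ms, merged, sorted

    def add_cue(self, t_cue: float) -> None:
        t0, t1 = t_cue, t_cue + self.sn.cue_duration_ms
        for w in self.windows:
            if t0 <= w[1] and t1 >= w[0]:
                w[0] = min(w[0], t0)
                w[1] = max(w[1], t1)
                return
        self.windows.append([t0, t1])
        self.windows.sort()

    def spikes_between(self, t0: float, t1: float) -> np.ndarray:
        """SN spike times in [t0, t1): regular firing at ``rate_hz`` from
        each window start."""
        isi = 1e3 / self.sn.rate_hz
        out: list[float] = []
        for w0, w1 in self.windows:
            if w1 < t0 or w0 >= t1:
                continue
            k0 = max(0, math.ceil((t0 - w0) / isi - 1e-9))
            t = w0 + k0 * isi
            while t < t1 and t <= w1 + 1e-9:
                out.append(t)
                t += isi
        return np.asarray(sorted(out))


# ---------------------------------------------------------------------------
# event log
# ---------------------------------------------------------------------------

class EventLog:
    """Timestamped record of detections, cues, pauses and derived events."""

    KINDS = ("SO_DETECT", "CUE", "PAUSE_START", "PAUSE_END",
             "SPINDLE", "SO_START", "SO_END")

    def __init__(self) -> None:
        self.rows: list[tuple[float, str, str, int, float]] = []

    def add(self, t_ms: float, kind: str, protocol: str = "",
            point: int = 0, aux: float = math.nan) -> None:
        if kind not in self.KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        self.rows.append((float(t_ms), kind, protocol, int(point), aux))

    def times(self, kind: str) -> np.ndarray:
        return np.asarray([r[0] for r in self.rows if r[1] == kind])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["t_ms", "kind", "protocol", "point", "aux"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "EventLog":
        df = pd.read_csv(path, sep="\t")
        log = cls()
        for r in df.itertuples(index=False):
            log.rows.append((float(r.t_ms), str(r.kind), str(r.protocol),
                             int(r.point), float(r.aux)))
        return log
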