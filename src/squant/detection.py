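"""Spontaneous-event detection and per-event kinetics.

Events are detected with a band-limited derivative threshold: the trace is
Savitzky–Golay smoothed, threshold crossings of the first derivative at
``k``·MAD of the derivative noise mark onsets, the subsequent extremum is the
peak, and the local baseline is the median of a short pre-onset window.
Each event carries its baseline-to-peak amplitude, 10–90% rise time
(RT 10-90) and rate of rise RR = 0.8·amplitude / RT 10-90 — the slope of the
main rising phase.  Crossings whose peaks fall closer than one rise time
plus 1 ms are merged into a single event (summation, no decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .trace import Trace

__all__ = [
    "DetectionConfig",
    "EventRecord",
    "EventTable",
    "detect_events",
    "measure_event",
    "compute_ieis",
    "summarize_cell",
]

CSV_COLUMNS = [
    "peak_time_s",
    "amplitude_pA",
    "rt_10_90_ms",
    "rate_of_rise_pA_per_ms",
    "size_class",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable detection parameters.

    ``threshold_mads``: derivative threshold in MADs of the derivative noise.
    ``min_amplitude_sigmas``: discard events smaller than this multiple of
    the robust baseline noise SD.
    ``baseline_ms``: pre-onset window whose median is the local baseline.
    ``peak_search_ms``: how far past an onset to look for the peak.
    ``smooth_ms``: Savitzky–Golay window for the derivative (order 2).
    ``merge_extra_ms``: peaks closer than (rise time + this) merge.
    """

    threshold_mads: float = 4.0
    min_amplitude_sigmas: float = 4.0
    baseline_ms: float = 2.0
    peak_search_ms: float = 10.0
    smooth_ms: float = 2.0
    merge_extra_ms: float = 1.0


@dataclass(frozen=True)
class EventRecord:
    """One detected event; amplitude is a positive magnitude."""

    peak_time: float  # s
    amplitude: float  # pA, baseline-to-peak
    rt_10_90: float  # ms
    rate_of_rise: float  # pA/ms = 0.8*amplitude/rt_10_90
    size_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.rt_10_90 <= 0:
            raise ValueError("amplitude and rt_10_90 must be positive")


@dataclass
class EventTable:
    """Ordered collection of events from one recording.

    ``analyzed_duration`` already has exclusion windows subtracted, so
    ``frequency`` is events per analyzed second.
    """

    events: list[EventRecord]
    polarity: str = "outward"
    analyzed_duration: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [e.peak_time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time for e in self.events])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e.amplitude for e in self.events])

    @property
    def rates_of_rise(self) -> np.ndarray:
        return np.array([e.rate_of_rise for e in self.events])

    @property
    def frequency(self) -> float:
        return len(self.events) / self.analyzed_duration

    @property
    def mean_amplitude(self) -> float:
        return float(np.mean(self.amplitudes)) if self.events else float("nan")

    @property
    def ieis(self) -> np.ndarray:
        return compute_ieis(self)

    def subset(self, mask: np.ndarray) -> "EventTable":
        ev = [e for e, m in zip(self.events, mask) if m]
        return EventTable(ev, self.polarity, self.analyzed_duration, dict(self.meta))

    def with_classes(self, classes: list[str]) -> "EventTable":
        ev = [replace(e, size_class=c) for e, c in zip(self.events, classes)]
        return EventTable(ev, self.polarity, self.analyzed_duration, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_time_s": [e.peak_time for e in self.events],
                "amplitude_pA": [e.amplitude for e in self.events],
                "rt_10_90_ms": [e.rt_10_90 for e in self.events],
                "rate_of_rise_pA_per_ms": [e.rate_of_rise for e in self.events],
                "size_class": [e.size_class for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, polarity: str = "outward", analyzed_duration=float("nan")):
        df = pd.read_csv(path)
        events = [
            EventRecord(
                peak_time=r.peak_time_s,
                amplitude=r.amplitude_pA,
                rt_10_90=r.rt_10_90_ms,
                rate_of_rise=r.rate_of_rise_pA_per_ms,
                size_class=str(r.size_class),
            )
            for r in df.itertuples()
        ]
        return cls(events, polarity, analyzed_duration)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def _oriented(trace: Trace, polarity: str) -> np.ndarray:
    """Trace samples flipped so events are positive deflections."""
    return trace.samples if polarity == "outward" else -trace.samples


def measure_event(
    trace: Trace,
    peak_index: int,
    polarity: str = "outward",
    cfg: DetectionConfig = DetectionConfig(),
    onset_index: int | None = None,
) -> EventRecord | None:
    """Measure amplitude, RT 10-90 and rate of rise at a detected extremum.

    Baseline is the median of a ``cfg.baseline_ms`` window ending at the
    event onset (or just before the peak if no onset is given).  The 10% and
    90% crossings are located scanning back from the peak with linear
    sub-sample interpolation: the last 10% crossing and the first 90%
    crossing before the peak.  Returns ``None`` when the 10% crossing cannot
    be resolved (event at the trace start).
    """
    s = _oriented(trace, polarity)
    fs = trace.fs
    nb = max(int(round(cfg.baseline_ms * 1e-3 * fs)), 1)
    if onset_index is None:
        # walk back down the rising phase to anchor the baseline pre-event
        i = peak_index
        while i > 0 and s[i - 1] < s[i]:
            i -= 1
        anchor = i
    else:
        anchor = onset_index
    b0 = max(anchor - nb, 0)
    if b0 == anchor:
        return None
    baseline = float(np.median(s[b0:anchor]))
    amplitude = float(s[peak_index] - baseline)
    if amplitude <= 0:
        return None

    lo = baseline + 0.1 * amplitude
    hi = baseline + 0.9 * amplitude

    def cross_back(level: float) -> float | None:
        """Last upward crossing of ``level`` before the peak (fractional index)."""
        i = peak_index
        while i > 0 and s[i - 1] > level:
            i -= 1
        if i == 0 and s[0] > level:
            return None  # unresolvable: trace starts above the level
        if s[i] == level:
            return float(i)
        frac = (level - s[i - 1]) / (s[i] - s[i - 1])
        return i - 1 + frac

    t90 = cross_back(hi)
    if t90 is None:
        return None
    t10 = cross_back(lo)
    if t10 is None:
        return None
    rt_ms = (t90 - t10) / fs * 1e3
    if rt_ms <= 0:
        return None
    return EventRecord(
        peak_time=peak_index / fs,
        amplitude=amplitude,
        rt_10_90=rt_ms,
        rate_of_rise=0.8 * amplitude / rt_ms,
    )


def detect_events(
    trace: Trace,
    polarity: str = "outward",
    cfg: DetectionConfig = DetectionConfig(),
) -> EventTable:
    """Detect spontaneous events in ``trace`` and measure their kinetics.

    Returns an empty table (with a warning) on flat or event-free traces.
    Events whose peak falls inside an exclusion window are dropped and the
    excluded time is subtracted from the duration used for the frequency.
    """
    s = _oriented(trace, polarity)
    fs = trace.fs
    win = max(int(round(cfg.smooth_ms * 1e-3 * fs)) | 1, 5)  # odd, >=5
    if len(s) <= 2 * win:
        warnings.warn("trace too short for detection; returning empty table")
        return EventTable([], polarity, trace.analyzed_duration)

    deriv = savgol_filter(s, win, 2, deriv=1, delta=1e3 / fs)  # pA/ms
    med = np.median(deriv)
    mad = np.median(np.abs(deriv - med)) * 1.4826
    if mad == 0:
        warnings.warn("flat trace (zero derivative MAD); returning empty table")
        return EventTable([], polarity, trace.analyzed_duration)
    thr = med + cfg.threshold_mads * mad

    # robust noise SD of the residual around the smoothed trace
    smooth = savgol_filter(s, win, 2)
    resid = s - smooth
    sigma_n = np.median(np.abs(resid - np.median(resid))) * 1.4826
    # fall back to derivative-based scale on noiseless traces
    noise_floor = max(sigma_n, mad * cfg.smooth_ms / 2) * cfg.min_amplitude_sigmas

    above = deriv > thr
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    n_peak = max(int(round(cfg.peak_search_ms * 1e-3 * fs)), 2)
    n_margin = max(int(round(0.5e-3 * fs)), 1)
    falling = deriv <= 0

    records: list[tuple[int, EventRecord]] = []
    seen_peaks: set[int] = set()
    for onset in onsets:
        # search up to the first derivative zero crossing (the local peak),
        # capped at peak_search_ms, so a nearby larger event is not grabbed
        stop = min(onset + n_peak, len(s))
        zc = np.flatnonzero(falling[onset:stop])
        if zc.size:
            stop = min(onset + int(zc[0]) + n_margin + 1, len(s))
        peak = onset + int(np.argmax(s[onset:stop]))
        if peak in seen_peaks:
            continue
        rec = measure_event(trace, peak, polarity, cfg, onset_index=onset)
        if rec is None or rec.amplitude < noise_floor:
            continue
        seen_peaks.add(peak)
        records.append((peak, rec))

    records.sort(key=lambda pr: pr[0])

    # merge rule: peaks closer than one rise time + merge_extra_ms are one event
    merged: list[EventRecord] = []
    for _, rec in records:
        if merged:
            gap_ms = (rec.peak_time - merged[-1].peak_time) * 1e3
            if gap_ms < merged[-1].rt_10_90 + cfg.merge_extra_ms:
                continue  # keep the first peak
        merged.append(rec)

    if trace.exclusion_windows:
        keep = ~trace.in_exclusion(np.array([r.peak_time for r in merged]))
        merged = [r for r, k in zip(merged, keep) if k]

    if not merged:
        warnings.warn("no events detected")
    return EventTable(merged, polarity, trace.analyzed_duration)


# --------------------------------------------------------------------------
# derived statistics
# --------------------------------------------------------------------------

def compute_ieis(table: EventTable) -> np.ndarray:
    """Inter-event intervals (s): time differences between adjacent events."""
    if len(table) < 2:
        return np.empty(0)
    return np.diff(table.peak_times)


def summarize_cell(
    table: EventTable,
    n_events: int,
    rng: np.random.Generator,
) -> dict:
    """Per-cell summary over a seeded random run of ``n_events`` consecutive events.

    A contiguous run (rather than i.i.d. subsampling) keeps the IEI sequence
    intact for burstiness/memory analysis.  If the table holds fewer than
    ``n_events`` events the whole table is used with a warning.
    """
    total = len(table)
    if total < n_events:
        warnings.warn(
            f"only {total} events available (< {n_events}); summarizing all"
        )
        start, run = 0, table
    else:
        start = int(rng.integers(0, total - n_events + 1))
        run = table.subset(
            np.arange(total) >= start
        ).subset(np.arange(total - start) < n_events)
    amps = run.amplitudes
    return {
        "start_index": start,
        "n_events": len(run),
        "frequency_hz": table.frequency,
        "mean_amplitude_pA": float(np.mean(amps)),
        "mean_rate_of_rise_pA_per_ms": float(np.mean(run.rates_of_rise)),
        "ieis_s": compute_ieis(run),
        "events": run,
    }
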