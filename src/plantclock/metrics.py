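"""Rhythm metrics: period, phase and amplitude of oscillating traces.

Periods are estimated by averaging successive peak-to-peak intervals
rather than by FFT or autocorrelation: simulated and experimental traces
are short (a handful of cycles) and carry transients after a change of
light conditions, so the first day of constant conditions is discarded by
default.  Peaks are localised to sub-sample precision by fitting a
parabola through the three samples around each discrete maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MERGE_WINDOW = 6.0          # h; closer peaks are merged keeping the larger
RHYTHMICITY_THRESHOLD = 0.1  # last-cycle amplitude relative to first-cycle


@dataclass
class RhythmSummary:
    period: float            # h; nan when not rhythmic
    period_sd: float
    peak_times: list[float]  # h, in trace time
    relative_amplitude: float
    rhythmic: bool

    def __post_init__(self):
        if self.rhythmic and not self.period > 0:
            raise ValueError("rhythmic summary requires period > 0")
        if any(b <= a for a, b in zip(self.peak_times, self.peak_times[1:])):
            raise ValueError("peak times must be strictly increasing")


def find_peaks(time: np.ndarray, values: np.ndarray,
               min_prominence: float = 0.05) -> list[float]:
    """Local maxima of a sampled trace, in hours.

    min_prominence is a fraction of the trace's full range; flat traces
    yield no peaks.  Peaks within MERGE_WINDOW hours of each other are
    merged, keeping the larger.
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    rng = float(x.max() - x.min())
    if rng <= 0:
        return []
    from scipy.signal import find_peaks as _fp

    idx, props = _fp(x, prominence=min_prominence * rng)
    cand = []
    for i in idx:
        # parabolic refinement through (i-1, i, i+1); uniform spacing assumed
        if 0 < i < len(x) - 1:
            denom = x[i - 1] - 2 * x[i] + x[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (x[i - 1] - x[i + 1]) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            dt = 0.5 * (t[min(i + 1, len(t) - 1)] - t[max(i - 1, 0)])
            cand.append((t[i] + shift * dt, x[i]))
        else:
            cand.append((t[i], x[i]))
    merged: list[tuple[float, float]] = []
    for pt, ph in cand:
        if merged and pt - merged[-1][0] < MERGE_WINDOW:
            if ph > merged[-1][1]:
                merged[-1] = (pt, ph)
        else:
            merged.append((pt, ph))
    return [pt for pt, _ in merged]


def estimate_period(time: np.ndarray, values: np.ndarray,
                    discard_initial: float = 24.0,
                    min_prominence: float = 0.05,
                    amplitude_threshold: float = RHYTHMICITY_THRESHOLD) -> RhythmSummary:
    """Mean successive peak interval after a transient-discard window."""
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    t0 = t[0] + discard_initial
    m = t >= t0
    if m.sum() < 3:
        raise ValueError("trace too short after the discard window")
    peaks = find_peaks(t[m], x[m], min_prominence=min_prominence)
    if len(peaks) < 2:
        return RhythmSummary(float("nan"), float("nan"), peaks, 0.0, False)
    intervals = np.diff(peaks)
    period = float(np.mean(intervals))
    sd = float(np.std(intervals, ddof=1)) if len(intervals) > 1 else 0.0

    def cycle_amp(center: float, width: float) -> float:
        w = (t >= center - width / 2) & (t <= center + width / 2)
        return float(x[w].max() - x[w].min()) if w.any() else 0.0

    first_amp = cycle_amp(peaks[0], period)
    last_amp = cycle_amp(peaks[-1], period)
    rel = last_amp / first_amp if first_amp > 0 else 0.0
    rhythmic = len(peaks) >= 3 and rel >= amplitude_threshold
    return RhythmSummary(period if rhythmic else float("nan"),
                         sd, peaks, rel, rhythmic)


def peak_phase(time: np.ndarray, values: np.ndarray, protocol,
               discard_initial: float = 24.0,
               min_prominence: float = 0.05) -> float:
    """ZT phase (hours after the most recent dawn) of the first peak after
    the discard window.  Raises ValueError for non-rhythmic traces."""
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    m = t >= t[0] + discard_initial
    peaks = find_peaks(t[m], x[m], min_prominence=min_prominence)
    if not peaks:
        raise ValueError("no peaks found; trace may be arrhythmic")
    first = peaks[0]
    dawn = protocol.last_dawn_before(first)
    return float((first - dawn) % 24.0)
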