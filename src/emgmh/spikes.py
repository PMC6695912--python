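"""Spike shape analysis.

A spike is a single upward-then-downward deflection exceeding a threshold
set from baseline activity (mean + 1.96 sd of the pre-onset samples, i.e.
the 95% confidence bound).  Each supra-threshold excursion is extended to
its bounding local minima (troughs); morphology statistics are computed per
spike and averaged over the segment:

* MSA  mean spike amplitude (peak minus deeper bounding trough),
* MSD  mean spike duration (trough-to-trough, seconds),
* MSF  mean spike frequency (spikes per second of segment),
* MSS  mean spike slope (max |dx/dt| within the spike),
* MNPPS mean number of internal supra-threshold peaks per spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Spike:
    peak_index: int
    amplitude: float
    duration: float
    max_slope: float
    n_peaks: int
    start: int
    end: int


@dataclass
class SpikeTrain:
    spikes: list[Spike]
    threshold: float
    segment_duration: float

    def __len__(self) -> int:
        return len(self.spikes)


def detect_spikes(x: np.ndarray, baseline: np.ndarray, fs: float) -> SpikeTrain:
    """Detect spikes in ``x`` using a threshold from ``baseline`` samples."""
    x = np.asarray(x, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline must be non-empty")
    threshold = baseline.mean() + 1.96 * baseline.std()
    duration_s = x.size / fs
    if x.size < 3:
        return SpikeTrain([], threshold, duration_s)

    above = x > threshold
    if not above.any():
        return SpikeTrain([], threshold, duration_s)

    # contiguous supra-threshold regions
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [x.size]))

    minima = np.flatnonzero(
        (x[1:-1] <= x[:-2]) & (x[1:-1] <= x[2:])
    ) + 1

    spikes: list[Spike] = []
    prev_end = -1
    for s, e in zip(starts, ends):
        lo_c = minima[minima < s]
        hi_c = minima[minima >= e]
        lo = int(lo_c[-1]) if lo_c.size else 0
        hi = int(hi_c[0]) if hi_c.size else x.size - 1
        if lo < prev_end:  # overlapping with previous spike: merge boundary
            lo = prev_end
        if hi <= lo:
            continue
        seg = x[lo: hi + 1]
        peak_rel = int(np.argmax(seg))
        amplitude = float(seg[peak_rel] - min(seg[0], seg[-1]))
        duration = (hi - lo) / fs
        max_slope = float(np.max(np.abs(np.diff(seg))) * fs) if seg.size > 1 else 0.0
        interior = x[s:e]
        if interior.size >= 3:
            n_peaks = int(
                np.sum((interior[1:-1] >= interior[:-2]) & (interior[1:-1] > interior[2:]))
            )
            n_peaks = max(n_peaks, 1)
        else:
            n_peaks = 1
        spikes.append(Spike(lo + peak_rel, amplitude, duration, max_slope, n_peaks, lo, hi))
        prev_end = hi
    return SpikeTrain(spikes, threshold, duration_s)


def spike_shape_features(train: SpikeTrain) -> dict[str, float]:
    """MSA/MSD/MSS/MNPPS means over spikes; MSF = count / segment duration."""
    if len(train) == 0:
        return {k: np.nan for k in ("MSA", "MSD", "MSF", "MSS", "MNPPS")}
    return {
        "MSA": float(np.mean([s.amplitude for s in train.spikes])),
        "MSD": float(np.mean([s.duration for s in train.spikes])),
        "MSF": len(train) / train.segment_duration,
        "MSS": float(np.mean([s.max_slope for s in train.spikes])),
        "MNPPS": float(np.mean([s.n_peaks for s in train.spikes])),
    }
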