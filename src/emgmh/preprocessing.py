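"""Signal conditioning and TKEO double-threshold burst segmentation.

Two conditioning paths, applied to each trial:

* onset path -- Teager-Kaiser energy operator (TKEO), rectification, 2nd
  order Butterworth 50 Hz low-pass: a smooth energy envelope on which the
  double-threshold onset detector runs (th1 = baseline mean + 15 sd,
  th2 = 25 consecutive samples);
* feature path -- zero-phase 2nd order Butterworth 20-400 Hz band-pass plus
  60 Hz notch; features are extracted from this path.

Segmentation is driven by the envelope summed across all channels (a
per-motion primary-mover override is available); all channels of a trial are
cut at the same indices.  Failures are reported as QC flags, never silently
dropped, and a manifest may carry hand-edited onset/offset pairs that take
precedence (the equivalent of manual resegmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Recording


@dataclass(frozen=True)
class SegmenterParams:
    th1_sigma_mult: float = 15.0
    th2_consecutive: int = 25
    baseline_window: float = 0.5
    lowpass_cutoff: float = 50.0
    lowpass_order: int = 2
    bandpass: tuple[float, float] = (20.0, 400.0)
    bandpass_order: int = 2
    notch: float = 60.0
    notch_q: float = 30.0
    offset_rule: int | None = None  # sub-threshold run closing a segment; default th2
    detection_channel: str | tuple[str, ...] | None = None  # None = sum of all channels
    refine_onset: bool = True
    min_duration: float = 0.25  # seconds; shorter detections are flagged noise

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not (0 < lo < hi):
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.th2_consecutive < 1:
            raise ValueError("th2_consecutive must be >= 1")

    @property
    def offset_consecutive(self) -> int:
        return self.offset_rule if self.offset_rule is not None else self.th2_consecutive


@dataclass
class MotionSegment:
    """A single-motion excerpt of all channels of one trial."""

    samples: np.ndarray  # [segment_length x n_channels]
    onset_index: int
    offset_index: int
    sampling_rate: float
    channel_names: list[str]
    meta: dict = field(default_factory=dict)
    qc: list[str] = field(default_factory=list)
    baseline: np.ndarray | None = None  # pre-onset samples (feature path)

    def __post_init__(self) -> None:
        if not (0 <= self.onset_index < self.offset_index):
            raise ValueError("require 0 <= onset < offset")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channel_names.index(name)]


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy operator, psi[x](n) = x(n)^2 - x(n+1) x(n-1).

    Defined on interior samples only: the output is 2 samples shorter than
    the input (the two boundary samples are dropped).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("tkeo requires a 1-D signal of length >= 3")
    return x[1:-1] ** 2 - x[2:] * x[:-2]


def condition_for_onset(x: np.ndarray, p: SegmenterParams, fs: float) -> np.ndarray:
    """TKEO -> rectify -> zero-phase low-pass; the thresholded envelope.

    The output is aligned to the original sample coordinates (the two TKEO
    boundary samples are padded back by edge replication) so detected indices
    need no re-offsetting.
    """
    if fs <= 2 * p.lowpass_cutoff:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    e = np.abs(tkeo(x))
    sos = signal.butter(p.lowpass_order, p.lowpass_cutoff, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, e)
    env = np.clip(env, 0.0, None)  # filter ringing can dip below zero
    return np.concatenate(([env[0]], env, [env[-1]]))


def _first_run_at_least(mask: np.ndarray, run: int, start: int = 0) -> int | None:
    """First index at which `mask` holds for `run` consecutive samples."""
    m = mask[start:]
    if run == 1:
        idx = np.flatnonzero(m)
        return int(idx[0]) + start if idx.size else None
    conv = np.convolve(m.astype(int), np.ones(run, dtype=int), mode="valid")
    idx = np.flatnonzero(conv == run)
    return int(idx[0]) + start if idx.size else None


def detect_onset_offset(
    envelope: np.ndarray, p: SegmenterParams, fs: float, search_start: int | None = None
) -> tuple[int, int, list[str]] | None:
    """Double-threshold detection on a conditioned envelope.

    th1 = mean + th1_sigma_mult * sd of the first ``baseline_window`` seconds;
    onset = first sample of a run of th2 consecutive supra-th1 samples
    (optionally refined backwards to the rise through baseline mean + 0.5 sd);
    offset = first sample after onset of a run of ``offset_consecutive``
    sub-th1 samples, else the trial end with a ``truncated`` flag.
    Returns None when no qualifying run exists.
    """
    n_base = int(round(p.baseline_window * fs))
    if n_base < 2 or n_base >= envelope.size:
        raise ValueError("baseline window must be shorter than the trial")
    base = envelope[:n_base]
    th1 = base.mean() + p.th1_sigma_mult * base.std()

    start = n_base if search_start is None else search_start
    trigger = _first_run_at_least(envelope >= th1, p.th2_consecutive, start)
    if trigger is None:
        return None

    flags: list[str] = []
    onset = trigger
    if p.refine_onset:
        # walk back from the trigger to where the envelope last rose through
        # a low threshold just above baseline: the 15-sigma trigger fires
        # partway up the ramp, the rise point is the physiological onset
        low = base.mean() + 0.5 * base.std()
        below = np.flatnonzero(envelope[:trigger] < low)
        if below.size:
            onset = int(below[-1]) + 1

    off = _first_run_at_least(envelope < th1, p.offset_consecutive,
                              trigger + p.th2_consecutive)
    if off is None:
        off = envelope.size
        flags.append("truncated")
    return onset, off, flags


def bandpass_notch(rec: Recording, p: SegmenterParams) -> Recording:
    """Zero-phase 20-400 Hz band-pass + 60 Hz notch on every channel."""
    fs = rec.sampling_rate
    lo, hi = p.bandpass
    if hi >= fs / 2:
        raise ValueError("band-pass upper edge must be below Nyquist")
    sos = signal.butter(p.bandpass_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    b_n, a_n = signal.iirnotch(p.notch, p.notch_q, fs=fs)
    y = signal.sosfiltfilt(sos, rec.samples, axis=0)
    y = signal.filtfilt(b_n, a_n, y, axis=0)
    return Recording(y, fs, list(rec.channel_names), dict(rec.meta))


def detection_envelope(rec: Recording, p: SegmenterParams) -> np.ndarray:
    """Conditioned envelope used for detection, summed over the detection
    channel(s) (all channels when none are named)."""
    sel = p.detection_channel
    if sel is None:
        names = rec.channel_names
    elif isinstance(sel, str):
        names = [sel]
    else:
        names = list(sel)
    env = np.zeros(rec.n_samples)
    for name in names:
        env += condition_for_onset(rec.channel(name), p, rec.sampling_rate)
    return env


def segment_trial(
    rec: Recording,
    p: SegmenterParams,
    expected_bursts: int | None = 1,
    manual_override: tuple[int, int] | None = None,
    filtered: Recording | None = None,
) -> list[MotionSegment]:
    """Segment one trial into motion segments.

    Detection runs on the raw-signal conditioning path; the returned segment
    samples are cut from ``filtered`` (the band-pass + notch path) when given,
    else from the raw recording.  A ``manual_override`` (onset, offset) pair
    plays the role of manual resegmentation and is flagged as such.
    """
    source = filtered if filtered is not None else rec
    fs = rec.sampling_rate

    def make(onset: int, offset: int, qc: list[str]) -> MotionSegment:
        return MotionSegment(
            samples=source.samples[onset:offset],
            onset_index=onset,
            offset_index=offset,
            sampling_rate=fs,
            channel_names=list(rec.channel_names),
            meta=dict(rec.meta),
            qc=qc,
            baseline=source.samples[:onset],
        )

    if manual_override is not None:
        onset, offset = manual_override
        return [make(onset, offset, ["manual-override"])]

    env = detection_envelope(rec, p)
    segments: list[MotionSegment] = []
    start = int(round(p.baseline_window * fs))
    n_min = int(round(p.min_duration * fs))
    while True:
        hit = detect_onset_offset(env, p, fs, search_start=start)
        if hit is None:
            break
        onset, offset, flags = hit
        if offset - onset < n_min and "truncated" not in flags:
            # supra-threshold blip shorter than a plausible motion: skip it
            # and keep searching (recorded as a trial-level QC note)
            if isinstance(rec.meta, dict):
                rec.meta.setdefault("qc", []).append("short-detection-skipped")
            start = offset + p.offset_consecutive
            continue
        segments.append(make(onset, offset, flags))
        if "truncated" in flags or offset >= env.size - p.th2_consecutive:
            break
        start = offset + p.offset_consecutive
        if expected_bursts is not None and len(segments) >= expected_bursts:
            break
    if not segments and isinstance(rec.meta, dict):
        rec.meta.setdefault("qc", []).append("no-onset-found")
    return segments
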