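"""Filtering, rule-based artifact rejection, segmentation and quality gating.

The conditioning chain mirrors a standard clinical resting-EEG protocol:

1. zero-phase 1 Hz high-pass (4th-order Butterworth, forward-backward,
   ~48 dB/oct combined roll-off) plus a zero-phase 50 Hz notch;
2. three amplitude rules evaluated per channel on every sample/window,
   each flagged region dilated by a rule-specific margin:

   (a) voltage step per sampling point  > 50 µV   -> ±100 ms margin
   (b) peak-to-peak over any 200 ms window > 200 µV -> ±100 ms margin
   (c) peak-to-peak over any 100 ms window < 0.5 µV -> ±500 ms margin
       (the flatline rule: physiological EEG is never that quiet);

3. segmentation into consecutive 500 ms segments; a segment is dropped
   for all channels if any of its samples is flagged on any channel;
4. a quality gate excluding recordings with fewer than 8 clean segments.

The measures of interaction downstream are computed on the concatenated
clean segments, discontinuities ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .io import Recording


@dataclass
class ArtifactRules:
    """Thresholds (µV) and margins/windows (seconds) of the three rules."""

    max_step: float = 50.0
    step_margin: float = 0.1
    max_diff: float = 200.0
    diff_window: float = 0.2
    diff_margin: float = 0.1
    min_diff: float = 0.5
    flat_window: float = 0.1
    flat_margin: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_step", "max_diff", "min_diff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SegmentedRecording:
    """Clean 500 ms segments of one recording plus their concatenation."""

    segments: np.ndarray  # (n_kept, channels, segment_len)
    kept_indices: list[int]
    n_segments_total: int
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.segments.shape[0]

    @property
    def concatenated(self) -> np.ndarray:
        """Kept segments joined in temporal order: channels x (len * n_kept)."""
        if self.n_kept == 0:
            return np.empty((self.segments.shape[1], 0))
        return np.concatenate(list(self.segments), axis=1)


def bandpass_condition(
    rec: Recording,
    highpass_hz: float = 1.0,
    notch_hz: float | None = 50.0,
    notch_bandwidth_hz: float = 2.0,
) -> Recording:
    """Zero-phase high-pass and notch filtering.

    The high-pass is a 4th-order Butterworth applied forward and backward
    (24 dB/oct per pass, ~48 dB/oct combined, no phase distortion); the
    notch is a second-order IIR notch of the given bandwidth, also run
    forward-backward.  Pass ``notch_hz=None`` to skip the notch.
    """
    if rec.duration < 3.0:
        raise ValueError(
            f"recording of {rec.duration:.2f} s is shorter than the 3 s filter warm-up"
        )
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch_hz is not None:
        b, a = signal.iirnotch(notch_hz, notch_hz / notch_bandwidth_hz, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return Recording(
        data=data,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        artifact_mask=rec.artifact_mask.copy(),
    )


def _flag_intervals(n: int, starts: np.ndarray, length: int, margin: int) -> np.ndarray:
    """Mask with [s - margin, s + length - 1 + margin] set for each start s."""
    delta = np.zeros(n + 1, dtype=np.int64)
    lo = np.clip(starts - margin, 0, n)
    hi = np.clip(starts + length + margin, 0, n)  # exclusive
    np.add.at(delta, lo, 1)
    np.add.at(delta, hi, -1)
    return np.cumsum(delta[:-1]) > 0


def _window_ptp(data: np.ndarray, wlen: int) -> np.ndarray:
    """Peak-to-peak over every sliding window; index = window start."""
    sw = sliding_window_view(data, wlen, axis=1)
    return sw.max(axis=-1) - sw.min(axis=-1)


def detect_artifacts(rec: Recording, rules: ArtifactRules | None = None) -> np.ndarray:
    """Boolean per-sample mask: union over channels and rules, with margins.

    Rule semantics (closed intervals in samples, clipped at the edges):

    * step: ``|x[t] - x[t-1]| > max_step`` flags sample ``t`` with
      ``±step_margin``;
    * max-diff: peak-to-peak of any sliding ``diff_window`` exceeding
      ``max_diff`` flags that window with ``±diff_margin``;
    * min-diff: peak-to-peak of any sliding ``flat_window`` below
      ``min_diff`` flags that window with ``±flat_margin``.
    """
    rules = rules or ArtifactRules()
    data = rec.data
    n = rec.n_samples
    fs = rec.fs
    mask = np.zeros(n, dtype=bool)

    # (a) voltage step per sampling point
    step_margin = int(round(rules.step_margin * fs))
    steps = np.abs(np.diff(data, axis=1)) > rules.max_step  # index t-1 -> sample t
    for ch in range(data.shape[0]):
        hits = np.flatnonzero(steps[ch]) + 1
        if hits.size:
            mask |= _flag_intervals(n, hits, 1, step_margin)

    # (b) maximum peak-to-peak difference on a 200 ms window
    wlen = int(round(rules.diff_window * fs))
    if n >= wlen:
        margin = int(round(rules.diff_margin * fs))
        ptp = _window_ptp(data, wlen)
        for ch in range(data.shape[0]):
            starts = np.flatnonzero(ptp[ch] > rules.max_diff)
            if starts.size:
                mask |= _flag_intervals(n, starts, wlen, margin)

    # (c) minimum peak-to-peak difference on a 100 ms window (flatline)
    wlen = int(round(rules.flat_window * fs))
    if n >= wlen:
        margin = int(round(rules.flat_margin * fs))
        ptp = _window_ptp(data, wlen)
        for ch in range(data.shape[0]):
            starts = np.flatnonzero(ptp[ch] < rules.min_diff)
            if starts.size:
                mask |= _flag_intervals(n, starts, wlen, margin)

    return mask


def segment_and_exclude(
    rec: Recording,
    mask: np.ndarray | None = None,
    segment_seconds: float = 0.5,
) -> SegmentedRecording:
    """Cut into consecutive 500 ms segments and drop any overlapping the mask.

    Segmentation starts at sample 0; the trailing partial segment is
    discarded.  A segment is excluded for *all* channels as soon as one
    of its samples is flagged.
    """
    if mask is None:
        mask = rec.artifact_mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (rec.n_samples,):
        raise ValueError("mask length must equal the sample count")
    seg_len = int(round(segment_seconds * rec.fs))
    if rec.n_samples < seg_len:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{seg_len}-sample segment"
        )
    n_total = rec.n_samples // seg_len
    seg_mask = mask[: n_total * seg_len].reshape(n_total, seg_len).any(axis=1)
    kept = np.flatnonzero(~seg_mask)
    segs = rec.data[:, : n_total * seg_len].reshape(
        rec.n_channels, n_total, seg_len
    ).transpose(1, 0, 2)[kept]
    return SegmentedRecording(
        segments=np.ascontiguousarray(segs),
        kept_indices=kept.tolist(),
        n_segments_total=n_total,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
    )


def quality_gate(seg: SegmentedRecording, min_segments: int = 8) -> bool:
    """True if the recording keeps at least ``min_segments`` clean segments."""
    return seg.n_kept >= min_segments


def preprocess_recording(
    rec: Recording,
    rules: ArtifactRules | None = None,
    highpass_hz: float = 1.0,
    notch_hz: float | None = 50.0,
    min_segments: int = 8,
    extra_mask: np.ndarray | None = None,
) -> tuple[SegmentedRecording, bool]:
    """Full conditioning chain: filter, detect, segment, gate.

    ``extra_mask`` allows a user-supplied override (e.g. from visual
    review) to be OR-ed with the automatic detection.
    """
    filtered = bandpass_condition(rec, highpass_hz=highpass_hz, notch_hz=notch_hz)
    mask = detect_artifacts(filtered, rules)
    if extra_mask is not None:
        mask = mask | np.asarray(extra_mask, dtype=bool)
    seg = segment_and_exclude(filtered, mask)
    return seg, quality_gate(seg, min_segments)


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open [start, stop) sample intervals."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def write_intervals(intervals: Sequence[tuple[int, int]], path) -> None:
    """Write artifact intervals as a BED-like 'name start stop' text file."""
    with open(path, "w") as fh:
        fh.write("# artifact\tstart_sample\tstop_sample (half-open)\n")
        for a, b in intervals:
            fh.write(f"artifact\t{a}\t{b}\n")
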