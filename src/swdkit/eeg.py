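"""EEG preprocessing, SWD detection and stimulation-block classification.

Implements the experimental event rules used with GAERS recordings: a
50 Hz notch plus 1-90 Hz band-pass, automatic detection of spike-and-wave
discharges (7-12 Hz rhythm at >= 2x baseline amplitude), the merging and
minimum-duration rules (< 1 s gaps merged, < 2 s events discarded), and
the classification of 6 s stimulation blocks into the eight categories
defined by their timing relative to seizures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGTrace",
    "SeizureInterval",
    "StimulationBlock",
    "BLOCK_LABELS",
    "preprocess_eeg",
    "detect_swd",
    "merge_and_filter",
    "overlap_fraction",
    "classify_stimulations",
]

BLOCK_LABELS = (
    "baseline",
    "fully_inside",
    "started_during_mostly_inside",
    "started_during_mostly_outside",
    "started_before_mostly_inside",
    "started_before_mostly_outside",
    "ended_seizure",
    "right_after_seizure",
)


@dataclass
class EEGTrace:
    """A sampled EEG channel (microvolts)."""

    samples: np.ndarray
    fs: float = 1024.0
    channel: str = "EEG"
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True, order=True)
class SeizureInterval:
    start: float  # s
    end: float    # s

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StimulationBlock:
    onset: float           # s
    duration: float = 6.0  # s
    label: str | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("block duration must be > 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration


def preprocess_eeg(trace: EEGTrace, notch_hz: float = 50.0,
                   band=(1.0, 90.0), order: int = 4) -> EEGTrace:
    """Zero-phase 50 Hz notch + Butterworth band-pass (1-90 Hz default).

    Both filters are applied forward-backward (``filtfilt``), so the
    output is zero-phase; the notch attenuates the mains component by
    >= 30 dB and the band-pass removes DC and high-frequency content.
    """
    if trace.fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {trace.fs} Hz too low for a {band[1]} Hz band edge"
        )
    b_notch, a_notch = sps.iirnotch(notch_hz, Q=30.0, fs=trace.fs)
    sos = sps.butter(order, band, btype="bandpass", fs=trace.fs, output="sos")
    x = sps.filtfilt(b_notch, a_notch, trace.samples)
    x = sps.sosfiltfilt(sos, x)
    return replace(trace, samples=x)


def _window_view(n, win, hop):
    starts = np.arange(0, n - win + 1, hop)
    return starts


def detect_swd(trace: EEGTrace, band=(7.0, 12.0), amp_ratio: float = 2.0,
               window: float = 0.5, band_fraction: float = 0.4,
               merge_gap: float = 1.0, min_duration: float = 2.0):
    """Detect spike-and-wave discharge intervals in a preprocessed trace.

    Sliding windows (``window`` s, 50% overlap) are marked when (a) the
    7-12 Hz fraction of 1-45 Hz spectral power exceeds ``band_fraction``
    and (b) the window RMS amplitude is at least ``amp_ratio`` times the
    rolling baseline amplitude (median window RMS outside detections,
    two-pass).  Marked windows are fused into intervals, then passed
    through :func:`merge_and_filter`; boundaries therefore snap to the
    half-window grid.
    """
    if trace.duration < 10.0:
        raise ValueError("need >= 10 s of EEG for baseline estimation")
    x = trace.samples
    if np.allclose(x, x[0]):
        return []
    fs = trace.fs
    win = int(round(window * fs))
    hop = win // 2
    starts = _window_view(x.size, win, hop)
    freqs = np.fft.rfftfreq(win, 1 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    total = (freqs >= 1.0) & (freqs <= 45.0)
    hann = np.hanning(win)

    rms = np.empty(starts.size)
    frac = np.empty(starts.size)
    for i, s in enumerate(starts):
        seg = x[s:s + win]
        rms[i] = np.sqrt(np.mean(seg**2))
        p = np.abs(np.fft.rfft((seg - seg.mean()) * hann)) ** 2
        tot = p[total].sum()
        frac[i] = p[in_band].sum() / tot if tot > 0 else 0.0

    # two-pass baseline: global median first, then median over windows
    # outside the first-pass detections
    def mark(baseline):
        return (frac > band_fraction) & (rms >= amp_ratio * baseline)

    hits = mark(np.median(rms))
    quiet = rms[~hits] if (~hits).any() else rms
    hits = mark(np.median(quiet))

    intervals = []
    i = 0
    while i < hits.size:
        if hits[i]:
            j = i
            while j + 1 < hits.size and hits[j + 1]:
                j += 1
            t_start = trace.t0 + starts[i] / fs
            t_end = trace.t0 + (starts[j] + win) / fs
            intervals.append(SeizureInterval(t_start, t_end))
            i = j + 1
        else:
            i += 1
    return merge_and_filter(intervals, merge_gap=merge_gap, min_duration=min_duration)


def merge_and_filter(intervals, merge_gap: float = 1.0, min_duration: float = 2.0):
    """Apply the seizure-counting rules: merge gaps < ``merge_gap`` s,
    then drop events shorter than ``min_duration`` s (inclusive bound:
    an event of exactly ``min_duration`` is kept).  Idempotent."""
    ivs = list(intervals)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError("intervals must be sorted and non-overlapping")
    merged: list[SeizureInterval] = []
    for iv in ivs:
        if merged and iv.start - merged[-1].end < merge_gap:
            merged[-1] = SeizureInterval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return [iv for iv in merged if iv.duration >= min_duration]


def overlap_fraction(block: StimulationBlock, interval: SeizureInterval) -> float:
    """Fraction of the block lying inside the seizure interval."""
    lo = max(block.onset, interval.start)
    hi = min(block.end, interval.end)
    return max(hi - lo, 0.0) / block.duration


def classify_stimulations(blocks, seizures, end_window: float = 2.0,
                          after_window: float = 2.0):
    """Assign each stimulation block exactly one timing label.

    Precedence (first match wins):

    1. ``ended_seizure`` — block starts inside a seizure whose end falls
       within [0, ``end_window``] s after the block onset;
    2. ``fully_inside`` — block contained in a seizure;
    3. ``started_during_mostly_inside`` / ``..._outside`` — block onset
       inside a seizure, split on overlap fraction > 0.5 (ties go to
       mostly_outside, matching the strict ">50% inside" rule);
    4. ``started_before_mostly_inside`` / ``..._outside`` — a seizure
       begins inside the block, same overlap split;
    5. ``right_after_seizure`` — onset within ``after_window`` s after a
       seizure end;
    6. ``baseline`` otherwise.

    Returns new StimulationBlock objects with labels set.
    """
    blocks = sorted(blocks, key=lambda b: b.onset)
    for a, b in zip(blocks, blocks[1:]):
        if b.onset < a.end:
            raise ValueError("stimulation blocks must not overlap")
    seizures = sorted(seizures)
    out = []
    for blk in blocks:
        label = "baseline"
        containing = next(
            (s for s in seizures if s.start <= blk.onset < s.end), None
        )
        if containing is not None:
            if 0.0 <= containing.end - blk.onset <= end_window:
                label = "ended_seizure"
            elif containing.start <= blk.onset and blk.end <= containing.end:
                label = "fully_inside"
            else:
                frac = sum(overlap_fraction(blk, s) for s in seizures)
                label = ("started_during_mostly_inside" if frac > 0.5
                         else "started_during_mostly_outside")
        else:
            starting = [s for s in seizures if blk.onset < s.start < blk.end]
            just_ended = [s for s in seizures
                          if 0.0 <= blk.onset - s.end <= after_window]
            if starting:
                frac = sum(overlap_fraction(blk, s) for s in seizures)
                label = ("started_before_mostly_inside" if frac > 0.5
                         else "started_before_mostly_outside")
            elif just_ended:
                label = "right_after_seizure"
        out.append(StimulationBlock(onset=blk.onset, duration=blk.duration, label=label))
    return out
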