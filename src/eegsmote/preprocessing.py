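"""Raw multichannel EEG -> labeled fixed-length windows.

The stages mirror a standard scalp-EEG seizure-detection front end:
a 0.5–50 Hz Butterworth bandpass (zero phase), a 4 s sliding window with
2 s step (1024 samples per window at 256 Hz), and one-way ANOVA channel
selection separating ictal from nonictal window energies.

Conventions: times in seconds, seizure intervals half-open [start, end),
sample indices 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal, stats

__all__ = ["EEGRecord", "SegmentSet", "ChannelSelection",
           "bandpass", "segment", "anova_select", "select_channels"]


@dataclass
class EEGRecord:
    """Multichannel EEG with sampling rate and seizure annotations.

    data : (n_channels, n_samples) array, microvolts
    fs : sampling rate in Hz
    channel_names : bipolar-montage labels, e.g. "T7-P7"
    seizure_intervals : list of [start_s, end_s) pairs, sorted and
        non-overlapping, within the record duration
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal n_channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        ivals = [(float(a), float(b)) for a, b in self.seizure_intervals]
        dur = self.duration_s
        prev_end = -np.inf
        for a, b in ivals:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"interval [{a}, {b}) outside [0, {dur})")
            if a < prev_end:
                raise ValueError("seizure intervals must be sorted and "
                                 "non-overlapping")
            prev_end = b
        self.seizure_intervals = ivals

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SegmentSet:
    """Windowed, labeled EEG segments (the classifier's input).

    segments : (n_segments, n_channels, window_samples) tensor
    labels : binary vector, 1 = ictal
    offsets : start time of each window in seconds, strictly increasing
    """

    segments: np.ndarray
    labels: np.ndarray
    fs: float
    window_s: float
    step_s: float
    offsets: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.segments.ndim != 3:
            raise ValueError("segments must be 3-D "
                             "(n_segments, n_channels, window_samples)")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        expected = round(self.window_s * self.fs)
        if self.segments.shape[2] != expected:
            raise ValueError(f"window_samples {self.segments.shape[2]} != "
                             f"round(window_s * fs) = {expected}")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]

    @property
    def window_samples(self) -> int:
        return self.segments.shape[2]

    def channel_view(self, channel: int | str) -> "SegmentSet":
        """Single-channel view (per-channel training)."""
        if isinstance(channel, str):
            channel = self.channel_names.index(channel)
        return SegmentSet(self.segments[:, [channel], :], self.labels,
                          self.fs, self.window_s, self.step_s, self.offsets,
                          [self.channel_names[channel]]
                          if self.channel_names else [])

    def flatten(self) -> np.ndarray:
        """(n_segments, n_channels * window_samples) feature matrix."""
        return self.segments.reshape(self.n_segments, -1)

    # -- serialization: compressed arrays + JSON sidecar ----------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"),
                            segments=self.segments, labels=self.labels,
                            offsets=self.offsets)
        meta = {"fs": self.fs, "window_s": self.window_s,
                "step_s": self.step_s, "channel_names": self.channel_names}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as f:
            return cls(f["segments"], f["labels"], meta["fs"],
                       meta["window_s"], meta["step_s"], f["offsets"],
                       meta["channel_names"])


@dataclass(frozen=True)
class ChannelSelection:
    """Per-channel one-way ANOVA outcome (ictal vs nonictal)."""

    f_statistic: np.ndarray
    p_value: np.ndarray
    retained: np.ndarray       # bool, retained <=> p < alpha
    alpha: float
    channel_names: tuple[str, ...] = ()

    @property
    def retained_channels(self) -> list[str]:
        if not self.channel_names:
            return []
        return [n for n, r in zip(self.channel_names, self.retained) if r]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bandpass(record: EEGRecord, low_hz: float = 0.5, high_hz: float = 50.0,
             order: int = 4) -> EEGRecord:
    """Zero-phase Butterworth bandpass, applied per channel.

    Forward-backward application doubles the effective order and cancels
    phase distortion, which matters when window labels are tied to
    annotated seizure onset times.
    """
    nyq = record.fs / 2
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=record.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, record.data, axis=1)
    return replace(record, data=filtered)


def _overlap_fraction(start: float, end: float,
                      intervals: list[tuple[float, float]]) -> float:
    win = end - start
    covered = sum(max(0.0, min(end, b) - max(start, a)) for a, b in intervals)
    return covered / win if win > 0 else 0.0


def segment(record: EEGRecord, window_s: float = 4.0, step_s: float = 2.0,
            label_rule: str = "majority-overlap") -> SegmentSet:
    """Slide a fixed window over the record and label each window.

    n_segments = floor((duration - window_s) / step_s) + 1.  Label rules:

    - "majority-overlap" (default): ictal iff >= 50% of the window lies
      inside a seizure interval;
    - "any-overlap": ictal iff the overlap is positive;
    - "full-containment": ictal iff the window lies entirely inside one
      interval.
    """
    if record.duration_s < window_s:
        raise ValueError(f"record duration {record.duration_s:.2f} s is "
                         f"shorter than the window ({window_s} s)")
    if label_rule not in ("majority-overlap", "any-overlap",
                         "full-containment"):
        raise ValueError(f"unknown label rule {label_rule!r}")
    win = round(window_s * record.fs)
    step = step_s * record.fs
    n_seg = int(np.floor((record.duration_s - window_s) / step_s)) + 1
    segs = np.empty((n_seg, record.n_channels, win))
    labels = np.empty(n_seg, int)
    offsets = np.empty(n_seg)
    for i in range(n_seg):
        s0 = round(i * step)
        offsets[i] = s0 / record.fs
        segs[i] = record.data[:, s0:s0 + win]
        frac = _overlap_fraction(offsets[i], offsets[i] + window_s,
                                 record.seizure_intervals)
        if label_rule == "majority-overlap":
            labels[i] = int(frac >= 0.5)
        elif label_rule == "any-overlap":
            labels[i] = int(frac > 0)
        else:
            labels[i] = int(frac >= 1.0 - 1e-12)
    return SegmentSet(segs, labels, record.fs, window_s, step_s, offsets,
                      list(record.channel_names))


_FEATURES = {
    "log_energy": lambda w: np.log(np.sum(w * w, axis=-1) + 1e-300),
    "mean_abs": lambda w: np.mean(np.abs(w), axis=-1),
    "variance": lambda w: np.var(w, axis=-1),
}


def anova_select(segs: SegmentSet, feature: str = "log_energy",
                 alpha: float = 0.05) -> ChannelSelection:
    """One-way two-group ANOVA per channel on a scalar window feature.

    Each window is reduced to one scalar per channel (default: log signal
    energy); the F statistic compares ictal vs nonictal groups and a
    channel is retained when p < alpha.  For two groups F equals the
    square of the pooled-variance two-sample t statistic.
    """
    if feature not in _FEATURES:
        raise ValueError(f"unknown feature {feature!r}; "
                         f"choose from {sorted(_FEATURES)}")
    y = segs.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both ictal and nonictal segments are required")
    vals = _FEATURES[feature](segs.segments)     # (n_segments, n_channels)
    F = np.empty(segs.n_channels)
    p = np.empty(segs.n_channels)
    for c in range(segs.n_channels):
        F[c], p[c] = stats.f_oneway(vals[y == 1, c], vals[y == 0, c])
    return ChannelSelection(F, p, p < alpha, alpha,
                            tuple(segs.channel_names))


def select_channels(record: EEGRecord, keep: list[str]) -> EEGRecord:
    """Subset channels by name, in the given order."""
    if not keep:
        raise ValueError("keep list must be nonempty")
    unknown = [n for n in keep if n not in record.channel_names]
    if unknown:
        raise KeyError(f"unknown channel names: {unknown}")
    idx = [record.channel_names.index(n) for n in keep]
    return replace(record, data=record.data[idx], channel_names=list(keep))
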