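"""Ground-truth-bearing synthetic fixtures.

Two families of generator make every stage of the pipeline testable
without any external recording:

* :func:`make_clusters` — imbalanced two-class Gaussian point clouds
  with an optional fraction of minority rows planted inside the majority
  core (labelled noise, ground truth returned, never inferred);
* :func:`make_eeg` — multichannel 256 Hz records with 1/f-type
  background noise and spike-wave-like oscillatory bursts (3 Hz, the
  canonical generalized-seizure motif) added to a chosen channel subset
  inside annotated seizure intervals.

:func:`make_imbalanced_segments` composes the two conventions the
segmentation stage expects: by default the ictal:nonictal window ratio is
about 1:30, the typical scalp-EEG imbalance for long-term monitoring.

All generators are pure functions of their configuration: the same seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset
from .preprocessing import EEGRecord, SegmentSet, segment

__all__ = ["ClusterConfig", "SynthEEGConfig", "make_clusters", "make_eeg",
           "make_imbalanced_segments", "standard_imbalanced_clusters"]


@dataclass(frozen=True)
class ClusterConfig:
    """Two spherical Gaussian classes with planted minority noise.

    separation : distance between the class means in units of the shared
        cluster standard deviation.  At separation >= 4 the clusters are
        essentially disjoint and planted noise is exactly recoverable.
    noise_frac : fraction of minority rows relocated into the majority
        core (drawn from the majority distribution) and recorded as
        ground-truth noise.
    """

    n_major: int = 300
    n_minor: int = 10
    n_features: int = 2
    separation: float = 4.0
    noise_frac: float = 0.0
    cluster_sd: float = 1.0
    seed: int = 0
    k_guard: int = 5
    guarantee_truth: bool = True

    def __post_init__(self) -> None:
        if not self.n_major >= self.n_minor >= 2:
            raise ValueError("require n_major >= n_minor >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 <= self.noise_frac < 1:
            raise ValueError("noise_frac must be in [0, 1)")


def _all_majority_neighborhood(X: np.ndarray, y: np.ndarray, row: int,
                               k: int) -> bool:
    """Brute-force check: are all k nearest neighbours of ``row`` majority?

    Kept independent of the package's kNN backend so the generator's
    ground truth is not defined by the code under test.
    """
    d = np.linalg.norm(X - X[row], axis=1)
    d[row] = np.inf
    nearest = np.argsort(d, kind="stable")[:k]
    return bool((y[nearest] == 0).all())


def make_clusters(cfg: ClusterConfig = ClusterConfig()
                  ) -> tuple[LabeledDataset, np.ndarray]:
    """Imbalanced Gaussian clusters; returns (dataset, planted-noise rows).

    Majority rows come first (label 0, mean at the origin), then minority
    rows (label 1, mean at distance ``separation * cluster_sd`` along the
    first axis).  ``noise_frac`` of the minority rows are replaced by
    draws inside the majority core; their dataset row indices are the
    returned truth set.

    When ``guarantee_truth`` is set and separation >= 4 sd, the planted
    truth is enforced by construction: minority draws whose entire
    ``k_guard``-neighbourhood is majority class are redrawn, and planted
    noise placements that pick up a minority neighbour (e.g. two noise
    rows landing next to each other) are relocated.  This truncates at
    most a few percent of the stated Gaussian tails; below 4 sd the
    guarantee is geometrically unattainable and raw draws are returned.
    """
    rng = np.random.default_rng(cfg.seed)
    sd = cfg.cluster_sd
    X_maj = rng.normal(0.0, sd, size=(cfg.n_major, cfg.n_features))
    mu = np.zeros(cfg.n_features)
    mu[0] = cfg.separation * sd
    X_min = rng.normal(mu, sd, size=(cfg.n_minor, cfg.n_features))
    n_noise = int(round(cfg.noise_frac * cfg.n_minor))
    noise_local = rng.choice(cfg.n_minor, size=n_noise, replace=False)

    def core_draw() -> np.ndarray:
        return rng.normal(0.0, sd / np.sqrt(cfg.n_features),
                          size=cfg.n_features)

    for i in noise_local:
        X_min[i] = core_draw()

    if cfg.guarantee_truth and cfg.separation >= 4:
        is_noise = np.zeros(cfg.n_minor, bool)
        is_noise[noise_local] = True
        y = np.concatenate([np.zeros(cfg.n_major, int),
                            np.ones(cfg.n_minor, int)])
        for _ in range(50):                      # redraw sweeps
            X = np.vstack([X_maj, X_min])
            clean_ok = noise_ok = True
            for i in range(cfg.n_minor):
                flagged = _all_majority_neighborhood(
                    X, y, cfg.n_major + i, cfg.k_guard)
                if is_noise[i] and not flagged:
                    X_min[i] = core_draw()       # e.g. two noise rows met
                    noise_ok = False
                elif not is_noise[i] and flagged:
                    X_min[i] = rng.normal(mu, sd)  # stray tail draw
                    clean_ok = False
            if clean_ok and noise_ok:
                break
        else:  # pragma: no cover - would need a pathological config
            raise RuntimeError("could not realise the planted noise truth; "
                               "increase separation or n_major")

    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(cfg.n_major, int),
                        np.ones(cfg.n_minor, int)])
    truth = np.sort(cfg.n_major + noise_local)
    return LabeledDataset(X, y), truth


def standard_imbalanced_clusters(seed: int = 0
                                 ) -> tuple[LabeledDataset, np.ndarray]:
    """The package's standard imbalanced benchmark fixture.

    A 1:30 minority:majority point cloud (the typical ictal:nonictal
    window ratio in long-term scalp-EEG monitoring) with an overlapping
    class boundary (means 3 sd apart) and 10% of minority rows planted as
    noise.  Used by the resampler-benefit benchmarks.
    """
    return make_clusters(ClusterConfig(n_major=300, n_minor=10,
                                       n_features=2, separation=3.0,
                                       noise_frac=0.1, seed=seed))


@dataclass(frozen=True)
class SynthEEGConfig:
    """Multichannel surrogate EEG with annotated oscillatory bursts.

    Background per channel is band-limited 1/f^exponent noise (exponent 1
    by default, the broad shape of resting scalp EEG).  Inside each
    seizure interval, ``affected_channels`` receive an added spike-wave-
    like oscillation at ``burst_freq_hz`` whose amplitude is
    ``burst_gain`` times the background standard deviation.
    """

    duration_s: float = 120.0
    fs: float = 256.0
    n_channels: int = 23
    seizure_intervals: tuple[tuple[float, float], ...] = ((40.0, 60.0),)
    affected_channels: tuple[int, ...] = (0, 1, 2, 3)
    burst_freq_hz: float = 3.0
    burst_gain: float = 5.0
    background_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.burst_freq_hz:
            raise ValueError("fs must exceed twice the burst frequency")
        if any(c < 0 or c >= self.n_channels for c in self.affected_channels):
            raise ValueError("affected_channels out of range")


def _pink_noise(n: int, exponent: float, rng: np.random.Generator
                ) -> np.ndarray:
    """Band-limited 1/f^exponent noise, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2)
    scale[0] = 0.0                       # no DC
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _spike_wave(t: np.ndarray, f: float) -> np.ndarray:
    """Sharpened oscillation: fundamental plus decaying harmonics."""
    w = np.sin(2 * np.pi * f * t)
    w += 0.5 * np.sin(2 * np.pi * 2 * f * t)
    w += 0.25 * np.sin(2 * np.pi * 3 * f * t)
    return w / np.std(w)


def make_eeg(cfg: SynthEEGConfig = SynthEEGConfig()) -> EEGRecord:
    """Surrogate multichannel EEG record with annotated seizure bursts."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    data = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        data[c] = 10.0 * _pink_noise(n, cfg.background_exponent, rng)
    if cfg.burst_gain > 0:
        for (a, b) in cfg.seizure_intervals:
            i0, i1 = int(round(a * cfg.fs)), int(round(b * cfg.fs))
            burst = _spike_wave(t[i0:i1], cfg.burst_freq_hz)
            # smooth onset/offset so the burst does not ring the filter
            ramp = min(int(0.5 * cfg.fs), (i1 - i0) // 4)
            env = np.ones(i1 - i0)
            if ramp > 0:
                env[:ramp] = np.linspace(0, 1, ramp)
                env[-ramp:] = np.linspace(1, 0, ramp)
            for c in cfg.affected_channels:
                data[c, i0:i1] += 10.0 * cfg.burst_gain * burst * env
    names = [f"CH{c:02d}" for c in range(cfg.n_channels)]
    return EEGRecord(data=data, fs=cfg.fs, channel_names=names,
                     seizure_intervals=list(cfg.seizure_intervals))


def make_imbalanced_segments(ratio: float = 1 / 30, duration_s: float = 600.0,
                             window_s: float = 4.0, step_s: float = 2.0,
                             n_channels: int = 4, burst_gain: float = 2.0,
                             seed: int = 0,
                             ) -> tuple[SegmentSet, float]:
    """Windowed surrogate EEG at a requested ictal:nonictal segment ratio.

    Sizes one seizure interval so that, after 4 s / 2 s sliding-window
    segmentation, the fraction of ictal windows is about
    ``ratio / (1 + ratio)`` (default 1:30).  Returns the SegmentSet and
    the achieved minority fraction.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    minority_frac = ratio / (1 + ratio)
    seiz_dur = minority_frac * duration_s
    start = duration_s / 2 - seiz_dur / 2
    start = step_s * round(start / step_s)      # align to the window grid
    cfg = SynthEEGConfig(
        duration_s=duration_s, n_channels=n_channels,
        seizure_intervals=((start, start + seiz_dur),),
        affected_channels=tuple(range(n_channels)),
        burst_gain=burst_gain, seed=seed)
    record = make_eeg(cfg)
    segs = segment(record, window_s=window_s, step_s=step_s)
    achieved = float(segs.labels.mean())
    return segs, achieved
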