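"""Sliding-window segmentation and the four classic time-domain EMG features.

The feature set is the standard one for myoelectric pattern recognition:
zero crossings (ZC), slope sign changes (SSC), mean absolute value (MAV) and
waveform length (WL) per channel per window.  Windows are 250 ms long and
advance in 125-ms steps (50% overlap); the trailing windows truncate at the
signal end, so a signal of N samples yields ceil(N / step) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import TaskSignal

__all__ = [
    "WindowSpec",
    "WindowFeatureSet",
    "FEATURE_NAMES",
    "sliding_windows",
    "window_bounds",
    "zero_crossings",
    "slope_sign_changes",
    "mean_absolute_value",
    "waveform_length",
    "extract_features",
    "combine_feature_sets",
]

FEATURE_NAMES = ("ZC", "SSC", "MAV", "WL")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry plus the amplitude deadband epsilon.

    ``epsilon`` guards ZC/SSC against counting noise-floor wiggles; it is in
    the same (arbitrary) units as the samples.  ``None`` defaults to 1% of the
    per-channel RMS of the signal being featured.
    """

    window_ms: float = 250.0
    step_ms: float = 125.0
    epsilon: float | Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.step_ms <= 0 or self.window_ms <= 0:
            raise ValueError("window and step must be positive")
        if self.step_ms > self.window_ms:
            raise ValueError("step must not exceed the window length")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))


@dataclass
class WindowFeatureSet:
    """Feature matrix (windows x 4*n_channels) with labels and provenance.

    Columns are ordered [ZC, SSC, MAV, WL] per channel, channels in signal
    order.  ``groups`` records (task, loading, repetition) per window so that
    splits can be made at whole-trial granularity.
    """

    X: np.ndarray
    y: np.ndarray
    groups: list[tuple[str, str, int]]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.shape[0] != len(self.y) or len(self.groups) != len(self.y):
            raise ValueError("X, y and groups must agree in length")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [f"{ch}_{f}" for ch in self.channels for f in FEATURE_NAMES]

    def subset(self, idx: np.ndarray) -> "WindowFeatureSet":
        idx = np.asarray(idx)
        return WindowFeatureSet(self.X[idx], self.y[idx],
                                [self.groups[i] for i in idx], self.channels)


# ---------------------------------------------------------------------------
# single-window features
# ---------------------------------------------------------------------------

def zero_crossings(x: np.ndarray, epsilon: float = 0.0) -> int:
    """Sign changes between adjacent samples whose jump reaches epsilon."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0
    return int(np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(np.diff(x)) >= epsilon)))


def slope_sign_changes(x: np.ndarray, epsilon: float = 0.0) -> int:
    """Interior local extrema whose step to a neighbour reaches epsilon."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return 0
    a, b, c = x[:-2], x[1:-1], x[2:]
    extremum = ((b > a) & (b > c)) | ((b < a) & (b < c))
    step = (np.abs(b - c) >= epsilon) | (np.abs(b - a) >= epsilon)
    return int(np.count_nonzero(extremum & step))


def mean_absolute_value(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def waveform_length(x: np.ndarray) -> float:
    """Total path length: sum of absolute first differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.sum(np.abs(np.diff(x))))


# ---------------------------------------------------------------------------
# windowing and extraction
# ---------------------------------------------------------------------------

def window_bounds(n_samples: int, fs: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds: starts at every step, trailing truncation."""
    if n_samples < 1:
        raise ValueError("empty signal")
    w = spec.window_samples(fs)
    s = spec.step_samples(fs)
    return [(start, min(start + w, n_samples)) for start in range(0, n_samples, s)]


def sliding_windows(sig: TaskSignal, spec: WindowSpec) -> list[np.ndarray]:
    """Channel-blocks (channels x window) for every window position."""
    return [sig.samples[:, a:b] for a, b in window_bounds(sig.n_samples, sig.fs, spec)]


def _resolve_epsilon(sig: TaskSignal, spec: WindowSpec) -> np.ndarray:
    if spec.epsilon is None:
        rms = np.sqrt(np.mean(sig.samples**2, axis=1))
        return 0.01 * rms
    eps = np.asarray(spec.epsilon, dtype=float)
    if eps.ndim == 0:
        return np.full(len(sig.channels), float(eps))
    if eps.shape != (len(sig.channels),):
        raise ValueError(f"epsilon must be scalar or per-channel ({len(sig.channels)},)")
    return eps


def extract_features(sig: TaskSignal, spec: WindowSpec | None = None) -> WindowFeatureSet:
    """Hudgins-style feature matrix of one concatenated task signal.

    Every window inherits the signal's task label; its repetition is that of
    the window's first sample, so windows straddling a concatenation boundary
    stay with the trial they start in.
    """
    spec = spec or WindowSpec()
    eps = _resolve_epsilon(sig, spec)
    bounds = window_bounds(sig.n_samples, sig.fs, spec)
    n_ch = len(sig.channels)
    X = np.empty((len(bounds), 4 * n_ch))
    groups: list[tuple[str, str, int]] = []
    for w, (a, b) in enumerate(bounds):
        block = sig.samples[:, a:b]
        for c in range(n_ch):
            x = block[c]
            X[w, 4 * c:4 * c + 4] = (
                zero_crossings(x, eps[c]),
                slope_sign_changes(x, eps[c]),
                mean_absolute_value(x),
                waveform_length(x),
            )
        rep = sig.repetition_of_sample(a) if sig.segment_lengths else 0
        groups.append((sig.task, sig.loading, rep))
    y = np.array([sig.task] * len(bounds), dtype=object)
    return WindowFeatureSet(X=X, y=y, groups=groups, channels=sig.channels)


def combine_feature_sets(parts: Sequence[WindowFeatureSet]) -> WindowFeatureSet:
    """Stack feature sets (e.g. the three tasks of one loading) row-wise."""
    if not parts:
        raise ValueError("nothing to combine")
    channels = parts[0].channels
    if any(p.channels != channels for p in parts):
        raise ValueError("feature sets disagree on channels")
    return WindowFeatureSet(
        X=np.vstack([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        groups=[g for p in parts for g in p.groups],
        channels=channels,
    )
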