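"""Subject- and muscle-specific band-stop filters built from coherence bands.

Significant abductor-distal coherence bands are identified per hand task,
merged across the three tasks, and turned into 4th-order Butterworth
band-stop filters (one cascade stage per band, applied zero-phase).  Subjects
whose merged bands are empty or peak-only are flagged ineligible: no filter is
applied and they are excluded from before/after comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .coherence import (CoherenceConfig, FrequencyBand, global_coherence,
                        monte_carlo_threshold, significant_bands, wavelet_coherence)
from .io import TASKS, Recording, TaskSignal, segment_concatenate

__all__ = [
    "FilterBank",
    "SynergyFilterConfig",
    "merge_bands",
    "exclusion_rule",
    "design_bandstop",
    "apply_filterbank",
    "build_subject_filters",
]


@dataclass(frozen=True)
class SynergyFilterConfig:
    """Which muscle pairs drive the filter design and how bands are vetted.

    Coherence is computed between each distal channel and the proximal
    (abductor) channel; only the distal channels are ever filtered, since the
    synergy-induced component is defined at the wrist/fingers.
    """

    coherence: CoherenceConfig = field(default_factory=CoherenceConfig)
    proximal_channel: str = "mDEL"
    distal_channels: tuple[str, ...] = ("FCR", "FDS", "ECR", "EDC")
    min_width_hz: float = 0.0
    min_stop_width_hz: float = 2.0
    order: int = 4
    #: seconds trimmed from each end of every repetition before coherence.
    #: Coherence during the holding phase is steady; the co-activation
    #: transients at task onset/offset are synchronized amplitude bursts that
    #: bias low-frequency coherence upward in every muscle pair.
    steady_margin_s: float = 0.5


@dataclass
class FilterBank:
    """Per-channel stop bands for one subject at one loading level."""

    subject_id: str
    loading: str
    fs: float
    stop_bands: dict[str, list[FrequencyBand]]
    order: int = 4
    eligible: bool = True

    @property
    def applied_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch, bands in self.stop_bands.items() if bands)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "subject_id": self.subject_id,
            "loading": self.loading,
            "fs": self.fs,
            "order": self.order,
            "eligible": self.eligible,
            "stop_bands": {ch: [[b.lo_hz, b.hi_hz] for b in bands]
                           for ch, bands in self.stop_bands.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterBank":
        doc = json.loads(Path(path).read_text())
        return cls(
            subject_id=doc["subject_id"], loading=doc["loading"], fs=doc["fs"],
            order=doc["order"], eligible=doc["eligible"],
            stop_bands={ch: [FrequencyBand(lo, hi) for lo, hi in bands]
                        for ch, bands in doc["stop_bands"].items()},
        )


def merge_bands(per_task_bands: Mapping[str, Sequence[FrequencyBand]]) -> list[FrequencyBand]:
    """Interval union of significant bands across tasks, coalescing overlaps.

    Abutting intervals (shared endpoint) merge; output is sorted by lower edge.
    """
    intervals = sorted(
        ((b.lo_hz, b.hi_hz) for bands in per_task_bands.values() for b in bands)
    )
    merged: list[list[float]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [FrequencyBand(lo, hi) for lo, hi in merged]


def exclusion_rule(merged: Sequence[FrequencyBand], min_width_hz: float = 0.0) -> bool:
    """True when the merged bands justify building a filter.

    False — meaning the subject passes through unfiltered and is excluded from
    before/after comparison — when the list is empty or every band is
    peak-only (zero width) or narrower than ``min_width_hz``.
    """
    return any((not b.is_peak_only) and b.width_hz >= min_width_hz for b in merged)


def design_bandstop(bands: Sequence[FrequencyBand], fs: float, order: int = 4,
                    min_stop_width_hz: float = 2.0) -> list[np.ndarray]:
    """One 4th-order Butterworth band-stop (second-order sections) per band.

    Bands narrower than ``min_stop_width_hz`` are padded symmetrically before
    design — very narrow IIR notches are numerically fragile.  An empty band
    list yields an empty cascade (identity).  Bands touching 0 or Nyquist are
    rejected.
    """
    cascade: list[np.ndarray] = []
    for b in bands:
        lo, hi = b.lo_hz, b.hi_hz
        if hi - lo < min_stop_width_hz:
            pad = (min_stop_width_hz - (hi - lo)) / 2
            lo, hi = lo - pad, hi + pad
        if lo <= 0 or hi >= fs / 2:
            raise ValueError(f"stop band [{lo:.2f}, {hi:.2f}] Hz touches 0 or Nyquist ({fs / 2} Hz)")
        sos = signal.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
        _, poles, _ = signal.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(f"designed stop band [{lo:.2f}, {hi:.2f}] Hz is unstable")
        cascade.append(sos)
    return cascade


def apply_filterbank(sig: TaskSignal, bank: FilterBank,
                     min_stop_width_hz: float = 2.0) -> TaskSignal:
    """Zero-phase application of a filter bank; untouched channels pass through.

    Length is preserved; zero-phase (forward-backward) application squares
    each stage's magnitude response.  When the signal records its repetition
    segments, each is filtered independently: the splices between trials are
    artificial discontinuities that would otherwise ring through a narrow
    band-stop.
    """
    unknown = set(bank.stop_bands) - set(sig.channels)
    if unknown:
        raise ValueError(f"filter bank channels {sorted(unknown)} not present in signal "
                         f"(has {sig.channels})")
    edges = np.cumsum([0] + list(sig.segment_lengths or [sig.n_samples]))
    out = sig.samples.copy()
    for ch, bands in bank.stop_bands.items():
        if not bands:
            continue
        i = sig.channels.index(ch)
        cascade = design_bandstop(bands, sig.fs, bank.order, min_stop_width_hz)
        for a, b in zip(edges[:-1], edges[1:]):
            x = out[i, a:b]
            for sos in cascade:
                x = signal.sosfiltfilt(sos, x)
            out[i, a:b] = x
    return TaskSignal(samples=out, fs=sig.fs, channels=sig.channels,
                      task=sig.task, loading=sig.loading,
                      source_trials=list(sig.source_trials),
                      segment_lengths=list(sig.segment_lengths))


def steady_phase(sig: TaskSignal, margin_s: float) -> TaskSignal:
    """Drop ``margin_s`` seconds from both ends of every concatenated repetition."""
    m = int(round(margin_s * sig.fs))
    if m == 0 or not sig.segment_lengths:
        return sig
    parts, reps, lengths = [], [], []
    start = 0
    for rep, length in zip(sig.source_trials, sig.segment_lengths):
        a, b = start + m, start + length - m
        if b - a > 0:
            parts.append(sig.samples[:, a:b])
            reps.append(rep)
            lengths.append(b - a)
        start += length
    if not parts:
        raise ValueError(f"steady margin {margin_s} s leaves no data in any repetition")
    return TaskSignal(samples=np.concatenate(parts, axis=1), fs=sig.fs,
                      channels=sig.channels, task=sig.task, loading=sig.loading,
                      source_trials=reps, segment_lengths=lengths)


def build_subject_filters(rec: Recording, cfg: SynergyFilterConfig | None = None,
                          loadings: Sequence[str] | None = None,
                          seed: int = 0) -> dict[str, FilterBank]:
    """Design one filter bank per loading level from a subject's recording.

    For every distal channel, coherence with the proximal channel is computed
    on the concatenated task signal of each of the three hand tasks, the
    Monte-Carlo threshold is attached, significant bands are extracted and
    merged across tasks.  The exclusion rule is applied at the subject level
    (pooled over channels): an ineligible subject gets a bank with
    ``eligible=False`` and empty stop bands.
    """
    cfg = cfg or SynergyFilterConfig()
    loadings = tuple(loadings) if loadings is not None else rec.loadings
    banks: dict[str, FilterBank] = {}
    root = np.random.SeedSequence((int(seed), 90210))
    for li, loading in enumerate(loadings):
        tasks = tuple(t for t in TASKS
                      if any(a.task == t and a.loading == loading for a in rec.annotations))
        if len(tasks) < len(TASKS):
            raise ValueError(
                f"loading {loading!r} is missing task(s) {set(TASKS) - set(tasks)}"
            )
        signals = {t: steady_phase(segment_concatenate(rec, t, loading), cfg.steady_margin_s)
                   for t in tasks}
        stop_bands: dict[str, list[FrequencyBand]] = {}
        for ci, ch in enumerate(cfg.distal_channels):
            per_task: dict[str, list[FrequencyBand]] = {}
            for ti, task in enumerate(tasks):
                sig = signals[task]
                x = sig.channel(cfg.proximal_channel)
                y = sig.channel(ch)
                cmap = wavelet_coherence(x, y, sig.fs, cfg.coherence)
                sub = np.random.SeedSequence((int(seed), 90210, li, ci, ti))
                cmap.threshold = monte_carlo_threshold(x, y, sig.fs, cfg.coherence, seed=sub)
                gc = global_coherence(cmap, cfg.coherence)
                per_task[task] = significant_bands(gc)
            stop_bands[ch] = merge_bands(per_task)
        all_bands = [b for bands in stop_bands.values() for b in bands]
        eligible = exclusion_rule(all_bands, cfg.min_width_hz)
        banks[loading] = FilterBank(
            subject_id=rec.subject_id, loading=loading, fs=rec.fs,
            stop_bands=stop_bands if eligible else {ch: [] for ch in cfg.distal_channels},
            order=cfg.order, eligible=eligible,
        )
    return banks
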