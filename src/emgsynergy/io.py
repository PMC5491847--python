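"""Annotated multichannel surface-EMG recordings: containers, file I/O, preprocessing.

A :class:`Recording` holds a channels x time sample matrix at a fixed sampling
rate together with trial annotations (hand task, shoulder-abduction loading,
repetition number).  Samples travel as a plain CSV file with one header row of
channel labels; the sampling rate and annotations travel in a YAML sidecar.
Units are arbitrary: nothing downstream assumes a microvolt calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

#: Closed vocabulary of hand tasks, in canonical (tie-break) order.
TASKS = ("relax", "open", "grasp")

#: Closed vocabulary of shoulder-abduction loading levels: arm supported on a
#: table, or lifted against 25% / 50% of maximal abduction torque.
LOADINGS = ("table", "sabd25", "sabd50")

#: Default montage: intermediate deltoid plus wrist/finger flexors and extensors.
DEFAULT_CHANNELS = ("mDEL", "FCR", "FDS", "ECR", "EDC")


@dataclass(frozen=True)
class TrialAnnotation:
    """Half-open sample interval ``[start_sample, end_sample)`` of one trial."""

    start_sample: int
    end_sample: int
    task: str
    loading: str
    repetition: int

    def __post_init__(self) -> None:
        if not self.start_sample < self.end_sample:
            raise ValueError(
                f"annotation ({self.task}, {self.loading}, rep {self.repetition}): "
                f"start_sample {self.start_sample} must be < end_sample {self.end_sample}"
            )
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.loading not in LOADINGS:
            raise ValueError(f"unknown loading {self.loading!r}; expected one of {LOADINGS}")
        if self.repetition < 1:
            raise ValueError(f"repetition must be >= 1, got {self.repetition}")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class Recording:
    """Multichannel EMG samples (channels x time) plus trial annotations."""

    samples: np.ndarray
    fs: float
    channels: tuple[str, ...]
    annotations: list[TrialAnnotation] = field(default_factory=list)
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channels = tuple(self.channels)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but {len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel labels must be unique, got {self.channels}")
        n = self.n_samples
        for a in self.annotations:
            if a.start_sample < 0 or a.end_sample > n:
                raise ValueError(
                    f"annotation ({a.task}, {a.loading}, rep {a.repetition}) interval "
                    f"[{a.start_sample}, {a.end_sample}) lies outside [0, {n})"
                )
        for a, b in zip(sorted(self.annotations, key=lambda t: t.start_sample),
                        sorted(self.annotations, key=lambda t: t.start_sample)[1:]):
            if b.start_sample < a.end_sample:
                raise ValueError(
                    f"annotations overlap: ({a.task}, rep {a.repetition}) and "
                    f"({b.task}, rep {b.repetition})"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording (has {self.channels})") from None

    @property
    def loadings(self) -> tuple[str, ...]:
        present = {a.loading for a in self.annotations}
        return tuple(l for l in LOADINGS if l in present)


@dataclass
class TaskSignal:
    """Concatenated task-phase EMG for one (task, loading) cell.

    ``source_trials`` lists the contributing repetition ids in concatenation
    order and ``segment_lengths`` the corresponding lengths, so any sample can
    be traced back to its repetition.
    """

    samples: np.ndarray
    fs: float
    channels: tuple[str, ...]
    task: str
    loading: str
    source_trials: list[int] = field(default_factory=list)
    segment_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channels = tuple(self.channels)
        if self.segment_lengths and sum(self.segment_lengths) != self.n_samples:
            raise ValueError("segment_lengths must sum to the signal length")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channels.index(name)]

    def repetition_of_sample(self, i: int) -> int:
        """Repetition id owning sample index ``i`` of the concatenated signal."""
        edges = np.cumsum(self.segment_lengths)
        k = int(np.searchsorted(edges, i, side="right"))
        if k >= len(self.source_trials):
            raise IndexError(f"sample {i} beyond concatenated length {edges[-1] if len(edges) else 0}")
        return self.source_trials[k]


# ---------------------------------------------------------------------------
# File round-trip
# ---------------------------------------------------------------------------

def read_recording(data_path: str | Path, meta_path: str | Path) -> Recording:
    """Read a CSV sample file plus YAML metadata sidecar into a :class:`Recording`."""
    data_path, meta_path = Path(data_path), Path(meta_path)
    try:
        frame = pd.read_csv(data_path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"could not parse sample file {data_path}: {exc}") from exc
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "fs" not in meta:
        raise ValueError(f"metadata file {meta_path} must declare 'fs'")
    channels = tuple(meta.get("channels", frame.columns.tolist()))
    missing = [c for c in channels if c not in frame.columns]
    if missing:
        raise ValueError(f"sample file {data_path} is missing channel column(s) {missing}")
    sub = frame[list(channels)]
    bad = sub.columns[sub.apply(lambda c: not np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric values in column(s) {list(bad)} of {data_path}")
    if sub.isna().any().any():
        row = int(sub.isna().any(axis=1).idxmax())
        raise ValueError(f"non-numeric or missing cell near row {row} of {data_path}")
    annotations = [
        TrialAnnotation(
            start_sample=int(rec["start_sample"]),
            end_sample=int(rec["end_sample"]),
            task=str(rec["task"]),
            loading=str(rec["loading"]),
            repetition=int(rec["repetition"]),
        )
        for rec in meta.get("annotations", [])
    ]
    return Recording(
        samples=sub.to_numpy().T,
        fs=float(meta["fs"]),
        channels=channels,
        annotations=annotations,
        subject_id=str(meta.get("subject_id", "S00")),
    )


def write_recording(rec: Recording, data_path: str | Path, meta_path: str | Path) -> None:
    """Write ``rec`` as a CSV sample file plus YAML metadata sidecar."""
    frame = pd.DataFrame(rec.samples.T, columns=list(rec.channels))
    frame.to_csv(data_path, index=False, float_format="%.12g")
    meta = {
        "fs": float(rec.fs),
        "subject_id": rec.subject_id,
        "channels": list(rec.channels),
        "annotations": [
            {
                "start_sample": int(a.start_sample),
                "end_sample": int(a.end_sample),
                "task": a.task,
                "loading": a.loading,
                "repetition": int(a.repetition),
            }
            for a in rec.annotations
        ],
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Preprocessing and segmentation
# ---------------------------------------------------------------------------

def bandpass_preprocess(rec: Recording, lo_hz: float = 5.0, hi_hz: float = 450.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel.

    The 5-450 Hz default is the conventional surface-EMG conditioning band.
    Annotations are carried over unchanged (zero-phase filtering does not
    shift trial boundaries).
    """
    if hi_hz >= rec.fs / 2:
        raise ValueError(f"upper cutoff {hi_hz} Hz must be below Nyquist {rec.fs / 2} Hz")
    if lo_hz <= 0 or lo_hz >= hi_hz:
        raise ValueError(f"invalid band ({lo_hz}, {hi_hz}) Hz")
    sos = signal.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def segment_concatenate(rec: Recording, task: str, loading: str) -> TaskSignal:
    """Concatenate all annotated intervals of one (task, loading) cell.

    Output order follows the repetition number, not the position in the file,
    so shuffled trial orders still concatenate deterministically.
    """
    matches = sorted(
        (a for a in rec.annotations if a.task == task and a.loading == loading),
        key=lambda a: a.repetition,
    )
    if not matches:
        raise ValueError(f"no annotations for task={task!r}, loading={loading!r}")
    parts = [rec.samples[:, a.start_sample:a.end_sample] for a in matches]
    return TaskSignal(
        samples=np.concatenate(parts, axis=1),
        fs=rec.fs,
        channels=rec.channels,
        task=task,
        loading=loading,
        source_trials=[a.repetition for a in matches],
        segment_lengths=[a.n_samples for a in matches],
    )
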