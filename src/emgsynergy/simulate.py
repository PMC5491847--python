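"""Synthetic surface-EMG sessions with a flexion-synergy coupling structure.

The generative model is deliberately phenomenological, not biophysical.  Each
channel is an amplitude-modulated broadband carrier (Gaussian noise band-limited
to 5-400 Hz, shaped by a trapezoidal task envelope).  On top of the carriers
ride two shared band-limited drives:

* an alpha-band (8-13 Hz) "synergy" process, added to the shoulder abductor
  and the wrist/finger flexors with a gain that grows with shoulder-abduction
  loading and with subject severity — present in *every* task, including
  relax, which is what contaminates the relax/grasp distinction.  A small
  broadband involuntary co-contraction of the same flexors rides along with
  it (flexion synergy activates the muscle, not just the coherent drive);
* a beta-band (15-30 Hz) "voluntary" process shared among the distal muscles
  that the task activates (flexors for grasp, extensors for open), standing in
  for fast corticospinal common drive.  The abductor does not share it, so
  abductor-distal coherence concentrates in the alpha band only.

Voluntary effort and synergy expression carry lognormal trial-to-trial
jitter: paretic activation is weak (distal voluntary gain well below the
proximal gain) and variable, which is what makes the unfiltered
classification problem genuinely hard at high loading.

All randomness is keyed: each trial draws from a substream derived from
(master seed, subject, task, loading, repetition), so any single trial can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .io import DEFAULT_CHANNELS, LOADINGS, TASKS, Recording, TaskSignal, TrialAnnotation

__all__ = ["SubjectProfile", "ProtocolSpec", "generate_trial", "generate_session", "make_cohort"]

#: distal muscles activated by each task
TASK_AGONISTS: dict[str, tuple[str, ...]] = {
    "grasp": ("FCR", "FDS"),
    "open": ("ECR", "EDC"),
    "relax": (),
}

#: shoulder-abduction effort as a fraction of maximum, per loading level
LOADING_EFFORT: dict[str, float] = {"table": 0.0, "sabd25": 0.5, "sabd50": 1.0}


@dataclass(frozen=True)
class SubjectProfile:
    """Parameters of one simulated subject.

    ``severity`` in [0, 1] scales the synergy coupling; 0 reproduces a
    neurologically intact control with no shared alpha drive.  Amplitudes are
    in carrier-noise units: the resting carrier has sd ``carrier_noise_sd``
    and a fully active muscle's envelope adds ``voluntary_gain``.
    """

    subject_id: str = "S00"
    synergy_band: tuple[float, float] = (8.0, 13.0)
    voluntary_band: tuple[float, float] = (15.0, 30.0)
    synergy_gain: Mapping[str, float] = field(
        default_factory=lambda: {"table": 0.0, "sabd25": 1.0, "sabd50": 2.0}
    )
    synergy_targets: tuple[str, ...] = ("mDEL", "FCR", "FDS")
    voluntary_gain: Mapping[str, float] = field(
        default_factory=lambda: {"mDEL": 1.0, "FCR": 0.4, "FDS": 0.4, "ECR": 0.4, "EDC": 0.4}
    )
    beta_gain: float = 0.3
    #: broadband involuntary co-contraction of the distal synergy targets per
    #: unit severity x loading: flexion synergy activates the muscle (wideband
    #: interference EMG), not just the coherent alpha drive riding on it
    involuntary_gain: float = 0.1
    #: lognormal sigma of per-trial voluntary effort / synergy expression;
    #: paretic activation fluctuates markedly from repetition to repetition
    effort_jitter_sd: float = 0.3
    synergy_jitter_sd: float = 0.4
    carrier_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in DEFAULT_CHANNELS}
    )
    severity: float = 1.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        lo, hi = self.synergy_band
        if not 0 < lo <= hi:
            raise ValueError(f"invalid synergy band {self.synergy_band}")
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must lie in [0, 1]")
        gains = [self.synergy_gain.get(l, 0.0) for l in LOADINGS]
        if any(g < 0 for g in gains) or any(b > a for a, b in zip(gains[1:], gains[:-1])):
            raise ValueError("synergy_gain must be non-negative and non-decreasing in loading")
        if any(v < 0 for v in self.voluntary_gain.values()):
            raise ValueError("voluntary_gain must be non-negative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Session layout: which (task, loading) cells, how many repetitions."""

    tasks: tuple[str, ...] = TASKS
    loadings: tuple[str, ...] = ("sabd25", "sabd50")
    repetitions: int = 12
    trial_duration_s: float = 5.0
    gap_s: float = 1.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.trial_duration_s <= 0 or self.fs <= 0:
            raise ValueError("trial duration and fs must be positive")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        for l in self.loadings:
            if l not in LOADINGS:
                raise ValueError(f"unknown loading {l!r}")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (4th-order Butterworth)."""
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _trapezoid(n: int, fs: float, rise_s: float = 0.25) -> np.ndarray:
    """Trapezoidal activation envelope: linear rise/fall of ``rise_s`` seconds."""
    r = min(int(round(rise_s * fs)), n // 2)
    env = np.ones(n)
    if r > 0:
        ramp = np.linspace(0.0, 1.0, r, endpoint=False)
        env[:r] = ramp
        env[n - r:] = ramp[::-1]
    return env


def _trial_rng(seed: int, subject_idx: int, task: str, loading: str, rep: int) -> np.random.Generator:
    key = (int(seed), int(subject_idx), TASKS.index(task), LOADINGS.index(loading), int(rep))
    return np.random.default_rng(np.random.SeedSequence(key))


def _trial_samples(profile: SubjectProfile, task: str, loading: str,
                   n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    channels = profile.channels
    env = _trapezoid(n, fs)
    effort = LOADING_EFFORT[loading]
    alpha = _bandlimited_noise(rng, n, fs, profile.synergy_band)
    beta = _bandlimited_noise(rng, n, fs, profile.voluntary_band)
    effort_jit = float(np.exp(profile.effort_jitter_sd * rng.standard_normal()))
    synergy_jit = float(np.exp(profile.synergy_jitter_sd * rng.standard_normal()))
    alpha_gain = (profile.severity * synergy_jit
                  * float(profile.synergy_gain.get(loading, 0.0)))
    agonists = TASK_AGONISTS[task]
    out = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        carrier = _bandlimited_noise(rng, n, fs, (5.0, 400.0))
        base = float(profile.carrier_noise_sd.get(ch, 0.25))
        vol = float(profile.voluntary_gain.get(ch, 0.0))
        if ch == "mDEL":
            # the abductor works whenever the arm is lifted, whatever the hand does
            amplitude = base + vol * effort * effort_jit * env
        elif ch in agonists:
            amplitude = base + vol * effort_jit * env
        else:
            amplitude = np.full(n, base)
        if ch in profile.synergy_targets and ch != "mDEL":
            # involuntary flexor co-contraction rides along with the synergy
            amplitude = amplitude + alpha_gain * profile.involuntary_gain
        x = amplitude * carrier
        if ch in profile.synergy_targets:
            x = x + alpha_gain * alpha
        if ch in agonists:
            x = x + profile.beta_gain * env * beta
        out[i] = x
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_trial(profile: SubjectProfile, task: str, loading: str,
                   duration_s: float = 5.0, fs: float = 1000.0,
                   seed: int = 0, subject_idx: int = 0, repetition: int = 1) -> TaskSignal:
    """One labelled trial; bit-identical for identical arguments."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if loading not in LOADINGS:
        raise ValueError(f"unknown loading {loading!r}")
    n = int(round(duration_s * fs))
    rng = _trial_rng(seed, subject_idx, task, loading, repetition)
    samples = _trial_samples(profile, task, loading, n, fs, rng)
    return TaskSignal(samples=samples, fs=fs, channels=profile.channels,
                      task=task, loading=loading,
                      source_trials=[repetition], segment_lengths=[n])


def generate_session(profile: SubjectProfile, protocol: ProtocolSpec,
                     subject_idx: int = 0) -> Recording:
    """Full annotated session: every (task, loading, repetition), shuffled order.

    Trials are separated by short idle gaps of resting-level noise, so the
    annotated intervals carry the task EMG and the gaps emulate the idling
    activity that segmentation discards.
    """
    fs = protocol.fs
    n_trial = int(round(protocol.trial_duration_s * fs))
    n_gap = int(round(protocol.gap_s * fs))
    cells = [(t, l, r) for l in protocol.loadings for t in protocol.tasks
             for r in range(1, protocol.repetitions + 1)]
    order_rng = np.random.default_rng(np.random.SeedSequence((protocol.seed, subject_idx, 777)))
    order_rng.shuffle(cells)
    gap_rng = np.random.default_rng(np.random.SeedSequence((protocol.seed, subject_idx, 778)))
    pieces: list[np.ndarray] = []
    annotations: list[TrialAnnotation] = []
    cursor = 0
    base_sd = np.array([float(profile.carrier_noise_sd.get(c, 0.25)) for c in profile.channels])
    for task, loading, rep in cells:
        if n_gap > 0:
            pieces.append(base_sd[:, None] * gap_rng.standard_normal((len(profile.channels), n_gap)))
            cursor += n_gap
        rng = _trial_rng(protocol.seed, subject_idx, task, loading, rep)
        pieces.append(_trial_samples(profile, task, loading, n_trial, fs, rng))
        annotations.append(TrialAnnotation(cursor, cursor + n_trial, task, loading, rep))
        cursor += n_trial
    return Recording(samples=np.concatenate(pieces, axis=1), fs=fs,
                     channels=profile.channels, annotations=annotations,
                     subject_id=profile.subject_id)


def make_cohort(n_subjects: int, severity_range: tuple[float, float] = (0.3, 1.0),
                seed: int = 0) -> list[SubjectProfile]:
    """Cohort of subject profiles with jittered synergy bands and spread severities.

    Band centers and widths are perturbed per subject so no two subjects share
    an identical significant band, mirroring the between-subject variability
    seen in intermuscular coherence after stroke.
    """
    lo, hi = severity_range
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not (0 <= lo <= hi <= 1):
        raise ValueError(f"invalid severity range {severity_range}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 424242)))
    profiles = []
    for i in range(n_subjects):
        severity = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        center = float(rng.uniform(9.0, 12.0))
        width = float(rng.uniform(4.0, 6.0))
        profiles.append(SubjectProfile(
            subject_id=f"S{i:02d}",
            severity=severity,
            synergy_band=(center - width / 2, center + width / 2),
        ))
    return profiles
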