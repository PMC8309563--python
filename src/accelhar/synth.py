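"""Synthetic waist-worn triaxial accelerometer datasets.

Emulates the statistical structure of a scripted activity-recognition
protocol: several subjects each perform a sequence of ten activities
(stair ascent A1, stair descent A2, walk A3, run A4, sit A5, four
directed falls A6-A9, lying A10) over repeated trials, recorded by a
single waist accelerometer at 64 Hz.  The generator reproduces the
features downstream stages depend on, not biomechanics:

* dynamic activities are a gravity baseline plus a band-limited periodic
  signal (fundamental + one harmonic per axis) with white noise; stair
  classes differ from walking by amplitude ratios and a slow vertical
  drift term, running by a higher frequency and amplitude;
* static activities are gravity-oriented constants plus noise;
* falls are brief high-amplitude half-sine transients whose sign pattern
  on the (x, y) axes encodes the direction, followed by a
  direction-dependent lying orientation;
* short ``transition`` stretches (1-3 s) separate activities and must be
  removed by preprocessing;
* inter-subject variability enters through per-subject gain, orientation
  and frequency perturbations, intra-subject variability through
  trial-level phase, duration jitter and noise realisations.

Axis convention: x mediolateral, y anteroposterior, z vertical, so the
upright gravity direction is (0, 0, 1) and units are g.

All randomness flows from a single root seed through
``numpy.random.SeedSequence((root, subject_id))`` for subject profiles
and ``(profile.seed, subject_id, trial_no)`` for trials, so any fold or
trial can be regenerated independently of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .activities import ACTIVITY_CLASSES, TRANSITION_LABEL
from .dataio import Recording

_UPRIGHT = np.array([0.0, 0.0, 1.0])


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class ActivityModel:
    """Signal model for one activity class.

    ``base_freq`` is the dominant oscillation frequency in Hz (0 for
    static classes and falls), ``amplitude`` the per-axis oscillation
    amplitude in g, ``gravity_dir`` the unit orientation of the static
    gravity component, ``duration`` the nominal duration in seconds and
    ``noise_sd`` the additive white-noise standard deviation in g.
    ``drift`` adds a slow (0.2 Hz) vertical oscillation (stair classes);
    ``fall_dir`` is the (x, y) sign pattern of the fall transient and
    ``lying_dir`` the post-impact orientation, both None for non-falls.
    """

    label: str
    base_freq: float
    amplitude: tuple[float, float, float]
    gravity_dir: tuple[float, float, float]
    duration: float
    noise_sd: float
    drift: float = 0.0
    harmonic_ratio: float = 0.3
    fall_peak: float = 0.0
    fall_dir: tuple[float, float] | None = None
    lying_dir: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.base_freq < 0:
            raise ValueError("base_freq must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if abs(np.linalg.norm(self.gravity_dir) - 1.0) > 1e-6:
            raise ValueError("gravity_dir must have unit length")
        if self.fall_dir is not None and self.duration > 2.0:
            raise ValueError("fall classes must last at most 2 s")

    @property
    def is_fall(self) -> bool:
        return self.fall_dir is not None


def default_activity_models() -> dict[str, ActivityModel]:
    """The ten default activity models (durations chosen so walking
    dominates the class balance, sitting is intermediate and falls are
    rare, as in real scripted protocols)."""
    m = {
        "A1": ActivityModel("A1", 1.5, (0.30, 0.22, 0.34), (0, 0, 1), 20.0, 0.05, drift=0.10),
        "A2": ActivityModel("A2", 1.8, (0.38, 0.26, 0.30), (0, 0, 1), 18.0, 0.05, drift=-0.10),
        "A3": ActivityModel("A3", 2.1, (0.18, 0.12, 0.45), (0, 0, 1), 35.0, 0.05),
        "A4": ActivityModel("A4", 2.9, (0.40, 0.30, 0.90), (0, 0, 1), 25.0, 0.07),
        "A5": ActivityModel(
            "A5", 0.0, (0.0, 0.0, 0.0), tuple(_unit((0.25, 0.35, 0.90))), 22.0, 0.02
        ),
        "A10": ActivityModel(
            "A10", 0.0, (0.0, 0.0, 0.0), tuple(_unit((0.60, -0.78, 0.18))), 15.0, 0.02
        ),
    }
    falls = {
        "A6": ((1.0, 0.0), (1.0, 0.0, 0.0)),    # fall-right
        "A7": ((-1.0, 0.0), (-1.0, 0.0, 0.0)),  # fall-left
        "A8": ((0.0, 1.0), (0.0, 1.0, 0.0)),    # fall-front
        "A9": ((0.0, -1.0), (0.0, -1.0, 0.0)),  # fall-back
    }
    for label, (direction, lying) in falls.items():
        m[label] = ActivityModel(
            label,
            0.0,
            (0.0, 0.0, 0.0),
            (0, 0, 1),
            1.5,
            0.08,
            fall_peak=3.0,
            fall_dir=direction,
            lying_dir=lying,
        )
    return m


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject variability: axis gains, frequency jitter and a small
    fixed orientation offset of the sensor, all drawn once per subject."""

    subject_id: int
    gain: tuple[float, float, float]
    freq_jitter: float
    orientation: np.ndarray  # 3x3 rotation matrix
    seed: int

    def __post_init__(self):
        if self.subject_id < 1:
            raise ValueError("subject_id must be >= 1")
        if any(g <= 0 for g in self.gain):
            raise ValueError("gain components must be positive")


def draw_profile(
    subject_id: int,
    seed: int,
    gain_sd: float = 0.03,
    freq_sd: float = 0.03,
    tilt_sd_deg: float = 3.0,
) -> SubjectProfile:
    """Draw a subject profile deterministically from (seed, subject_id)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, subject_id)))
    gain = tuple(np.clip(1.0 + gain_sd * rng.standard_normal(3), 0.5, 2.0))
    freq_jitter = float(np.clip(1.0 + freq_sd * rng.standard_normal(), 0.5, 2.0))
    axis = _unit(rng.standard_normal(3))
    angle = math.radians(tilt_sd_deg) * rng.standard_normal()
    orientation = Rotation.from_rotvec(angle * axis).as_matrix()
    return SubjectProfile(subject_id, gain, freq_jitter, orientation, seed)


@dataclass
class DatasetConfig:
    """Generator configuration: activity models (imbalance lives in
    their durations), sampling rate and variability knobs."""

    models: dict[str, ActivityModel] = field(default_factory=default_activity_models)
    fs: float = 64.0
    transition_range: tuple[float, float] = (1.0, 3.0)
    gain_sd: float = 0.03
    freq_sd: float = 0.03
    tilt_sd_deg: float = 3.0
    duration_jitter: float = 0.03
    shuffle_sequence: bool = True


def _dynamic_block(model: ActivityModel, n: int, fs: float, freq_scale: float, rng) -> np.ndarray:
    """Periodic activity: gravity + fundamental + harmonic + drift + noise."""
    t = np.arange(n) / fs
    f = model.base_freq * freq_scale
    phase = rng.uniform(0, 2 * math.pi)
    phase2 = rng.uniform(0, 2 * math.pi)
    sig = np.empty((n, 3))
    for j in range(3):
        sig[:, j] = model.amplitude[j] * (
            np.sin(2 * math.pi * f * t + phase)
            + model.harmonic_ratio * np.sin(2 * math.pi * 2 * f * t + phase2)
        )
    sig += np.asarray(model.gravity_dir)
    if model.drift:
        sig[:, 2] += model.drift * np.sin(2 * math.pi * 0.2 * t + rng.uniform(0, 2 * math.pi))
    sig += model.noise_sd * rng.standard_normal((n, 3))
    return sig


def _static_block(model: ActivityModel, n: int, rng) -> np.ndarray:
    return np.asarray(model.gravity_dir) + model.noise_sd * rng.standard_normal((n, 3))


def _fall_block(model: ActivityModel, n: int, fs: float, rng) -> np.ndarray:
    """Directed fall: 1-s half-sine impact transient with the direction
    sign pattern on (x, y), gravity rotating upright -> lying, then the
    lying orientation for the remainder."""
    t = np.arange(n) / fs
    lying = np.asarray(model.lying_dir)
    sig = np.empty((n, 3))
    impact = t < 1.0
    frac = np.clip(t / 1.0, 0, 1)[:, None]
    sig[:] = (1 - frac) * _UPRIGHT + frac * lying  # gravity re-orientation
    spike = model.fall_peak * np.sin(math.pi * np.clip(t, 0, 1.0)) * impact
    sig[:, 0] += model.fall_dir[0] * spike
    sig[:, 1] += model.fall_dir[1] * spike
    # impact also shakes the vertical axis
    sig[:, 2] += 0.5 * model.fall_peak * np.sin(2 * math.pi * np.clip(t, 0, 1.0)) * impact
    sig += model.noise_sd * rng.standard_normal((n, 3))
    return sig


def _transition_block(g_from: np.ndarray, g_to: np.ndarray, n: int, rng) -> np.ndarray:
    frac = np.linspace(0, 1, n)[:, None]
    sig = (1 - frac) * g_from + frac * g_to
    sig += 0.03 * rng.standard_normal((n, 3))
    return sig


def _rest_orientation(model: ActivityModel) -> np.ndarray:
    """Orientation the body settles into at the end of an activity."""
    if model.is_fall:
        return np.asarray(model.lying_dir, dtype=float)
    return np.asarray(model.gravity_dir, dtype=float)


def generate_trial(
    profile: SubjectProfile,
    trial_no: int,
    activity_sequence: list[str],
    fs: float = 64.0,
    config: DatasetConfig | None = None,
) -> Recording:
    """Generate one labelled trial for a subject.

    The stream is a concatenation of activity blocks in the given order,
    separated by short ``transition`` stretches; per-sample labels tile
    the timeline with no gaps.  Deterministic in
    (profile, trial_no, activity_sequence, fs, config).
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    cfg = config or DatasetConfig(fs=fs)
    models = cfg.models
    unknown = [a for a in activity_sequence if a not in models]
    if unknown:
        raise ValueError(f"unknown activity label(s): {unknown}")

    rng = np.random.default_rng(
        np.random.SeedSequence((profile.seed, profile.subject_id, trial_no))
    )
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    prev_orientation = _UPRIGHT
    for i, label in enumerate(activity_sequence):
        model = models[label]
        if i > 0:
            start = np.asarray(model.gravity_dir, dtype=float)
            if model.is_fall or model.base_freq > 0:
                start = _UPRIGHT
            n_tr = int(round(rng.uniform(*cfg.transition_range) * fs))
            if n_tr > 0:
                blocks.append(_transition_block(prev_orientation, start, n_tr, rng))
                labels.append(np.full(n_tr, TRANSITION_LABEL, dtype=object))
        dur = model.duration * (1.0 + cfg.duration_jitter * rng.standard_normal())
        n = max(1, int(round(dur * fs)))
        if model.is_fall:
            block = _fall_block(model, n, fs, rng)
        elif model.base_freq > 0:
            block = _dynamic_block(model, n, fs, profile.freq_jitter, rng)
        else:
            block = _static_block(model, n, rng)
        blocks.append(block)
        labels.append(np.full(n, model.label, dtype=object))
        prev_orientation = _rest_orientation(model)

    body = np.vstack(blocks)
    # sensor frame: subject orientation offset, then per-axis gain
    sensor = body @ profile.orientation.T
    sensor *= np.asarray(profile.gain)
    n_total = len(sensor)
    timestamps = (np.arange(n_total) * 1000.0 / fs).astype(np.int64)
    return Recording(
        subject_id=profile.subject_id,
        trial_no=trial_no,
        timestamps=timestamps,
        ax=sensor[:, 0],
        ay=sensor[:, 1],
        az=sensor[:, 2],
        labels=np.concatenate(labels),
    )


def generate_trial_exact(
    profile: SubjectProfile,
    trial_no: int,
    activity_durations: list[tuple[str, float]],
    fs: float = 64.0,
    config: DatasetConfig | None = None,
) -> Recording:
    """Like :func:`generate_trial` but with exact durations (seconds) and
    no transitions or jitter; convenient for fixtures and oracles."""
    cfg = config or DatasetConfig(fs=fs)
    cfg = replace(cfg, transition_range=(0.0, 0.0), duration_jitter=0.0)
    models = dict(cfg.models)
    seq = []
    for i, (label, dur) in enumerate(activity_durations):
        if label not in models:
            raise ValueError(f"unknown activity label: {label}")
        key = f"{label}#{i}"
        models[key] = replace(models[label], label=label, duration=dur)
        seq.append(key)
    cfg = replace(cfg, models=models)
    return generate_trial(profile, trial_no, seq, fs=fs, config=cfg)


def generate_dataset(
    n_subjects: int,
    n_trials: int,
    config: DatasetConfig | None = None,
    seed: int = 0,
) -> list[Recording]:
    """Generate ``n_subjects * n_trials`` Recordings.

    Each subject gets a profile drawn from (seed, subject_id); each
    trial performs all ten activities, in an order permuted per trial
    when ``config.shuffle_sequence`` is set.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out")
    if n_trials < 1:
        raise ValueError("need at least 1 trial")
    cfg = config or DatasetConfig()
    recordings = []
    for subject in range(1, n_subjects + 1):
        profile = draw_profile(
            subject, seed, gain_sd=cfg.gain_sd, freq_sd=cfg.freq_sd,
            tilt_sd_deg=cfg.tilt_sd_deg,
        )
        for trial in range(1, n_trials + 1):
            sequence = [c for c in ACTIVITY_CLASSES if c in cfg.models]
            if cfg.shuffle_sequence:
                order_rng = np.random.default_rng(
                    np.random.SeedSequence((seed, subject, trial, 0xA11))
                )
                sequence = list(order_rng.permutation(sequence))
            recordings.append(
                generate_trial(profile, trial, sequence, fs=cfg.fs, config=cfg)
            )
    return recordings
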