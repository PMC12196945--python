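"""Synthetic smart-mattress data emulating the acquisition protocol.

The study population is 30 adults, each holding six postures (prone, supine,
left log, left fetus, right log, right fetus) long enough to yield 25
windows per posture, i.e. 30 x 6 x 25 = 4500 labeled windows from an array
of eight triaxial accelerometers (sites A-H: shoulder blades A/B, spine C,
coccyx D, hip-sacrum E/F, knees G/H) sampled at 30 Hz per channel.

Each posture is modeled as a static 8 x 3 gravity-loading template (units g).
A window is the template held for T samples, modulated by

* a per-subject loading scale and small per-sensor offsets (anthropometric
  variability),
* a low-frequency breathing sinusoid on the torso sensors (A-F, vertical
  axis),
* a per-window random micro-shift (the deliberate small positional
  adjustments of the protocol), and
* white sensor noise.

A second generator reproduces the rotating-rig evaluation of the sensors:
each sensor read at 5 degree increments over a 0-180 degree arc, where an
ideal sensor reports g*cos(theta) on the aligned axis; per-sensor gain and
offset errors and read noise are configurable.  A one-way ANOVA over the
residuals from the ideal cosine checks between-sensor consistency the same
way the rig evaluation does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

POSTURES: tuple[str, ...] = (
    "prone",
    "supine",
    "left_log",
    "left_fetus",
    "right_log",
    "right_fetus",
)
SENSOR_SITES: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")
#: index pairs swapped by the left/right mirror map (bilateral sensor pairs)
MIRROR_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (4, 5), (6, 7))
TORSO_SENSORS = slice(0, 6)  # A-F carry the breathing modulation

__all__ = [
    "POSTURES",
    "SENSOR_SITES",
    "PostureTemplate",
    "SubjectProfile",
    "GeneratorConfig",
    "PostureDataset",
    "CalibrationSweep",
    "make_templates",
    "mirror_template",
    "generate_dataset",
    "channel_means",
    "simulate_rotation_sweep",
    "anova_consistency",
]


@dataclass(frozen=True)
class PostureTemplate:
    """Static mean gravity loading (8 sensors x 3 axes, units g) of a posture."""

    posture: str
    static_pattern: np.ndarray  # (8, 3)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject loading variation: global scale and per-sensor offsets."""

    subject_id: int
    scale: float
    shift: np.ndarray  # (8, 3), g


@dataclass(frozen=True)
class GeneratorConfig:
    """Protocol parameters; defaults reproduce the 30 x 6 x 25 = 4500 windows.

    Window length T defaults to 36 samples = 1.2 s at the 30 Hz per-channel
    rate, so a 30 s hold yields the protocol's 25 windows.  Noise scales are
    in g: ``noise_sd`` is white sensor noise per sample, ``breathing_amp``
    the chest-wall breathing modulation, ``micro_shift_sd`` the per-window
    repositioning, ``subject_scale_sd``/``sensor_shift_sd`` the between-
    subject variation.  ``separation`` multiplies the posture-specific part
    of every template and controls class contrast.
    """

    n_subjects: int = 30
    sets_per_posture: int = 25
    n_postures: int = 6
    T: int = 36
    per_channel_rate: float = 30.0
    noise_sd: float = 0.03
    breathing_amp: float = 0.02
    breathing_freq: float = 0.25
    micro_shift_sd: float = 0.05
    subject_scale_sd: float = 0.07
    sensor_shift_sd: float = 0.02
    separation: float = 1.0
    seed: int = 0

    @property
    def n_windows(self) -> int:
        return self.n_subjects * self.n_postures * self.sets_per_posture


@dataclass
class PostureDataset:
    """Window collection: signals (N, T, 24), labels (N,), subjects (N,).

    Channels are sensor-major: A_x, A_y, A_z, B_x, ..., H_z.
    """

    signals: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    posture_names: tuple[str, ...] = POSTURES
    config: GeneratorConfig | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return self.signals.shape[0]

    def subset(self, idx: np.ndarray) -> "PostureDataset":
        return PostureDataset(
            self.signals[idx],
            self.labels[idx],
            self.subjects[idx],
            self.posture_names,
            self.config,
        )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            # track_times=False keeps repeated runs byte-identical
            f.create_dataset(
                "signals", data=self.signals.astype(np.float32), track_times=False
            )
            f.create_dataset(
                "labels", data=self.labels.astype(np.int64), track_times=False
            )
            f.create_dataset(
                "subjects", data=self.subjects.astype(np.int64), track_times=False
            )
            f.attrs["posture_names"] = list(self.posture_names)

    @classmethod
    def load_hdf5(cls, path) -> "PostureDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                signals=np.asarray(f["signals"], dtype=np.float64),
                labels=np.asarray(f["labels"]),
                subjects=np.asarray(f["subjects"]),
                posture_names=tuple(f.attrs.get("posture_names", POSTURES)),
            )


# ---------------------------------------------------------------------------
# Posture templates

# Posture-specific gravity-loading deviations (units g) on top of a shared
# resting baseline.  Values express which sites bear load in each posture:
# supine loads shoulder blades/coccyx/hips vertically; prone shifts load
# toward spine and knees with a head-turn lateral component at the shoulders;
# side postures load the lying-side sensors with a strong lateral (y)
# component; fetus variants curl the legs up, unloading the knee sensors and
# shifting weight to coccyx/hips.  Right-side postures are the mirror image
# of the left-side ones (bilateral sensor columns swapped, y negated).
_BASE = np.zeros((8, 3))
_BASE[:, 2] = 0.1  # resting mattress load on the vertical axis

_DEV: dict[str, np.ndarray] = {}

_sup = np.zeros((8, 3))
_sup[:, 2] = [0.80, 0.80, 0.50, 0.90, 0.70, 0.70, 0.30, 0.30]
_DEV["supine"] = _sup

_pro = np.zeros((8, 3))
_pro[:, 2] = [0.70, 0.70, 0.80, 0.30, 0.60, 0.60, 0.55, 0.55]
_pro[0, 0] = _pro[1, 0] = -0.35
_DEV["prone"] = _pro

_llog = np.zeros((8, 3))
_llog[:, 2] = [0.95, 0.10, 0.30, 0.25, 0.90, 0.10, 0.60, 0.05]
_llog[:, 1] = [0.55, 0.05, 0.25, 0.15, 0.55, 0.05, 0.35, 0.00]
_DEV["left_log"] = _llog

_lfet = np.zeros((8, 3))
_lfet[:, 2] = [0.95, 0.10, 0.15, 0.50, 1.00, 0.15, 0.10, 0.02]
_lfet[:, 1] = [0.55, 0.05, 0.25, 0.20, 0.60, 0.05, 0.05, 0.00]
_lfet[6, 0] = 0.35
_lfet[7, 0] = 0.10
_DEV["left_fetus"] = _lfet


def mirror_template(pattern: np.ndarray) -> np.ndarray:
    """Left/right mirror: swap bilateral sensor rows and negate the y axis."""
    out = pattern.copy()
    for a, b in MIRROR_PAIRS:
        out[[a, b]] = out[[b, a]]
    out[:, 1] *= -1.0
    return out


_DEV["right_log"] = mirror_template(_DEV["left_log"])
_DEV["right_fetus"] = mirror_template(_DEV["left_fetus"])


def make_templates(separation: float = 1.0) -> list[PostureTemplate]:
    """The six deterministic posture templates at a given class contrast.

    ``separation`` scales the posture-specific deviation around the shared
    baseline; at 0 all templates coincide, which is rejected.
    """
    if separation <= 0:
        raise ValueError(
            "separation must be > 0: at 0 all posture templates are "
            "identical and classes are indistinguishable"
        )
    out = []
    for name in POSTURES:
        pattern = _BASE + separation * _DEV[name]
        out.append(PostureTemplate(posture=name, static_pattern=pattern))
    return out


# ---------------------------------------------------------------------------
# Dataset generation


def _subject_profiles(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> list[SubjectProfile]:
    profiles = []
    for s in range(cfg.n_subjects):
        scale = float(
            np.exp(rng.normal(0.0, cfg.subject_scale_sd))
        )  # lognormal, mean ~1, always positive
        shift = rng.normal(0.0, cfg.sensor_shift_sd, size=(8, 3))
        profiles.append(SubjectProfile(subject_id=s, scale=scale, shift=shift))
    return profiles


def generate_dataset(cfg: GeneratorConfig = GeneratorConfig()) -> PostureDataset:
    """Generate the full labeled window collection, reproducible from seed."""
    if cfg.n_subjects < 1 or cfg.sets_per_posture < 1 or cfg.T < 1:
        raise ValueError("n_subjects, sets_per_posture and T must be positive")
    if cfg.n_postures != 6:
        raise ValueError("the protocol defines exactly six postures")
    rng = np.random.default_rng(cfg.seed)
    templates = make_templates(cfg.separation)
    profiles = _subject_profiles(cfg, rng)
    t = np.arange(cfg.T) / cfg.per_channel_rate

    N = cfg.n_windows
    signals = np.empty((N, cfg.T, 24))
    labels = np.empty(N, dtype=np.int64)
    subjects = np.empty(N, dtype=np.int64)

    w = 0
    for prof in profiles:
        for label, tmpl in enumerate(templates):
            static = prof.scale * tmpl.static_pattern + prof.shift  # (8, 3)
            for _ in range(cfg.sets_per_posture):
                window = np.broadcast_to(static, (cfg.T, 8, 3)).copy()
                if cfg.breathing_amp > 0:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    breath = cfg.breathing_amp * np.sin(
                        2.0 * np.pi * cfg.breathing_freq * t + phase
                    )
                    window[:, TORSO_SENSORS, 2] += breath[:, None]
                if cfg.micro_shift_sd > 0:
                    window += rng.normal(0.0, cfg.micro_shift_sd, size=(8, 3))
                if cfg.noise_sd > 0:
                    window += rng.normal(0.0, cfg.noise_sd, size=(cfg.T, 8, 3))
                signals[w] = window.reshape(cfg.T, 24)
                labels[w] = label
                subjects[w] = prof.subject_id
                w += 1
    return PostureDataset(
        signals=signals,
        labels=labels,
        subjects=subjects,
        posture_names=POSTURES,
        config=cfg,
    )


def channel_means(dataset: PostureDataset) -> np.ndarray:
    """Default clustering features: per-channel time averages, (N, 24)."""
    return dataset.signals.mean(axis=1)


# ---------------------------------------------------------------------------
# Rotating-rig calibration sweep and between-sensor consistency ANOVA


@dataclass(frozen=True)
class CalibrationSweep:
    """Rotating-rig readings: sensors x angles (x replicates), plus truth."""

    angles_deg: np.ndarray  # (n_angles,)
    samples: np.ndarray  # (n_sensors, n_angles, samples_per_angle), g
    readings: np.ndarray  # per-cell means, (n_sensors, n_angles)
    gains: np.ndarray  # (n_sensors,)
    offsets: np.ndarray  # (n_sensors,)

    def to_frame(self) -> pd.DataFrame:
        n_sensors, n_angles, m = self.samples.shape
        rows = {
            "sensor": np.repeat(np.arange(n_sensors), n_angles * m),
            "angle_deg": np.tile(np.repeat(self.angles_deg, m), n_sensors),
            "reading_g": self.samples.ravel(),
        }
        return pd.DataFrame(rows)


def simulate_rotation_sweep(
    n_sensors: int = 8,
    step_deg: float = 5.0,
    noise_sd: float = 0.01,
    gain_sd: float = 0.0,
    offset_sd: float = 0.0,
    samples_per_angle: int = 8,
    seed: int = 0,
) -> CalibrationSweep:
    """Simulate the 0-180 degree rig sweep for an array of sensors.

    The aligned axis of an ideal sensor reads g*cos(theta); each simulated
    sensor applies a fixed gain and offset error and adds white read noise.
    """
    if step_deg <= 0 or 180.0 % step_deg != 0:
        raise ValueError("step_deg must be positive and divide 180")
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 180.0 + step_deg, step_deg)
    ideal = np.cos(np.deg2rad(angles))  # (n_angles,)
    gains = 1.0 + rng.normal(0.0, gain_sd, size=n_sensors)
    offsets = rng.normal(0.0, offset_sd, size=n_sensors)
    samples = (
        gains[:, None, None] * ideal[None, :, None]
        + offsets[:, None, None]
        + rng.normal(0.0, noise_sd, size=(n_sensors, angles.size, samples_per_angle))
    )
    return CalibrationSweep(
        angles_deg=angles,
        samples=samples,
        readings=samples.mean(axis=2),
        gains=gains,
        offsets=offsets,
    )


def anova_consistency(sweep: CalibrationSweep) -> tuple[float, float]:
    """One-way ANOVA of sensor identity over cosine residuals: (F, p).

    Residuals (reading minus the ideal g*cos(theta)) remove the angle effect
    so that sensor identity is the only factor; a large F (small p) indicates
    the sensors are *not* mutually consistent.
    """
    n_sensors = sweep.samples.shape[0]
    if n_sensors < 2:
        raise ValueError("ANOVA needs at least two sensors")
    if sweep.samples.shape[2] < 2:
        raise ValueError("ANOVA needs at least two replicates per angle")
    ideal = np.cos(np.deg2rad(sweep.angles_deg))
    residuals = sweep.samples - ideal[None, :, None]
    groups = [residuals[s].ravel() for s in range(n_sensors)]
    if all(np.ptp(grp) == 0 for grp in groups):
        raise ValueError("zero within-group variance; ANOVA undefined")
    f_stat, p_val = stats.f_oneway(*groups)
    return float(f_stat), float(p_val)
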