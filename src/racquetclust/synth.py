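"""Seeded synthetic 6-axis IMU recordings for nine racquet-sport movements.

The study protocol this emulates: five subjects each perform twenty tests
of nine movements (four table-tennis strokes, four badminton strokes and
walking) wearing a wrist IMU sampled at 50 Hz, one movement repetition
taking 1-1.2 s, repetitions of the same movement recorded continuously.
No such recordings are deposited anywhere, so this module generates
periodic, class-distinct arm-motion surrogates: per axis a fundamental
sinusoid plus one harmonic at the class amplitude/frequency/phase, a
constant gravity offset oriented by the class's nominal wrist attitude,
and additive Gaussian sensor noise.  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .units import STANDARD_GRAVITY

IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")

#: canonical movement names in class-id order
MOVEMENT_NAMES = (
    "walking",
    "tt_service",
    "tt_stroke",
    "tt_spin",
    "tt_pickup",
    "bd_service",
    "bd_drive",
    "bd_smash",
    "bd_pickup",
)


class ImuCsvError(ValueError):
    """Raised when an IMU CSV file cannot be parsed."""


@dataclass(frozen=True)
class MovementClassSpec:
    """Signal-level parameters of one movement class.

    Amplitudes are per axis (x, y, z): accelerometer in m/s², gyroscope in
    °/s.  ``base_frequency`` is the fundamental of the periodic arm motion
    in Hz, ``phase_offsets`` the per-axis phase in radians.
    ``gravity_direction`` is the unit vector along which the constant
    9.8 m/s² gravity offset appears in the sensor frame (the nominal wrist
    attitude while performing the movement).
    """

    class_id: int
    name: str
    accel_amplitude: tuple[float, float, float]
    gyro_amplitude: tuple[float, float, float]
    base_frequency: float
    phase_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rep_duration_range: tuple[float, float] = (1.0, 1.2)
    noise_sigma_accel: float = 0.0
    noise_sigma_gyro: float = 0.0
    gravity_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if any(a < 0 for a in self.accel_amplitude) or any(a < 0 for a in self.gyro_amplitude):
            raise ValueError(f"class {self.name}: amplitudes must be non-negative")
        lo, hi = self.rep_duration_range
        if not (0 < lo <= hi):
            raise ValueError(f"class {self.name}: rep_duration_range must satisfy 0 < lo <= hi, got {lo}, {hi}")
        if self.noise_sigma_accel < 0 or self.noise_sigma_gyro < 0:
            raise ValueError(f"class {self.name}: noise sigmas must be non-negative")
        if self.base_frequency <= 0:
            raise ValueError(f"class {self.name}: base_frequency must be positive")
        n = float(np.linalg.norm(self.gravity_direction))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"class {self.name}: gravity_direction must be a unit vector (norm={n:.4f})")

    def scaled(self, factor: float) -> "MovementClassSpec":
        """Return a copy with all motion amplitudes multiplied by ``factor``."""
        return dataclasses.replace(
            self,
            accel_amplitude=tuple(a * factor for a in self.accel_amplitude),
            gyro_amplitude=tuple(a * factor for a in self.gyro_amplitude),
        )


@dataclass(frozen=True)
class SynthConfig:
    """Full synthetic collection protocol: who, what, how often."""

    classes: tuple[MovementClassSpec, ...]
    n_subjects: int = 5
    reps_per_test: int = 20
    sample_rate: float = 50.0
    seed: int = 0
    subject_scale_jitter: float = 0.1

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not self.classes:
            raise ValueError("class list must not be empty")
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"class_ids must be unique, got {ids}")
        if self.n_subjects < 1 or self.reps_per_test < 1:
            raise ValueError("n_subjects and reps_per_test must be >= 1")


@dataclass
class ImuSeries:
    """Uniformly sampled 6-axis record: accelerometer (m/s²) + gyroscope (°/s)."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    sample_rate: float

    def __post_init__(self):
        chans = [self.t, self.ax, self.ay, self.az, self.gx, self.gy, self.gz]
        n = len(self.t)
        if any(len(c) != n for c in chans):
            raise ValueError("all channels must share the same length")
        if not all(np.all(np.isfinite(c)) for c in chans):
            raise ValueError("IMU series contains non-finite values")
        if n > 1:
            dt = np.diff(self.t)
            if dt.min() <= 0 or np.ptp(dt) > 1e-9:
                raise ValueError("time grid must be strictly increasing and uniform to 1e-9 s")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sample_period(self) -> float:
        """Sampling period T = 1/rate in seconds."""
        return 1.0 / self.sample_rate

    @property
    def accel(self) -> np.ndarray:
        """(n, 3) accelerometer array."""
        return np.column_stack([self.ax, self.ay, self.az])

    @property
    def gyro(self) -> np.ndarray:
        """(n, 3) gyroscope array."""
        return np.column_stack([self.gx, self.gy, self.gz])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in IMU_COLUMNS})


@dataclass
class InstanceRecord:
    """One test: a single movement repetition by one subject."""

    subject: int
    class_id: int
    rep: int
    series: ImuSeries


@dataclass
class MovementSet:
    """Continuous recording of all repetitions of one movement by one subject."""

    subject: int
    class_id: int
    series: ImuSeries
    rep_boundaries: list[tuple[int, int]]  # [start, end) sample spans of each rep

    @property
    def rep_count(self) -> int:
        return len(self.rep_boundaries)


@dataclass
class Dataset:
    """A labelled collection of instances plus per-(subject, class) continuous sets."""

    instances: list[InstanceRecord]
    sets: list[MovementSet]
    config: SynthConfig | None = None

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def class_ids(self) -> list[int]:
        return sorted({r.class_id for r in self.instances})

    def instances_per_class(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.instances:
            out[r.class_id] = out.get(r.class_id, 0) + 1
        return out

    def subset(self, class_ids: Sequence[int]) -> "Dataset":
        """Restrict to the given movement classes (e.g. one sport's four strokes)."""
        keep = set(class_ids)
        return Dataset(
            instances=[r for r in self.instances if r.class_id in keep],
            sets=[s for s in self.sets if s.class_id in keep],
            config=self.config,
        )


def _waveform(amplitude, freq, phase, t, kind):
    """Fundamental plus one 0.35-weight harmonic; sin for accel, cos for gyro."""
    f = np.sin if kind == "sin" else np.cos
    w = 2.0 * np.pi * freq
    return amplitude * (f(w * t + phase) + 0.35 * f(2.0 * w * t + 2.0 * phase))


#: swing amplitude as a fraction of the class oscillation amplitude
SWING_FRACTION = 0.5


def _swing_profile(t, duration):
    """One smooth stroke bump per repetition: sin²(πt/D), peaking mid-rep.

    The repetition-scale swing is what gives the integrated velocity and
    displacement streams genuine signal content; the faster oscillation
    alone integrates to almost nothing.
    """
    return np.sin(np.pi * t / duration) ** 2


def generate_instance(
    spec: MovementClassSpec,
    duration: float,
    rate: float,
    seed,
) -> ImuSeries:
    """Generate one repetition of ``spec``'s movement.

    The accelerometer carries a constant gravity offset of 9.8 m/s² along
    ``spec.gravity_direction``, the periodic oscillation term, a
    repetition-scale swing bump (half the oscillation amplitude) and
    Gaussian noise at ``noise_sigma_accel``; the gyroscope is the
    quadrature (cosine) waveform plus the same swing bump and noise at
    ``noise_sigma_gyro``.  Identical (spec, duration, rate, seed) gives
    bit-identical output.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    if n < 1:
        raise ValueError(f"duration {duration} s at {rate} Hz yields no samples")
    t = np.arange(n) / rate
    g = STANDARD_GRAVITY * np.asarray(spec.gravity_direction)
    swing = _swing_profile(t, duration)
    acc = np.empty((n, 3))
    gyr = np.empty((n, 3))
    for i in range(3):
        acc[:, i] = (g[i] + _waveform(spec.accel_amplitude[i], spec.base_frequency, spec.phase_offsets[i], t, "sin")
                     + SWING_FRACTION * spec.accel_amplitude[i] * swing)
        gyr[:, i] = (_waveform(spec.gyro_amplitude[i], spec.base_frequency, spec.phase_offsets[i], t, "cos")
                     + SWING_FRACTION * spec.gyro_amplitude[i] * swing)
    if spec.noise_sigma_accel > 0:
        acc += rng.normal(0.0, spec.noise_sigma_accel, size=acc.shape)
    if spec.noise_sigma_gyro > 0:
        gyr += rng.normal(0.0, spec.noise_sigma_gyro, size=gyr.shape)
    return ImuSeries(t, acc[:, 0], acc[:, 1], acc[:, 2], gyr[:, 0], gyr[:, 1], gyr[:, 2], sample_rate=rate)


def _concat_series(parts: list[ImuSeries], rate: float) -> ImuSeries:
    n = sum(len(p) for p in parts)
    t = np.arange(n) / rate
    cols = {c: np.concatenate([getattr(p, c) for p in parts]) for c in IMU_COLUMNS[1:]}
    return ImuSeries(t, sample_rate=rate, **cols)


def generate_dataset(config: SynthConfig) -> Dataset:
    """Generate the full collection protocol.

    Emits ``n_subjects × |classes| × reps_per_test`` single-repetition
    instances, plus one continuous per-(subject, class) movement set with
    the true repetition boundaries recorded (repetitions of one movement
    are recorded back to back, different movements separately).  Each
    subject's motion amplitudes carry a multiplicative jitter drawn once
    per subject.
    """
    rng_subjects = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    scale = 1.0 + config.subject_scale_jitter * rng_subjects.uniform(-1.0, 1.0, size=config.n_subjects)

    instances: list[InstanceRecord] = []
    sets: list[MovementSet] = []
    for s in range(config.n_subjects):
        for spec in config.classes:
            sspec = spec.scaled(scale[s])
            parts: list[ImuSeries] = []
            bounds: list[tuple[int, int]] = []
            pos = 0
            for r in range(config.reps_per_test):
                key = (1, s, spec.class_id, r)
                rng_dur = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key + (0,)))
                lo, hi = spec.rep_duration_range
                duration = rng_dur.uniform(lo, hi)
                inst = generate_instance(
                    sspec, duration, config.sample_rate,
                    seed=np.random.SeedSequence(entropy=config.seed, spawn_key=key + (1,)),
                )
                instances.append(InstanceRecord(subject=s, class_id=spec.class_id, rep=r, series=inst))
                parts.append(inst)
                bounds.append((pos, pos + len(inst)))
                pos += len(inst)
            sets.append(
                MovementSet(subject=s, class_id=spec.class_id,
                            series=_concat_series(parts, config.sample_rate), rep_boundaries=bounds)
            )
    return Dataset(instances=instances, sets=sets, config=config)


def write_imu_csv(series: ImuSeries, path) -> None:
    """Write a series as comma-separated text with the canonical header."""
    series.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_imu_csv(path) -> ImuSeries:
    """Read a series written by :func:`write_imu_csv`.

    Raises :class:`ImuCsvError` naming the offending line for missing
    columns or non-numeric fields.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header:
        raise ImuCsvError(f"{path}: line 1: empty file, expected header {','.join(IMU_COLUMNS)}")
    names = tuple(h.strip() for h in header.split(","))
    if names != IMU_COLUMNS:
        raise ImuCsvError(f"{path}: line 1: expected columns {','.join(IMU_COLUMNS)}, got {header!r}")
    try:
        df = pd.read_csv(path, dtype=float)
    except ValueError:
        # locate the first malformed line for the error message
        with open(path, "r", encoding="utf-8") as fh:
            fh.readline()
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split(",")
                if len(fields) != len(IMU_COLUMNS):
                    raise ImuCsvError(f"{path}: line {lineno}: expected {len(IMU_COLUMNS)} fields, got {len(fields)}")
                for f in fields:
                    try:
                        float(f)
                    except ValueError:
                        raise ImuCsvError(f"{path}: line {lineno}: non-numeric field {f!r}") from None
        raise ImuCsvError(f"{path}: malformed numeric data")
    if len(df) == 0:
        raise ImuCsvError(f"{path}: line 2: no data rows")
    t = df["t"].to_numpy()
    rate = 1.0 / (t[1] - t[0]) if len(t) > 1 else 50.0
    return ImuSeries(t, df["ax"].to_numpy(), df["ay"].to_numpy(), df["az"].to_numpy(),
                     df["gx"].to_numpy(), df["gy"].to_numpy(), df["gz"].to_numpy(), sample_rate=rate)


def load_classes(path) -> tuple[MovementClassSpec, ...]:
    """Load a movement-class table from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _classes_from_obj(raw)


def _classes_from_obj(raw) -> tuple[MovementClassSpec, ...]:
    specs = []
    for item in raw["classes"]:
        specs.append(
            MovementClassSpec(
                class_id=int(item["class_id"]),
                name=str(item["name"]),
                accel_amplitude=tuple(float(v) for v in item["accel_amplitude"]),
                gyro_amplitude=tuple(float(v) for v in item["gyro_amplitude"]),
                base_frequency=float(item["base_frequency"]),
                phase_offsets=tuple(float(v) for v in item.get("phase_offsets", (0, 0, 0))),
                rep_duration_range=tuple(float(v) for v in item.get("rep_duration_range", (1.0, 1.2))),
                noise_sigma_accel=float(item.get("noise_sigma_accel", 0.0)),
                noise_sigma_gyro=float(item.get("noise_sigma_gyro", 0.0)),
                gravity_direction=tuple(float(v) for v in item.get("gravity_direction", (0, 0, 1))),
            )
        )
    return tuple(specs)


def default_classes() -> tuple[MovementClassSpec, ...]:
    """The shipped nine-movement class table (see data/default_classes.yaml)."""
    ref = resources.files("racquetclust").joinpath("data/default_classes.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _classes_from_obj(raw)


def default_synth_config(seed: int = 0, **overrides) -> SynthConfig:
    """The shipped collection protocol: 5 subjects × 9 classes × 20 reps at 50 Hz."""
    return SynthConfig(classes=default_classes(), seed=seed, **overrides)
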