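"""Noise reduction and sensor fusion for raw 6-axis IMU signals.

Median filtering removes impulse noise from the raw channels.  Orientation
is then estimated by a complementary filter (here called HBL): the
gyro-propagated angle is trusted over short horizons and periodically
corrected by the accelerometer-derived gravity angle,

    theta[t] = alpha * (theta[t-1] + gyro[t] * T) + (1 - alpha) * theta_acc[t]

with weight ``alpha`` close to 1.  The same convex weighting applied on the
acceleration channels (accelerometer reading vs the gravity vector
predicted by the gyro-propagated attitude) yields a denoised gravity
estimate whose magnitude can be checked against g = 9.8 m/s².  A minimal
scalar unscented Kalman filter on the state model

    ACC_k = ACC_{k-1} * cos²(theta_k) + w_k,      z_k = ACC_k + v_k

is provided as the comparison baseline.  Angles are degrees throughout
(the gyroscope reads °/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _nd_median

from .synth import ImuSeries
from .units import STANDARD_GRAVITY


@dataclass(frozen=True)
class FilterConfig:
    """Preprocessing parameters.

    alpha : complementary-filter weight in [0, 1]; 0.98 is the
        conventional choice (gyro trusted for ~1 s at 50 Hz).
    median_window : odd sample count of the median prefilter.
    sample_period : seconds between samples (T = 1/rate).
    """

    alpha: float = 0.98
    median_window: int = 3
    sample_period: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError(f"median_window must be odd and >= 1, got {self.median_window}")
        if self.sample_period <= 0:
            raise ValueError(f"sample_period must be positive, got {self.sample_period}")


@dataclass
class FusedSeries:
    """Complementary-filter output: denoised gravity estimate + fused angles.

    acc_hbl : (n, 3) m/s², convex blend of accelerometer and
        gyro-predicted gravity per axis.
    theta : (n, 3) degrees, fused rotation angles about x (roll),
        y (pitch) and z (yaw; gyro integration only).
    """

    acc_hbl: np.ndarray
    theta: np.ndarray


@dataclass
class UkfState:
    """Initial state of the scalar gravity UKF."""

    acc_estimate: float = STANDARD_GRAVITY
    theta: float = 0.0  # rotation angle, degrees
    process_noise_var: float = 1e-4
    measurement_noise_var: float = 1e-2
    cov: float = 1.0

    def __post_init__(self):
        if self.process_noise_var <= 0 or self.measurement_noise_var <= 0:
            raise ValueError("noise variances must be positive")


def median_filter(x, window: int) -> np.ndarray:
    """Centered running median with replicated boundary values.

    ``window`` must be odd and no longer than the sequence.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > x.shape[-1]:
        raise ValueError(f"window {window} exceeds sequence length {x.shape[-1]}")
    return _nd_median(x, size=window, mode="nearest")


def accel_angles(acc: np.ndarray) -> np.ndarray:
    """Accelerometer-derived attitude angles in degrees, (n, 3).

    Roll (about x) and pitch (about y) from the arctangent of gravity
    components; yaw is unobservable from gravity and returned as 0.
    """
    ax, ay, az = acc[:, 0], acc[:, 1], acc[:, 2]
    roll = np.degrees(np.arctan2(ay, az))
    pitch = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))
    return np.column_stack([roll, pitch, np.zeros_like(roll)])


def complementary_filter(gyro_rate, accel_angle, alpha: float, T: float, theta0: float | None = None) -> np.ndarray:
    """Scalar complementary recursion on one axis.

    theta[t] = alpha*(theta[t-1] + gyro_rate[t]*T) + (1-alpha)*accel_angle[t];
    theta[0] defaults to accel_angle[0].
    """
    gyro_rate = np.asarray(gyro_rate, dtype=float)
    accel_angle = np.asarray(accel_angle, dtype=float)
    n = len(gyro_rate)
    out = np.empty(n)
    prev = accel_angle[0] if theta0 is None else float(theta0)
    for t in range(n):
        prev = alpha * (prev + gyro_rate[t] * T) + (1.0 - alpha) * accel_angle[t]
        out[t] = prev
    return out


def _gravity_from_angles(theta: np.ndarray) -> np.ndarray:
    """Sensor-frame gravity vector predicted by (roll, pitch) in degrees."""
    roll = np.radians(theta[:, 0])
    pitch = np.radians(theta[:, 1])
    g = STANDARD_GRAVITY
    return np.column_stack([
        -g * np.sin(pitch),
        g * np.sin(roll) * np.cos(pitch),
        g * np.cos(roll) * np.cos(pitch),
    ])


def hbl_fuse(series: ImuSeries, config: FilterConfig, theta0=None) -> FusedSeries:
    """Complementary fusion of accelerometer and gyroscope.

    Fused angles follow the per-axis recursion above (yaw by pure gyro
    integration, since gravity carries no yaw information).  ``acc_hbl``
    blends the accelerometer reading with the gravity vector predicted by
    the gyro-propagated attitude:
    ``alpha * acc + (1 - alpha) * acc_gyro``.

    theta0 : optional (3,) initial angles in degrees; defaults to the
        accelerometer-derived angles of the first sample.
    """
    T = config.sample_period
    a = config.alpha
    acc = series.accel
    gyr = series.gyro
    th_acc = accel_angles(acc)
    # the correction term is the running average of the accelerometer-derived
    # angle: the periodic motion component averages out over a cycle, leaving
    # the quasi-static attitude the accelerometer actually observes
    th_corr = np.cumsum(th_acc, axis=0) / np.arange(1, len(th_acc) + 1)[:, None]
    init = th_acc[0] if theta0 is None else np.asarray(theta0, dtype=float)

    theta = np.empty_like(th_acc)
    theta[:, 0] = complementary_filter(gyr[:, 0], th_corr[:, 0], a, T, theta0=init[0])
    theta[:, 1] = complementary_filter(gyr[:, 1], th_corr[:, 1], a, T, theta0=init[1])
    theta[:, 2] = init[2] + np.cumsum(gyr[:, 2]) * T  # yaw: gyro only

    # gyro-propagated attitude (no accelerometer correction) -> predicted gravity
    th_gyro = init[None, :2] + np.cumsum(gyr[:, :2], axis=0) * T
    acc_gyro = _gravity_from_angles(np.column_stack([th_gyro, theta[:, 2]]))
    acc_hbl = a * acc + (1.0 - a) * acc_gyro
    return FusedSeries(acc_hbl=acc_hbl, theta=theta)


def ukf_fuse(z_sequence, state0: UkfState, thetas=None, ukf_alpha: float = 1e-3,
             ukf_beta: float = 2.0, ukf_kappa: float = 0.0) -> np.ndarray:
    """Scalar unscented Kalman recursion on the gravity state model.

    Dynamics ACC_k = ACC_{k-1}*cos²(theta_k) + w_k with observation
    z_k = ACC_k + v_k.  ``thetas`` is the known rotation-angle sequence in
    degrees (constant ``state0.theta`` if omitted).  Returns the filtered
    estimate per step.
    """
    z = np.asarray(z_sequence, dtype=float)
    if state0.process_noise_var <= 0 or state0.measurement_noise_var <= 0:
        raise ValueError("noise variances must be positive")
    n_steps = len(z)
    th = np.full(n_steps, state0.theta, dtype=float) if thetas is None else np.asarray(thetas, dtype=float)

    n = 1  # state dimension
    lam = ukf_alpha**2 * (n + ukf_kappa) - n
    wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = wm[0] + (1.0 - ukf_alpha**2 + ukf_beta)

    x = float(state0.acc_estimate)
    P = float(state0.cov)
    Q = state0.process_noise_var
    R = state0.measurement_noise_var
    out = np.empty(n_steps)
    for k in range(n_steps):
        s = np.sqrt(max((n + lam) * P, 0.0))
        sigma = np.array([x, x + s, x - s])
        c = np.cos(np.radians(th[k])) ** 2
        prop = sigma * c
        x_pred = float(wm @ prop)
        P_pred = float(wc @ (prop - x_pred) ** 2) + Q
        # linear observation h(x) = x
        S = P_pred + R
        K = P_pred / S
        x = x_pred + K * (z[k] - x_pred)
        P = (1.0 - K) * P_pred
        out[k] = x
    return out
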