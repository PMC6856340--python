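"""Skin-stretch device control law.

The fingertip contactor rotates at an angular velocity commanded from the
body pitch angle theta_p through a PID law,

    omega_c = Kp * theta_p + Ki * integral(theta_p) dt + Kd * d theta_p/dt ,

saturated at +/- omega_max.  The study configuration is derivative-only
(Kp = Ki = 0): the contactor speed encodes sway *velocity*, so a subject
holding any constant lean feels nothing, and a constant bias in the pitch
measurement (IMU drift) has no effect on the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SignalError

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "contactor_velocity",
    "run_controller",
    "saturation_frequency_hz",
]

#: Device cap on contactor angular velocity, rad/s (about 4 Hz).
DEFAULT_OMEGA_MAX = 25.0


@dataclass(frozen=True)
class ControllerConfig:
    """PID gains, saturation limit and sample interval.

    kp has units 1/s, ki 1/s^2 (applied to the running integral in rad s),
    kd is dimensionless.  Defaults are the derivative-only configuration.
    """

    kp: float = 0.0
    ki: float = 0.0
    kd: float = 1.0
    omega_max: float = DEFAULT_OMEGA_MAX
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.omega_max <= 0:
            raise ParameterError("omega_max must be > 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")


@dataclass(frozen=True)
class ControllerState:
    """Running integral of pitch and the previous pitch sample."""

    integral: float = 0.0
    prev_theta: float | None = None


def contactor_velocity(
    theta_p: float, state: ControllerState, cfg: ControllerConfig
) -> tuple[float, ControllerState]:
    """One control step: pitch angle in, saturated contactor velocity out.

    The pitch rate is a backward difference from the previous sample (zero
    on the first sample).  Returns the commanded velocity and the updated
    state.
    """
    if not np.isfinite(theta_p):
        raise SignalError(f"non-finite pitch sample: {theta_p!r}")
    theta_dot = (
        0.0 if state.prev_theta is None else (theta_p - state.prev_theta) / cfg.dt
    )
    integral = state.integral + theta_p * cfg.dt
    omega = cfg.kp * theta_p + cfg.ki * integral + cfg.kd * theta_dot
    omega = float(np.clip(omega, -cfg.omega_max, cfg.omega_max))
    return omega, ControllerState(integral=integral, prev_theta=theta_p)


def run_controller(theta_trace: np.ndarray, cfg: ControllerConfig) -> np.ndarray:
    """Apply the control law to a uniformly sampled pitch-angle trace."""
    theta = np.asarray(theta_trace, dtype=float)
    if theta.ndim != 1:
        raise SignalError("pitch trace must be one-dimensional")
    if not np.all(np.isfinite(theta)):
        raise SignalError("pitch trace contains non-finite samples")
    theta_dot = np.empty_like(theta)
    theta_dot[0] = 0.0
    np.divide(np.diff(theta), cfg.dt, out=theta_dot[1:])
    integral = np.cumsum(theta) * cfg.dt
    omega = cfg.kp * theta + cfg.ki * integral + cfg.kd * theta_dot
    return np.clip(omega, -cfg.omega_max, cfg.omega_max)


def saturation_frequency_hz(omega_max: float = DEFAULT_OMEGA_MAX) -> float:
    """Rotation frequency corresponding to the saturation velocity."""
    return omega_max / (2.0 * np.pi)
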