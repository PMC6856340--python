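"""Synthetic quiet-standing data generators.

Three generators with the statistical structure the sway analyses assume:

* :func:`simulate_quiet_standing` -- a linearized single-link inverted
  pendulum balanced by delayed proportional-derivative "neural" torque
  acting on noisy state estimates.  The sensory-augmentation conditions are
  modelled purely as a change in sensory signal-to-noise ratio: the
  ``snr_gain`` multiplier scales the sensory noise corrupting the
  anterior-posterior state estimate (the axis the feedback device encodes).
  Better estimates tighten the sway distribution, which is exactly the
  mechanism by which augmented feedback is expected to lower sway entropy.
* :func:`simulate_two_regime_process` -- a mean-reverting process driven by
  exponentially smoothed noise.  The smooth drive makes short-lag
  increments persistent (scaling exponent above 0.5) while mean reversion
  bounds the variance, making long-lag behaviour antipersistent -- the
  canonical two-regime stabilogram.
* :func:`generate_cohort` -- a full study cohort (subjects x conditions x
  trials) with per-subject parameter jitter, all randomness derived from a
  single master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InstabilityError, ParameterError
from .signal import SSD_OFF, SSD_ON, CopTrial, DirectionalSeries

__all__ = [
    "PendulumConfig",
    "TwoRegimeConfig",
    "CohortConfig",
    "simulate_quiet_standing",
    "simulate_two_regime_process",
    "generate_cohort",
]


@dataclass(frozen=True)
class PendulumConfig:
    """Inverted-pendulum sway model parameters.

    The body is a point mass ``mass`` at height ``com_height`` pivoting at
    the ankle; gravity destabilizes it with torque gradient m g h.  A
    delayed PD controller (stiffness ``ankle_stiffness`` > m g h for
    stabilizability, damping ``ankle_damping``) acts on state estimates
    delayed by ``neural_delay`` and corrupted by coloured sensory noise.
    ``motor_noise_sd`` is the white torque-noise intensity (Nm per root
    second); ``sensory_noise_sd`` sets the stationary sd of the pitch-rate
    estimate noise (rad/s), with the position-estimate noise scaled from it
    by a 0.1 s equivalence time.  ``snr_gain`` multiplies the AP sensory
    noise: 1.0 is the unaugmented baseline, values below 1 model augmented
    feedback.
    """

    mass: float = 70.0
    com_height: float = 1.0
    g: float = 9.81
    ankle_stiffness: float | None = None  # default 1.1 * m g h
    ankle_damping: float = 350.0
    neural_delay: float = 0.15
    motor_noise_sd: float = 1.0
    sensory_noise_sd: float = 0.005
    sensory_noise_tau: float = 0.1
    snr_gain: float = 1.0
    initial_pitch: float = 0.0
    dt: float = 0.001
    duration: float = 30.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ParameterError("dt and duration must be > 0")
        if self.neural_delay < 0:
            raise ParameterError("neural_delay must be >= 0")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("duration must be an integral number of steps")
        if self.stiffness <= self.mgh:
            raise ParameterError(
                f"ankle_stiffness {self.stiffness:.1f} Nm/rad must exceed "
                f"the gravitational toppling gradient m*g*h = {self.mgh:.1f}"
            )

    @property
    def mgh(self) -> float:
        return self.mass * self.g * self.com_height

    @property
    def stiffness(self) -> float:
        return (
            1.1 * self.mgh if self.ankle_stiffness is None else self.ankle_stiffness
        )

    @property
    def inertia(self) -> float:
        return self.mass * self.com_height**2

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class TwoRegimeConfig:
    """Two-regime sway surrogate parameters.

    ``mean_reversion_rate`` (1/s) bounds the long-run variance;
    ``drive_time_constant`` (s) smooths the driving noise so short-lag
    increments are persistent; ``drive_sd`` (mm per root second) sets the
    drive intensity.
    """

    mean_reversion_rate: float = 0.5
    drive_time_constant: float = 0.2
    drive_sd: float = 1.0
    fs: float = 100.0
    duration: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "mean_reversion_rate", "drive_time_constant", "drive_sd", "fs", "duration"
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    15 subjects by 2 conditions by 10 trials of 30 s quiet standing, with
    the two conditions differing only in the sensory SNR gain.
    ``between_subject_sd`` is the log-scale sd of multiplicative jitter
    applied per subject to the pendulum parameters.
    """

    n_subjects: int = 15
    trials_per_condition: int = 10
    snr_off: float = 1.0
    snr_on: float = 0.5
    master_seed: int = 0
    between_subject_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("need at least 2 subjects")
        if self.trials_per_condition < 1:
            raise ParameterError("need at least 1 trial per condition")


def _ar1(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples (exact AR(1) discretization)."""
    if sd == 0.0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    w = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), n)
    x0 = rng.normal(0.0, sd)
    x, _ = sps.lfilter([1.0], [1.0, -a], w, zi=np.array([a * x0]))
    return x


def _simulate_axis(
    cfg: PendulumConfig, snr: float, seed_seq: np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one sway axis; returns (pitch angle rad, COP mm)."""
    rng = np.random.default_rng(seed_seq)
    n = cfg.n_samples
    dt = cfg.dt
    inertia, mgh = cfg.inertia, cfg.mgh
    K, B = cfg.stiffness, cfg.ankle_damping
    d = int(round(cfg.neural_delay / dt))

    pos_sd = snr * cfg.sensory_noise_sd * cfg.sensory_noise_tau
    vel_sd = snr * cfg.sensory_noise_sd
    n_th = _ar1(rng, n, dt, cfg.sensory_noise_tau, pos_sd)
    n_om = _ar1(rng, n, dt, cfg.sensory_noise_tau, vel_sd)
    kick = rng.normal(0.0, cfg.motor_noise_sd * np.sqrt(dt) / inertia, n)

    th = np.zeros(n)
    th[0] = cfg.initial_pitch
    om = np.zeros(n)
    cop = np.zeros(n)
    cop_scale = 1000.0 / (cfg.mass * cfg.g)  # torque (Nm) -> COP (mm)
    for i in range(n):
        th_d = th[i - d] if i >= d else 0.0
        om_d = om[i - d] if i >= d else 0.0
        torque = K * (th_d + n_th[i]) + B * (om_d + n_om[i])
        cop[i] = torque * cop_scale
        if i + 1 < n:
            om[i + 1] = om[i] + dt * (mgh * th[i] - torque) / inertia + kick[i]
            th[i + 1] = th[i] + dt * om[i]
            if abs(th[i + 1]) > 0.5:
                raise InstabilityError(
                    "pendulum diverged (|pitch| > 0.5 rad) with "
                    f"stiffness={K:.1f} Nm/rad, damping={B:.1f} Nms/rad, "
                    f"delay={cfg.neural_delay:.3f} s"
                )
    return th, cop


#: Physiologically plausible range of preprocessed COP sd, mm.
_COP_SD_RANGE_MM = (0.5, 15.0)


def simulate_quiet_standing(
    cfg: PendulumConfig,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sim",
    condition: str = SSD_OFF,
    trial_index: int = 1,
) -> CopTrial:
    """Simulate one quiet-standing trial at the raw acquisition rate.

    The AP axis uses ``cfg.snr_gain``; the ML axis is an independent,
    identically structured process at the unaugmented SNR of 1 (the device
    encodes AP sway only).  The same seed always yields the identical
    trial.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ap_ss, ml_ss = ss.spawn(2)
    _, cop_ap = _simulate_axis(cfg, cfg.snr_gain, ap_ss)
    _, cop_ml = _simulate_axis(cfg, 1.0, ml_ss)
    sd = float(np.std(cop_ap))
    if not (_COP_SD_RANGE_MM[0] <= sd <= _COP_SD_RANGE_MM[1]) and sd > 0:
        warnings.warn(
            f"simulated AP COP sd {sd:.2f} mm outside the physiological "
            f"range {_COP_SD_RANGE_MM} mm",
            stacklevel=2,
        )
    t = np.arange(cfg.n_samples) / cfg.fs
    return CopTrial(
        subject_id=subject_id,
        condition=condition,
        trial_index=trial_index,
        fs=cfg.fs,
        t=t,
        ap=cop_ap,
        ml=cop_ml,
    )


def simulate_pitch_trace(
    cfg: PendulumConfig, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Body pitch-angle trace (rad) of the AP axis, for driving the controller."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    th, _ = _simulate_axis(cfg, cfg.snr_gain, ss)
    return th


def simulate_two_regime_process(
    cfg: TwoRegimeConfig | None = None, seed: int | np.random.SeedSequence = 0
) -> DirectionalSeries:
    """Bounded sway surrogate with persistent short-lag behaviour.

    The position x relaxes toward zero at ``mean_reversion_rate`` while
    integrating a drive u that is itself an Ornstein-Uhlenbeck process with
    time constant ``drive_time_constant``:

        du = -u/tau dt + sigma dW,     dx = (-lambda x + u) dt .

    Over lags shorter than tau the drive barely changes, so x moves
    ballistically (msd ~ dt^2, persistent); over lags past 1/lambda the
    variance saturates (antipersistent).
    """
    cfg = cfg or TwoRegimeConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = int(round(cfg.duration * cfg.fs))
    dt = 1.0 / cfg.fs
    tau = cfg.drive_time_constant
    sd_u = cfg.drive_sd * np.sqrt(tau / 2.0)  # stationary sd of the drive
    u = _ar1(rng, n, dt, tau, sd_u)
    # x[i+1] = a x[i] + u[i] dt with a = exp(-lambda dt): AR(1) in x
    a = np.exp(-cfg.mean_reversion_rate * dt)
    x, _ = sps.lfilter([0.0, dt], [1.0, -a], u, zi=np.array([0.0]))
    x = x - x.mean()
    return DirectionalSeries(direction="AP", fs=cfg.fs, x=x)


def _jittered(base: PendulumConfig, rng: np.random.Generator, sd: float) -> PendulumConfig:
    """Per-subject multiplicative jitter preserving stabilizability."""
    f = np.exp(rng.normal(0.0, sd, 4))
    margin = (base.stiffness - base.mgh) * f[0]
    return replace(
        base,
        ankle_stiffness=base.mgh + margin,
        ankle_damping=base.ankle_damping * f[1],
        motor_noise_sd=base.motor_noise_sd * f[2],
        sensory_noise_sd=base.sensory_noise_sd * f[3],
    )


def generate_cohort(
    cfg: CohortConfig | None = None,
    pendulum: PendulumConfig | None = None,
) -> tuple[list[CopTrial], pd.DataFrame]:
    """Generate a full synthetic cohort and its manifest.

    Each subject gets one jittered parameter set used for both conditions,
    so conditions differ only in the AP sensory SNR gain.  Returns the
    trials and a manifest with one row per (subject, condition, trial).
    """
    cfg = cfg or CohortConfig()
    base = pendulum or PendulumConfig()
    master = np.random.SeedSequence(cfg.master_seed)
    subject_seqs = master.spawn(cfg.n_subjects)
    trials: list[CopTrial] = []
    rows = []
    for s, sub_ss in enumerate(subject_seqs, start=1):
        subject_id = f"S{s:02d}"
        param_ss, data_ss = sub_ss.spawn(2)
        sub_cfg = _jittered(base, np.random.default_rng(param_ss), cfg.between_subject_sd)
        trial_seqs = iter(data_ss.spawn(2 * cfg.trials_per_condition))
        for condition, snr in ((SSD_OFF, cfg.snr_off), (SSD_ON, cfg.snr_on)):
            cond_cfg = replace(sub_cfg, snr_gain=snr)
            for k in range(1, cfg.trials_per_condition + 1):
                trial = simulate_quiet_standing(
                    cond_cfg,
                    next(trial_seqs),
                    subject_id=subject_id,
                    condition=condition,
                    trial_index=k,
                )
                trials.append(trial)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "condition": condition,
                        "trial_index": k,
                        "path": f"{subject_id}_{condition}_{k:02d}.csv",
                    }
                )
    return trials, pd.DataFrame(rows)
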