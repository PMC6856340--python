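"""Center-of-pressure (COP) trial data model, file I/O and preprocessing.

A quiet-standing trial is a planar COP trajectory sampled uniformly in time:
anterior-posterior (AP) and medio-lateral (ML) displacement in millimetres.
Trials are stored one per file as comma-delimited text with a header row and
columns ``t_s``, ``cop_ap_mm``, ``cop_ml_mm``; trial metadata (subject,
condition, trial index) lives in a sidecar manifest or the filename.

Preprocessing is zero-phase low-pass filtering followed by resampling and
per-channel mean removal, after which the three directional series used by
the analyses (AP, ML, and radial distance from the mean COP) can be derived.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError, FormatError, ParameterError

#: The two sensory-augmentation conditions of the study design.
SSD_OFF = "SSD_OFF"
SSD_ON = "SSD_ON"
CONDITIONS = (SSD_OFF, SSD_ON)

#: Directional series labels.
DIRECTIONS = ("AP", "ML", "Rad")

_REQUIRED_COLUMNS = ("t_s", "cop_ap_mm", "cop_ml_mm")
_TIME_UNIFORMITY_TOL_S = 1e-9


@dataclass(frozen=True)
class CopTrial:
    """One quiet-standing trial: uniform time base plus AP/ML COP series (mm)."""

    subject_id: str
    condition: str
    trial_index: int
    fs: float
    t: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    preprocessed: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.trial_index < 1:
            raise ParameterError("trial_index must be >= 1")
        t, ap, ml = map(np.asarray, (self.t, self.ap, self.ml))
        if not (len(t) == len(ap) == len(ml)):
            raise DataError("t, ap and ml must have equal length")
        if len(t) < 2:
            raise DataError("a trial needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time base must be strictly increasing")
        if np.max(np.abs(dt - np.median(dt))) > _TIME_UNIFORMITY_TOL_S:
            raise DataError(
                "time base is not uniform within "
                f"{_TIME_UNIFORMITY_TOL_S} s (max deviation "
                f"{np.max(np.abs(dt - np.median(dt))):.3g} s)"
            )
        expected = self.fs * (t[-1] - t[0])
        if abs(expected - (len(t) - 1)) > 0.5:
            raise DataError(
                f"sampling rate {self.fs} Hz inconsistent with time span "
                f"{t[-1] - t[0]:.6f} s over {len(t)} samples"
            )
        object.__setattr__(self, "t", t.astype(float))
        object.__setattr__(self, "ap", ap.astype(float))
        object.__setattr__(self, "ml", ml.astype(float))

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (span of the time base)."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class DirectionalSeries:
    """A single directional displacement series derived from a trial.

    AP and ML series are zero-mean signed displacements; the radial (Rad)
    series is the per-sample Euclidean distance from the mean COP point and
    is therefore nonnegative.  For Rad the underlying zero-mean AP and ML
    channels are retained so planar increments can be formed downstream.
    """

    direction: str
    fs: float
    x: np.ndarray
    ap: np.ndarray | None = None
    ml: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ParameterError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        x = np.asarray(self.x, dtype=float)
        if self.direction == "Rad":
            if np.any(x < 0):
                raise DataError("radial series must be nonnegative")
        object.__setattr__(self, "x", x)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    lowpass_cutoff : Hz
        Zero-phase Butterworth low-pass corner.  Postural sway power lies
        almost entirely below a few Hz; 10 Hz keeps the physiological band
        while rejecting measurement noise.
    target_fs : Hz
        Rate the trial is resampled to before analysis.  State-transition
        statistics are lag dependent, so the analysis rate is pinned.
    detrend : {"mean_remove"}
        Only per-channel mean removal is supported.
    """

    lowpass_cutoff: float = 10.0
    target_fs: float = 100.0
    detrend: str = "mean_remove"
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.lowpass_cutoff < self.target_fs / 2:
            raise ParameterError(
                "need 0 < lowpass_cutoff < target_fs/2, got "
                f"cutoff={self.lowpass_cutoff}, target_fs={self.target_fs}"
            )
        if self.detrend != "mean_remove":
            raise ParameterError(f"unsupported detrend mode {self.detrend!r}")


def load_cop_trial(
    path: str | os.PathLike,
    subject_id: str,
    condition: str,
    trial_index: int,
) -> CopTrial:
    """Read one trial from a delimited text file.

    The file must contain a header row with columns ``t_s``, ``cop_ap_mm``
    and ``cop_ml_mm``.  The sampling rate is inferred from the median time
    step.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path}: fewer than two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return CopTrial(
        subject_id=subject_id,
        condition=condition,
        trial_index=trial_index,
        fs=fs,
        t=t,
        ap=df["cop_ap_mm"].to_numpy(dtype=float),
        ml=df["cop_ml_mm"].to_numpy(dtype=float),
    )


def write_cop_trial(trial: CopTrial, path: str | os.PathLike) -> None:
    """Write a trial in the package's delimited-text dialect."""
    pd.DataFrame(
        {"t_s": trial.t, "cop_ap_mm": trial.ap, "cop_ml_mm": trial.ml}
    ).to_csv(path, index=False)


def trial_filename(trial: CopTrial) -> str:
    """Canonical ``subject_condition_trial.csv`` filename for a trial."""
    return f"{trial.subject_id}_{trial.condition}_{trial.trial_index:02d}.csv"


def preprocess(trial: CopTrial, cfg: PreprocessConfig | None = None) -> CopTrial:
    """Low-pass filter (zero phase), resample and mean-remove a trial.

    A trial that has already been preprocessed at the requested rate is only
    re-centred, which leaves it unchanged; preprocessing is therefore
    idempotent at a fixed target rate.
    """
    cfg = cfg or PreprocessConfig()
    if trial.preprocessed and abs(trial.fs - cfg.target_fs) < 1e-9:
        ap = trial.ap - trial.ap.mean()
        ml = trial.ml - trial.ml.mean()
        return dataclasses.replace(trial, ap=ap, ml=ml)

    # Two settle times of the filter (~3 time constants each) must fit.
    min_duration = 2.0 * 3.0 / cfg.lowpass_cutoff
    if trial.duration < min_duration:
        raise DataError(
            f"trial of {trial.duration:.3f} s is shorter than twice the "
            f"filter settle time ({min_duration:.3f} s at "
            f"{cfg.lowpass_cutoff} Hz cutoff)"
        )
    if cfg.target_fs > trial.fs:
        raise ParameterError(
            f"target_fs {cfg.target_fs} Hz exceeds trial rate {trial.fs} Hz"
        )

    sos = sps.butter(
        cfg.filter_order, cfg.lowpass_cutoff, btype="low", fs=trial.fs, output="sos"
    )
    ap = sps.sosfiltfilt(sos, trial.ap)
    ml = sps.sosfiltfilt(sos, trial.ml)

    if abs(trial.fs - cfg.target_fs) > 1e-9:
        from fractions import Fraction

        frac = Fraction(cfg.target_fs / trial.fs).limit_denominator(10000)
        ap = sps.resample_poly(ap, frac.numerator, frac.denominator, padtype="line")
        ml = sps.resample_poly(ml, frac.numerator, frac.denominator, padtype="line")

    ap = ap - ap.mean()
    ml = ml - ml.mean()
    t = np.arange(len(ap)) / cfg.target_fs
    return CopTrial(
        subject_id=trial.subject_id,
        condition=trial.condition,
        trial_index=trial.trial_index,
        fs=cfg.target_fs,
        t=t,
        ap=ap,
        ml=ml,
        preprocessed=True,
    )


def directional_series(trial: CopTrial, direction: str) -> DirectionalSeries:
    """Extract the AP, ML or radial displacement series from a trial.

    AP/ML are the mean-removed channels.  Rad is the per-sample Euclidean
    distance from the mean COP point.
    """
    if direction not in DIRECTIONS:
        raise ParameterError(
            f"direction must be one of {DIRECTIONS}, got {direction!r}"
        )
    ap = trial.ap - trial.ap.mean()
    ml = trial.ml - trial.ml.mean()
    if direction == "AP":
        return DirectionalSeries(direction="AP", fs=trial.fs, x=ap)
    if direction == "ML":
        return DirectionalSeries(direction="ML", fs=trial.fs, x=ml)
    rad = np.hypot(ap, ml)
    return DirectionalSeries(direction="Rad", fs=trial.fs, x=rad, ap=ap, ml=ml)


# ---------------------------------------------------------------------------
# Manifest: subject/condition/trial -> file path


def write_manifest(entries: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a manifest mapping (subject, condition, trial) to trial files."""
    required = {"subject_id", "condition", "trial_index", "path"}
    if not required.issubset(entries.columns):
        raise FormatError(f"manifest needs columns {sorted(required)}")
    entries.to_csv(path, index=False)


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "condition", "trial_index", "path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    if len(df) == 0:
        raise DataError(f"{path}: empty manifest")
    return df


def load_trials_from_manifest(
    manifest_path: str | os.PathLike,
) -> list[CopTrial]:
    """Load every trial listed in a manifest (paths relative to the manifest)."""
    df = load_manifest(manifest_path)
    base = os.path.dirname(os.fspath(manifest_path))
    trials = []
    for row in df.itertuples(index=False):
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        trials.append(
            load_cop_trial(
                p,
                subject_id=str(row.subject_id),
                condition=str(row.condition),
                trial_index=int(row.trial_index),
            )
        )
    return trials
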