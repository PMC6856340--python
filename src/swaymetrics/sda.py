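"""Stabilogram Diffusion Analysis (SDA).

The mean-square displacement (MSD) of the centre of pressure is computed as
a function of time lag,

    msd(dt) = < [x(t + dt) - x(t)]^2 >_t ,

averaged over all overlapping sample pairs.  Quiet-standing stabilograms
show two regimes: over short lags the sway drifts away from equilibrium
(persistent, effective scaling exponent H > 0.5) and over long lags it is
pulled back (antipersistent, H < 0.5).  The lag separating the regimes --
the critical point (dt_c, msd_c) -- is located at the first minimum of the
second derivative of the linear MSD curve.  Each regime is then summarized
by a diffusion coefficient D (one-half of the slope of a straight-line fit
to msd vs lag) and a scaling exponent H (one-half of the log-log slope,
from msd ~ dt^(2H)).

For the radial direction the MSD uses planar increments,
d r^2 = d ap^2 + d ml^2, i.e. the resultant planar stabilogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import DataError, FitError, ParameterError
from .signal import DirectionalSeries

__all__ = [
    "SdaConfig",
    "SdaCurve",
    "SdaResult",
    "mean_square_displacement",
    "critical_point",
    "fit_diffusion",
    "fit_scaling",
    "sda_summary",
]


@dataclass(frozen=True)
class SdaConfig:
    """SDA parameters.

    max_lag_s : s
        Longest lag evaluated; one third of a 30 s record keeps the
        high-variance tail of the MSD out of the fits.
    smoothing_window_s : s
        Width of the local quadratic (Savitzky-Golay) smoother applied
        before differentiating the MSD; the raw second difference of an
        empirical MSD is noise-dominated.
    search_range_s : (s, s)
        Lag interval searched for the critical point.
    short_margin, long_margin :
        The short-term region is fit on [first lag, short_margin * dt_c]
        and the long-term region on [long_margin * dt_c, max_lag], keeping
        both fits clear of the regime transition.
    """

    max_lag_s: float = 10.0
    smoothing_window_s: float = 0.5
    search_range_s: tuple[float, float] = (0.2, 5.0)
    short_margin: float = 0.9
    long_margin: float = 1.5


@dataclass(frozen=True)
class SdaCurve:
    """MSD (mm^2) on a uniform grid of positive lags (s)."""

    lags: np.ndarray
    msd: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        if len(lags) != len(msd):
            raise DataError("lags and msd must have equal length")
        if len(lags) == 0 or lags[0] <= 0 or np.any(np.diff(lags) <= 0):
            raise DataError("lags must be positive and increasing")
        if np.any(msd < 0):
            raise DataError("msd must be nonnegative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else float(self.lags[0])


@dataclass(frozen=True)
class SdaResult:
    """Fitted SDA parameters for one directional series.

    Sentinel NaNs mark quantities that could not be determined (e.g. no
    critical point on a single-regime curve); the reason is recorded in
    ``diagnostics``.
    """

    Ds: float
    Dl: float
    Hs: float
    Hl: float
    dt_c: float
    msd_c: float
    r2_short: float = np.nan
    r2_long: float = np.nan
    diagnostics: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {
            "Ds_mm2_s": self.Ds,
            "Dl_mm2_s": self.Dl,
            "Hs": self.Hs,
            "Hl": self.Hl,
            "dt_c_s": self.dt_c,
            "msd_c_mm2": self.msd_c,
        }


def _msd_1d(x: np.ndarray, max_lag_samples: int) -> np.ndarray:
    """MSD of one channel at lags 1..max_lag_samples (overlapping pairs)."""
    return np.array(
        [np.mean((x[k:] - x[:-k]) ** 2) for k in range(1, max_lag_samples + 1)]
    )


def mean_square_displacement(
    series: DirectionalSeries, max_lag_s: float = 10.0
) -> SdaCurve:
    """MSD versus lag for a directional series.

    AP/ML use scalar increments of the signed displacement.  Rad uses
    planar increments (d ap^2 + d ml^2) of the underlying zero-mean
    channels, which must be attached to the series.
    """
    n = len(series)
    max_lag = int(round(max_lag_s * series.fs))
    if max_lag < 1:
        raise ParameterError("max_lag_s shorter than one sample interval")
    if n < 2 * max_lag:
        raise ParameterError(
            f"series of {n} samples too short for max lag {max_lag} samples "
            "(need at least twice the lag)"
        )
    if series.direction == "Rad":
        if series.ap is None or series.ml is None:
            raise DataError(
                "radial MSD needs the underlying AP/ML channels; build the "
                "series with signal.directional_series"
            )
        msd = _msd_1d(series.ap, max_lag) + _msd_1d(series.ml, max_lag)
    else:
        msd = _msd_1d(series.x, max_lag)
    lags = np.arange(1, max_lag + 1) / series.fs
    return SdaCurve(lags=lags, msd=msd, direction=series.direction)


def _smooth(curve: SdaCurve, window_s: float) -> np.ndarray:
    w = int(round(window_s / curve.dt))
    w = max(w | 1, 5)  # odd, at least 5 points for a quadratic
    w = min(w, len(curve.msd) - (1 - len(curve.msd) % 2))
    if w < 5:
        return curve.msd.copy()
    return sps.savgol_filter(curve.msd, w, polyorder=2)


def critical_point(
    curve: SdaCurve,
    smoothing_window_s: float = 0.5,
    search_range_s: tuple[float, float] = (0.2, 5.0),
) -> tuple[float, float]:
    """Locate the regime transition of a stabilogram-diffusion curve.

    The MSD is smoothed by a local quadratic fit, its second derivative is
    formed by central differences on the uniform lag grid, and the critical
    lag is the first local minimum of that second derivative inside the
    search range.  Returns ``(nan, nan)`` with a warning when the curve has
    no interior minimum (single-regime data).
    """
    lo, hi = search_range_s
    if curve.lags[-1] < hi:
        hi = float(curve.lags[-1])
    if lo >= hi:
        raise ParameterError("empty critical-point search range")
    m = _smooth(curve, smoothing_window_s)
    d2 = np.full_like(m, np.nan)
    d2[1:-1] = (m[2:] - 2 * m[1:-1] + m[:-2]) / curve.dt**2
    in_range = (curve.lags >= lo) & (curve.lags <= hi)
    idx = np.flatnonzero(in_range)
    idx = idx[(idx > 1) & (idx < len(m) - 2)]
    if len(idx) == 0:
        raise ParameterError("no lags inside the critical-point search range")
    # Only dips that are appreciably concave count as minima: pure float
    # jitter on a straight line must not produce a critical point.
    floor = -1e-8 * np.max(np.abs(curve.msd)) / curve.dt**2
    for i in idx:
        if d2[i] < d2[i - 1] and d2[i] <= d2[i + 1] and d2[i] < floor:
            return float(curve.lags[i]), float(m[i])
    warnings.warn(
        "no critical point found: second derivative has no interior minimum "
        "in the search range",
        stacklevel=2,
    )
    return float("nan"), float("nan")


def _region_mask(curve: SdaCurve, region: tuple[float, float]) -> np.ndarray:
    lo, hi = region
    return (curve.lags >= lo) & (curve.lags <= hi)


def fit_diffusion(curve: SdaCurve, region: tuple[float, float]) -> tuple[float, float]:
    """Diffusion coefficient D (mm^2/s) in a lag region.

    D is one-half of the slope of the least-squares line through
    (lag, msd).  Returns ``(D, r_squared)``.
    """
    mask = _region_mask(curve, region)
    if mask.sum() < 3:
        raise FitError(
            f"fewer than 3 lags in region [{region[0]:.3g}, {region[1]:.3g}] s"
        )
    res = stats.linregress(curve.lags[mask], curve.msd[mask])
    return float(res.slope) / 2.0, float(res.rvalue**2)


def fit_scaling(curve: SdaCurve, region: tuple[float, float]) -> float:
    """Scaling exponent H in a lag region, from msd ~ dt^(2H).

    H is one-half of the slope of the least-squares line through
    (log lag, log msd).
    """
    mask = _region_mask(curve, region)
    if mask.sum() < 3:
        raise FitError(
            f"fewer than 3 lags in region [{region[0]:.3g}, {region[1]:.3g}] s"
        )
    msd = curve.msd[mask]
    if np.any(msd <= 0):
        raise FitError("nonpositive msd in region: log-log fit undefined")
    res = stats.linregress(np.log(curve.lags[mask]), np.log(msd))
    return float(res.slope) / 2.0


def sda_summary(
    series: DirectionalSeries, cfg: SdaConfig | None = None
) -> SdaResult:
    """Full SDA of one directional series: curve, critical point, regime fits."""
    cfg = cfg or SdaConfig()
    curve = mean_square_displacement(series, cfg.max_lag_s)
    diagnostics: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        dt_c, msd_c = critical_point(
            curve, cfg.smoothing_window_s, cfg.search_range_s
        )
        diagnostics.extend(str(w.message) for w in caught)
    if np.isnan(dt_c):
        return SdaResult(
            Ds=np.nan, Dl=np.nan, Hs=np.nan, Hl=np.nan,
            dt_c=np.nan, msd_c=np.nan, diagnostics=tuple(diagnostics),
        )
    short = (float(curve.lags[0]), cfg.short_margin * dt_c)
    long = (cfg.long_margin * dt_c, cfg.max_lag_s)
    try:
        Ds, r2_s = fit_diffusion(curve, short)
        Hs = fit_scaling(curve, short)
    except FitError as exc:
        diagnostics.append(f"short-term fit failed: {exc}")
        Ds = Hs = r2_s = np.nan
    try:
        Dl, r2_l = fit_diffusion(curve, long)
        Hl = fit_scaling(curve, long)
    except FitError as exc:
        diagnostics.append(f"long-term fit failed: {exc}")
        Dl = Hl = r2_l = np.nan
    return SdaResult(
        Ds=Ds, Dl=Dl, Hs=Hs, Hl=Hl, dt_c=dt_c, msd_c=msd_c,
        r2_short=r2_s, r2_long=r2_l, diagnostics=tuple(diagnostics),
    )
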