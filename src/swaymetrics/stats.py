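"""Paired condition comparison of sway measures.

Each subject's trials are averaged within condition, then every measure is
compared across the two conditions with a two-tailed paired t-test
(alpha = 0.05) and Cohen's d for paired samples,

    t = mean(diff) / (sd(diff) / sqrt(n)),    d = |mean(diff)| / sd(diff),

so that d = |t| / sqrt(n).  Differences are taken as ON minus OFF: a
negative t means the measure decreased under augmented feedback.  p values
between 0.05 and 0.10 are flagged as a tendency; no multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DataError, PairingError, ParameterError
from .signal import SSD_OFF, SSD_ON

__all__ = [
    "paired_t",
    "cohens_dz",
    "eta2_to_f",
    "significance_flag",
    "compare_conditions",
]

ALPHA_SIGNIFICANT = 0.05
ALPHA_TENDENCY = 0.10

#: Measures produced by the analysis pipeline, in report order.
MEASURE_COLUMNS = (
    "P_peak",
    "D_bar_mm",
    "D95_mm",
    "lambda2",
    "H_bits",
    "z_lambda2_mm",
    "Ds_mm2_s",
    "Dl_mm2_s",
    "Hs",
    "Hl",
    "dt_c_s",
    "msd_c_mm2",
)


def _paired_diff(off: np.ndarray, on: np.ndarray) -> np.ndarray:
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    if off.shape != on.shape or off.ndim != 1:
        raise DataError("paired samples must be 1-D arrays of equal length")
    if len(off) < 2:
        raise DataError("need at least 2 pairs")
    return on - off


def paired_t(off: np.ndarray, on: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed paired t-test of ON vs OFF; returns (t, df, p).

    Identical vectors give t = 0, p = 1.  A nonzero constant difference
    has zero variance and no defined t; that raises :class:`DataError`.
    """
    diff = _paired_diff(off, on)
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return 0.0, n - 1, 1.0
        raise DataError("all pairwise differences identical and nonzero")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p)


def cohens_dz(off: np.ndarray, on: np.ndarray) -> float:
    """Cohen's d for paired samples: |mean difference| / sd of differences."""
    diff = _paired_diff(off, on)
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return 0.0
        raise DataError("all pairwise differences identical and nonzero")
    return float(abs(diff.mean()) / sd)


def eta2_to_f(partial_eta2: float) -> float:
    """Convert partial eta squared to Cohen's f: f = sqrt(eta2 / (1 - eta2))."""
    if not 0.0 <= partial_eta2 < 1.0:
        raise ParameterError("partial eta squared must be in [0, 1)")
    return float(np.sqrt(partial_eta2 / (1.0 - partial_eta2)))


def significance_flag(p: float) -> str:
    """'significant' (p < 0.05), 'tendency' (0.05 <= p < 0.10) or 'ns'."""
    if p < ALPHA_SIGNIFICANT:
        return "significant"
    if p < ALPHA_TENDENCY:
        return "tendency"
    return "ns"


@dataclass(frozen=True)
class ComparisonTable:
    """Per-measure paired statistics across conditions."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def formatted(self) -> str:
        """Human-readable table: mean (sd) per condition, t, d, p, flag."""
        rows = []
        for r in self.table.itertuples(index=False):
            rows.append(
                f"{r.measure:>12}  {r.direction:>3}  "
                f"{r.mean_off:10.4g} ({r.sd_off:.3g})  "
                f"{r.mean_on:10.4g} ({r.sd_on:.3g})  "
                f"t({r.df})={r.t:6.2f}  d={r.d:4.2f}  p={r.p:5.3f}  {r.flag}"
            )
        header = (
            f"{'measure':>12}  {'dir':>3}  {'OFF mean (sd)':>20}  "
            f"{'ON mean (sd)':>20}   paired t, Cohen's d, p"
        )
        return "\n".join([header, *rows])


def subject_means(results: pd.DataFrame) -> pd.DataFrame:
    """Average trials within (subject, condition, direction) for every measure."""
    measures = [c for c in MEASURE_COLUMNS if c in results.columns]
    if not measures:
        raise DataError("results contain none of the known measure columns")
    return (
        results.groupby(["subject_id", "condition", "direction"], sort=True)[measures]
        .mean()
        .reset_index()
    )


def compare_conditions(results: pd.DataFrame) -> ComparisonTable:
    """Build the per-measure paired comparison table for a cohort.

    ``results`` holds one row per (subject, condition, trial, direction)
    with measure columns.  Trials are first averaged per subject and
    condition; each measure in each direction is then tested ON vs OFF.
    Sentinel NaN trials are excluded from the averages.
    """
    required = {"subject_id", "condition", "direction"}
    missing = required - set(results.columns)
    if missing:
        raise DataError(f"results missing columns {sorted(missing)}")
    means = subject_means(results)
    subj_off = set(means.loc[means.condition == SSD_OFF, "subject_id"])
    subj_on = set(means.loc[means.condition == SSD_ON, "subject_id"])
    if subj_off != subj_on:
        unpaired = sorted(subj_off ^ subj_on)
        raise PairingError(f"subjects missing a condition: {unpaired}")
    subjects = sorted(subj_off)
    measures = [c for c in MEASURE_COLUMNS if c in means.columns]
    rows = []
    for direction in sorted(means.direction.unique()):
        sub = means[means.direction == direction]
        off = sub[sub.condition == SSD_OFF].set_index("subject_id").loc[subjects]
        on = sub[sub.condition == SSD_ON].set_index("subject_id").loc[subjects]
        for m in measures:
            a, b = off[m].to_numpy(), on[m].to_numpy()
            finite = np.isfinite(a) & np.isfinite(b)
            if finite.sum() < 2:
                rows.append(
                    {
                        "measure": m, "direction": direction,
                        "mean_off": np.nan, "sd_off": np.nan,
                        "mean_on": np.nan, "sd_on": np.nan,
                        "t": np.nan, "df": 0, "d": np.nan, "p": np.nan,
                        "flag": "ns",
                    }
                )
                continue
            a, b = a[finite], b[finite]
            try:
                t, df, p = paired_t(a, b)
                d = cohens_dz(a, b)
            except DataError:
                # zero variance of a nonzero difference (e.g. a measure
                # quantized to a coarse grid): undetermined, not an error
                t = d = p = np.nan
                df = len(a) - 1
            rows.append(
                {
                    "measure": m,
                    "direction": direction,
                    "mean_off": a.mean(),
                    "sd_off": a.std(ddof=1),
                    "mean_on": b.mean(),
                    "sd_on": b.std(ddof=1),
                    "t": t,
                    "df": df,
                    "d": d,
                    "p": p,
                    "flag": "ns" if np.isnan(p) else significance_flag(p),
                }
            )
    return ComparisonTable(table=pd.DataFrame(rows))
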