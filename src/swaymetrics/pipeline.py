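"""End-to-end analysis: trials -> per-trial IDA + SDA measure table.

Bin geometries for the Markov-chain discretization are pooled per direction
across every trial being analyzed, so all trials of a comparison share one
state space (entropies on different state spaces are not comparable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ida, sda
from .errors import DataError
from .signal import DIRECTIONS, CopTrial, PreprocessConfig, directional_series, preprocess

__all__ = ["AnalysisConfig", "analyze_cohort"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the combined IDA + SDA pipeline."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_states: int = ida.DEFAULT_N_STATES
    lag: int = ida.DEFAULT_LAG
    epsilon: float = ida.DEFAULT_EPSILON
    sda: sda.SdaConfig = field(default_factory=sda.SdaConfig)


def analyze_cohort(
    trials: list[CopTrial], cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Run IDA and SDA on every trial in all three directions.

    Returns one row per (subject, condition, trial, direction) with all
    twelve measure columns.
    """
    cfg = cfg or AnalysisConfig()
    if not trials:
        raise DataError("no trials to analyze")
    pre = [preprocess(tr, cfg.preprocess) for tr in trials]
    series = {
        d: [directional_series(tr, d) for tr in pre] for d in DIRECTIONS
    }
    bins = {d: ida.make_bins(series[d], cfg.n_states) for d in DIRECTIONS}
    rows = []
    for i, tr in enumerate(pre):
        for d in DIRECTIONS:
            s = series[d][i]
            ida_res = ida.analyze_series(s, bins[d], lag=cfg.lag, epsilon=cfg.epsilon)
            sda_res = sda.sda_summary(s, cfg.sda)
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "condition": tr.condition,
                    "trial_index": tr.trial_index,
                    "direction": d,
                    **ida_res.as_dict(),
                    **sda_res.as_dict(),
                }
            )
    return pd.DataFrame(rows)
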