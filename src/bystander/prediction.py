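"""Cross-experiment out-of-sample prediction.

One experiment's group-averaged winning-model function is applied to
the other experiment's trials (the regressors share scales across the
two designs), and the predictions are scored per participant by
regressing observed standardized responses on predicted ones. Good
generalization means slopes near 1, intercepts near 0 and high r²,
assessed by group-level one-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, InsufficientDataError
from .features import FEATURE_COLUMNS, add_features
from .fitting import fit_ols
from .simulate import linear_prediction


def predict_from_function(
    coefficients: dict[str, float], schedule: pd.DataFrame
) -> np.ndarray:
    """Deterministic per-trial prediction from a group coefficient map.

    Features are computed from the schedule if absent.
    """
    if not set(FEATURE_COLUMNS) <= set(schedule.columns):
        schedule = add_features(schedule)
    return linear_prediction(schedule, coefficients)


@dataclass
class PredictionEvaluation:
    """Per-participant calibration fits and their group-level summary."""

    per_participant: pd.DataFrame  # participant, slope, intercept, r2
    summary: dict  # means ± sem, t-tests of slope vs 1 and intercept vs 0

    @property
    def mean_r2(self) -> float:
        return float(self.per_participant["r2"].mean())


def evaluate_prediction(
    data: pd.DataFrame,
    observed: str = "feeling",
    predicted: str = "predicted",
) -> PredictionEvaluation:
    """Score predictions by per-participant OLS of observed on predicted.

    ``data`` holds paired ``observed`` and ``predicted`` columns plus
    ``participant``; rows with a missing observation are ignored. Group
    tests: one-sample t of slopes against 1 and intercepts against 0.
    """
    rows = []
    for pid, grp in data.groupby("participant"):
        grp = grp[grp[observed].notna() & grp[predicted].notna()]
        if len(grp) < 3:
            raise InsufficientDataError(f"participant {pid}: fewer than 3 paired trials")
        x = grp[predicted].to_numpy(dtype=float)
        y = grp[observed].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise DegenerateInputError(f"participant {pid}: constant predicted series")
        res = fit_ols(np.column_stack([np.ones(len(x)), x]), y)
        rows.append(
            {
                "participant": pid,
                "intercept": float(res["coefficients"][0]),
                "slope": float(res["coefficients"][1]),
                "r2": res["r2"],
            }
        )
    per = pd.DataFrame(rows)

    slopes = per["slope"].to_numpy()
    intercepts = per["intercept"].to_numpy()
    n = len(per)
    summary = {
        "n_participants": n,
        "mean_r2": float(per["r2"].mean()),
        "sem_r2": float(per["r2"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "slope_mean": float(slopes.mean()),
        "slope_sem": float(slopes.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "intercept_mean": float(intercepts.mean()),
        "intercept_sem": float(intercepts.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
    }
    if n > 1 and slopes.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(slopes, 1.0)
        summary.update(slope_t=float(t), slope_df=n - 1, slope_p=float(p))
    if n > 1 and intercepts.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(intercepts, 0.0)
        summary.update(intercept_t=float(t), intercept_df=n - 1, intercept_p=float(p))
    return PredictionEvaluation(per_participant=per, summary=summary)
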