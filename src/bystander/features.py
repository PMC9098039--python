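"""Trial regressors: selfishness, inequality, endowment scaling, even-split stick.

Selfishness is the fraction of the endowment the allocator ends up with
(taken share in experiment 1; kept share, i.e. 1 − given, in
experiment 2). Inequality is the absolute difference between the two
players' final shares, which on the fraction scale is exactly
``|2·selfishness − 1|``. The even-split "stick" is an indicator active
only at the exact 50/50 split; the 10%-step design grid makes exact
comparison safe. Endowment is standardized on the design grid (mean 8,
population spread of the discrete uniform 1..15), and the interaction
terms are products of the scaled regressors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError

#: Canonical regressor order used throughout the package.
REGRESSORS = ("selfishness", "inequality", "self_x_endow", "even_split", "ineq_x_endow")

#: Feature columns appended to a trials table.
FEATURE_COLUMNS = ("selfishness", "inequality", "endow_z", "even_split",
                   "self_x_endow", "ineq_x_endow")

ENDOWMENT_MEAN = 8.0
#: Population spread of the discrete uniform grid 1..15 (≈ 4.3205).
ENDOWMENT_SD = float(np.sqrt(np.mean((np.arange(1, 16) - ENDOWMENT_MEAN) ** 2)))

_GRID = {1: set(range(10, 101, 10)), 2: set(range(0, 91, 10))}


def selfishness_fraction(experiment_id, allocation_pct):
    """Fraction of the endowment the allocator keeps for themselves.

    Experiment 1: the allocation is the percent *taken*, so the share
    kept is ``allocation_pct / 100``. Experiment 2: the allocation is
    the percent *given* away, so the share kept is
    ``1 − allocation_pct / 100``.
    """
    if experiment_id not in (1, 2):
        raise ValueError(f"experiment_id must be 1 or 2, got {experiment_id!r}")
    pct = np.asarray(allocation_pct)
    if not np.isin(pct, list(_GRID[experiment_id])).all():
        raise ValueError(
            f"allocation_pct off the experiment {experiment_id} grid: {allocation_pct!r}"
        )
    frac = pct / 100.0 if experiment_id == 1 else 1.0 - pct / 100.0
    return float(frac) if np.isscalar(allocation_pct) else frac


def inequality_fraction(selfishness):
    """Absolute difference between the players' final shares, |2s − 1|."""
    s = np.asarray(selfishness, dtype=float)
    if (s < 0).any() or (s > 1).any():
        raise ValueError(f"selfishness must lie in [0, 1], got {selfishness!r}")
    out = np.abs(2.0 * s - 1.0)
    return float(out) if np.isscalar(selfishness) else out


def even_split_indicator(selfishness):
    """1 exactly at the 50/50 split, else 0."""
    s = np.asarray(selfishness, dtype=float)
    out = (s == 0.5).astype(int)
    return int(out) if np.isscalar(selfishness) else out


def scale_endowment(endowment):
    """Standardize endowment on the design grid: (e − 8) / σ_grid."""
    e = np.asarray(endowment, dtype=float)
    if (e < 1).any() or (e > 15).any():
        raise ValueError(f"endowment must lie in 1..15, got {endowment!r}")
    out = (e - ENDOWMENT_MEAN) / ENDOWMENT_SD
    return float(out) if np.isscalar(endowment) else out


def classify_allocator(selfishness):
    """Partition trials into 'selfish' (>0.5), 'equal' (=0.5), 'generous' (<0.5)."""
    s = np.asarray(selfishness, dtype=float)
    if (s < 0).any() or (s > 1).any():
        raise ValueError(f"selfishness must lie in [0, 1], got {selfishness!r}")
    out = np.where(s > 0.5, "selfish", np.where(s == 0.5, "equal", "generous"))
    return str(out) if np.isscalar(selfishness) else out


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample spread 1 (n − 1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"zscore needs at least 2 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot z-score a constant series (zero spread)")
    return (x - x.mean()) / sd


def add_features(trials: pd.DataFrame) -> pd.DataFrame:
    """Append the regressor columns to a trials table.

    Handles tables mixing both experiments (the selfishness mapping is
    applied per experiment). Returns a copy with
    :data:`FEATURE_COLUMNS` added.
    """
    out = trials.copy()
    s = np.empty(len(out), dtype=float)
    for exp in out["experiment"].unique():
        mask = (out["experiment"] == exp).to_numpy()
        s[mask] = selfishness_fraction(int(exp), out.loc[mask, "allocation_pct"].to_numpy())
    out["selfishness"] = s
    out["inequality"] = inequality_fraction(s)
    out["endow_z"] = scale_endowment(out["endowment_gbp"].to_numpy())
    out["even_split"] = even_split_indicator(s)
    out["self_x_endow"] = out["selfishness"] * out["endow_z"]
    out["ineq_x_endow"] = out["inequality"] * out["endow_z"]
    return out
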