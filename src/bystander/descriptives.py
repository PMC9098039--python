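"""Behavioral descriptives: allocator-type summaries, ANOVA, t-tests,
and the feelings–punishment coupling.

Trials are partitioned by allocator type (selfish / equal / generous
splits). Punishment is recorded as the fraction of the allocator's
punishable amount; deductions below 1% count as non-punishment (slider
motor-error allowance), at or above 1% as punishment. Allocator-type
effects are tested with one-way repeated-measures ANOVAs (uncorrected
degrees of freedom, partial η² effect size) and followed up with
paired t-tests with Cohen's d.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .exceptions import (
    DataError,
    DegenerateInputError,
    InsufficientDataError,
    SchemaError,
)
from .features import classify_allocator, zscore

#: Punishment fractions below this count as non-punishment.
PUNISHMENT_THRESHOLD = 0.01

ALLOCATOR_TYPES = ("selfish", "equal", "generous")


def _with_allocator_type(data: pd.DataFrame) -> pd.DataFrame:
    if "allocator_type" in data.columns:
        return data
    if "selfishness" not in data.columns:
        raise SchemaError("need a 'selfishness' or 'allocator_type' column")
    out = data.copy()
    out["allocator_type"] = classify_allocator(out["selfishness"].to_numpy())
    return out


def feeling_summary(data: pd.DataFrame, response: str = "feeling") -> pd.DataFrame:
    """Mean feeling per participant per allocator type (collected trials only)."""
    data = _with_allocator_type(data)
    data = data[data[response].notna()]
    return (
        data.groupby(["participant", "allocator_type"])[response]
        .mean()
        .unstack("allocator_type")
        .reindex(columns=list(ALLOCATOR_TYPES))
    )


def punishment_metrics(data: pd.DataFrame, response: str = "punishment") -> pd.DataFrame:
    """Punishment frequency and mean amount per participant per allocator type.

    The punishment column must be a fraction of the punishable amount
    in [0, 1]. Frequency is the proportion of trials with a deduction
    of at least 1%; amount is the mean fraction over all trials of the
    category.
    """
    data = _with_allocator_type(data)
    data = data[data[response].notna()]
    vals = data[response].to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise DataError("punishment fractions must lie in [0, 1]")
    out = data.assign(punished=(data[response] >= PUNISHMENT_THRESHOLD).astype(float))
    agg = out.groupby(["participant", "allocator_type"]).agg(
        frequency=("punished", "mean"), mean_amount=(response, "mean")
    )
    return agg.reset_index()


def one_way_rm_anova(wide: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA on a participants × conditions matrix.

    Returns F, df1, df2, p (uncorrected) and partial η²
    (SS_effect / (SS_effect + SS_error)). No sphericity correction is
    applied.
    """
    if wide.isna().any().any():
        raise SchemaError("repeated-measures ANOVA requires a complete matrix")
    if len(wide) < 3:
        raise InsufficientDataError(f"need >= 3 participants, got {len(wide)}")
    vals = wide.to_numpy(dtype=float)
    n, k = vals.shape
    ss_effect = n * float(((vals.mean(axis=0) - vals.mean()) ** 2).sum())
    if ss_effect == 0:  # identical condition means: no effect by definition
        return {"F": 0.0, "df1": k - 1, "df2": (k - 1) * (n - 1), "p": 1.0,
                "partial_eta_sq": 0.0}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-error matrices produce benign divide warnings
        res = pg.rm_anova(wide.reset_index(drop=True), effsize="np2")
    row = res.iloc[0]
    return {
        "F": float(row["F"]),
        "df1": int(row["ddof1"]),
        "df2": int(row["ddof2"]),
        "p": float(row["p_unc"]),
        "partial_eta_sq": float(row["np2"]),
    }


def paired_and_one_sample_tests(a, b=None, mu: float = 0.0) -> dict:
    """Two-sided t-test with Cohen's d.

    One-sample against ``mu`` when ``b`` is None (d = (mean − mu)/sd),
    else paired (d = mean diff / sd of diffs).
    """
    a = np.asarray(a, dtype=float)
    if b is None:
        diffs = a - mu
    else:
        b = np.asarray(b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired series must have equal length")
        diffs = a - b
    if len(diffs) < 2:
        raise InsufficientDataError("need >= 2 observations")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero spread; t-test undefined")
    t = diffs.mean() / (sd / np.sqrt(len(diffs)))
    df = len(diffs) - 1
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(p), "cohens_d": float(diffs.mean() / sd)}


def feelings_punishment_correlation(
    data: pd.DataFrame, feeling: str = "feeling", punishment: str = "punishment"
) -> tuple[pd.DataFrame, dict]:
    """Per-participant Pearson r between standardized feelings and
    punishment on trials carrying both, plus a group one-sample t of
    the r values against zero.

    Returns ``(per_participant, group)`` where ``per_participant`` has
    columns participant, r, n_trials.
    """
    rows = []
    for pid, grp in data.groupby("participant"):
        paired = grp[grp[feeling].notna() & grp[punishment].notna()]
        if len(paired) < 3:
            raise InsufficientDataError(f"participant {pid}: fewer than 3 paired trials")
        f = zscore(paired[feeling].to_numpy())
        p = zscore(paired[punishment].to_numpy())
        r, _ = stats.pearsonr(f, p)
        rows.append({"participant": pid, "r": float(r), "n_trials": len(paired)})
    per = pd.DataFrame(rows)
    rs = per["r"].to_numpy()
    if rs.std(ddof=1) == 0:
        # every participant has the identical r (e.g. exact coupling):
        # the t statistic degenerates to a sign
        mean = float(rs.mean())
        t = float(np.sign(mean)) * np.inf if mean != 0 else 0.0
        group = {"t": t, "df": len(rs) - 1, "p": 0.0 if mean != 0 else 1.0,
                 "cohens_d": t}
    else:
        group = paired_and_one_sample_tests(rs)
    group["mean_r"] = float(per["r"].mean())
    return per, group
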