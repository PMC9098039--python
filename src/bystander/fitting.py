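"""Per-participant OLS fitting, BIC scoring and group-level model selection.

Every candidate model is an ordinary least-squares regression of a
participant's (optionally z-scored) responses on a subset of the trial
regressors plus a constant, fitted separately per participant. Models
are compared at the group level by summing each model's BIC across
participants; the winner is the model with the smallest sum, with ties
broken deterministically towards the lowest model id.

BIC uses the Gaussian concentrated log-likelihood form
``n·ln(RSS/n) + k·ln(n)`` with ``k`` counting the constant plus the
regressors. The noise variance is not counted: it would add an equal
offset to every model and cannot change the ranking.

The estimator surface follows scikit-learn conventions:
:class:`TrialRegression` fits one model spec, :class:`NestedModelSelector`
fits the whole space over a cohort. The module-level functions are thin
wrappers used by the rest of the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    DegenerateDesignError,
    DegenerateInputError,
    InsufficientDataError,
    SchemaError,
)
from .features import REGRESSORS, zscore
from .models import MODEL_SPACE, ModelSpec, build_design_matrix

logger = logging.getLogger(__name__)


def fit_ols(X: np.ndarray, y: np.ndarray) -> dict:
    """Least-squares fit of ``y`` on a full design matrix ``X``
    (constant column included by the caller).

    Returns coefficients, RSS, r², the unbiased residual spread
    ``sqrt(RSS / (n − k))`` with ``k`` the number of columns, and n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)} values")
    if n < k + 1:
        raise InsufficientDataError(f"need at least {k + 1} observations for {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise DegenerateDesignError("design matrix is rank deficient")

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    residual_sd = math.sqrt(rss / (n - k)) if n > k else 0.0
    return {
        "coefficients": coef,
        "rss": rss,
        "r2": r2,
        "residual_sd": residual_sd,
        "n": n,
    }


def bic(n: int, rss: float, k_params: int) -> float:
    """Gaussian concentrated-likelihood BIC: ``n·ln(rss/n) + k·ln(n)``."""
    if n <= 0 or k_params < 1:
        raise ValueError("n must be positive and k_params >= 1")
    if rss <= 0:
        raise DegenerateInputError("BIC undefined for a perfect fit (rss <= 0)")
    return n * math.log(rss / n) + k_params * math.log(n)


class TrialRegression(RegressorMixin, BaseEstimator):
    """OLS of a response on a subset of trial regressors plus a constant.

    Parameters
    ----------
    regressors : tuple of str
        Subset of the canonical regressors, default the full set.

    Attributes (after :meth:`fit`)
    ------------------------------
    intercept_ : float
    coef_ : ndarray aligned with ``regressors_used_`` (canonical order)
    rss_, r2_, residual_sd_, bic_, n_obs_ : fit summaries
    """

    def __init__(self, regressors: tuple[str, ...] = REGRESSORS):
        self.regressors = regressors

    def _spec(self) -> ModelSpec:
        return ModelSpec(0, tuple(self.regressors))

    def fit(self, X: pd.DataFrame, y):
        spec = self._spec()
        y = np.asarray(y, dtype=float)
        Xd = build_design_matrix(X, spec)
        if len(y) < Xd.shape[1] + 1:
            raise InsufficientDataError(
                f"need >= {Xd.shape[1] + 1} trials to fit {Xd.shape[1]} parameters"
            )
        res = fit_ols(Xd, y)
        self.regressors_used_ = tuple(r for r in REGRESSORS if r in spec.regressors)
        self.intercept_ = float(res["coefficients"][0])
        self.coef_ = np.asarray(res["coefficients"][1:])
        self.rss_ = res["rss"]
        self.r2_ = res["r2"]
        self.residual_sd_ = res["residual_sd"]
        self.n_obs_ = res["n"]
        self.bic_ = bic(res["n"], res["rss"], Xd.shape[1]) if res["rss"] > 0 else -math.inf
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = build_design_matrix(X, self._spec())
        return Xd @ np.concatenate([[self.intercept_], self.coef_])

    def coefficients(self) -> dict[str, float]:
        """Named coefficient map including the constant."""
        out = {"const": self.intercept_}
        out.update(dict(zip(self.regressors_used_, self.coef_)))
        return out


def fit_cohort(
    data: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    standardize: bool = True,
    response: str = "feeling",
) -> pd.DataFrame:
    """Fit every spec to every participant's responses.

    ``data`` must carry ``participant``, the feature columns and the
    response column; rows with a missing response are ignored, so
    participants with incomplete blocks are fitted on their available
    trials. With ``standardize`` the response is z-scored within
    participant first; a participant with constant responses is flagged
    and skipped with a warning rather than aborting the cohort.

    Returns a long table with one row per participant × spec:
    participant, model_id, const, one column per canonical regressor
    (NaN where the model omits it), r2, bic, n, residual_sd.
    """
    if specs is None:
        specs = MODEL_SPACE
    if response not in data.columns:
        raise SchemaError(f"response column {response!r} not in table")

    rows = []
    for pid, grp in data.groupby("participant"):
        grp = grp[grp[response].notna()]
        y = grp[response].to_numpy(dtype=float)
        if len(y) == 0:
            continue
        if standardize:
            try:
                y = zscore(y)
            except DegenerateInputError:
                logger.warning(
                    "participant %s has constant %s responses; skipped", pid, response
                )
                continue
        for spec in specs:
            est = TrialRegression(spec.regressors).fit(grp, y)
            row = {"participant": pid, "model_id": spec.model_id, "const": est.intercept_}
            row.update({r: np.nan for r in REGRESSORS})
            row.update(dict(zip(est.regressors_used_, est.coef_)))
            row.update(
                r2=est.r2_, bic=est.bic_, n=est.n_obs_, residual_sd=est.residual_sd_
            )
            rows.append(row)
    if not rows:
        raise InsufficientDataError("no participant could be fitted")
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Group-level model ranking by summed BIC."""

    table: pd.DataFrame  # model_id, summed_bic, delta_bic, rank
    winner_id: int

    @property
    def margin(self) -> float:
        """ΔBIC between the best and second-best models."""
        ordered = self.table.sort_values("rank")
        if len(ordered) < 2:
            return math.inf
        return float(ordered["delta_bic"].iloc[1])


def compare_models(fits: pd.DataFrame) -> GroupComparison:
    """Sum BIC across participants per model and rank the models.

    Requires a complete participant × model grid. The winner is the
    model with the lowest summed BIC; exact ties go to the lowest
    model id.
    """
    counts = fits.pivot_table(index="participant", columns="model_id", values="bic")
    if counts.isna().any().any():
        missing = [
            (p, int(m)) for p, m in zip(*np.where(counts.isna().to_numpy()))
        ]
        raise SchemaError(f"missing (participant, model) fits: {missing[:5]}")
    summed = fits.groupby("model_id")["bic"].sum().rename("summed_bic").reset_index()
    summed = summed.sort_values(["summed_bic", "model_id"], kind="stable").reset_index(drop=True)
    summed["delta_bic"] = summed["summed_bic"] - summed["summed_bic"].iloc[0]
    summed["rank"] = np.arange(1, len(summed) + 1)
    winner_id = int(summed["model_id"].iloc[0])
    return GroupComparison(table=summed.sort_values("model_id").reset_index(drop=True),
                           winner_id=winner_id)


def group_coefficient_tests(fits_one_model: pd.DataFrame) -> pd.DataFrame:
    """One-sample t-tests of each coefficient against zero across participants.

    Input is the fits table restricted to a single model. Returns one
    row per term (constant first): mean, sem, 95% CI from the t
    distribution, t, df, p.
    """
    if fits_one_model["model_id"].nunique() != 1:
        raise SchemaError("group_coefficient_tests expects fits for exactly one model")
    n = fits_one_model["participant"].nunique()
    if n < 3:
        raise InsufficientDataError(f"need >= 3 participants, got {n}")

    terms = ["const"] + [
        r for r in REGRESSORS if fits_one_model[r].notna().all()
    ]
    rows = []
    for term in terms:
        vals = fits_one_model[term].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"coefficient {term!r} has zero spread across participants")
        mean = vals.mean()
        sem = sd / math.sqrt(len(vals))
        t, p = stats.ttest_1samp(vals, 0.0)
        lo, hi = stats.t.interval(0.95, len(vals) - 1, loc=mean, scale=sem)
        rows.append(
            {
                "term": term,
                "mean": mean,
                "sem": sem,
                "ci95_low": lo,
                "ci95_high": hi,
                "t": float(t),
                "df": len(vals) - 1,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


class NestedModelSelector(BaseEstimator):
    """Fit the whole nested model space to a cohort and select by summed BIC.

    Parameters
    ----------
    specs : list of ModelSpec or None
        Candidate models; default the full 31-member space.
    standardize : bool
        z-score each participant's responses before fitting.
    response : str
        Response column name ('feeling' or 'punishment').

    Attributes (after :meth:`fit`)
    ------------------------------
    fits_ : per participant × model fit table
    comparison_ : :class:`GroupComparison`
    winner_id_ : selected model id
    winner_spec_ : the selected :class:`ModelSpec`
    """

    def __init__(self, specs=None, standardize: bool = True, response: str = "feeling"):
        self.specs = specs
        self.standardize = standardize
        self.response = response

    def fit(self, data: pd.DataFrame, y=None):
        specs = self.specs if self.specs is not None else MODEL_SPACE
        self.fits_ = fit_cohort(
            data, specs, standardize=self.standardize, response=self.response
        )
        self.comparison_ = compare_models(self.fits_)
        self.winner_id_ = self.comparison_.winner_id
        self.winner_spec_ = next(s for s in specs if s.model_id == self.winner_id_)
        return self

    def coefficient_tests(self, model_id: int | None = None) -> pd.DataFrame:
        """Group-level coefficient tests for the winner (or a given model)."""
        mid = self.winner_id_ if model_id is None else model_id
        return group_coefficient_tests(self.fits_[self.fits_["model_id"] == mid])
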