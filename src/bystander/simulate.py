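"""Synthetic-participant generator.

Responses are generated from a linear model on the trial regressors
plus additive Gaussian noise: feeling ratings and punishment choices
live on the same standardized (z-scored) scale the fitting operates
on; ratings are not re-discretized to the −3..+3 slider. The printed
group-level winning-model equations for both experiments ship as
module constants so cohorts with the published structure can be
simulated directly, optionally with across-participant coefficient
heterogeneity whose default spreads derive from the published
standard errors (sd = SEM·√n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .features import FEATURE_COLUMNS, add_features
from .models import ModelSpec, winning_model

#: Group-level winning-model (model 26) coefficients, standardized response scale.
EXP1_FEELING_COEF = {
    "const": 1.7, "selfishness": -1.86, "inequality": -0.52,
    "self_x_endow": -0.44, "even_split": 0.70,
}
EXP2_FEELING_COEF = {
    "const": 1.1, "selfishness": -0.88, "inequality": -1.10,
    "self_x_endow": -0.42, "even_split": 0.63,
}
EXP1_PUNISHMENT_COEF = {
    "const": -1.93, "selfishness": 2.54, "inequality": 0.25,
    "self_x_endow": 0.30, "even_split": -0.64,
}
EXP2_PUNISHMENT_COEF = {
    "const": -1.6, "selfishness": 1.69, "inequality": 0.99,
    "self_x_endow": 0.68, "even_split": -0.12,
}

#: Published standard errors of the group means (no SEM is published for
#: the constant, so it defaults to homogeneous).
EXP1_FEELING_SEM = {"selfishness": 0.28, "inequality": 0.17, "self_x_endow": 0.09, "even_split": 0.12}
EXP2_FEELING_SEM = {"selfishness": 0.32, "inequality": 0.15, "self_x_endow": 0.09, "even_split": 0.16}
EXP1_PUNISHMENT_SEM = {"selfishness": 0.14, "inequality": 0.12, "self_x_endow": 0.07, "even_split": 0.08}
EXP2_PUNISHMENT_SEM = {"selfishness": 0.20, "inequality": 0.10, "self_x_endow": 0.13, "even_split": 0.06}

#: Cohort sizes of the two source experiments.
N_EXP1 = 32
N_EXP2 = 35

#: Default simulation noise spread on the standardized response scale.
DEFAULT_NOISE_SD = 0.5


def group_function(experiment_id: int, response: str) -> dict[str, float]:
    """The published group-level winning-model coefficient map."""
    table = {
        (1, "feeling"): EXP1_FEELING_COEF,
        (2, "feeling"): EXP2_FEELING_COEF,
        (1, "punishment"): EXP1_PUNISHMENT_COEF,
        (2, "punishment"): EXP2_PUNISHMENT_COEF,
    }
    try:
        return dict(table[(experiment_id, response)])
    except KeyError:
        raise ValueError(f"no group function for experiment {experiment_id!r}, {response!r}")


def between_participant_sds(experiment_id: int, response: str) -> dict[str, float]:
    """Heterogeneity spreads derived from published SEMs: sd = SEM·√n."""
    sems = {
        (1, "feeling"): EXP1_FEELING_SEM,
        (2, "feeling"): EXP2_FEELING_SEM,
        (1, "punishment"): EXP1_PUNISHMENT_SEM,
        (2, "punishment"): EXP2_PUNISHMENT_SEM,
    }[(experiment_id, response)]
    n = N_EXP1 if experiment_id == 1 else N_EXP2
    out = {k: v * np.sqrt(n) for k, v in sems.items()}
    out["const"] = 0.0
    return out


@dataclass
class GenerativeModel:
    """A model spec with concrete coefficients and a noise level."""

    spec: ModelSpec
    coefficients: dict[str, float]
    noise_sd: float = DEFAULT_NOISE_SD
    response_kind: str = "feeling"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.response_kind not in ("feeling", "punishment"):
            raise ValueError(f"response_kind must be feeling/punishment, got {self.response_kind!r}")
        expected = set(self.spec.regressors) | {"const"}
        if set(self.coefficients) != expected:
            raise SchemaError(
                f"coefficients must cover exactly {sorted(expected)}, "
                f"got {sorted(self.coefficients)}"
            )

    @classmethod
    def published(cls, experiment_id: int, response: str,
                  noise_sd: float = DEFAULT_NOISE_SD) -> "GenerativeModel":
        """The published winning-model group function for one experiment."""
        return cls(winning_model(), group_function(experiment_id, response),
                   noise_sd=noise_sd, response_kind=response)


def sample_participant_coefficients(
    group_means: dict[str, float],
    between_sds: dict[str, float],
    n: int,
    seed: int,
) -> list[dict[str, float]]:
    """Draw per-participant coefficient maps, Normal(mean, sd) per term.

    A spread of zero reproduces the group mean exactly for that term.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if any(sd < 0 for sd in between_sds.values()):
        raise ValueError("between-participant spreads must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            {
                term: mean + between_sds.get(term, 0.0) * rng.standard_normal()
                if between_sds.get(term, 0.0) > 0
                else mean
                for term, mean in group_means.items()
            }
        )
    return out


def linear_prediction(features: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    """Deterministic linear prediction of a coefficient map on trial features."""
    pred = np.full(len(features), float(coefficients.get("const", 0.0)))
    for term, beta in coefficients.items():
        if term == "const":
            continue
        if term not in features.columns:
            raise SchemaError(f"feature column {term!r} missing for coefficient map")
        pred = pred + beta * features[term].to_numpy(dtype=float)
    return pred


def simulate_responses(
    schedule: pd.DataFrame,
    model: GenerativeModel,
    per_participant_coeffs: dict[int, dict[str, float]] | None = None,
    seed: int = 0,
    clip: bool = False,
    noise_sds: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Generate responses for every trial whose collection flag is set.

    Each participant's response is their coefficient map (``model``'s
    by default, overridden per participant via ``per_participant_coeffs``)
    applied to the trial features, plus Gaussian noise with spread
    ``model.noise_sd`` (overridden per participant via ``noise_sds``).
    ``clip=True`` treats punishment as a fraction of the punishable
    amount and truncates it to [0, 1]; truncation biases OLS recovery
    and is therefore off by default and in every recovery procedure.

    Returns a copy of the schedule with features and a response column
    (``model.response_kind``) filled where collected, NaN elsewhere.
    Deterministic given ``seed``.
    """
    out = schedule.copy()
    if not set(FEATURE_COLUMNS) <= set(out.columns):
        out = add_features(out)
    flag = "collect_feeling" if model.response_kind == "feeling" else "collect_punishment"
    rng = np.random.default_rng(seed)
    response = np.full(len(out), np.nan)
    for pid, grp in out.groupby("participant", sort=True):
        coeffs = (per_participant_coeffs or {}).get(pid, model.coefficients)
        missing = (set(model.spec.regressors) | {"const"}) - set(coeffs)
        if missing:
            raise SchemaError(f"participant {pid}: missing coefficient(s) {sorted(missing)}")
        sd = (noise_sds or {}).get(pid, model.noise_sd)
        collected = grp[grp[flag]]
        pred = linear_prediction(collected, coeffs)
        if sd > 0:
            pred = pred + sd * rng.standard_normal(len(pred))
        if clip and model.response_kind == "punishment":
            pred = np.clip(pred, 0.0, 1.0)
        response[out.index.get_indexer(collected.index)] = pred
    out[model.response_kind] = response
    return out


def residual_spread_from_fit(fit) -> float:
    """The residual spread of a fit record, reused as simulation noise."""
    if hasattr(fit, "residual_sd_"):
        return float(fit.residual_sd_)
    return float(fit["residual_sd"])
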