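"""Parameter- and model-recovery diagnostics.

Parameter recovery: take each participant's fitted coefficients and
residual spread for a model, simulate a fresh response set from them
(each participant gets their own coefficients and own noise level),
refit the same model, and correlate true with recovered coefficients
across participants, per regressor.

Model recovery: for each candidate generator model, simulate a cohort
the same way, fit *all* candidate models, and select by summed BIC. The
winner is recorded only when it beats the runner-up by more than a
ΔBIC decision threshold (default 30); otherwise the row is undecided.
Perfect recovery puts the indicator on the diagonal for every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import generate_experiment
from .exceptions import InsufficientDataError
from .features import REGRESSORS, add_features
from .fitting import compare_models, fit_cohort
from .models import ModelSpec, winning_model
from .simulate import GenerativeModel, simulate_responses

#: ΔBIC margin required to call a model-recovery row decided.
DEFAULT_DELTA_THRESHOLD = 30.0
#: ΔBIC margin the empirical winner is reported against.
SELECTION_DELTA_THRESHOLD = 50.0


def _cohort_inputs(spec: ModelSpec, cohort_fits: pd.DataFrame):
    """Extract per-participant coefficient maps and noise levels for a spec."""
    fits = cohort_fits[cohort_fits["model_id"] == spec.model_id]
    if fits.empty:
        fits = cohort_fits
    coeffs, noise = {}, {}
    for _, row in fits.iterrows():
        pid = row["participant"]
        coeffs[pid] = {"const": float(row["const"])}
        coeffs[pid].update({r: float(row[r]) for r in spec.regressors})
        noise[pid] = float(row["residual_sd"])
    return coeffs, noise


def parameter_recovery(
    spec: ModelSpec,
    cohort_fits: pd.DataFrame,
    schedule: pd.DataFrame,
    seed: int,
    response: str = "feeling",
) -> pd.DataFrame:
    """Simulate-and-refit correlation between true and recovered coefficients.

    ``cohort_fits`` is a fits table (as from :func:`~bystander.fitting.fit_cohort`)
    holding, per participant, the spec's coefficients and residual
    spread. Simulated responses are refitted *without* re-standardizing
    so coefficients are recoverable on the generative scale. Returns one
    row per term: Pearson r, p, n, and a ``degenerate`` flag set when
    the true values have no spread (r undefined, reported as NaN).
    """
    coeffs, noise = _cohort_inputs(spec, cohort_fits)
    if len(coeffs) < 3:
        raise InsufficientDataError(f"need >= 3 participants, got {len(coeffs)}")

    model = GenerativeModel(spec, {t: 0.0 for t in ("const", *spec.regressors)},
                            noise_sd=0.0, response_kind=response)
    simulated = simulate_responses(schedule, model, per_participant_coeffs=coeffs,
                                   seed=seed, noise_sds=noise)
    refits = fit_cohort(simulated, [spec], standardize=False, response=response)

    rows = []
    pids = sorted(coeffs)
    refits = refits.set_index("participant")
    for term in ("const", *[r for r in REGRESSORS if r in spec.regressors]):
        true = np.array([coeffs[p][term] for p in pids])
        rec_col = "const" if term == "const" else term
        recovered = refits.loc[pids, rec_col].to_numpy(dtype=float)
        degenerate = np.std(true) == 0 or np.std(recovered) == 0
        if degenerate:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(true, recovered)
        rows.append({"term": term, "r": float(r), "p": float(p),
                     "n": len(pids), "degenerate": bool(degenerate)})
    return pd.DataFrame(rows)


def model_recovery(
    specs: list[ModelSpec],
    cohort_fits: pd.DataFrame,
    schedule: pd.DataFrame,
    seed: int,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    response: str = "feeling",
    candidates: list[ModelSpec] | None = None,
) -> pd.DataFrame:
    """Confusion matrix of summed-BIC selection over simulated generators.

    For each generator spec, a cohort is simulated from that spec's
    per-participant fitted coefficients and matched noise, then every
    candidate spec (default: the generators themselves) is fitted and
    the group winner selected. Returns one row per generator:
    generator_id, winner_id, margin (ΔBIC to the runner-up), decided
    (margin > ``delta_threshold``), correct (decided and winner ==
    generator).
    """
    if candidates is None:
        candidates = specs
    seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    rows = []
    for gen_spec, sub_seed in zip(specs, seeds):
        coeffs, noise = _cohort_inputs(gen_spec, cohort_fits)
        if len(coeffs) < 3:
            raise InsufficientDataError(f"need >= 3 participants, got {len(coeffs)}")
        model = GenerativeModel(gen_spec, {t: 0.0 for t in ("const", *gen_spec.regressors)},
                                noise_sd=0.0, response_kind=response)
        simulated = simulate_responses(schedule, model, per_participant_coeffs=coeffs,
                                       seed=int(sub_seed), noise_sds=noise)
        fits = fit_cohort(simulated, candidates, standardize=False, response=response)
        comparison = compare_models(fits)
        decided = comparison.margin > delta_threshold
        rows.append(
            {
                "generator_id": gen_spec.model_id,
                "winner_id": comparison.winner_id if decided else pd.NA,
                "margin": comparison.margin,
                "decided": decided,
                "correct": bool(decided and comparison.winner_id == gen_spec.model_id),
            }
        )
    return pd.DataFrame(rows)


def confusion_matrix(recovery_table: pd.DataFrame, specs: list[ModelSpec]) -> pd.DataFrame:
    """Generator × fitted 0/1 indicator matrix from a model-recovery table."""
    ids = [s.model_id for s in specs]
    mat = pd.DataFrame(0, index=pd.Index(ids, name="generator_id"),
                       columns=pd.Index(ids, name="fitted_id"))
    for _, row in recovery_table.iterrows():
        if row["decided"]:
            mat.loc[row["generator_id"], row["winner_id"]] = 1
    return mat


def recover_published_function(
    experiment_id: int,
    response: str,
    n_participants: int = 200,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Simulate a homogeneous cohort from the published group-level
    winning-model function and refit the winning model.

    Every simulated participant carries the group-level coefficients;
    Gaussian noise with spread ``noise_sd`` is added on the trials the
    design collects the response on, and the winning model is refitted
    without re-standardizing. OLS unbiasedness makes the group-mean
    recovered coefficients converge on the generating ones.

    Returns ``(group_means, fits)`` where ``group_means`` maps each
    term (constant + regressors) to its across-participant mean.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    schedule = add_features(generate_experiment(experiment_id, n_participants, int(seeds[0])))
    model = GenerativeModel.published(experiment_id, response, noise_sd=noise_sd)
    simulated = simulate_responses(schedule, model, seed=int(seeds[1]))
    fits = fit_cohort(simulated, [winning_model()], standardize=False, response=response)
    terms = ("const", *winning_model().regressors)
    means = {t: float(fits[t].mean()) for t in terms}
    return means, fits


@dataclass
class RecoveryReport:
    """Bundle of both diagnostics plus the settings that produced them."""

    parameter_recovery: pd.DataFrame
    model_recovery: pd.DataFrame
    settings: dict = field(default_factory=dict)
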