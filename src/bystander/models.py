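"""The nested model space over the five trial regressors.

The full feeling/punishment model is a linear function of selfishness,
inequality, selfishness×endowment, inequality×endowment and the
even-split stick, plus a constant. The model space is every non-empty
subset of the five regressors (all 2^5 − 1 = 31 members, each with the
constant), enumerated by subset size and then lexicographically in the
canonical regressor order — a stable numbering under which the winning
four-regressor model {selfishness, inequality, self_x_endow,
even_split} is model 26 and {selfishness} alone is model 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, SchemaError
from .features import REGRESSORS

#: Model id of the winning four-regressor model.
WINNING_MODEL_ID = 26


@dataclass(frozen=True)
class ModelSpec:
    """One member of the nested model space (a regressor subset + constant)."""

    model_id: int
    regressors: tuple[str, ...]

    def __post_init__(self):
        if not self.regressors:
            raise ValueError("a model must contain at least one regressor")
        if len(set(self.regressors)) != len(self.regressors):
            raise ValueError("duplicate regressors in model spec")
        unknown = set(self.regressors) - set(REGRESSORS)
        if unknown:
            raise ValueError(f"unknown regressors: {sorted(unknown)}")

    @property
    def k_params(self) -> int:
        """Number of free mean parameters (constant + regressors)."""
        return 1 + len(self.regressors)

    def __contains__(self, other: "ModelSpec") -> bool:
        return set(other.regressors) <= set(self.regressors)


def enumerate_models() -> list[ModelSpec]:
    """All 31 models, ordered by subset size then lexicographically."""
    specs = []
    model_id = 1
    for size in range(1, len(REGRESSORS) + 1):
        for combo in itertools.combinations(range(len(REGRESSORS)), size):
            specs.append(ModelSpec(model_id, tuple(REGRESSORS[i] for i in combo)))
            model_id += 1
    return specs


#: The canonical model space, indexable by ``MODEL_SPACE[model_id - 1]``.
MODEL_SPACE: list[ModelSpec] = enumerate_models()


def get_model(model_id: int) -> ModelSpec:
    """Look up a model by its canonical id (1..31)."""
    if not 1 <= model_id <= len(MODEL_SPACE):
        raise ValueError(f"model_id must be in 1..{len(MODEL_SPACE)}, got {model_id!r}")
    return MODEL_SPACE[model_id - 1]


def winning_model() -> ModelSpec:
    return get_model(WINNING_MODEL_ID)


def model_space_table() -> pd.DataFrame:
    """Serializable view: model_id plus one 0/1 flag column per regressor."""
    rows = [
        {"model_id": spec.model_id, **{r: int(r in spec.regressors) for r in REGRESSORS}}
        for spec in MODEL_SPACE
    ]
    return pd.DataFrame(rows)


def build_design_matrix(features: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """n × (k+1) design matrix: a leading column of ones, then the
    spec's regressors in canonical order.
    """
    missing = [r for r in spec.regressors if r not in features.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s): {missing}")
    cols = [r for r in REGRESSORS if r in spec.regressors]
    X = np.column_stack(
        [np.ones(len(features))] + [features[c].to_numpy(dtype=float) for c in cols]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            f"design matrix for model {spec.model_id} is rank deficient"
        )
    return X
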