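"""Trial-schedule generation for the two observation experiments.

Both experiments present 4 blocks of 60 trials. On every trial an
allocator divides an endowment of £1–£15 between themselves and another
player; the participant merely observes. In experiment 1 the allocator
*takes* a percentage of the endowment (10–100%, with selfish splits
over-represented so behaviour looks realistic); in experiment 2 the
allocator *gives* a percentage away (0–90%, uniform). Which blocks
collect feeling ratings and which collect punishment decisions differs
between the experiments and is encoded in the ``collect_*`` flags.

Endowment and allocation sequences are independent uniform permutations
of their fixed per-block multisets, so allocation is not a function of
endowment by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import BystanderError

#: Fixed columns of a trial schedule table.
TRIAL_COLUMNS = [
    "experiment",
    "participant",
    "block",
    "trial",
    "endowment_gbp",
    "allocation_pct",
    "collect_feeling",
    "collect_punishment",
]

N_BLOCKS = 4
TRIALS_PER_BLOCK = 60
ENDOWMENTS = np.arange(1, 16)

# Per-block allocation multisets. Experiment 1: taking 60-100% appears
# 9 times each, 10-50% three times each. Experiment 2: each giving
# percentage 0-90% appears 6 times.
EXP1_ALLOCATION_COUNTS = {100: 9, 90: 9, 80: 9, 70: 9, 60: 9, 50: 3, 40: 3, 30: 3, 20: 3, 10: 3}
EXP2_ALLOCATION_COUNTS = {pct: 6 for pct in range(0, 91, 10)}

#: Blocks on which each response is collected, per experiment.
FEELING_BLOCKS = {1: (2, 4), 2: (1, 3)}
PUNISHMENT_BLOCKS = {1: (1, 2, 3, 4), 2: (2, 4)}


def _validate_experiment(experiment_id: int) -> None:
    if experiment_id not in (1, 2):
        raise ValueError(f"experiment_id must be 1 or 2, got {experiment_id!r}")


def allocation_counts(experiment_id: int) -> dict[int, int]:
    """Per-block histogram of allocation percentages for an experiment."""
    _validate_experiment(experiment_id)
    return dict(EXP1_ALLOCATION_COUNTS if experiment_id == 1 else EXP2_ALLOCATION_COUNTS)


def block_seed(seed: int, experiment_id: int, participant_id: int, block: int) -> int:
    """Derive the per-(participant, block) sub-seed from a master seed.

    The rule is a fixed function of the identifiers (via
    ``numpy.random.SeedSequence``), so any single block of any
    participant can be regenerated in isolation.
    """
    ss = np.random.SeedSequence([int(seed), int(experiment_id), int(participant_id), int(block)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_block(
    experiment_id: int, block: int, seed: int, participant_id: int = 1
) -> pd.DataFrame:
    """Generate the 60 trials of one block.

    Returns a DataFrame with :data:`TRIAL_COLUMNS`. Deterministic for a
    given ``(experiment_id, block, seed)``.
    """
    _validate_experiment(experiment_id)
    if block not in (1, 2, 3, 4):
        raise ValueError(f"block must be in 1..4, got {block!r}")

    rng = np.random.default_rng(seed)
    endowments = np.repeat(ENDOWMENTS, 4)
    counts = allocation_counts(experiment_id)
    allocations = np.repeat(
        np.fromiter(counts.keys(), dtype=int), np.fromiter(counts.values(), dtype=int)
    )
    endowments = rng.permutation(endowments)
    allocations = rng.permutation(allocations)

    return pd.DataFrame(
        {
            "experiment": experiment_id,
            "participant": participant_id,
            "block": block,
            "trial": np.arange(1, TRIALS_PER_BLOCK + 1),
            "endowment_gbp": endowments,
            "allocation_pct": allocations,
            "collect_feeling": block in FEELING_BLOCKS[experiment_id],
            "collect_punishment": block in PUNISHMENT_BLOCKS[experiment_id],
        }
    )


def generate_experiment(experiment_id: int, n_participants: int, seed: int) -> pd.DataFrame:
    """Generate full 4-block schedules for a cohort.

    Per-participant, per-block sub-seeds come from :func:`block_seed`,
    so the output equals the concatenation of the corresponding
    :func:`generate_block` calls.
    """
    _validate_experiment(experiment_id)
    if n_participants < 1:
        raise ValueError(f"n_participants must be >= 1, got {n_participants!r}")

    blocks = [
        generate_block(
            experiment_id,
            block,
            block_seed(seed, experiment_id, pid, block),
            participant_id=pid,
        )
        for pid in range(1, n_participants + 1)
        for block in range(1, N_BLOCKS + 1)
    ]
    return pd.concat(blocks, ignore_index=True)


def check_schedule(trials: pd.DataFrame) -> None:
    """Raise :class:`BystanderError` if a schedule violates the design invariants."""
    for (exp, _pid, _block), grp in trials.groupby(["experiment", "participant", "block"]):
        if len(grp) != TRIALS_PER_BLOCK:
            raise BystanderError(f"block has {len(grp)} trials, expected {TRIALS_PER_BLOCK}")
        endow = grp["endowment_gbp"].value_counts()
        if not (endow.sort_index().eq(4).all() and set(endow.index) == set(ENDOWMENTS)):
            raise BystanderError("endowment histogram violated (each of 1..15 must appear 4x)")
        alloc = grp["allocation_pct"].value_counts().to_dict()
        if alloc != allocation_counts(int(exp)):
            raise BystanderError("allocation histogram violated")
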