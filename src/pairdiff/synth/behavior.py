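"""Behavioural outcome generator.

Pair-level scene–object memory outcomes ("correct" vs "interference",
plus a small fixed rate of "other" errors that downstream analysis
excludes) whose log-odds of a correct outcome depend on the pair's
representational difference score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .._rng import substream

__all__ = ["BehaviorModelTruth", "simulate_behavior"]


@dataclass(frozen=True)
class BehaviorModelTruth:
    """Generative coefficients on the log-odds of a correct outcome.

    logit P(correct) = intercept + slope * score + condition effect
                       + repetition_effect * (repetition - 1)
                       + interaction * score * (repetition - 1)
                       + subject intercept,  subject ~ N(0, subject_sd^2)
    """

    intercept: float = 1.0
    slope_score: float = -2.0
    condition_effects: Mapping[str, float] = field(default_factory=dict)
    repetition_effect: float = 0.8
    interaction: float = 0.0
    subject_sd: float = 0.5
    other_rate: float = 0.04
    n_repetitions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("subject random-intercept sd must be >= 0")
        if not (0.0 <= self.other_rate < 1.0):
            raise ValueError("other_rate must be in [0, 1)")


def simulate_behavior(
    truth: BehaviorModelTruth,
    pair_scores: pd.DataFrame,
    n_subjects: int,
) -> pd.DataFrame:
    """Draw pair x repetition outcomes for ``n_subjects`` subjects.

    ``pair_scores`` needs columns ``pair``, ``condition`` and
    ``difference_score``; an optional ``subject`` column restricts each
    subject to their own rows (otherwise every subject sees the same
    scores).  Returns the behaviour table with columns subject, pair_id,
    condition, test_repetition, outcome, n_interference_errors.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    required = {"pair", "condition", "difference_score"}
    if not required.issubset(pair_scores.columns):
        raise ValueError(f"pair_scores must have columns {sorted(required)}")
    if not np.isfinite(pair_scores["difference_score"]).all():
        raise ValueError("difference scores must be finite")

    rng = substream(truth.seed, "synth", "behaviour")
    subject_intercepts = truth.subject_sd * rng.standard_normal(n_subjects)

    rows = []
    per_subject = "subject" in pair_scores.columns
    subjects = (
        sorted(pair_scores["subject"].unique()) if per_subject else list(range(n_subjects))
    )
    if per_subject and len(subjects) != n_subjects:
        raise ValueError(
            f"pair_scores lists {len(subjects)} subjects but n_subjects={n_subjects}"
        )
    for s_idx, subj in enumerate(subjects[:n_subjects]):
        scores = (
            pair_scores[pair_scores["subject"] == subj] if per_subject else pair_scores
        )
        for row in scores.itertuples(index=False):
            score = float(row.difference_score)
            cond_eff = float(truth.condition_effects.get(row.condition, 0.0))
            for rep in range(1, truth.n_repetitions + 1):
                lp = (
                    truth.intercept
                    + truth.slope_score * score
                    + cond_eff
                    + truth.repetition_effect * (rep - 1)
                    + truth.interaction * score * (rep - 1)
                    + subject_intercepts[s_idx]
                )
                if rng.random() < truth.other_rate:
                    outcome, n_int = "other", 0
                else:
                    correct = rng.random() < expit(lp)
                    if correct:
                        outcome, n_int = "correct", 0
                    else:
                        outcome, n_int = "interference", 1 + int(rng.random() < 0.3)
                rows.append(
                    {
                        "subject": subj,
                        "pair_id": row.pair,
                        "condition": row.condition,
                        "test_repetition": rep,
                        "outcome": outcome,
                        "n_interference_errors": n_int,
                    }
                )
    return pd.DataFrame(rows)
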