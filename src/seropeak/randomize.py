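"""Over-fitting control: re-assign samples to pseudo-groups at random,
balanced for sex and approximately for age, and rerun the LOOCV.

With real between-group structure the randomized run should lose the
separation (scores of the pseudo-groups overlap, the group p-value grows by
orders of magnitude); retained separation under shuffled labels would
indicate over-fitting of the peak-selection machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loocv import LoocvResult, run_loocv
from .preprocess import PeakMatrix

logger = logging.getLogger(__name__)

__all__ = ["ShufflePlan", "balanced_shuffle", "randomized_loocv"]


@dataclass
class ShufflePlan:
    """A balanced random relabeling of the cohort.

    ``assignment`` maps sample_id to its randomized group. Group sizes and
    per-group sex counts are preserved exactly (labels are permuted within
    sex strata); the plan is accepted once both randomized groups' age means
    lie within ``age_tol`` years of the original groups', retrying up to a
    bounded number of draws.
    """

    seed: int
    assignment: pd.Series
    group_sizes: dict
    sex_counts: dict
    age_mean_shift: dict  # |randomized - original| group age mean, years
    n_draws: int
    age_constraint_met: bool


def balanced_shuffle(
    meta: pd.DataFrame, seed: int, age_tol: float = 5.0, max_draws: int = 200
) -> ShufflePlan:
    """Permute group labels uniformly at random within sex strata, accepting
    the first draw whose per-group age means stay within ``age_tol`` years
    of the originals.

    Permuting within each sex stratum preserves the original group sizes and
    per-group sex counts exactly. If no draw meets the age tolerance within
    ``max_draws`` attempts the best draw seen is returned with a warning.
    """
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    groups = list(pd.unique(meta["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    rng = np.random.default_rng(seed)
    labels = meta["group"]
    strata = (
        meta["sex"] if "sex" in meta.columns and meta["sex"].notna().all() else pd.Series("all", index=meta.index)
    )
    orig_age = {g: meta.loc[labels == g, "age"].mean() for g in groups}

    best = None
    for draw in range(1, max_draws + 1):
        assignment = labels.copy()
        for s in strata.unique():
            idx = meta.index[strata == s]
            assignment.loc[idx] = rng.permutation(labels.loc[idx].to_numpy())
        shift = {
            g: abs(meta.loc[assignment == g, "age"].mean() - orig_age[g]) for g in groups
        }
        worst = max(shift.values())
        if best is None or worst < best[0]:
            best = (worst, assignment, shift, draw)
        if worst <= age_tol:
            break
    worst, assignment, shift, draw = best
    ok = worst <= age_tol
    if not ok:
        logger.warning(
            "age balance not met after %d draws (worst shift %.1f y > tol %.1f)",
            max_draws, worst, age_tol,
        )
    return ShufflePlan(
        seed=seed,
        assignment=assignment.rename("group"),
        group_sizes={g: int((assignment == g).sum()) for g in groups},
        sex_counts={
            g: meta.loc[assignment == g, "sex"].value_counts().to_dict()
            if "sex" in meta.columns else {}
            for g in groups
        },
        age_mean_shift={g: float(v) for g, v in shift.items()},
        n_draws=draw,
        age_constraint_met=ok,
    )


def randomized_loocv(
    matrix: PeakMatrix, plan: ShufflePlan, disease_label=None, alpha: float = 0.05
) -> LoocvResult:
    """Run the identical LOOCV pipeline with the plan's relabeled groups.

    ``disease_label`` defaults to the matrix's original disease-side label
    (the first group); nothing else about the procedure changes.
    """
    if not set(matrix.sample_ids) <= set(plan.assignment.index):
        raise ValueError("shuffle plan does not cover all samples")
    relabeled = matrix.relabeled(plan.assignment)
    if disease_label is None:
        disease_label = relabeled.groups[0]
    return run_loocv(relabeled, disease_label, alpha=alpha)
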