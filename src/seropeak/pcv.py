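"""Per-fold peak statistics: one-tailed t screening, peak classification
values (PCV), and per-peak classification of a left-out sample.

At every unit-m/z bin the left-in samples of the two groups are compared
with a pooled-variance Student's t-test, one-tailed in the direction of the
observed mean difference. Significant bins (p < alpha) each receive a PCV —
the midpoint of the two left-in group means — and an owner (the
higher-mean group). A left-out sample's peak is assigned to the owner group
when its area exceeds the PCV and to the other group when it is at or below
it; the percentage of peaks assigned to the disease group is that sample's
LOOCV score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PeakStat",
    "InsufficientDataError",
    "peak_ttest_onetailed",
    "two_group_peak_table",
    "select_significant_peaks",
    "compute_pcv",
    "classify_peak",
    "score_left_out_sample",
]


class InsufficientDataError(ValueError):
    """Raised when a group has too few samples for the per-peak t-test."""


@dataclass
class PeakStat:
    """Left-in statistics for one significant peak.

    ``group1``/``group2`` name the two study groups so the non-owner group
    is recoverable; ``owner`` is the higher-mean one of the two.
    """

    mz_bin: float
    mean_g1: float
    sd_g1: float
    mean_g2: float
    sd_g2: float
    p_value: float
    owner: object  # group label with the higher mean
    pcv: float = np.nan
    group1: object = "g1"
    group2: object = "g2"

    @property
    def non_owner(self):
        return self.group2 if self.owner == self.group1 else self.group1


def peak_ttest_onetailed(areas_g1, areas_g2) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic with a one-tailed p-value in
    the direction of the observed mean difference.

    Degenerate input with zero pooled variance and equal means gives
    (t, p) = (0, 0.5); zero variance with unequal means gives p = 0.
    """
    x = np.asarray(areas_g1, dtype=float)
    y = np.asarray(areas_g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need at least 2 samples per group")
    t, p = _vector_ttest(x[:, None], y[:, None])
    return float(t[0]), float(p[0])


def _vector_ttest(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise pooled t and one-tailed (observed-direction) p for
    (n1, k) and (n2, k) arrays."""
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = np.where(
        se > 0,
        sps.t.sf(np.abs(t), df),
        np.where(diff == 0, 0.5, 0.0),
    )
    return t, p


def two_group_peak_table(
    areas: pd.DataFrame, labels: pd.Series, group1, group2
) -> pd.DataFrame:
    """Per-bin group means, SDs, pooled t and one-tailed p for every column
    of a samples x bins area table.

    Returns a DataFrame indexed by bin with columns mean_g1, sd_g1, mean_g2,
    sd_g2, t, p, owner. The owner is the higher-mean group (group2 on exact
    ties, matching the at-or-below classification rule).
    """
    x = areas.values[np.asarray(labels == group1)]
    y = areas.values[np.asarray(labels == group2)]
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise InsufficientDataError(
            f"need >= 2 samples per group, got {x.shape[0]} vs {y.shape[0]}"
        )
    t, p = _vector_ttest(x, y)
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    tab = pd.DataFrame(
        {
            "mean_g1": m1,
            "sd_g1": x.std(axis=0, ddof=1),
            "mean_g2": m2,
            "sd_g2": y.std(axis=0, ddof=1),
            "t": t,
            "p": p,
        },
        # copy: renaming the index below must not touch the caller's columns
        index=areas.columns.copy(),
    )
    tab["owner"] = np.where(m1 > m2, group1, group2)
    tab["pcv"] = (m1 + m2) / 2.0
    tab.index.name = "mz_bin"
    return tab


def select_significant_peaks(
    areas: pd.DataFrame, labels: pd.Series, group1, group2, alpha: float = 0.05
) -> pd.DataFrame:
    """Bins differing between the left-in groups at p < alpha, with owner
    and PCV columns.

    Bins with zero variance in both groups and equal means carry no
    information and are excluded (their p is 0.5 anyway).
    """
    tab = two_group_peak_table(areas, labels, group1, group2)
    keep = tab["p"] < alpha
    degenerate = (tab["sd_g1"] == 0) & (tab["sd_g2"] == 0) & (tab["mean_g1"] == tab["mean_g2"])
    return tab[keep & ~degenerate]


def compute_pcv(stat: PeakStat) -> float:
    """Peak classification value: the midpoint of the two left-in group
    means at this bin. Lies strictly between the means whenever they differ."""
    return (stat.mean_g1 + stat.mean_g2) / 2.0


def classify_peak(stat: PeakStat, left_out_area: float):
    """Assign a left-out sample's peak to the owner group when its area is
    strictly above the PCV, otherwise (at or below) to the other group."""
    pcv = stat.pcv if np.isfinite(stat.pcv) else compute_pcv(stat)
    return stat.owner if left_out_area > pcv else stat.non_owner


def score_left_out_sample(
    stats_table: pd.DataFrame, left_out_areas: pd.Series, disease_label
) -> float:
    """Percent of significant left-in peaks at which the left-out sample
    classifies into ``disease_label``.

    ``stats_table`` is the output of :func:`select_significant_peaks`;
    ``left_out_areas`` is the sample's bin -> area series (bins missing from
    the sample count as area 0).
    """
    if len(stats_table) == 0:
        raise ValueError("no significant peaks: score undefined")
    areas = left_out_areas.reindex(stats_table.index).fillna(0.0).to_numpy()
    above = areas > stats_table["pcv"].to_numpy()
    owner_is_disease = stats_table["owner"].to_numpy() == disease_label
    as_disease = np.where(above, owner_is_disease, ~owner_is_disease)
    return 100.0 * float(as_disease.sum()) / len(stats_table)
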