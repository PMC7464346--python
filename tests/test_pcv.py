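"""Per-peak statistics: one-tailed t screening, PCV thresholds, and
left-out-sample classification, checked against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from seropeak import (
    PeakStat,
    classify_peak,
    compute_pcv,
    peak_ttest_onetailed,
    score_left_out_sample,
    select_significant_peaks,
)
from seropeak.pcv import InsufficientDataError


def t_tail_oracle(t_abs: float, df: int) -> float:
    """Upper-tail t probability by direct numerical integration of the
    explicit Student density (independent of scipy.stats.t)."""
    c = math.gamma((df + 1) / 2) / (math.gamma(df / 2) * math.sqrt(df * math.pi))
    val, _ = quad(lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2), t_abs, np.inf)
    return val


class TestPeakTtest:
    def test_frozen_example(self):
        """(1,2,3) vs (4,5,6): pooled t = -3.674, one-tailed p = 0.01066
        (frozen from the t-density integral at df = 4)."""
        t, p = peak_ttest_onetailed([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.0106558, abs=1e-6)

    def test_null_gives_half(self):
        _, p = peak_ttest_onetailed([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert p == pytest.approx(t_tail_oracle(0.0, 4), abs=1e-9)

    def test_degenerate_equal_groups(self):
        t, p = peak_ttest_onetailed([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 0.5)

    def test_zero_variance_separated(self):
        _, p = peak_ttest_onetailed([5.0, 5.0], [9.0, 9.0])
        assert p == 0.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            peak_ttest_onetailed([1.0], [2.0, 3.0])

    def test_matches_integration_oracle_on_random_instances(self):
        """t statistic and one-tailed p agree with an independently derived
        pooled t and a quadrature tail integral on random small groups."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 8, size=2)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n1)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n2)
            t, p = peak_ttest_onetailed(x, y)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
            t_ref = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert p == pytest.approx(t_tail_oracle(abs(t_ref), n1 + n2 - 2), abs=1e-7)


def _areas(data: dict) -> pd.DataFrame:
    return pd.DataFrame(data, index=[f"s{i}" for i in range(len(next(iter(data.values()))))])


class TestSelectSignificantPeaks:
    def test_identical_groups_select_nothing(self):
        areas = _areas({500.0: [1, 1, 1, 1], 501.0: [2, 2, 2, 2]})
        labels = pd.Series(["a", "a", "b", "b"], index=areas.index)
        assert len(select_significant_peaks(areas, labels, "a", "b")) == 0

    def test_strong_difference_selected_with_owner(self):
        areas = _areas({500.0: [10, 11, 9, 1.0, 1.2, 0.9]})
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=areas.index)
        tab = select_significant_peaks(areas, labels, "a", "b")
        assert list(tab.index) == [500.0]
        assert tab["owner"].iloc[0] == "a"
        assert tab["pcv"].iloc[0] == pytest.approx((10 + 11 + 9) / 6 + (1.0 + 1.2 + 0.9) / 6)

    def test_permuted_labels_select_at_twice_alpha(self):
        """On null data the observed-direction one-tailed screen fires at
        ~2*alpha (the direction is chosen after seeing the difference)."""
        rng = np.random.default_rng(12)
        n_bins = 800
        areas = pd.DataFrame(
            rng.lognormal(0, 1, size=(30, n_bins)),
            index=[f"s{i}" for i in range(30)],
            columns=np.arange(400.0, 400.0 + n_bins),
        )
        labels = pd.Series(rng.permutation(["a"] * 15 + ["b"] * 15), index=areas.index)
        rate = len(select_significant_peaks(areas, labels, "a", "b")) / n_bins
        sd = math.sqrt(0.10 * 0.90 / n_bins)
        assert abs(rate - 0.10) < 3 * sd


class TestPcvAndClassification:
    def test_pcv_midpoint_examples(self):
        s = PeakStat(919.0, 10.0, 1.0, 4.0, 1.0, 0.01, "epilepsy", group1="epilepsy", group2="control")
        assert compute_pcv(s) == pytest.approx(7.0)
        s2 = PeakStat(919.0, 100.0, 1.0, 0.0, 0.0, 0.01, "epilepsy")
        assert compute_pcv(s2) == pytest.approx(50.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=1e6, allow_nan=False),
        st.floats(min_value=0, max_value=1e6, allow_nan=False),
    )
    def test_pcv_strictly_between_unequal_means(self, m1, m2):
        if m1 == m2:
            return
        s = PeakStat(500.0, m1, 1.0, m2, 1.0, 0.01, "a")
        lo, hi = min(m1, m2), max(m1, m2)
        assert lo < compute_pcv(s) < hi

    def test_above_pcv_goes_to_owner(self):
        s = PeakStat(919.0, 10, 1, 4, 1, 0.01, "epilepsy", pcv=7.0,
                     group1="epilepsy", group2="control")
        assert classify_peak(s, 8.0) == "epilepsy"

    def test_at_or_below_pcv_goes_to_non_owner(self):
        s = PeakStat(919.0, 10, 1, 4, 1, 0.01, "epilepsy", pcv=7.0,
                     group1="epilepsy", group2="control")
        assert classify_peak(s, 7.0) == "control"
        assert classify_peak(s, 0.0) == "control"


def _brute_score(tab: pd.DataFrame, areas: dict, disease, other) -> float:
    """Exhaustive per-peak reclassification, written independently."""
    n_dis = 0
    for b, row in tab.iterrows():
        a = areas.get(b, 0.0)
        g = row["owner"] if a > row["pcv"] else (other if row["owner"] == disease else disease)
        n_dis += g == disease
    return 100.0 * n_dis / len(tab)


class TestScoring:
    def _table(self, owners, pcvs):
        return pd.DataFrame(
            {"owner": owners, "pcv": pcvs},
            index=np.arange(500.0, 500.0 + len(owners)),
        )

    def test_all_none_and_fraction(self):
        tab = self._table(["d", "d", "d", "d"], [1.0, 1.0, 1.0, 1.0])
        high = pd.Series(2.0, index=tab.index)
        low = pd.Series(0.0, index=tab.index)
        assert score_left_out_sample(tab, high, "d") == 100.0
        assert score_left_out_sample(tab, low, "d") == 0.0
        mixed = pd.Series([2.0, 2.0, 2.0, 0.0], index=tab.index)
        assert score_left_out_sample(tab, mixed, "d") == 75.0

    def test_empty_stats_error(self):
        with pytest.raises(ValueError):
            score_left_out_sample(self._table([], []), pd.Series(dtype=float), "d")

    def test_matches_brute_force_on_random_toys(self):
        """Scoring agrees with an exhaustive reclassification on random
        instances of up to 5 peaks, including missing-bin (=0) cases."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            k = rng.integers(1, 6)
            tab = self._table(
                rng.choice(["d", "c"], size=k), rng.uniform(0, 10, size=k)
            )
            areas = {
                b: float(rng.uniform(0, 10)) for b in tab.index if rng.random() < 0.8
            }
            got = score_left_out_sample(tab, pd.Series(areas, dtype=float), "d")
            assert got == pytest.approx(_brute_score(tab, areas, "d", "c"))

    def test_label_swap_symmetry(self):
        """Swapping which group is called 'disease' maps every score s to
        100 - s."""
        rng = np.random.default_rng(2)
        tab = self._table(rng.choice(["d", "c"], size=7), rng.uniform(0, 5, size=7))
        areas = pd.Series(rng.uniform(0, 5, size=7), index=tab.index)
        s_d = score_left_out_sample(tab, areas, "d")
        s_c = score_left_out_sample(tab, areas, "c")
        assert s_d + s_c == pytest.approx(100.0)
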