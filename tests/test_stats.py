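"""Cell-status classification and group comparison statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ktr.stats import (
    classify_cell_status,
    compare_groups,
    mann_whitney_one_tailed,
    student_t_two_tailed,
)


class TestClassification:
    @pytest.mark.parametrize(
        "dt, sab, expected",
        [
            (1.5, 0.5, "young"),
            (1.0, 0.99, "young"),
            (2.0, 0.0, "young"),
            (6.0, 3.0, "mid_old"),
            (5.0, 4.99, "mid_old"),
            (7.0, 0.0, "mid_old"),
            (20.0, 80.0, "old"),
            (14.5, 66.0, "old"),
            # outside every printed band
            (10.0, 20.0, "unclassified"),
            (3.0, 0.5, "unclassified"),  # DT gap between young and mid-old
            (0.5, 0.0, "unclassified"),  # faster than the young band
            (2.0, 1.0, "unclassified"),  # SA-b-Gal not < 1%
            (6.0, 5.0, "unclassified"),  # SA-b-Gal not < 5%
            (14.0, 70.0, "unclassified"),  # DT not > 14
            (20.0, 65.0, "unclassified"),  # SA-b-Gal not > 65%
        ],
    )
    def test_band_membership(self, dt, sab, expected):
        assert classify_cell_status(dt, sab).status == expected

    @pytest.mark.parametrize("dt, sab", [(0.0, 10.0), (-1.0, 10.0), (5.0, -1.0), (5.0, 101.0)])
    def test_out_of_range_rejected(self, dt, sab):
        with pytest.raises(ValueError):
            classify_cell_status(dt, sab)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        dt=st.floats(min_value=0.01, max_value=60.0, allow_nan=False),
        sab=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    )
    def test_partition_every_input_one_status(self, dt, sab):
        status = classify_cell_status(dt, sab).status
        assert status in ("young", "mid_old", "old", "unclassified")
        # membership in the three bands is mutually exclusive
        in_young = 1.0 <= dt <= 2.0 and sab < 1.0
        in_mid = 5.0 <= dt <= 7.0 and sab < 5.0
        in_old = dt > 14.0 and sab > 65.0
        assert sum((in_young, in_mid, in_old)) <= 1
        assert status == (
            "young" if in_young else "mid_old" if in_mid else "old" if in_old else "unclassified"
        )


class TestMannWhitney:
    def test_fully_separated_samples_exact_p(self):
        # all 20 rank arrangements: only one puts x entirely below y
        u, p = mann_whitney_one_tailed([1, 2, 3], [4, 5, 6], "less")
        assert u == 0
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_with_ties_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        for alt in ("less", "greater"):
            _, p = mann_whitney_one_tailed(x, x, alt)
            assert p >= 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])

    def test_u_within_range_and_complementary(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=8)
            u, _ = mann_whitney_one_tailed(x, y, "less")
            u2, _ = mann_whitney_one_tailed(y, x, "less")
            assert 0 <= u <= 48
            assert u + u2 == pytest.approx(48)

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.uniform(0, 100, size=5)
            y = rng.uniform(0, 100, size=6)
            for alt in ("less", "greater"):
                u, p = mann_whitney_one_tailed(x, y, alt)
                ref = sps.mannwhitneyu(x, y, alternative=alt, method="exact")
                assert u == pytest.approx(ref.statistic)
                assert p == pytest.approx(ref.pvalue)

    def test_exact_vs_normal_approximation_close(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rng.uniform(0, 100, size=6)
            y = rng.uniform(0, 100, size=6)
            _, p_exact = mann_whitney_one_tailed(x, y, "less")
            from ktr.stats import _approx_p, _u_statistic

            p_norm = _approx_p(_u_statistic(x, y), x, y, "less")
            assert abs(p_exact - p_norm) <= 0.02

    def test_tied_large_samples_match_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.uniform(0, 10, size=15))
        y = np.round(rng.uniform(0, 10, size=12))
        u, p = mann_whitney_one_tailed(x, y, "greater")
        ref = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestCompareGroups:
    def _fits(self, seed=0, n=20, shift=3.0):
        rng = np.random.default_rng(seed)
        young = rng.normal(10.0 + shift, 1.0, size=n)
        old = rng.normal(10.0, 1.0, size=n)
        return pd.DataFrame(
            {
                "status": ["young"] * n + ["old"] * n,
                "k_on": np.concatenate([young, old]),
            }
        )

    def test_detects_generated_effect(self):
        fits = self._fits()
        (comp,) = compare_groups(fits, parameters=["k_on"], alternatives="greater")
        assert comp.group_x == "young" and comp.group_y == "old"
        assert comp.p_one_tailed < 0.05
        assert comp.n_x == comp.n_y == 20
        assert 0 <= comp.u_statistic <= 400

    def test_mean_sd_reported(self):
        fits = self._fits(shift=0.0)
        (comp,) = compare_groups(fits, parameters=["k_on"], alternatives="greater")
        x = fits.loc[fits["status"] == "young", "k_on"]
        assert comp.mean_x == pytest.approx(x.mean())
        assert comp.sd_x == pytest.approx(x.std(ddof=1))

    def test_single_group_yields_no_comparisons(self):
        fits = pd.DataFrame({"status": ["young"] * 5, "k_on": np.arange(5.0)})
        assert compare_groups(fits, parameters=["k_on"]) == []

    def test_small_group_skipped(self):
        fits = pd.DataFrame(
            {"status": ["young", "young", "old"], "k_on": [1.0, 2.0, 3.0]}
        )
        assert compare_groups(fits, parameters=["k_on"]) == []

    def test_row_order_invariance(self):
        fits = self._fits()
        shuffled = fits.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = compare_groups(fits, parameters=["k_on"], alternatives="greater")
        b = compare_groups(shuffled, parameters=["k_on"], alternatives="greater")
        assert len(a) == len(b) == 1
        ca, cb = a[0], b[0]
        assert (ca.parameter, ca.group_x, ca.group_y, ca.n_x, ca.n_y) == (
            cb.parameter, cb.group_x, cb.group_y, cb.n_x, cb.n_y
        )
        assert ca.u_statistic == cb.u_statistic
        assert ca.p_one_tailed == pytest.approx(cb.p_one_tailed)
        assert ca.mean_x == pytest.approx(cb.mean_x)
        assert ca.sd_x == pytest.approx(cb.sd_x)

    def test_per_parameter_direction_mapping(self):
        fits = self._fits()
        fits["R_eq"] = fits["k_on"]
        comps = compare_groups(
            fits,
            parameters=["k_on", "R_eq"],
            alternatives={"k_on": "greater", "R_eq": "less"},
        )
        by_param = {c.parameter: c for c in comps}
        assert by_param["k_on"].alternative == "greater"
        assert by_param["R_eq"].alternative == "less"


def test_student_t_two_tailed_matches_scipy():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=10), rng.normal(size=12)
    t, p = student_t_two_tailed(x, y)
    ref = sps.ttest_ind(x, y)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
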