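"""Heterosis/heterobeltiosis arithmetic, trait standardization, exact MWU."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from hybridexpr import (
    ValidationError,
    heterobeltiosis,
    heterosis,
    mann_whitney_exact,
    standardize_by_length,
)

BODY_WEIGHT_MEANS = {"PC": 41.3, "PB": 14.4, "F1BC": 19.5, "F1CB": 23.3}


class TestHeterosis:
    def test_f1_at_midparent_is_zero(self):
        r = heterosis({"PC": 10, "PB": 20, "F1BC": 15, "F1CB": 15})
        assert r.heterosis_pct == pytest.approx(0.0)

    def test_f1_above_midparent(self):
        r = heterosis({"PC": 10, "PB": 20, "F1BC": 18, "F1CB": 18})
        assert r.heterosis_pct == pytest.approx(20.0)

    def test_tank_culture_body_weight_is_negative(self):
        """F1 mean 21.4 vs mid-parent 27.85: growth heterosis is absent."""
        r = heterosis(BODY_WEIGHT_MEANS, trait="body_weight")
        assert r.midparent == pytest.approx(27.85)
        assert r.f1_mean == pytest.approx(21.4)
        assert r.heterosis_pct == pytest.approx(100 * (21.4 - 27.85) / 27.85)
        assert r.heterosis_pct == pytest.approx(-23.2, abs=0.05)

    @given(st.floats(min_value=0.01, max_value=1000))
    def test_common_rescaling_invariance(self, c):
        base = heterosis(BODY_WEIGHT_MEANS).heterosis_pct
        scaled = heterosis({k: c * v for k, v in BODY_WEIGHT_MEANS.items()})
        assert scaled.heterosis_pct == pytest.approx(base, rel=1e-9)

    def test_sign_flips_when_f1s_mirror_around_midparent(self):
        means = {"PC": 10.0, "PB": 20.0, "F1BC": 18.0, "F1CB": 18.0}
        mid = 15.0
        mirrored = dict(means, F1BC=2 * mid - 18.0, F1CB=2 * mid - 18.0)
        assert heterosis(mirrored).heterosis_pct == pytest.approx(
            -heterosis(means).heterosis_pct
        )

    def test_zero_midparent_signalled(self):
        with pytest.raises(ValidationError):
            heterosis({"PC": 0, "PB": 0, "F1BC": 1, "F1CB": 1})

    def test_missing_type_signalled(self):
        with pytest.raises(ValidationError, match="F1CB"):
            heterosis({"PC": 1, "PB": 2, "F1BC": 3})


class TestHeterobeltiosis:
    def test_exceeding_the_best_parent(self):
        best, hb, exceeds = heterobeltiosis({"PC": 10, "PB": 20, "F1BC": 25, "F1CB": 25})
        assert (best, hb, exceeds) == ("PB", pytest.approx(25.0), True)

    def test_matching_the_best_parent_does_not_exceed(self):
        _, hb, exceeds = heterobeltiosis({"PC": 10, "PB": 20, "F1BC": 20, "F1CB": 20})
        assert hb == pytest.approx(0.0)
        assert exceeds is False

    def test_tank_culture_body_weight(self):
        best, hb, exceeds = heterobeltiosis(BODY_WEIGHT_MEANS)
        assert best == "PC"
        assert hb == pytest.approx(100 * (21.4 - 41.3) / 41.3)
        assert hb == pytest.approx(-48.2, abs=0.05)
        assert exceeds is False


class TestStandardizeByLength:
    def test_simple_ratio(self):
        t = pd.DataFrame(
            {
                "individual_id": ["a"],
                "genetic_type": ["PC"],
                "total_length": [2.0],
                "body_depth": [1.0],
            }
        )
        out = standardize_by_length(t)
        assert out.loc[0, "body_depth"] == pytest.approx(0.5)
        assert out.loc[0, "total_length"] == pytest.approx(2.0)

    def test_identical_fish_stay_identical(self):
        t = pd.DataFrame(
            {
                "individual_id": ["a", "b"],
                "genetic_type": ["PC", "PB"],
                "total_length": [3.0, 3.0],
                "body_weight": [6.0, 6.0],
            }
        )
        out = standardize_by_length(t)
        assert out["body_weight"].nunique() == 1

    def test_matches_rowwise_division_oracle(self, rng):
        n = 24
        t = pd.DataFrame(
            {
                "individual_id": [f"f{i}" for i in range(n)],
                "genetic_type": ["PC", "PB", "F1BC", "F1CB"] * 6,
                "total_length": rng.uniform(10, 20, n),
                "body_weight": rng.uniform(10, 50, n),
                "head_depth": rng.uniform(1, 4, n),
            }
        )
        out = standardize_by_length(t)
        for col in ("body_weight", "head_depth"):
            assert np.allclose(out[col], t[col] / t["total_length"])

    def test_zero_length_rejected(self):
        t = pd.DataFrame(
            {
                "individual_id": ["a"],
                "genetic_type": ["PC"],
                "total_length": [0.0],
                "body_depth": [1.0],
            }
        )
        with pytest.raises(ValidationError):
            standardize_by_length(t)


def oracle_mwu_two_sided(x, y):
    """Permutation-distribution oracle built from direct pair counting."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_of(range(n1))
    us = [u_of(idx) for idx in combinations(range(n), n1)]
    m = len(us)
    p_le = sum(u <= u_obs + 1e-9 for u in us) / m
    p_ge = sum(u >= u_obs - 1e-9 for u in us) / m
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitneyExact:
    def test_complete_separation_three_vs_three(self):
        res = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.p_two_sided == pytest.approx(2 / 20)
        assert res.method == "exact"

    def test_single_tied_pair(self):
        res = mann_whitney_exact([5.0], [5.0])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_complete_separation_six_vs_six(self):
        """The design's group size: the most extreme split of C(12,6)=924."""
        res = mann_whitney_exact(np.arange(6), np.arange(10, 16))
        assert res.p_two_sided == pytest.approx(2 / 924)

    @pytest.mark.parametrize("n1,n2", [(1, 5), (2, 4), (3, 3), (4, 5), (5, 5), (6, 6)])
    def test_matches_permutation_oracle_with_ties(self, n1, n2, rng):
        x = rng.integers(0, 4, size=n1).astype(float)  # coarse grid forces ties
        y = rng.integers(0, 4, size=n2).astype(float)
        got = mann_whitney_exact(x, y)
        u_want, p_want = oracle_mwu_two_sided(x, y)
        assert got.U == pytest.approx(u_want)
        assert got.p_two_sided == pytest.approx(p_want)

    def test_agrees_with_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(1.0, size=6)
        got = mann_whitney_exact(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert got.U == pytest.approx(ref.statistic)
        assert got.p_two_sided == pytest.approx(ref.pvalue)

    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=5),
        st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=5),
    )
    def test_u_complement_and_swap_invariance(self, x, y):
        a = mann_whitney_exact(x, y)
        b = mann_whitney_exact(y, x)
        assert a.U + b.U == pytest.approx(len(x) * len(y))
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_large_samples_fall_back_to_normal_approx(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = mann_whitney_exact(x, y)
        assert res.method == "normal-approx"
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_exact([], [1.0])

    def test_exact_cap_respected(self):
        assert comb(12, 6) == 924  # the study's size stays in the exact regime
        res = mann_whitney_exact(np.arange(6), np.arange(6) + 0.5, exact_cap=900)
        assert res.method == "normal-approx"
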