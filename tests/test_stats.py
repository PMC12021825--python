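"""Rank-sum comparisons, normality screen, summaries, histograms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonmorph import (adjust_pvalues, compare_groups, histogram,
                       mann_whitney_u, relative_change, shapiro_wilk,
                       summarize)


def exact_two_sided_p(x, y):
    """Independent oracle: exhaustive enumeration of all rank splits."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    mu = n1 * len(y) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = sum(1 for xi in xs for yj in ys if xi > yj) \
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_tiny_sample_exact(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.U == 0
        assert r.method == "exact"
        assert r.p == pytest.approx(0.100, abs=1e-9)

    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney_u(x, list(x))
        assert r.U == pytest.approx(len(x) ** 2 / 2)
        assert r.p == pytest.approx(1.0)
        assert r.direction == "a=b"

    def test_antisymmetry_under_argument_swap(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        r1 = mann_whitney_u(x, y)
        r2 = mann_whitney_u(y, x)
        assert r1.U + r2.U == pytest.approx(len(x) * len(y))
        assert r1.p == pytest.approx(r2.p)

    def test_reported_p_tracks_enumeration_at_small_n(self):
        """For tie-free samples with n1+n2 <= 12 the returned p comes from
        the exact permutation path and matches exhaustive enumeration; the
        plain normal approximation stays within its known small-sample
        deviation envelope (<= 0.05 for n1, n2 >= 3)."""
        rng = np.random.default_rng(17)
        for n1, n2 in [(3, 3), (4, 4), (5, 5), (6, 6), (4, 8), (3, 9)]:
            for _ in range(4):
                pooled = rng.permutation(rng.normal(size=n1 + n2))
                x, y = pooled[:n1], pooled[n1:]
                r = mann_whitney_u(x, y)
                assert r.method == "exact"
                assert abs(r.p - exact_two_sided_p(x, y)) < 1e-12
                r_asym = mann_whitney_u(x, y, exact_threshold=0)
                assert r_asym.method == "asymptotic"
                assert abs(r_asym.p - exact_two_sided_p(x, y)) < 0.05

    def test_exact_path_matches_enumeration_exactly(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=5), rng.normal(size=6)
        r = mann_whitney_u(x, y)
        assert r.method == "exact"
        assert r.p == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=12),
           st.lists(st.integers(0, 5), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_u_complement_identity_with_ties(self, x, y):
        r1 = mann_whitney_u(x, y)
        r2 = mann_whitney_u(y, x)
        assert r1.U + r2.U == pytest.approx(len(x) * len(y))
        assert 0 <= r1.U <= len(x) * len(y)
        assert 0 < r1.p <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestShapiroWilk:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(1)
        W, p = shapiro_wilk(rng.normal(0, 1, 100))
        assert p > 0.05
        assert 0 < W <= 1

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-4, 0.3, 50), rng.normal(4, 0.3, 50)])
        _, p = shapiro_wilk(x)
        assert p < 0.001

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([3.0] * 10)

    def test_subsampling_is_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=9000)
        assert shapiro_wilk(x, n_max=500) == shapiro_wilk(x, n_max=500)


class TestSummarize:
    def test_closed_form(self):
        s = summarize([0.6, 0.7, 0.8])
        assert s["mean"] == pytest.approx(0.7)
        assert s["sd"] == pytest.approx(0.1)
        assert s["median"] == pytest.approx(0.7)
        assert s["n"] == 3

    def test_singleton_flagged(self):
        s = summarize([1.5])
        assert s["sd"] == 0.0 and not s["sd_defined"]

    def test_translation_equivariance(self):
        a = summarize([1.0, 2.0, 5.0])
        b = summarize([11.0, 12.0, 15.0])
        assert b["mean"] == pytest.approx(a["mean"] + 10)
        assert b["sd"] == pytest.approx(a["sd"])


class TestRelativeChange:
    def test_whole_section_counts(self):
        # the two whole-section instance counts of the source study
        assert round(relative_change(625754, 458671), 1) == 36.4

    def test_no_change_and_simple_case(self):
        assert relative_change(42, 42) == 0.0
        assert relative_change(150, 100) == pytest.approx(50.0)

    def test_reciprocal_identity(self):
        r_ab = relative_change(625754, 458671)
        r_ba = relative_change(458671, 625754)
        assert (1 + r_ab / 100) * (1 + r_ba / 100) == pytest.approx(1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_change(5, 0)


def _group_table(rng, n, thickness_shift=0.0):
    sub = rng.choice(["genu", "body", "splenium"], size=n)
    return pd.DataFrame({
        "thickness_dt": rng.normal(0.168 + thickness_shift, 0.014, n),
        "g_ratio": rng.normal(0.699, 0.025, n),
        "subregion": sub,
    })


class TestCompareGroups:
    def test_identical_tables_give_p_one(self):
        rng = np.random.default_rng(4)
        t = _group_table(rng, 60)
        res = compare_groups({"wt": t, "mut": t.copy()}, ["thickness_dt"])
        assert all(r.p == pytest.approx(1.0) for r in res)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        a = _group_table(rng, 500)
        b = _group_table(rng, 500, thickness_shift=0.05)
        res = compare_groups({"wt": a, "mut": b}, ["thickness_dt"])
        assert res[0].p < 0.001
        assert res[0].direction == "a<b"

    def test_stratified_structure(self):
        rng = np.random.default_rng(8)
        a, b = _group_table(rng, 90), _group_table(rng, 90)
        res = compare_groups({"wt": a, "mut": b}, ["g_ratio"],
                             strata="subregion")
        # 1 pooled + 3 between-group-within-subregion
        #   + 2 groups * C(3,2) between-subregion-within-group
        assert len(res) == 1 + 3 + 6
        strata = [r.stratum for r in res]
        for s in ("genu", "body", "splenium"):
            assert s in strata

    def test_missing_metric_errors(self):
        rng = np.random.default_rng(9)
        with pytest.raises(KeyError):
            compare_groups({"wt": _group_table(rng, 10)}, ["nope"])


class TestHistogram:
    def test_single_bin(self):
        edges, counts = histogram([1, 1, 1], bins=1)
        assert counts.tolist() == [3]

    def test_uniform_grid_ten_equal_bins(self):
        vals = (np.arange(100) + 0.5) / 100.0  # bin midpoints, no edge hits
        edges, counts = histogram(vals, bins=np.linspace(0, 1, 11))
        assert counts.tolist() == [10] * 10

    def test_counts_conservation_random_input(self):
        rng = np.random.default_rng(10)
        x = rng.lognormal(size=357)
        _, counts = histogram(x)  # Freedman-Diaconis default
        assert counts.sum() == 357


class TestAdjustment:
    def test_bonferroni_and_bh(self):
        class R:
            def __init__(self, p):
                self.p = p

        res = [R(0.01), R(0.02), R(0.04)]
        np.testing.assert_allclose(adjust_pvalues(res, "bonferroni"),
                                   [0.03, 0.06, 0.12])
        np.testing.assert_allclose(adjust_pvalues(res, "bh"),
                                   [0.03, 0.03, 0.04])
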