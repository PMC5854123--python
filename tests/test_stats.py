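"""Randomization tests: p-value arithmetic, nulls, correlation procedures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import dronehap as dh
from dronehap.datasets import observed_variance, per_drone_snm_counts
from dronehap.errors import (InputError, ParameterError, UndefinedResultError)


class TestMcPvalue:
    @pytest.mark.parametrize("n,m,expect", [
        (73, 10_000, 0.0074), (8_245, 10_000, 0.8245), (0, 1, 0.5),
    ])
    def test_published_and_degenerate_values(self, n, m, expect):
        assert round(dh.mc_pvalue(n, m), 4) == expect

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_bounds_and_monotonicity(self, a, b):
        reps = max(a, b)
        p1, p2 = dh.mc_pvalue(min(a, b), reps), dh.mc_pvalue(max(a, b), reps)
        assert 0 < p1 <= p2 <= 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            dh.mc_pvalue(5, 4)
        with pytest.raises(ParameterError):
            dh.mc_pvalue(-1, 10)


class TestMergeRankCorrelate:
    def _table(self, n=200, seed=0, rho=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        return pd.DataFrame({"x": x, "y": y})

    def test_identity_gives_perfect_correlation(self):
        t = self._table(100, seed=1)
        t["y"] = t["x"]
        out = dh.merge_rank_correlate(t, "x", "y", n_bins=23)
        assert out["r"] == pytest.approx(1.0)

    def test_independent_columns_give_small_r(self):
        rs = [dh.merge_rank_correlate(self._table(400, seed=s), "x", "y")["r"]
              for s in range(5)]
        assert np.mean(np.abs(rs)) < 0.5  # bin means of noise stay uncorrelated

    def test_bin_sizes_differ_by_at_most_one(self):
        out = dh.merge_rank_correlate(self._table(230, seed=2), "x", "y",
                                      n_bins=21)
        sizes = out["bin_sizes"]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 230

    def test_unconventional_bin_count_warns_but_computes(self):
        with pytest.warns(UserWarning):
            out = dh.merge_rank_correlate(self._table(100, seed=3), "x", "y",
                                          n_bins=10)
        assert np.isfinite(out["r"])


class TestPartialSpearman:
    def test_independent_control_leaves_plain_spearman(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=600)
        y = 0.6 * x + rng.normal(size=600)
        z = rng.normal(size=600)
        plain = sps.spearmanr(x, y).statistic
        partial = dh.partial_spearman(x, y, z)
        assert abs(partial - plain) < 0.08

    def test_degenerate_control_is_flagged(self):
        x = np.arange(10.0)
        y = x[::-1].copy()
        with pytest.raises(UndefinedResultError):
            dh.partial_spearman(x, y, y)  # control equals y exactly
        with pytest.raises(UndefinedResultError):
            dh.partial_spearman(x, np.ones(10), np.arange(10.0))

    def test_matches_closed_form_on_trivariate_normal(self):
        # known correlations: partial = (rxy - rxz*ryz)/sqrt((1-rxz^2)(1-ryz^2))
        rng = np.random.default_rng(5)
        rxy, rxz, ryz = 0.6, 0.5, 0.4
        cov = np.array([[1, rxy, rxz], [rxy, 1, ryz], [rxz, ryz, 1]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        expect = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        got = dh.partial_spearman(data[:, 0], data[:, 1], data[:, 2])
        assert abs(got - expect) < 0.05


class TestDispersionTest:
    def test_published_fixture_variance(self):
        counts = per_drone_snm_counts()
        assert len(counts) == 32 and counts.sum() == 23
        assert round(observed_variance(), 3) == 0.789

    def test_equal_counts_never_overdispersed(self):
        res = dh.dispersion_test(np.full(10, 2), reps=500, seed=1)
        assert res.observed == 0.0 and res.p > 0.99

    def test_null_mean_matches_multinomial_oracle(self):
        counts = per_drone_snm_counts().to_numpy()
        res = dh.dispersion_test(counts, reps=20_000, seed=2)
        n, total = len(counts), counts.sum()
        # with the row sum fixed, E[(n-1)-denominator variance] of
        # equal-probability multinomial counts is exactly total/n:
        # sum Var(c_i) = total (1 - 1/n) over n - 1 degrees of freedom
        expect = total / n
        assert res.extra["null_mean_variance"] == pytest.approx(expect, rel=0.02)
        # this is the study's printed null mean variance at 23 over 32
        assert round(expect, 3) == 0.719

    def test_seeded_reproducibility(self):
        counts = per_drone_snm_counts().to_numpy()
        a = dh.dispersion_test(counts, reps=1000, seed=3)
        b = dh.dispersion_test(counts, reps=1000, seed=3)
        assert a.p == b.p and a.n_extreme == b.n_extreme


class TestColonyHeterogeneity:
    def test_published_expectations(self):
        out = dh.colony_heterogeneity([17, 6], [22, 10])
        assert round(out["expected"][0], 2) == 15.81
        assert round(out["expected"][1], 2) == 7.19

    def test_equal_observed_and_expected_gives_zero(self):
        out = dh.colony_heterogeneity([11, 5], [22, 10])
        assert out["chi2"] == pytest.approx(0.0)

    def test_matches_direct_cell_summation(self):
        obs, sizes = np.array([17.0, 6.0]), np.array([22.0, 10.0])
        out = dh.colony_heterogeneity(obs, sizes)
        exp = obs.sum() * sizes / sizes.sum()
        brute = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert out["chi2"] == pytest.approx(brute)

    def test_zero_total_rejected(self):
        with pytest.raises(UndefinedResultError):
            dh.colony_heterogeneity([0, 0], [22, 10])


def _co_events(rows):
    return pd.DataFrame([
        {"drone": d, "chrom": c, "phase_set": 0, "kind": "CO",
         "left": l, "right": r, "tract_start": np.nan, "tract_end": np.nan,
         "n_converted": 0, "shared_group": -1, "category": 0,
         "excluded": False, "reason": "", "gap_overlap": False}
        for d, c, l, r in rows])


class TestProximityTest:
    def test_mutation_146bp_from_breakpoint_counts_as_proximal(self):
        events = _co_events([("D1", "c1", 499_854, 500_000)])
        muts = pd.DataFrame({"drone": ["D1"], "chrom": ["c1"],
                             "pos": [500_146]})  # 146 bp past the interval
        res = dh.proximity_test(muts, events, {"c1": 10_000_000},
                                window_bp=1_000, reps=200, seed=1)
        assert res.observed == 1.0

    def test_zero_window_counts_only_exact_coincidence(self):
        events = _co_events([("D1", "c1", 100, 200)])
        muts = pd.DataFrame({"drone": ["D1", "D1"], "chrom": ["c1", "c1"],
                             "pos": [200, 201]})
        res = dh.proximity_test(muts, events, {"c1": 1_000_000},
                                window_bp=0, reps=200, seed=2)
        assert res.observed == 1.0

    def test_other_drones_breakpoints_do_not_count_unless_pooled(self):
        events = _co_events([("D2", "c1", 100, 200)])
        muts = pd.DataFrame({"drone": ["D1"], "chrom": ["c1"], "pos": [150]})
        own = dh.proximity_test(muts, events, {"c1": 1_000_000},
                                reps=200, seed=3)
        pooled = dh.proximity_test(muts, events, {"c1": 1_000_000},
                                   reps=200, seed=3, pooled=True)
        assert own.observed == 0.0 and pooled.observed == 1.0

    def test_null_rate_matches_analytic_approximation(self):
        # k breakpoints per drone, window w, genome L: per-site proximal
        # probability ~ 2wk/L (small-w), so E[null count] ~ n * 2wk/L
        rng = np.random.default_rng(6)
        L, k, w, n = 50_000_000, 20, 1_000, 40
        rows = []
        for i in range(4):
            for p in rng.integers(0, L, size=k):
                rows.append((f"D{i}", "c1", int(p), int(p) + 1))
        events = _co_events(rows)
        muts = pd.DataFrame({"drone": [f"D{i % 4}" for i in range(n)],
                             "chrom": "c1", "pos": rng.integers(0, L, size=n)})
        res = dh.proximity_test(muts, events, {"c1": L}, window_bp=w,
                                reps=4_000, seed=7)
        expect = n * 2 * w * k / L
        sd = np.sqrt(expect / 4_000) * 10  # generous Monte-Carlo tolerance
        assert abs(res.null.mean() - expect) < max(3 * sd, 0.3 * expect)

    def test_no_events_is_undefined(self):
        muts = pd.DataFrame({"drone": ["D1"], "chrom": ["c1"], "pos": [1]})
        with pytest.raises(UndefinedResultError):
            dh.proximity_test(muts, _co_events([]), {"c1": 100}, reps=200)


class TestConversionBias:
    def test_no_informative_sites_declines(self):
        conv = pd.DataFrame({"from_allele": ["G", "A"], "to_allele": ["C", "T"]})
        res = dh.conversion_bias_test(conv, reps=100, seed=1)
        assert res.extra["declined"] and np.isnan(res.p)

    def test_published_direction_split(self):
        conv = pd.DataFrame({
            "from_allele": ["A"] * 23 + ["G"] * 13,
            "to_allele": ["G"] * 23 + ["A"] * 13})
        res = dh.conversion_bias_test(conv, reps=2_000, seed=2)
        assert res.extra["toward_gc"] == 23 and res.extra["toward_at"] == 13

    def test_binomial_closed_form_matches_exact_tail_summation(self):
        conv = pd.DataFrame({
            "from_allele": ["A"] * 23 + ["G"] * 13,
            "to_allele": ["G"] * 23 + ["A"] * 13})
        res = dh.conversion_bias_test(conv, reps=500, seed=3)
        # oracle: two-sided exact binomial tail sum at 23/36, fair coin
        pmf = np.array([sps.binom.pmf(k, 36, 0.5) for k in range(37)])
        p_two = float(pmf[pmf <= pmf[23] * (1 + 1e-9)].sum())
        assert res.extra["binomial_p_two_sided"] == pytest.approx(p_two, rel=1e-6)
        # the 0.066 tail is the one-sided P(X >= 23)
        assert round(res.extra["binomial_p_one_sided"], 3) == 0.066


class TestRateDifferencePermutation:
    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        res = dh.rate_difference_permutation(a, a.copy(), reps=500, seed=1)
        assert res.observed == 0.0 and res.p == 1.0

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for s in range(60):
            pooled = rng.poisson(3.0, size=30).astype(float)
            res = dh.rate_difference_permutation(pooled[:18], pooled[18:],
                                                 reps=199, seed=s)
            ps.append(res.p)
        assert 0.2 < np.mean(ps) < 0.8
        assert min(ps) < 0.3 and max(ps) > 0.7

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            dh.rate_difference_permutation([], [1.0], reps=100)


class TestWindowTable:
    def test_gc_het_and_rates_tabulated(self, sim_colony, events):
        wt = dh.build_window_table(
            sim_colony.queen.reference, sim_colony.queen.het_positions,
            events, n_drones=10, window_bp=500_000)
        assert {"gc", "het", "cm_per_mb"} <= set(wt.columns)
        assert ((wt["gc"] > 0.2) & (wt["gc"] < 0.55)).all()
        # overall heterozygosity close to the simulated 0.26%
        total_het = (wt["het"] * (wt["end"] - wt["start"])).sum()
        assert total_het == pytest.approx(sim_colony.queen.n_het, rel=1e-6)
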