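"""ΔΔCt, t-tests, correlations, clustering, exact Fisher and survival."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cafkit.stats import (
    StatsError,
    cluster_two,
    correlation_matrix,
    cox_stepwise,
    ddct,
    fisher_exact,
    fisher_exact_mc,
    km_logrank,
    one_sample_test,
    paired_test,
)
from cafkit.synthetic import SimConfig, gen_qpcr


def qpcr_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample", "condition", "gene", "ct_target", "ct_ref"]
    )


class TestDdct:
    def test_control_matching_sample_gives_fold_one(self):
        df = qpcr_frame([
            ("c1", "control", "MCT1", 22.0, 20.0),
            ("s1", "coculture", "MCT1", 22.0, 20.0),
        ])
        out = ddct(df, "control")
        assert out.loc[1, "fold_change"] == pytest.approx(1.0)

    def test_ddct_minus_two_gives_fold_four(self):
        df = qpcr_frame([
            ("c1", "control", "MCT1", 22.0, 20.0),
            ("s1", "coculture", "MCT1", 20.0, 20.0),
        ])
        out = ddct(df, "control")
        assert out.loc[1, "ddct"] == pytest.approx(-2.0)
        assert out.loc[1, "fold_change"] == pytest.approx(4.0)

    def test_missing_control_named(self):
        df = qpcr_frame([("s1", "coculture", "MCT4", 22.0, 20.0)])
        with pytest.raises(StatsError, match="MCT4"):
            ddct(df, "control")

    def test_planted_fold_change_recovered(self):
        recovered = []
        for seed in range(10):
            cfg = SimConfig(seed=seed)
            cfg.qpcr_spec.true_log2fc = {"MCT1": {"coculture": 1.5}}
            table, _ = gen_qpcr(cfg)
            out = ddct(table, "control")
            cc = out[out["condition"] == "coculture"]
            recovered.append(cc["log2fc"].mean())
        # mean over seeds within 3 sd of the planted value
        se = np.std(recovered, ddof=1) / math.sqrt(len(recovered))
        assert abs(np.mean(recovered) - 1.5) <= 3 * se + 1e-9


class TestSmallSampleTests:
    def test_symmetric_values_null(self):
        t, p = one_sample_test([-1.0, 1.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_t_formula(self):
        vals = [1.0, 1.1, 0.9]
        t, p = one_sample_test(vals)
        t_hand = np.mean(vals) / (np.std(vals, ddof=1) / math.sqrt(3))
        assert t == pytest.approx(t_hand)
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            one_sample_test([2.0, 2.0, 2.0])

    def test_paired_identical(self):
        t, p = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_paired_constant_difference(self):
        # zero within-pair noise: p shrinks as n grows
        ps = []
        for n in (3, 6, 12):
            before = list(np.linspace(0, 1, n))
            after = [b + 0.5 + 1e-6 * i for i, b in enumerate(before)]
            ps.append(paired_test(before, after)[1])
        assert ps[2] < ps[1] < ps[0]

    def test_paired_length_mismatch(self):
        with pytest.raises(StatsError):
            paired_test([1.0, 2.0], [1.0])

    @pytest.mark.parametrize("kind", ["one_sample", "paired"])
    def test_type_one_error_calibrated(self, kind, rng):
        n, reps = 8, 1000
        if kind == "one_sample":
            x = rng.normal(size=(reps, n))
            p = sps.ttest_1samp(x, 0.0, axis=1).pvalue
        else:
            a = rng.normal(size=(reps, n))
            b = rng.normal(size=(reps, n))
            p = sps.ttest_rel(a, b, axis=1).pvalue
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07


class TestCorrelationMatrix:
    def test_self_correlation_and_planted(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = 0.8 * x + math.sqrt(1 - 0.64) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        out = correlation_matrix(df)
        assert out["r"].loc["x", "x"] == 1.0
        assert abs(out["r"].loc["x", "y"] - 0.8) <= 0.1
        assert out["significant"].loc["x", "y"]

    def test_independent_columns_mostly_insignificant(self):
        hits = 0
        for seed in range(40):
            g = np.random.default_rng(seed)
            df = pd.DataFrame({"a": g.normal(size=50), "b": g.normal(size=50)})
            out = correlation_matrix(df)
            hits += abs(out["r"].loc["a", "b"]) < 0.3
        assert hits >= 38  # >= 95% of seeds

    def test_constant_column_flagged_not_raised(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0],
                           "b": [1.0, 2.0, 3.0, 4.0]})
        out = correlation_matrix(df)
        assert np.isnan(out["r"].loc["a", "b"])
        assert not out["significant"].loc["a", "b"]


class TestClusterTwo:
    @staticmethod
    def blobs(rng, n1=20, n2=15, sep=4.0):
        genes = ["MCT1", "MCT4", "CD147", "CAV1", "ACTA2"]
        lo = rng.normal(0.0, 1.0, size=(n1, 5))
        hi = rng.normal(sep, 1.0, size=(n2, 5))
        x = pd.DataFrame(np.vstack([lo, hi]), columns=genes,
                         index=[f"s{i}" for i in range(n1 + n2)])
        truth = np.array([1] * n1 + [2] * n2)
        return x, truth

    def test_two_samples_split(self):
        x, _ = self.blobs(np.random.default_rng(0), n1=1, n2=1)
        lab = cluster_two(x)
        assert set(lab) == {1, 2}

    def test_separated_blobs_recovered_with_low_cluster_first(self, rng):
        x, truth = self.blobs(rng)
        lab = cluster_two(x)
        assert np.array_equal(lab.values, truth)  # cluster 1 = low expression

    def test_duplicates_co_cluster(self, rng):
        x, _ = self.blobs(rng)
        doubled = pd.concat([x, x.set_index(x.index + "_dup")])
        lab = cluster_two(doubled)
        for s in x.index:
            assert lab[s] == lab[s + "_dup"]

    def test_sample_order_and_affine_invariance(self, rng):
        x, _ = self.blobs(rng)
        lab = cluster_two(x)
        shuffled = x.sample(frac=1.0, random_state=1)
        assert (cluster_two(shuffled).sort_index() == lab.sort_index()).all()
        rescaled = x * 3.0 + 100.0
        assert (cluster_two(rescaled) == lab).all()

    def test_missing_panel_gene(self):
        with pytest.raises(StatsError):
            cluster_two(pd.DataFrame({"MCT1": [1.0, 2.0]}))


def exact_2x2_p(a, b, c, d):
    """Independent oracle: exact integer enumeration for a 2x2 table."""
    r1, c1, n = a + b, a + c, a + b + c + d
    n_obs = math.comb(c1, a) * math.comb(n - c1, r1 - a)
    total = 0
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        w = math.comb(c1, x) * math.comb(n - c1, r1 - x)
        if w <= n_obs:
            total += w
    return total / math.comb(n, r1)


def exact_2x3_p(row1, row2):
    """Independent oracle for 2x3 tables, exact integer arithmetic."""
    cols = [row1[i] + row2[i] for i in range(3)]
    r1 = sum(row1)
    n = r1 + sum(row2)
    n_obs = math.prod(math.comb(cols[i], row1[i]) for i in range(3))
    total = 0
    for x in range(cols[0] + 1):
        for y in range(cols[1] + 1):
            z = r1 - x - y
            if 0 <= z <= cols[2]:
                w = math.comb(cols[0], x) * math.comb(cols[1], y) \
                    * math.comb(cols[2], z)
                if w <= n_obs:
                    total += w
    return total / math.comb(n, r1)


class TestFisherExact:
    def test_proportional_rows(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_paper_style_2x4(self):
        p = fisher_exact([[12, 9, 12, 4], [6, 2, 2, 8]])
        assert round(p, 5) == 0.03059

    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            ours = fisher_exact(t)
            ref = sps.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_all_2x2_totals_up_to_15_match_bruteforce(self):
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        ours = fisher_exact([[a, b], [c, d]])
                        oracle = exact_2x2_p(a, b, c, d)
                        assert abs(ours - oracle) < 1e-10, (a, b, c, d)

    def test_2x3_totals_up_to_15_match_bruteforce(self):
        rng = np.random.default_rng(99)
        # exhaustive over all 2x3 tables at total 15 is large; cover all
        # first rows and random second rows at several totals
        for n in (5, 9, 15):
            for _ in range(200):
                flat = rng.multinomial(n, np.ones(6) / 6)
                t = flat.reshape(2, 3)
                ours = fisher_exact(t)
                oracle = exact_2x3_p(tuple(t[0]), tuple(t[1]))
                assert abs(ours - oracle) < 1e-10, t

    def test_p_in_unit_interval_and_row_relabel_invariant(self, rng):
        for _ in range(30):
            t = rng.integers(0, 10, size=(3, 3))
            if t.sum() == 0:
                continue
            p = fisher_exact(t)
            assert 0.0 <= p <= 1.0
            assert fisher_exact(t[::-1]) == pytest.approx(p, abs=1e-12)
            assert fisher_exact(t.T) == pytest.approx(p, abs=1e-12)

    def test_enumeration_guard_and_mc_fallback(self):
        big = np.full((2, 2), 200)
        with pytest.raises(StatsError, match="Monte-Carlo"):
            fisher_exact(big)
        small = [[8, 2], [3, 7]]
        p_mc = fisher_exact_mc(small, n_permutations=20000, seed=5)
        assert p_mc == pytest.approx(fisher_exact(small), abs=0.01)


class TestSurvival:
    @staticmethod
    def sim_survival(seed, n=200, hr=3.0, p2=0.4, censor_to=3000.0):
        rng = np.random.default_rng(seed)
        group = (rng.random(n) < p2).astype(int)
        t = rng.exponential(1.0 / (0.001 * hr**group))
        c = rng.uniform(0, censor_to, n)
        return pd.DataFrame({
            "time": np.minimum(t, c), "event": (t <= c).astype(int),
            "group": group,
        })

    def test_identical_groups_logrank_null(self):
        df = self.sim_survival(0, n=60, hr=1.0)
        dup = pd.concat([df.assign(group=0), df.assign(group=1)])
        res = km_logrank(dup, "group")
        assert res.logrank_p == pytest.approx(1.0)

    def test_extreme_separation(self):
        df = pd.DataFrame({
            "time": list(range(1, 21)) + list(range(100, 120)),
            "event": [1] * 40,
            "group": ["A"] * 20 + ["B"] * 20,
        })
        res = km_logrank(df, "group")
        assert res.logrank_p < 1e-6

    def test_single_group_no_test(self):
        df = self.sim_survival(1).assign(group=0)
        res = km_logrank(df, "group")
        assert res.logrank_p is None and len(res.curves) == 1

    def test_logrank_power_on_planted_hazard_ratio(self):
        hits = sum(
            km_logrank(self.sim_survival(seed), "group").logrank_p < 0.05
            for seed in range(20)
        )
        assert hits >= 18  # >= 90% of seeds

    def test_km_curve_is_product_limit(self):
        # no censoring: survival steps to k/n after the k-th ordered death
        df = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1],
                           "group": [0] * 4})
        res = km_logrank(df, "group")
        curve = res.curves["0"]
        assert curve.loc[2.0].iloc[0] == pytest.approx(0.5)
        assert curve.loc[4.0].iloc[0] == pytest.approx(0.0)


class TestCoxStepwise:
    @staticmethod
    def sim_cox(seed, n=300, hr=3.0, noise_covs=4):
        rng = np.random.default_rng(seed)
        cluster = (rng.random(n) < 0.4).astype(int)
        t = rng.exponential(1.0 / (0.001 * hr**cluster))
        c = rng.uniform(0, 3000, n)
        df = pd.DataFrame({
            "time": np.minimum(t, c), "event": (t <= c).astype(int),
            "cluster": cluster,
        })
        for i in range(noise_covs):
            df[f"x{i}"] = rng.integers(0, 2, n)
        return df

    def test_no_events_rejected(self):
        df = self.sim_cox(0).assign(event=0)
        with pytest.raises(StatsError):
            cox_stepwise(df, ["cluster"])

    def test_planted_effect_retained(self):
        df = self.sim_cox(3)
        res = cox_stepwise(df, ["cluster"] + [f"x{i}" for i in range(4)])
        assert "cluster" in res.selected
        hr = res.summary.loc["cluster", "HR"]
        assert 1.5 < hr < 6.0

    def test_coefficient_recovery_single_covariate(self):
        df = self.sim_cox(4, n=500, noise_covs=0)
        res = cox_stepwise(df, ["cluster"])
        beta = math.log(res.summary.loc["cluster", "HR"])
        assert abs(beta - math.log(3.0)) <= 0.2

    def test_degenerate_covariate_flagged(self):
        df = self.sim_cox(5)
        df["const"] = 1
        res = cox_stepwise(df, ["cluster", "const"])
        assert "const" in res.failed
        assert "cluster" in res.selected
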