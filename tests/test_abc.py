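import numpy as np
import pandas as pd
import pytest

from peripagen import abc as ab
from peripagen import coalescent as ce


def toy_table(rng, n_per=60, sep=3.0, n_stats=3):
    """2-scenario Gaussian-statistic toy reference table."""
    rows = []
    for s, mu in (("S1", 0.0), ("S2", sep)):
        for r in range(n_per):
            x = rng.normal(mu, 1.0, n_stats)
            rows.append({"scenario": s, "theta": rng.uniform(1, 2),
                         **{f"x{i}": x[i] for i in range(n_stats)}})
    return ab.ReferenceTable(pd.DataFrame(rows),
                             [f"x{i}" for i in range(n_stats)], ["theta"])


class TestPriors:
    def test_bounds_and_mean(self):
        spec = ab.PriorSpec({"a": (0.0, 1.0)})
        df = ab.sample_priors(spec, 10_000, seed=1)
        assert df["a"].min() >= 0 and df["a"].max() <= 1
        assert abs(df["a"].mean() - 0.5) < 3 * df["a"].std() / 100

    def test_order_constraint_always_satisfied(self):
        spec = ab.PriorSpec({"t0": (0.0, 10.0), "t3": (0.0, 10.0)},
                            constraints=[("t0", "t3")])
        df = ab.sample_priors(spec, 5000, seed=2)
        assert (df["t0"] < df["t3"]).all()

    def test_log_uniform_median(self):
        spec = ab.PriorSpec({"N": (1e3, 1e6, "log")})
        df = ab.sample_priors(spec, 20_000, seed=3)
        assert np.log10(df["N"].median()) == pytest.approx(4.5, abs=0.05)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ab.PriorSpec({"a": (1.0, 0.5)})


class TestRejection:
    def test_exact_row_retained_first(self, rng):
        table = toy_table(rng)
        obs = table.df.loc[17, table.stat_names].to_numpy(float)
        kept = ab.abc_reject(obs, table, tolerance=1.0 / len(table.df))
        assert len(kept) == 1 and kept.index[0] == 17

    def test_tolerance_one_keeps_all(self, rng):
        table = toy_table(rng)
        assert len(ab.abc_reject(np.zeros(3), table, 1.0)) == len(table.df)

    def test_matches_bruteforce_sort(self, rng):
        table = toy_table(rng)
        obs = np.array([0.5, -0.2, 1.0])
        kept = ab.abc_reject(obs, table, tolerance=0.25)
        center, scale = table.standardization()
        Z = (table.stats_matrix() - center) / scale
        zo = (obs - center) / scale
        d = np.sqrt(((Z - zo) ** 2).sum(axis=1))
        expect = np.argsort(d, kind="stable")[:len(kept)]
        assert list(kept.index) == list(table.df.index[expect])

    def test_retained_count_is_ceiling(self, rng):
        table = toy_table(rng, n_per=51)  # 102 rows, 1% -> ceil = 2
        kept = ab.abc_reject(np.zeros(3), table, 0.01)
        assert len(kept) == 2

    def test_standardization_invariance(self, rng):
        """Rescaling a raw statistic by a positive constant leaves the
        retained set unchanged (median/MAD standardization)."""
        table = toy_table(rng)
        obs = np.array([0.5, -0.2, 1.0])
        kept1 = ab.abc_reject(obs, table, 0.1)
        df2 = table.df.copy()
        df2["x1"] = df2["x1"] * 1000.0
        table2 = ab.ReferenceTable(df2, table.stat_names, table.param_names)
        kept2 = ab.abc_reject(obs * np.array([1, 1000.0, 1]), table2, 0.1)
        assert list(kept1.index) == list(kept2.index)


class TestPosteriors:
    def test_direct_hand_count(self, rng):
        retained = pd.DataFrame({"scenario": ["A1"] * 3 + ["B1"] * 1})
        post = ab.posterior_direct(retained)
        assert post == {"A1": 0.75, "B1": 0.25}
        assert sum(post.values()) == pytest.approx(1.0)

    def test_direct_single_scenario(self):
        post = ab.posterior_direct(pd.DataFrame({"scenario": ["B1"] * 5}))
        assert post == {"B1": 1.0}

    def test_logistic_no_signal_matches_direct(self, rng):
        # statistics independent of the label: logistic ~ direct frequencies
        n = 400
        df = pd.DataFrame({
            "scenario": ["A"] * (3 * n // 4) + ["B"] * (n // 4),
            "x0": rng.normal(size=n), "x1": rng.normal(size=n)})
        probs, _ = ab.posterior_logistic(df, np.zeros(2), ["x0", "x1"])
        assert probs["A"] == pytest.approx(0.75, abs=0.07)

    def test_logistic_separable(self, rng):
        df = pd.DataFrame({"scenario": ["A"] * 50 + ["B"] * 50,
                           "x0": np.r_[rng.normal(-3, 0.3, 50),
                                       rng.normal(3, 0.3, 50)]})
        # observed at the A side
        probs, ci = ab.posterior_logistic(df, np.array([-3.0]), ["x0"])
        assert probs["A"] > 0.95
        assert ci["A"][0] <= probs["A"] <= ci["A"][1]

    def test_logistic_matches_sklearn(self, rng):
        """Ridge multinomial fit agrees with an independent implementation."""
        from sklearn.linear_model import LogisticRegression

        n = 300
        X = rng.normal(size=(n, 2))
        logits = 1.5 * X[:, 0] - 1.0 * X[:, 1]
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-logits)), "A", "B")
        df = pd.DataFrame({"scenario": y, "x0": X[:, 0], "x1": X[:, 1]})
        obs = np.array([0.3, -0.4])
        probs, _ = ab.posterior_logistic(df, obs, ["x0", "x1"], lam=1e-8)
        sk = LogisticRegression(C=np.inf, tol=1e-12, max_iter=10_000)
        sk.fit(X - obs, y)
        p_sk = sk.predict_proba(np.zeros((1, 2)))[0]
        for i, s in enumerate(sk.classes_):
            assert probs[s] == pytest.approx(p_sk[i], abs=1e-4)

    def test_posterior_sums_to_one(self, rng):
        table = toy_table(rng)
        kept = ab.abc_reject(np.array([1.0, 1.0, 1.0]), table, 0.2)
        probs, _ = ab.posterior_logistic(kept, np.ones(3), table.stat_names)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


class TestLocLinear:
    def _retained(self, rng, slope, n=200, noise=1.0):
        theta = rng.uniform(5, 15, n)
        x = slope * theta + rng.normal(0, noise, n)
        df = pd.DataFrame({"scenario": "A", "theta": theta, "x0": x})
        df["distance"] = np.abs(x - x.mean())
        return df

    def test_uncorrelated_stat_keeps_raw_distribution(self, rng):
        df = self._retained(rng, slope=0.0)
        obs = np.array([0.0])
        samples, _ = ab.adjust_params_loclinear(df, obs, ["x0"], ["theta"])
        assert samples["theta"].mean() == pytest.approx(df["theta"].mean(),
                                                        abs=0.5)

    def test_linear_toy_recovers_truth(self, rng):
        # stat = 2*theta + small noise; observing stat=20 implies theta=10
        df = self._retained(rng, slope=2.0, noise=0.1)
        samples, qs = ab.adjust_params_loclinear(df, np.array([20.0]), ["x0"],
                                                 ["theta"])
        assert samples["theta"].mean() == pytest.approx(10.0, abs=0.1)
        assert qs.loc[0.025, "theta"] < 10.0 < qs.loc[0.975, "theta"]

    def test_uniform_kernel_equals_ols(self, rng):
        df = self._retained(rng, slope=1.0)
        obs = np.array([10.0])
        s_uni, _ = ab.adjust_params_loclinear(df, obs, ["x0"], ["theta"],
                                              kernel="uniform")
        # hand OLS adjustment
        X = df["x0"].to_numpy() - 10.0
        X = X / X.std()
        A = np.c_[np.ones_like(X), X]
        beta = np.linalg.lstsq(A, df["theta"].to_numpy(), rcond=None)[0]
        expect = df["theta"].to_numpy() - X * beta[1]
        assert s_uni["theta"].to_numpy() == pytest.approx(expect, abs=1e-6)

    def test_minimum_rows(self, rng):
        df = self._retained(rng, slope=1.0, n=10)
        with pytest.raises(ValueError, match=">= 50"):
            ab.adjust_params_loclinear(df, np.array([0.0]), ["x0"], ["theta"])

    def test_clipped_to_prior_support(self, rng):
        df = self._retained(rng, slope=2.0, noise=0.1)
        spec = ab.PriorSpec({"theta": (9.9, 10.1)})
        samples, _ = ab.adjust_params_loclinear(df, np.array([20.0]), ["x0"],
                                                ["theta"], spec=spec)
        assert samples["theta"].between(9.9, 10.1).all()


class TestConfidence:
    def test_confusion_rows_sum_to_one(self, rng):
        table = toy_table(rng)
        conf = ab.evaluate_confidence(table, n_pods=10, seed=5, tolerance=0.1)
        assert conf[["S1", "S2"]].sum(axis=1).to_numpy() == pytest.approx(
            [1.0, 1.0])

    def test_separated_scenarios_beat_chance(self, rng):
        table = toy_table(rng, sep=5.0)
        conf = ab.evaluate_confidence(table, n_pods=15, seed=6, tolerance=0.1)
        assert (conf["type1"] < 0.5).all()

    def test_indistinguishable_limit(self, rng):
        table = toy_table(rng, sep=0.0, n_per=150)
        conf = ab.evaluate_confidence(table, n_pods=20, seed=7, tolerance=0.1)
        # error rate ~ 1 - 1/2 for two identical scenarios
        assert conf["type1"].mean() == pytest.approx(0.5, abs=0.2)


class TestReferenceTablePipeline:
    def test_smoke_table_and_consistency(self):
        loci = [ce.LocusConfig(300)] * 3
        table = ab.build_reference_table(["A1", "B1"], ab.DEFAULT_PRIORS, 10,
                                         loci, 8, 6, seed=9)
        assert len(table.df) == 20
        assert not table.df[table.stat_names].isna().any().any()
        # stats recomputed independently from the same simulated dataset agree
        row = table.df.iloc[0]
        params = ce.ScenarioParams(**{k: float(row[k])
                                      for k in ab.DEFAULT_PRIORS.names})
        scen = ce.build_scenario("A1", params)
        ds = ce.simulate_dataset(scen, loci, 8, 6, ce._substream(9, 0, 0))
        vec = ab.dataset_stat_vector(ds, 8, 6)
        assert vec == pytest.approx(
            row[table.stat_names].to_numpy(float), rel=1e-12)

    def test_binary_stats_match_alignment_stats(self, rng):
        """Fast binary-path statistics equal the general alignment path."""
        from peripagen import stats as st
        from peripagen.alignments import LocusAlignment, PopulationMap

        derived = rng.random((12, 10)) < 0.4
        L = 50
        seqs = ce.matrix_to_sequences(derived, np.arange(12) * 3, L)
        aln = LocusAlignment("b", [(f"s{i}", 0, s) for i, s in enumerate(seqs)])
        pm = PopulationMap({f"s{i}": ("p1" if i < 6 else "p2")
                            for i in range(10)})
        row = ab.binary_locus_stats(derived, L, 6, 4)
        assert row["pi1"] * L + row["pi2"] * L == pytest.approx(
            st.mean_pairwise_differences(aln.subset(pm.samples("p1"))) +
            st.mean_pairwise_differences(aln.subset(pm.samples("p2"))))
        phist, _ = st.phi_st(aln, pm)
        assert row["phist"] == pytest.approx(phist)
        assert row["S1"] == st.segregating_sites(aln.subset(pm.samples("p1")))
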