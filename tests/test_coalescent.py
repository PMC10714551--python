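import numpy as np
import pytest

from peripagen import abc as abcmod
from peripagen import coalescent as ce


def harmonic(n, p=1):
    return sum(1.0 / i**p for i in range(1, n))


PARAMS = dict(N1=2000.0, N2=500.0, N2f=100.0, NA=1500.0, N1b=300.0,
              t0=400.0, t1=800.0, t2=1500.0, t3=4000.0,
              m12=1e-4, m21=2e-4)


class TestBuildScenario:
    def test_b3_structure(self):
        p = ce.ScenarioParams(**PARAMS)
        scen = ce.build_scenario("B3", p)
        assert scen.mode == "peripatric"
        # recent migration only: the single window is [0, t0]
        assert scen.migration_windows == [(0.0, 400.0)]
        times = [t for t, _ in scen.events]
        assert 4000.0 in times and 400.0 in times and 800.0 in times
        # after the merge the deme-1 size is the ancestral size
        assert scen.size0[-1] == p.NA

    def test_a1_has_no_migration(self):
        scen = ce.build_scenario("A1", ce.ScenarioParams(**PARAMS))
        assert scen.migration_windows == []
        assert (scen.mig01 == 0).all() and (scen.mig10 == 0).all()

    def test_migration_regimes(self):
        p = ce.ScenarioParams(**PARAMS)
        assert ce.build_scenario("A2", p).migration_windows == [(800.0, 4000.0)]
        assert ce.build_scenario("A5", p).migration_windows == [(0.0, 4000.0)]
        w4 = ce.build_scenario("A4", p).migration_windows
        assert w4 == [(0.0, 400.0), (800.0, 4000.0)]

    def test_c_family_bottleneck_window(self):
        scen = ce.build_scenario("C1", ce.ScenarioParams(**PARAMS))
        # deme-2 size is N2f exactly on [t1, t2)
        e_t1 = np.searchsorted(scen.t_bounds, 800.0, side="right") - 1
        e_t2 = np.searchsorted(scen.t_bounds, 1500.0, side="right") - 1
        assert scen.size1[e_t1] == 100.0
        assert scen.size1[e_t2] == 500.0
        assert scen.mode == "vicariant"

    def test_invalid_code(self):
        with pytest.raises(ValueError, match="unknown scenario code"):
            ce.build_scenario("E1", ce.ScenarioParams(**PARAMS))

    def test_ordering_violation_named(self):
        bad = dict(PARAMS, t1=5000.0)
        with pytest.raises(ValueError, match="t1 < t3"):
            ce.build_scenario("A1", ce.ScenarioParams(**bad))

    def test_mode_tags(self):
        p = ce.ScenarioParams(**PARAMS)
        assert ce.build_scenario("C3", p).mode == "vicariant"
        assert ce.build_scenario("B4", p).mode == "parapatric"
        assert ce.build_scenario("D5", p).mode == "complex"


class TestGenealogy:
    def test_single_lineage(self, panmictic):
        g = ce.simulate_genealogy(panmictic, 1, 0, seed=1)
        assert g.tmrca == 0.0 and g.n == 1

    def test_pair_tmrca_mean(self, panmictic):
        """E[T2] = 2N generations for a diploid deme of size N."""
        reps = 4000
        t = [ce.simulate_genealogy(panmictic, 2, 0, seed=i).tmrca
             for i in range(reps)]
        se = np.std(t) / np.sqrt(reps)
        assert abs(np.mean(t) - 2000.0) < 3 * se

    def test_total_branch_length_mean(self, panmictic):
        """E[L_total] = 4N sum_{i<n} 1/i."""
        reps = 4000
        L = [ce.simulate_genealogy(panmictic, 10, 0, seed=10**6 + i)
             .total_branch_length for i in range(reps)]
        expect = 4 * 1000 * harmonic(10)
        se = np.std(L) / np.sqrt(reps)
        assert abs(np.mean(L) - expect) < 3 * se


class TestMutations:
    def test_mu_zero_monomorphic(self, panmictic):
        locus = ce.LocusConfig(100, mu=0.0)
        derived, pos = ce.simulate_locus_matrix(panmictic, locus, 6, 0, seed=2)
        assert derived.shape == (0, 6) and len(pos) == 0

    def test_watterson_segsites_mean(self, panmictic):
        """E[S] = theta * sum 1/i at theta = 4 N mu L = 5, n = 20."""
        theta = 5.0
        locus = ce.LocusConfig(1000, mu=theta / (4 * 1000 * 1000))
        reps = 3000
        S = [ce.simulate_locus_matrix(panmictic, locus, 20, 0, seed=i)[0].shape[0]
             for i in range(reps)]
        expect = theta * harmonic(20)
        se = np.std(S) / np.sqrt(reps)
        assert abs(np.mean(S) - expect) < 3 * se

    def test_overflow_guard(self):
        scen = ce.single_deme_scenario(1e6)
        with pytest.raises(OverflowError):
            ce.simulate_locus_matrix(scen, ce.LocusConfig(10, mu=1e-2), 20, 0,
                                     seed=3)

    def test_positions_unique_sorted(self, panmictic):
        locus = ce.LocusConfig(500, mu=1e-5)
        _, pos = ce.simulate_locus_matrix(panmictic, locus, 10, 0, seed=4)
        assert (np.diff(pos) > 0).all()


class TestDataset:
    def test_determinism(self):
        scen = ce.build_scenario("B3", ce.ScenarioParams(**PARAMS))
        loci = [ce.LocusConfig(300, mu=1e-6)] * 3
        a = ce.simulate_dataset(scen, loci, 6, 4, seed=99)
        b = ce.simulate_dataset(scen, loci, 6, 4, seed=99)
        for (_, d1, p1), (_, d2, p2) in zip(a, b):
            assert (d1 == d2).all() and (p1 == p2).all()

    def test_shape_contract(self):
        scen = ce.build_scenario("B3", ce.ScenarioParams(**PARAMS))
        ds = ce.simulate_dataset(scen, [ce.LocusConfig(200, mu=1e-6)], 8, 6,
                                 seed=5)
        assert ds[0][1].shape[1] == 14

    def test_deep_divergence_high_phist(self):
        """With t3 >> 4N and no migration, mean PhiST approaches 1."""
        deep = dict(PARAMS, t3=4e5, t2=1500.0, m12=0.0, m21=0.0)
        scen = ce.build_scenario("A1", ce.ScenarioParams(**deep))
        loci = [ce.LocusConfig(2000, mu=5e-8)] * 4
        vals = []
        for r in range(40):
            ds = ce.simulate_dataset(scen, loci, 10, 10, seed=r)
            vals.append(abcmod.dataset_stat_vector(ds, 10, 10)[
                abcmod.STAT_SET_V1.index("phist_mean")])
        assert np.mean(vals) > 0.8

    def test_phist_increases_with_divergence_time(self):
        means = []
        for t3 in (2000.0, 20000.0, 200000.0):
            p = ce.ScenarioParams(**dict(PARAMS, t3=t3, t2=min(1500.0, t3 / 3),
                                         t1=min(800.0, t3 / 5)))
            scen = ce.build_scenario("A1", p)
            loci = [ce.LocusConfig(2000, mu=1e-7)] * 3
            vals = [abcmod.dataset_stat_vector(
                ce.simulate_dataset(scen, loci, 8, 8, seed=1000 + r), 8, 8)[
                    abcmod.STAT_SET_V1.index("phist_mean")]
                for r in range(60)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestExpectedJSFS:
    def test_probabilities_normalized(self):
        scen = ce.build_scenario("A1", ce.ScenarioParams(**PARAMS))
        P = ce.expected_joint_sfs(scen, [ce.LocusConfig(500)], 6, 4, 200,
                                  seed=1)
        assert P.sum() == pytest.approx(1.0)
        assert P[0, 0] == 0 and P[6, 4] == 0
        assert (P[1:, :].sum() + P[0, 1:].sum()) > 0

    def test_symmetric_scenario_symmetric_spectrum(self):
        p = ce.ScenarioParams(N1=1000.0, N2=1000.0, N2f=1000.0, NA=1000.0,
                              t1=500.0, t3=2000.0, m12=1e-3, m21=1e-3)
        scen = ce.build_scenario("A5", p)
        P = ce.expected_joint_sfs(scen, [ce.LocusConfig(500)], 6, 6, 3000,
                                  seed=2)
        asym = np.abs(P - P.T).max()
        assert asym < 0.02

    def test_merged_single_deme_marginal_is_neutral_sfs(self):
        """A panmictic deme's expected SFS is proportional to 1/i."""
        scen = ce.single_deme_scenario(1000.0)
        n = 8
        P = ce.expected_joint_sfs(scen, [ce.LocusConfig(500)], n, 0, 4000,
                                  seed=3)
        xi = P[1:n, 0]
        expect = (1.0 / np.arange(1, n)) / harmonic(n)
        assert np.abs(xi / xi.sum() - expect).max() < 0.01

    def test_mu_zero_flagged(self):
        scen = ce.single_deme_scenario(1000.0)
        with pytest.raises(ValueError, match="degenerate"):
            ce.expected_joint_sfs(scen, [ce.LocusConfig(500, mu=0.0)], 4, 0,
                                  10, seed=4)


class TestMsprimeOracle:
    """Cross-check mean S and PhiST against msprime on the same demography.

    msprime is configured with ploidy 1 and sizes 2N so its pair-coalescence
    rate 1/(2N) matches the engine's diploid convention.
    """

    @staticmethod
    def _msprime_demography(code):
        import msprime

        p = ce.ScenarioParams(**PARAMS)
        dem = msprime.Demography()
        dem.add_population(name="p0", initial_size=2 * p.N1)
        dem.add_population(name="p1", initial_size=2 * p.N2)
        dem.add_population(name="anc", initial_size=2 * p.NA)
        if code == "A1":
            dem.add_population_parameters_change(time=p.t1, population="p1",
                                                 initial_size=2 * p.N2f)
        elif code == "C1":
            dem.add_population_parameters_change(time=p.t1, population="p1",
                                                 initial_size=2 * p.N2f)
            dem.add_population_parameters_change(time=p.t2, population="p1",
                                                 initial_size=2 * p.N2)
        dem.add_population_split(time=p.t3, derived=["p0", "p1"],
                                 ancestral="anc")
        return dem

    @pytest.mark.parametrize("code", ["A1", "C1"])
    def test_mean_s_and_phist_match(self, code):
        import msprime

        n1, n2 = 8, 6
        L, mu = 500, 2e-6
        reps = 1500
        scen = ce.build_scenario(code, ce.ScenarioParams(**PARAMS))
        locus = ce.LocusConfig(L, mu=mu)
        mine_S, mine_phi = [], []
        for r in range(reps):
            derived, _ = ce.simulate_locus_matrix(scen, locus, n1, n2, seed=r)
            row = abcmod.binary_locus_stats(derived, L, n1, n2)
            mine_S.append(derived.shape[0])
            mine_phi.append(row["phist"])
        other_S, other_phi = [], []
        dem = self._msprime_demography(code)
        anc = msprime.sim_ancestry(
            samples={"p0": n1, "p1": n2}, demography=dem, ploidy=1,
            sequence_length=L, num_replicates=reps, random_seed=777)
        for r, ts in enumerate(anc):
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=1000 + r,
                                        discrete_genome=False)
            G = mts.genotype_matrix()
            derived = G.astype(bool)
            row = abcmod.binary_locus_stats(derived, L, n1, n2)
            other_S.append(derived.shape[0])
            other_phi.append(row["phist"])
        for mine, other in ((mine_S, other_S), (mine_phi, other_phi)):
            se = np.sqrt(np.var(mine) / reps + np.var(other) / reps)
            assert abs(np.mean(mine) - np.mean(other)) < 3 * se
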