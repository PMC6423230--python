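import numpy as np
import pytest
from scipy import stats as sps

from hybridpop.coalsim import (Admixture, ScenarioSpec, Split,
                               drop_mutations, simulate,
                               simulate_genealogy)
from hybridpop.popgen import harmonic


def one_pop(n, N=1000.0):
    return ScenarioSpec("one", {"p": N}, [], {"p": n})


class TestValidate:
    def test_admixture_after_parents_merged(self):
        sc = ScenarioSpec(
            "bad", {"p1": 100.0, "p2": 100.0, "h": 100.0, "anc": 100.0},
            [Split(50.0, "p1", "anc"), Split(50.0, "p2", "anc"),
             Admixture(80.0, "h", "p1", "p2", 0.5)],
            {"p1": 2, "p2": 2, "h": 2})
        assert sc.validate()

    def test_admixture_origin_scenario_ok(self):
        sc = ScenarioSpec(
            "ok", {"p1": 100.0, "p2": 100.0, "h": 100.0, "anc": 100.0},
            [Admixture(30.0, "h", "p1", "p2", 0.5),
             Split(90.0, "p1", "anc"), Split(90.0, "p2", "anc")],
            {"p1": 2, "p2": 2, "h": 2})
        assert sc.validate() == []

    def test_rate_out_of_bounds(self):
        sc = ScenarioSpec(
            "bad", {"p1": 100.0, "p2": 100.0, "h": 100.0, "anc": 100.0},
            [Admixture(30.0, "h", "p1", "p2", 1.3),
             Split(90.0, "p1", "anc"), Split(90.0, "p2", "anc")],
            {"p1": 2, "p2": 2, "h": 2})
        assert any("rate" in v for v in sc.validate())

    def test_undeclared_population(self):
        sc = ScenarioSpec("bad", {"p": 100.0}, [], {"q": 2})
        assert any("no declared size" in v for v in sc.validate())


class TestGenealogies:
    def test_mean_tmrca_matches_coalescent_expectation(self):
        rng = np.random.default_rng(0)
        sc = one_pop(2, N=1000.0)
        tm = [simulate_genealogy(sc, rng, validate=False).tmrca()
              for _ in range(5000)]
        assert np.mean(tm) == pytest.approx(2000.0, rel=0.05)

    def test_admixture_rate_one_equals_pure_split(self):
        # r=1 sends every hybrid lineage to parent 1: the pairwise
        # difference distribution must match the split-only scenario
        rng = np.random.default_rng(1)
        shared = {"p1": 500.0, "p2": 500.0, "h": 500.0, "anc": 500.0}
        admix = ScenarioSpec(
            "a", dict(shared),
            [Admixture(200.0, "h", "p1", "p2", 1.0),
             Split(5000.0, "p1", "anc"), Split(5000.0, "p2", "anc")],
            {"p1": 1, "h": 1})
        split = ScenarioSpec(
            "s", dict(shared),
            [Split(200.0, "h", "p1"),
             Split(5000.0, "p1", "anc"), Split(5000.0, "p2", "anc")],
            {"p1": 1, "h": 1})
        ta = [simulate_genealogy(admix, rng, validate=False).tmrca()
              for _ in range(2000)]
        tb = [simulate_genealogy(split, rng, validate=False).tmrca()
              for _ in range(2000)]
        assert sps.ks_2samp(ta, tb).pvalue > 0.01

    def test_zero_depth_split_is_panmictic(self):
        rng = np.random.default_rng(2)
        eps = 1e-9
        two = ScenarioSpec("two", {"p1": 800.0, "p2": 800.0},
                           [Split(eps, "p2", "p1")], {"p1": 1, "p2": 1})
        one = one_pop(2, N=800.0)
        ta = [simulate_genealogy(two, rng, validate=False).tmrca()
              for _ in range(2000)]
        tb = [simulate_genealogy(one, rng, validate=False).tmrca()
              for _ in range(2000)]
        assert sps.ks_2samp(ta, tb).pvalue > 0.01

    def test_ultrametric_and_binary(self):
        rng = np.random.default_rng(3)
        gen = simulate_genealogy(one_pop(12), rng)
        assert gen.n_nodes == 2 * 12 - 1
        assert (gen.time[:12] == 0).all()
        assert (gen.branch_lengths()[:-1] >= 0).all() or \
            (gen.branch_lengths() >= 0).all()
        # every non-root node has a parent strictly older than itself
        for i in range(gen.n_nodes):
            p = gen.parent[i]
            if p >= 0:
                assert gen.time[p] > gen.time[i] or gen.time[i] == 0


class TestMutationsAndStats:
    def test_expected_pairwise_diversity(self):
        # E[pi] = theta = 4*N*mu per site
        rng = np.random.default_rng(4)
        N, mu, L = 1000.0, 2.5e-6, 500
        sc = one_pop(2, N=N)
        diffs = []
        for _ in range(5000):
            gen = simulate_genealogy(sc, rng, validate=False)
            _, states = drop_mutations(gen, L, mu, rng)
            diffs.append((states[0] != states[1]).sum() / L)
        assert np.mean(diffs) == pytest.approx(4 * N * mu, rel=0.05)

    def test_expected_segregating_sites(self):
        # E[S] = a_{n-1} * theta_locus (Watterson)
        rng = np.random.default_rng(5)
        n, N, mu, L = 10, 1000.0, 2.5e-6, 500
        sc = one_pop(n, N=N)
        theta_locus = 4 * N * mu * L
        S = []
        for _ in range(3000):
            gen = simulate_genealogy(sc, rng, validate=False)
            _, states = drop_mutations(gen, L, mu, rng)
            S.append(int((states != states[0]).any(axis=0).sum()))
        assert np.mean(S) == pytest.approx(harmonic(n - 1) * theta_locus,
                                           rel=0.05)

    def test_msprime_oracle_structured_scenario(self):
        # two populations split 4000 generations ago: compare the mean
        # between-population pairwise difference with msprime
        msprime = pytest.importorskip("msprime")
        rng = np.random.default_rng(6)
        N, mu, L, t = 1000.0, 2.5e-6, 400, 4000.0
        sc = ScenarioSpec("two", {"p1": N, "p2": N, "anc": N},
                          [Split(t, "p1", "anc"), Split(t, "p2", "anc")],
                          {"p1": 1, "p2": 1})
        ours = []
        for _ in range(3000):
            gen = simulate_genealogy(sc, rng, validate=False)
            _, states = drop_mutations(gen, L, mu, rng)
            ours.append((states[0] != states[1]).sum())
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=N)
        dem.add_population(name="p2", initial_size=N)
        dem.add_population(name="anc", initial_size=N)
        dem.add_population_split(time=t, derived=["p1", "p2"],
                                 ancestral="anc")
        theirs = []
        reps = msprime.sim_ancestry(
            samples={"p1": 1, "p2": 1}, ploidy=1, demography=dem,
            sequence_length=L, num_replicates=3000, random_seed=7)
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=1)
            theirs.append(mts.divergence([[0], [1]], span_normalise=False))
        assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=0.05)


class TestSimulateDatasets:
    def test_bitwise_reproducibility(self):
        sc = one_pop(4, N=500.0)
        a = simulate(sc, [(100, 1e-5), (80, 1e-5)], seed=42)
        b = simulate(sc, [(100, 1e-5), (80, 1e-5)], seed=42)
        for x, y in zip(a.alignments, b.alignments):
            assert x.rows == y.rows

    def test_diploid_pairing_and_shapes(self):
        sc = ScenarioSpec("two", {"p1": 500.0, "p2": 500.0, "anc": 500.0},
                          [Split(1000.0, "p1", "anc"),
                           Split(1000.0, "p2", "anc")],
                          {"p1": 4, "p2": 4})
        ds = simulate(sc, [(120, 1e-5)], seed=0)
        aln = ds.alignments[0]
        assert aln.n_rows == 8 and aln.length == 120
        assert len(ds.samples.individual_ids) == 4
        assert set(ds.samples.table["taxon"]) == {"p1", "p2"}
        for ind in ds.samples.individual_ids:
            assert f"{ind}/1" in aln.sample_keys
            assert f"{ind}/2" in aln.sample_keys

    def test_odd_nuclear_lineages_rejected(self):
        with pytest.raises(ValueError, match="even"):
            simulate(one_pop(3), [(100, 1e-5)], seed=0)

    def test_invalid_scenario_rejected_before_running(self):
        sc = ScenarioSpec("bad", {"p": 100.0}, [Admixture(1.0, "p", "p", "p", 2.0)],
                          {"p": 2})
        with pytest.raises(ValueError, match="invalid scenario"):
            simulate(sc, [(100, 1e-5)], seed=0)
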