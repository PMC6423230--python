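import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybridpop.admixture import (ClusterPosterior, GenotypeMatrix,
                                 admixture_gibbs, align_cluster_labels,
                                 evanno_delta_k, genetic_distance_matrix,
                                 pca_from_distance)


def gm(calls, n_alleles=None, ploidy=None):
    calls = np.asarray(calls, dtype=np.int32)
    N, L, _ = calls.shape
    if n_alleles is None:
        n_alleles = calls.max(axis=(0, 2)) + 1
    return GenotypeMatrix([f"i{i}" for i in range(N)],
                          [f"l{j}" for j in range(L)], calls,
                          np.asarray(n_alleles, dtype=np.int32),
                          np.asarray(ploidy if ploidy is not None
                                     else [2] * L, dtype=np.int8))


def diagnostic_population(n_per_pop, n_loci, rng=None, f1_count=0):
    """Two populations fixed for different alleles, plus optional F1s."""
    rows = []
    for _ in range(n_per_pop):
        rows.append([[0, 0]] * n_loci)
    for _ in range(n_per_pop):
        rows.append([[1, 1]] * n_loci)
    for _ in range(f1_count):
        rows.append([[0, 1]] * n_loci)
    return gm(np.array(rows))


class TestGeneticDistance:
    def test_identical_genotypes_distance_zero(self):
        g = gm([[[0, 1]], [[0, 1]]])
        assert genetic_distance_matrix(g)[0, 1] == 0

    def test_allele_sharing_cases(self):
        # {a,a} vs {b,b} -> 2; {a,b} vs {a,c} -> 1; {a,a} vs {a,b} -> 1
        g = gm([[[0, 0]], [[1, 1]], [[0, 1]], [[0, 2]]])
        D = genetic_distance_matrix(g)
        assert D[0, 1] == 2
        assert D[2, 3] == 1
        assert D[0, 2] == 1

    def test_haploid_cells(self):
        g = gm([[[0, -1]], [[1, -1]], [[0, -1]]], n_alleles=[2],
               ploidy=[1])
        D = genetic_distance_matrix(g)
        assert D[0, 1] == 1 and D[0, 2] == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(6, 4, 2))
        D = genetic_distance_matrix(gm(calls))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        n = len(D)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestPcaFromDistance:
    def test_two_blocks_single_axis(self):
        D = np.zeros((6, 6))
        D[:3, 3:] = 4.0
        D[3:, :3] = 4.0
        coords, fractions = pca_from_distance(D)
        assert fractions[0] == pytest.approx(1.0)
        assert np.sign(coords[:3, 0]).tolist() != np.sign(coords[3:, 0]).tolist()

    def test_degenerate_all_identical(self):
        coords, fractions = pca_from_distance(np.zeros((5, 5)))
        assert coords.shape[1] == 0 and fractions.size == 0

    def test_classical_scaling_recovers_euclidean_distances(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        coords, _ = pca_from_distance(D)
        D2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)


class TestAdmixtureGibbs:
    def test_k1_forces_unit_membership(self):
        g = diagnostic_population(4, 5)
        run = admixture_gibbs(g, K=1, iters=60, burnin=20, seed=0)
        assert np.allclose(run.Q, 1.0)

    def test_two_population_recovery(self):
        g = diagnostic_population(10, 10)
        run = admixture_gibbs(g, K=2, iters=400, burnin=150, seed=1)
        assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)
        own = np.maximum(run.Q[:10, 0], run.Q[:10, 1])
        other = np.maximum(run.Q[10:, 0], run.Q[10:, 1])
        # each population concentrated in one cluster, and they differ
        assert own.min() >= 0.95 and other.min() >= 0.95
        assert np.argmax(run.Q[0]) != np.argmax(run.Q[10])

    def test_f1_membership_near_half(self):
        g = diagnostic_population(10, 10, f1_count=6)
        run = admixture_gibbs(g, K=2, iters=500, burnin=200, seed=2)
        f1 = run.Q[20:]
        assert np.all(np.abs(f1 - 0.5) <= 0.1)

    def test_identical_individuals_get_identical_ancestry(self):
        g = diagnostic_population(8, 8)
        run = admixture_gibbs(g, K=2, iters=400, burnin=150, seed=3)
        # rows 0 and 1 carry identical genotypes
        assert np.allclose(run.Q[0], run.Q[1], atol=0.05)

    def test_iters_must_exceed_burnin(self):
        with pytest.raises(ValueError):
            admixture_gibbs(diagnostic_population(2, 2), K=2, iters=10,
                            burnin=10, seed=0)


class TestEvannoDeltaK:
    def test_hand_arithmetic(self):
        runs = {1: [-100.0, -100.0], 2: [-50.0, -52.0], 3: [-49.0, -51.0]}
        table = evanno_delta_k(runs).table
        # second difference of means: |-50 - 2*(-51) + (-100)| = 48;
        # sd at K=2 is sqrt(2)
        assert table.loc[2, "delta_k"] == pytest.approx(48 / np.sqrt(2))
        assert np.isnan(table.loc[1, "delta_k"])
        assert np.isnan(table.loc[3, "delta_k"])

    def test_linear_lnpd_gives_small_delta_k(self):
        rng = np.random.default_rng(0)
        flat = {k: list(-100 + 10 * k + rng.normal(0, 1, 4)) for k in range(1, 6)}
        kinked = {k: list(-100 + (10 * k if k <= 3 else 30) + rng.normal(0, 1, 4))
                  for k in range(1, 6)}
        dk_flat = evanno_delta_k(flat).table["delta_k"].max()
        dk_kink = evanno_delta_k(kinked).best_k()
        assert dk_kink == 3
        assert dk_flat < evanno_delta_k(kinked).table["delta_k"].max()

    def test_zero_sd_flagged_undefined(self):
        runs = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.5]}
        table = evanno_delta_k(runs).table
        assert np.isnan(table.loc[2, "delta_k"])

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 consecutive"):
            evanno_delta_k({1: [-1.0, -1.0], 2: [-1.0, -2.0]})
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k({1: [-1.0] * 2, 3: [-1.0] * 2, 5: [-1.0] * 2})


class TestAlignClusterLabels:
    def _run(self, Q, seed=0):
        N, K = Q.shape
        return ClusterPosterior(K, [f"i{i}" for i in range(N)], Q,
                                np.ones((K, 1, 1)), -1.0, 1.0, seed, 10, 5)

    def test_column_swap_recovered(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet([1, 1, 1], size=12)
        runs = [self._run(Q), self._run(Q[:, [2, 0, 1]])]
        aligned, meanQ = align_cluster_labels(runs)
        assert np.allclose(aligned[1].Q, Q)
        assert np.allclose(meanQ, Q)

    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(1)
        Q = rng.dirichlet([1, 1], size=6)
        aligned, _ = align_cluster_labels([self._run(Q), self._run(Q)])
        assert np.allclose(aligned[1].Q, Q)

    def test_perturbed_permuted_copies_average_close(self):
        rng = np.random.default_rng(2)
        Q = rng.dirichlet([2, 2, 2], size=20)
        eps = 0.02
        runs = [self._run(Q)]
        for perm in ([1, 2, 0], [2, 1, 0], [0, 2, 1]):
            noisy = np.clip(Q + rng.normal(0, eps, Q.shape), 1e-6, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            runs.append(self._run(noisy[:, perm]))
        _, meanQ = align_cluster_labels(runs)
        assert np.abs(meanQ - Q).max() < 5 * eps

    def test_mismatched_k_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="differ in K"):
            align_cluster_labels([
                self._run(rng.dirichlet([1, 1], size=4)),
                self._run(rng.dirichlet([1, 1, 1], size=4))])
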