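"""Genetic structure: distance PCoA and Bayesian admixture clustering.

Individuals are scored as haplotype alleles per locus (the allele ids are
the haplotype numbers from :func:`hybridpop.seqio.collapse_haplotypes`),
giving a :class:`GenotypeMatrix`.  Structure is explored two ways:

* classical multidimensional scaling (principal coordinates) of a
  per-locus allele-sharing distance, and
* a Gibbs sampler over the admixture model: each allele copy carries a
  latent cluster of origin; individuals have Dirichlet-distributed
  membership vectors Q with a shared concentration alpha (uniform(0, 10)
  hyperprior, Metropolis-updated); clusters have per-locus allele
  frequencies with a Dirichlet(lambda) prior.

The number of clusters K is chosen from replicate runs via the model
log-evidence LnP(K) and the Evanno delta-K second-difference statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .seqio import (MultilocusDataset, collapse_haplotypes,
                    individual_of_key)

__all__ = [
    "GenotypeMatrix",
    "ClusterPosterior",
    "genetic_distance_matrix",
    "pca_from_distance",
    "admixture_gibbs",
    "evanno_delta_k",
    "align_cluster_labels",
    "structure_scan",
]


@dataclass
class GenotypeMatrix:
    """Haplotype-allele genotypes: (individuals, loci, 2) allele indices.

    Missing allele copies are -1; haploid loci (cpDNA) use -1 in the
    second slot with ``ploidy`` 1.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray              # int32 (N, L, 2)
    n_alleles: np.ndarray          # int32 (L,) catalogue size per locus
    ploidy: np.ndarray             # int8 (L,) 1 or 2

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("calls shape inconsistent with labels")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @classmethod
    def from_dataset(cls, ds: MultilocusDataset,
                     marker: str = "nuclear") -> "GenotypeMatrix":
        """Build the matrix from haplotype-collapsed alignments."""
        loci = ds.loci(marker)  # type: ignore[arg-type]
        inds = ds.samples.individual_ids
        idx = {ind: i for i, ind in enumerate(inds)}
        calls = np.full((len(inds), len(loci), 2), -1, dtype=np.int32)
        n_alleles = np.zeros(len(loci), dtype=np.int32)
        ploidy = np.full(len(loci), 2 if marker == "nuclear" else 1, np.int8)
        for l, aln in enumerate(loci):
            table = collapse_haplotypes(aln)
            n_alleles[l] = table.n_haplotypes
            slot: dict[str, int] = {}
            for h, (_, _, _, members) in enumerate(table.haplotypes):
                for key in members:
                    ind = individual_of_key(key)
                    c = slot.get(ind, 0)
                    if c >= 2:
                        raise ValueError(
                            f"more than 2 copies for {ind!r} at {aln.locus_id!r}"
                        )
                    calls[idx[ind], l, c] = h
                    slot[ind] = c + 1
        return cls(list(inds), [a.locus_id for a in loci], calls,
                   n_alleles, ploidy)


def genetic_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Allele-sharing distance: per locus, the number of allele copies not
    shared under the best pairing (0, 1 or 2 for diploid loci; 0 or 1 for
    haploid), summed over loci scored in both individuals."""
    N = g.n_individuals
    if N < 2:
        raise ValueError("need at least 2 individuals")
    D = np.zeros((N, N))
    scored = (g.calls[:, :, 0] >= 0)
    if not scored.any(axis=1).all():
        bad = [g.individuals[i] for i in np.where(~scored.any(axis=1))[0]]
        raise ValueError(f"individuals with no scored loci: {bad}")
    for i in range(N):
        for j in range(i + 1, N):
            both = scored[i] & scored[j]
            d = 0.0
            for l in np.where(both)[0]:
                a = [x for x in g.calls[i, l] if x >= 0]
                b = [x for x in g.calls[j, l] if x >= 0]
                shared = 0
                bb = list(b)
                for x in a:
                    if x in bb:
                        bb.remove(x)
                        shared += 1
                d += max(len(a), len(b)) - shared
            D[i, j] = D[j, i] = d
    return D


def pca_from_distance(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates (classical MDS) of a distance matrix.

    Gower-centers -0.5 * D**2 and eigendecomposes; coordinates are the
    eigenvectors scaled by sqrt of the positive eigenvalues; the second
    return value gives the fraction of positive-eigenvalue variance per
    axis (empty when the matrix is all-zero).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    B = -0.5 * D**2
    B -= B.mean(axis=0, keepdims=True)
    B -= B.mean(axis=1, keepdims=True)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10, 1e-10 * abs(vals).max()) if vals.size else vals > 0
    if not pos.any():
        return np.zeros((n, 0)), np.zeros(0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    fractions = vals[pos] / vals[pos].sum()
    return coords, fractions


@dataclass
class ClusterPosterior:
    """Posterior summary of one admixture run at a fixed K."""

    K: int
    individuals: list[str]
    Q: np.ndarray                  # (N, K) posterior mean memberships
    P: np.ndarray                  # (K, L, A) posterior mean allele freqs
    lnPD: float                    # log model evidence estimate
    alpha: float                   # posterior mean concentration
    seed: int
    iters: int
    burnin: int

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=self.individuals,
                            columns=[f"cluster{k + 1}" for k in range(self.K)])


def _flatten_copies(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ind, loc, copy = np.where(g.calls >= 0)
    allele = g.calls[ind, loc, copy]
    return ind, loc, allele


def admixture_gibbs(g: GenotypeMatrix, K: int, iters: int = 600,
                    burnin: int = 200, seed: int = 0,
                    lam: float = 1.0) -> ClusterPosterior:
    """Gibbs sampler for the admixture model with K clusters.

    Latent cluster origins per allele copy; Q_i ~ Dirichlet(alpha) with
    alpha ~ uniform(0, 10) updated by random-walk Metropolis; allele
    frequencies P_kl ~ Dirichlet(lam).  Returns post-burn-in means and an
    evidence estimate lnPD = mean(lnL) - var(lnL)/2.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    rng = np.random.default_rng(seed)
    N, L = g.n_individuals, g.n_loci
    Amax = int(g.n_alleles.max())
    ind_idx, loc_idx, allele = _flatten_copies(g)
    M = len(ind_idx)
    valid = np.zeros((L, Amax), dtype=bool)
    for l in range(L):
        valid[l, :g.n_alleles[l]] = True

    z = rng.integers(K, size=M)
    alpha = 1.0
    Q_sum = np.zeros((N, K))
    P_sum = np.zeros((K, L, Amax))
    lnL_trace = []
    alpha_sum = 0.0
    kept = 0

    for sweep in range(iters):
        # P | z
        C = np.zeros((K, L, Amax))
        np.add.at(C, (z, loc_idx, allele), 1.0)
        gam = rng.gamma(lam + C)
        gam[:, ~valid] = 0.0
        P = gam / gam.sum(axis=2, keepdims=True)
        # Q | z
        nik = np.zeros((N, K))
        np.add.at(nik, (ind_idx, z), 1.0)
        qg = np.clip(rng.gamma(alpha + nik), 1e-300, None)
        Q = qg / qg.sum(axis=1, keepdims=True)
        # z | P, Q
        w = Q[ind_idx] * P[:, loc_idx, allele].T          # (M, K)
        wsum = w.sum(axis=1)
        lnL = float(np.log(wsum).sum())
        u = rng.random(M) * wsum
        z = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
        # alpha | Q (random-walk Metropolis, uniform(0,10) prior)
        if K > 1:
            prop = alpha + rng.normal(0.0, 0.25)
            if 0.0 < prop < 10.0:
                logq = np.log(np.clip(Q, 1e-300, None)).sum()
                def lp(a: float) -> float:
                    return N * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * logq
                if math.log(rng.random()) < lp(prop) - lp(alpha):
                    alpha = prop
        if sweep >= burnin:
            Q_sum += Q
            P_sum += P
            lnL_trace.append(lnL)
            alpha_sum += alpha
            kept += 1

    lnL_arr = np.asarray(lnL_trace)
    lnPD = float(lnL_arr.mean() - lnL_arr.var() / 2.0)
    return ClusterPosterior(
        K=K, individuals=list(g.individuals), Q=Q_sum / kept,
        P=P_sum / kept, lnPD=lnPD, alpha=alpha_sum / kept,
        seed=seed, iters=iters, burnin=burnin,
    )


@dataclass
class DeltaKTable:
    """Per-K replicate summaries and the Evanno second-difference score."""

    table: pd.DataFrame  # index K; columns mean_lnPD, sd_lnPD, delta_k

    def best_k(self) -> int:
        dk = self.table["delta_k"].dropna()
        if dk.empty:
            raise ValueError("delta K undefined for every interior K")
        return int(dk.idxmax())


def evanno_delta_k(runs: dict[int, Sequence[float]]) -> DeltaKTable:
    """Evanno et al. delta-K from replicate lnPD values per K.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K with positive replicate sd.
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    means = {k: float(np.mean(runs[k])) for k in ks}
    sds = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = math.nan
        if ks[0] < k < ks[-1] and sds[k] > 0:
            dk = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
        rows.append({"K": k, "mean_lnPD": means[k], "sd_lnPD": sds[k],
                     "delta_k": dk})
    return DeltaKTable(pd.DataFrame(rows).set_index("K"))


def align_cluster_labels(runs: Sequence[ClusterPosterior]) -> tuple[list[ClusterPosterior], np.ndarray]:
    """Permute cluster labels of replicate runs to best match the first.

    Uses the optimal assignment maximizing the Frobenius inner product of
    Q matrices.  Returns the relabeled runs and the mean Q.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("runs differ in K")
    if any(r.individuals != runs[0].individuals for r in runs):
        raise ValueError("runs differ in individuals")
    ref = runs[0].Q
    aligned = [runs[0]]
    for r in runs[1:]:
        sim = ref.T @ r.Q                     # (K, K) similarity
        rows, cols = linear_sum_assignment(-sim)
        perm = np.empty(K, dtype=int)
        perm[rows] = cols
        aligned.append(ClusterPosterior(
            K=K, individuals=r.individuals, Q=r.Q[:, perm], P=r.P[perm],
            lnPD=r.lnPD, alpha=r.alpha, seed=r.seed, iters=r.iters,
            burnin=r.burnin,
        ))
    meanQ = np.mean([r.Q for r in aligned], axis=0)
    return aligned, meanQ


def structure_scan(g: GenotypeMatrix, k_range: Sequence[int],
                   replicates: int = 2, iters: int = 600,
                   burnin: int = 200, seed: int = 0) -> tuple[dict[int, list[ClusterPosterior]], DeltaKTable]:
    """Run the sampler over a K range with replicates and score delta-K.

    Replicate r of K uses seed ``seed + 1000 * K + r`` so every run is
    independently reproducible.
    """
    runs: dict[int, list[ClusterPosterior]] = {}
    for K in k_range:
        runs[K] = [
            admixture_gibbs(g, K, iters=iters, burnin=burnin,
                            seed=seed + 1000 * K + r)
            for r in range(replicates)
        ]
    table = evanno_delta_k({k: [r.lnPD for r in v] for k, v in runs.items()})
    return runs, table
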