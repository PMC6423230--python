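"""Bayesian assignment of individuals to six hybrid genotype classes.

Given genotype data from two parental species plus candidate hybrids,
each individual is assigned a posterior probability over the six
early-generation genotype classes: the two pure parents, F1, F2 and the
two first-generation backcrosses.  Each class implies Mendelian
probabilities (p11, p12, p22) that a locus carries two gene copies from
species 1, one from each, or two from species 2; genotype likelihoods
mix Hardy-Weinberg terms over the unknown parental allele frequencies,
which are estimated jointly by Gibbs sampling.

Reference individuals of known pure origin can be pinned to their class
(``z_fixed``); individuals can also be excluded from allele-frequency
estimation (``s_excluded``), e.g. to keep candidate hybrids from
contaminating the parental frequency estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .admixture import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "class_frequencies",
    "genotype_likelihood",
    "HybridClassPosterior",
    "newhybrids_mcmc",
]

CLASSES = ("Pure1", "Pure2", "F1", "F2", "BC1", "BC2")

# (p11, p12, p22): probability a locus has both copies from species 1,
# one from each, or both from species 2
_CLASS_TRIPLES = {
    "Pure1": (1.0, 0.0, 0.0),
    "Pure2": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC1": (0.5, 0.5, 0.0),
    "BC2": (0.0, 0.5, 0.5),
}


def class_frequencies() -> dict[str, tuple[float, float, float]]:
    """Mendelian gene-copy-origin triples for the six genotype classes."""
    return dict(_CLASS_TRIPLES)


def genotype_likelihood(genotype: tuple[int, int], cls: str,
                        f1: np.ndarray, f2: np.ndarray) -> float:
    """P(genotype | class, parental allele frequencies) at one locus.

    ``genotype`` is an unordered allele pair (indices into the locus
    catalogue); ``f1``/``f2`` are the parental allele frequency vectors.
    """
    a, b = genotype
    for x in (a, b):
        if not (0 <= x < len(f1) and x < len(f2)):
            raise ValueError(f"allele {x} outside both catalogues")
    p11, p12, p22 = _CLASS_TRIPLES[cls]

    def hw(f: np.ndarray) -> float:
        return f[a] * f[a] if a == b else 2 * f[a] * f[b]

    mixed = f1[a] * f2[a] if a == b else f1[a] * f2[b] + f1[b] * f2[a]
    return p11 * hw(f1) + p12 * mixed + p22 * hw(f2)


@dataclass
class HybridClassPosterior:
    """Per-individual posterior over the six genotype classes."""

    individuals: list[str]
    posterior: np.ndarray          # (N, 6)
    prior: str
    sweeps: int
    burnin: int
    seed: int
    convergence_warning: bool = False

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.posterior, index=self.individuals,
                            columns=list(CLASSES))

    def modal_class(self) -> pd.Series:
        f = self.frame()
        return f.idxmax(axis=1)


def _genotype_like_tables(calls: np.ndarray, F1: np.ndarray,
                          F2: np.ndarray) -> np.ndarray:
    """(N, L, 3) likelihoods of each genotype under origins 11, 12, 22.

    Missing loci (call -1) get likelihood 1 in every origin state.
    """
    a = calls[:, :, 0]
    b = calls[:, :, 1]
    miss = a < 0
    a = np.where(miss, 0, a)
    b = np.where(miss, 0, b)
    lidx = np.arange(calls.shape[1])[None, :]
    f1a, f1b = F1[lidx, a], F1[lidx, b]
    f2a, f2b = F2[lidx, a], F2[lidx, b]
    het = (a != b)
    hw1 = np.where(het, 2 * f1a * f1b, f1a * f1a)
    hw2 = np.where(het, 2 * f2a * f2b, f2a * f2a)
    mix = np.where(het, f1a * f2b + f1b * f2a, f1a * f2a)
    out = np.stack([hw1, mix, hw2], axis=2)
    out[miss] = 1.0
    return out


def newhybrids_mcmc(g: GenotypeMatrix, prior: str = "jeffreys_like",
                    z_fixed: Mapping[str, str] | None = None,
                    s_excluded: Sequence[str] = (),
                    sweeps: int = 1200, burnin: int = 400,
                    seed: int = 0, replicates: int = 2) -> HybridClassPosterior:
    """Gibbs sampler over genotype classes for a two-parent system.

    ``prior`` selects the per-locus allele-frequency prior: Dirichlet(1/A)
    (``jeffreys_like``, A = catalogue size) or Dirichlet(1) (``uniform``).
    ``z_fixed`` maps individual id to "Pure1"/"Pure2" for reference
    samples of known origin (they keep their class but still inform the
    frequency estimates unless also in ``s_excluded``).  Replicate runs
    are averaged; a maximum per-class posterior difference above 0.1
    between replicates sets ``convergence_warning``.
    """
    if prior not in ("jeffreys_like", "uniform"):
        raise ValueError(f"unknown prior {prior!r}")
    z_fixed = dict(z_fixed or {})
    for ind, cls in z_fixed.items():
        if cls not in ("Pure1", "Pure2"):
            raise ValueError(f"z-fixed class must be pure, got {cls!r}")
        if ind not in g.individuals:
            raise KeyError(ind)
    if not any(c == "Pure1" for c in z_fixed.values()) or \
       not any(c == "Pure2" for c in z_fixed.values()):
        raise ValueError("need >= 1 z-fixed reference individual per parent")

    results = []
    for rep in range(replicates):
        results.append(_one_run(g, prior, z_fixed, set(s_excluded),
                                sweeps, burnin, seed + rep))
    post = np.mean(results, axis=0)
    spread = float(np.max(np.abs(results[0] - results[-1]))) if replicates > 1 else 0.0
    warn = spread > 0.1
    if warn:
        logger.warning("replicate runs disagree (max diff %.3f)", spread)
    return HybridClassPosterior(list(g.individuals), post, prior,
                                sweeps, burnin, seed, warn)


def _one_run(g: GenotypeMatrix, prior: str, z_fixed: dict[str, str],
             s_excluded: set[str], sweeps: int, burnin: int,
             seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    N, L = g.n_individuals, g.n_loci
    Amax = int(g.n_alleles.max())
    calls = g.calls
    triples = np.array([_CLASS_TRIPLES[c] for c in CLASSES])   # (6, 3)
    lam = np.zeros((L, Amax))
    for l in range(L):
        A = int(g.n_alleles[l])
        lam[l, :A] = (1.0 / A) if prior == "jeffreys_like" else 1.0

    fixed_idx = {g.individuals.index(i): CLASSES.index(c)
                 for i, c in z_fixed.items()}
    excl = np.array([ind in s_excluded for ind in g.individuals])
    free = np.array([i not in fixed_idx for i in range(N)])

    # initial state: fixed classes honored, others random
    cls = rng.integers(len(CLASSES), size=N)
    for i, c in fixed_idx.items():
        cls[i] = c
    pi = np.full(len(CLASSES), 1.0 / len(CLASSES))
    F1 = lam / lam.sum(axis=1, keepdims=True)
    F2 = F1.copy()

    post = np.zeros((N, len(CLASSES)))
    kept = 0
    miss = calls[:, :, 0] < 0

    for sweep in range(sweeps):
        like3 = _genotype_like_tables(calls, F1, F2)      # (N, L, 3)
        # class update for free individuals
        per_class = like3 @ triples.T                     # (N, L, 6)
        per_class = np.clip(per_class, 1e-300, None)
        logp = np.log(per_class).sum(axis=1) + np.log(pi)[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        w = np.exp(logp)
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random(N)
        draw = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
        cls = np.where(free, draw, cls)
        # origin state per (individual, locus) given class
        tri = triples[cls][:, None, :] * like3            # (N, L, 3)
        tsum = tri.sum(axis=2, keepdims=True)
        tri = tri / np.clip(tsum, 1e-300, None)
        u2 = rng.random((N, L))
        origin = (tri.cumsum(axis=2) < u2[:, :, None]).sum(axis=2)  # 0,1,2
        # allele counts into the two parental pools
        C1 = np.zeros((L, Amax))
        C2 = np.zeros((L, Amax))
        a = np.where(miss, 0, calls[:, :, 0])
        b = np.where(miss, 0, calls[:, :, 1])
        use = (~miss) & (~excl[:, None])
        lgrid = np.broadcast_to(np.arange(L)[None, :], (N, L))
        # origin 0: both copies from species 1; origin 2: both from 2;
        # origin 1: one copy each -- split the het pair by frequency odds
        o0 = use & (origin == 0)
        o2 = use & (origin == 2)
        o1 = use & (origin == 1)
        np.add.at(C1, (lgrid[o0], a[o0]), 1.0)
        np.add.at(C1, (lgrid[o0], b[o0]), 1.0)
        np.add.at(C2, (lgrid[o2], a[o2]), 1.0)
        np.add.at(C2, (lgrid[o2], b[o2]), 1.0)
        if o1.any():
            la, aa, bb = lgrid[o1], a[o1], b[o1]
            pa = F1[la, aa] * F2[la, bb]
            pb = F1[la, bb] * F2[la, aa]
            tot = np.clip(pa + pb, 1e-300, None)
            first_to_1 = rng.random(len(la)) < pa / tot
            np.add.at(C1, (la, np.where(first_to_1, aa, bb)), 1.0)
            np.add.at(C2, (la, np.where(first_to_1, bb, aa)), 1.0)
        # frequency and mixing updates
        g1 = rng.gamma(lam + C1)
        g2 = rng.gamma(lam + C2)
        g1[lam == 0] = 0.0
        g2[lam == 0] = 0.0
        F1 = g1 / g1.sum(axis=1, keepdims=True)
        F2 = g2 / g2.sum(axis=1, keepdims=True)
        counts = np.bincount(cls[free], minlength=len(CLASSES))
        pg = rng.gamma(1.0 + counts)
        pi = pg / pg.sum()
        if sweep >= burnin:
            post[np.arange(N), cls] += 1.0
            kept += 1
    return post / kept
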