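"""Coalescent simulation over demographic DAGs with admixture pulses.

The demographic model is a set of populations with constant diploid
effective sizes and an ordered list of backward-in-time events:

* ``Split(t, derived, ancestor)`` — at time t (generations ago) every
  lineage in ``derived`` moves into ``ancestor`` (forward in time: the
  derived population originates from the ancestor at t);
* ``Admixture(t, hybrid, parent1, parent2, rate)`` — at time t each
  lineage in ``hybrid`` traces to ``parent1`` with probability ``rate``,
  else to ``parent2`` (forward in time: the hybrid population is founded
  at t by a pulse drawing a fraction ``rate`` of its ancestry from
  parent1).

Within a population, pairs of lineages coalesce at rate k(k-1)/2 per 2N
generations; waiting times are continuous exponentials interrupted
exactly by events.  Loci are unlinked and recombination-free.  Mutations
follow a finite-sites Jukes-Cantor model: a Poisson number of mutations
(rate mu * length * total branch length) is dropped uniformly on branches
and sites, and each hit replaces the current base by one of the other
three.

Genealogies are returned as parent/time arrays (leaves 0..n-1 in sample
order); ``simulate`` assembles full FASTA-ready alignments, while
``drop_mutations`` alone yields just the mutated-column states for fast
summary statistics (the two views are equivalent, monomorphic columns
carrying no information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import Alignment, MultilocusDataset, SampleTable
import pandas as pd

__all__ = [
    "Split",
    "Admixture",
    "ScenarioSpec",
    "Genealogy",
    "simulate_genealogy",
    "drop_mutations",
    "variants_to_alignment",
    "simulate",
]

BASES = "ACGT"


@dataclass(frozen=True)
class Split:
    time: float
    derived: str
    ancestor: str


@dataclass(frozen=True)
class Admixture:
    time: float
    hybrid: str
    parent1: str
    parent2: str
    rate: float  # fraction of lineages tracing to parent1


@dataclass
class ScenarioSpec:
    """A demographic scenario: populations, events, and sample sizes.

    ``pop_sizes`` are diploid effective sizes; ``samples`` maps population
    id to the number of haploid lineages sampled at time 0.
    """

    name: str
    pop_sizes: dict[str, float]
    events: list[Split | Admixture]
    samples: dict[str, int]

    def sorted_events(self) -> list[Split | Admixture]:
        return sorted(self.events, key=lambda e: e.time)

    def validate(self) -> list[str]:
        """Return a list of violations (empty = valid)."""
        v: list[str] = []
        for pop, size in self.pop_sizes.items():
            if not size > 0:
                v.append(f"population {pop!r} has non-positive size {size}")
        for pop, n in self.samples.items():
            if pop not in self.pop_sizes:
                v.append(f"sampled population {pop!r} has no declared size")
            if n < 0:
                v.append(f"negative sample size for {pop!r}")
        for ev in self.events:
            if not ev.time > 0:
                v.append(f"event at non-positive time {ev.time}")
            if isinstance(ev, Admixture) and not 0 <= ev.rate <= 1:
                v.append(f"admixture rate {ev.rate} outside [0, 1]")
            pops = ([ev.derived, ev.ancestor] if isinstance(ev, Split)
                    else [ev.hybrid, ev.parent1, ev.parent2])
            for p in pops:
                if p not in self.pop_sizes:
                    v.append(f"event references undeclared population {p!r}")
        if v:
            return v
        # replay events backward in time and track which pops hold lineages
        active = {p for p, n in self.samples.items() if n > 0}
        for ev in self.sorted_events():
            if isinstance(ev, Split):
                if ev.derived in active:
                    active.discard(ev.derived)
                    active.add(ev.ancestor)
            else:
                if ev.hybrid in active:
                    active.discard(ev.hybrid)
                    active.add(ev.parent1)
                    active.add(ev.parent2)
                else:
                    continue
                # both parents must still be mergeable later; checked below
        if len(active) > 1:
            v.append(
                f"populations {sorted(active)} never merge into a single root"
            )
        return v

    def require_valid(self) -> None:
        violations = self.validate()
        if violations:
            raise ValueError(
                f"invalid scenario {self.name!r}: " + "; ".join(violations)
            )


@dataclass
class Genealogy:
    """A coalescent tree: node i has parent ``parent[i]`` (-1 at the root)
    and age ``time[i]`` in generations; leaves are 0..n_leaves-1."""

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    sample_pops: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        """Branch length above each non-root node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time.max())

    def leaves_below(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves) matrix of descendant leaves."""
        below = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        below[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        order = np.argsort(self.time, kind="stable")
        for i in order:
            p = self.parent[i]
            if p >= 0:
                below[p] |= below[i]
        return below


def simulate_genealogy(scenario: ScenarioSpec,
                       rng: np.random.Generator,
                       validate: bool = True) -> Genealogy:
    """Simulate one genealogy under the scenario (validated by default;
    pass ``validate=False`` when the same spec is reused across loci)."""
    if validate:
        scenario.require_valid()
    sample_pops = [p for p, n in scenario.samples.items() for _ in range(n)]
    n = len(sample_pops)
    if n < 1:
        raise ValueError("scenario samples no lineages")

    parent = [-1] * n
    times = [0.0] * n
    # active lineages per population
    active: dict[str, list[int]] = {}
    for i, p in enumerate(sample_pops):
        active.setdefault(p, []).append(i)

    events = scenario.sorted_events()
    inv2N = {p: 0.5 / s for p, s in scenario.pop_sizes.items()}
    t = 0.0
    ev_idx = 0
    total = n
    # scalar RNG for the event loop (much cheaper per call); seeded from
    # the caller's generator so reproducibility is preserved
    import random as _random
    rnd = _random.Random(int(rng.integers(1 << 62)))
    unif = rnd.random
    expo = rnd.expovariate
    randint = rnd.randrange

    while total > 1 or ev_idx < len(events):
        next_ev = events[ev_idx].time if ev_idx < len(events) else math.inf
        # competing coalescence across populations with >= 2 lineages
        while True:
            R = 0.0
            for p, lin in active.items():
                k = len(lin)
                if k >= 2:
                    R += k * (k - 1) * 0.5 * inv2N[p]
            if R == 0.0:
                t = next_ev
                break
            dt = expo(R)
            if t + dt >= next_ev:
                t = next_ev
                break
            t += dt
            # choose population proportional to rate
            u = unif() * R
            acc = 0.0
            for p, lin in active.items():
                k = len(lin)
                if k >= 2:
                    acc += k * (k - 1) * 0.5 * inv2N[p]
                    if u <= acc:
                        break
            i = randint(len(lin))
            j = randint(len(lin) - 1)
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            a, b = lin[i], lin[j]
            node = len(parent)
            parent.append(-1)
            times.append(t)
            parent[a] = node
            parent[b] = node
            lin[j] = lin[-1]
            lin.pop()
            lin[i] = node
            total -= 1
        if ev_idx < len(events) and t == events[ev_idx].time:
            ev = events[ev_idx]
            ev_idx += 1
            if isinstance(ev, Split):
                moved = active.pop(ev.derived, [])
                if moved:
                    active.setdefault(ev.ancestor, []).extend(moved)
            else:
                moved = active.pop(ev.hybrid, [])
                if moved:
                    p1 = active.setdefault(ev.parent1, [])
                    p2 = active.setdefault(ev.parent2, [])
                    for lid in moved:
                        (p1 if unif() < ev.rate else p2).append(lid)

    return Genealogy(np.asarray(parent), np.asarray(times), n, sample_pops)


def drop_mutations(gen: Genealogy, length: int, mu: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place Jukes-Cantor mutations on the genealogy.

    Returns ``(sites, states)``: the 0-based positions of columns hit by
    at least one mutation and the resulting (n_leaves, n_sites) matrix of
    base codes 0..3 at those columns.  Columns may be monomorphic when a
    reversion erases the change.
    """
    bl = gen.branch_lengths()
    total = bl.sum()
    m = rng.poisson(mu * length * total)
    if m == 0:
        return np.empty(0, dtype=np.int64), np.empty((gen.n_leaves, 0), dtype=np.int8)
    cum = np.cumsum(bl)
    branches = np.searchsorted(cum, rng.random(m) * total, side="right")
    branches = np.minimum(branches, gen.n_nodes - 1)
    sites = rng.integers(0, length, size=m)
    # age of each mutation: uniform position on its branch
    ages = gen.time[branches] + rng.random(m) * bl[branches]
    below = gen.leaves_below()

    uniq_sites, inverse, counts = np.unique(sites, return_inverse=True,
                                            return_counts=True)
    n_sites = len(uniq_sites)
    roots = rng.integers(4, size=n_sites).astype(np.int8)
    states = np.tile(roots, (gen.n_leaves, 1))
    single = counts[inverse] == 1
    if single.any():
        cols = inverse[single]
        mask = below[branches[single]].T           # (n_leaves, m_single)
        new = ((roots[cols] + 1 + rng.integers(3, size=len(cols))) % 4
               ).astype(np.int8)
        sub = states[:, cols]
        states[:, cols] = np.where(mask, new[None, :], sub)
    multi_cols = np.unique(inverse[~single])
    for s_idx in multi_cols:
        hits = np.where(inverse == s_idx)[0]
        # oldest first so younger mutations overwrite within their subtree
        hits = hits[np.argsort(-ages[hits])]
        col = states[:, s_idx]
        for h in hits:
            msk = below[branches[h]]
            cur = col[msk][0] if msk.any() else 0
            col[msk] = (cur + 1 + rng.integers(3)) % 4
        states[:, s_idx] = col
    return uniq_sites, states


def variants_to_alignment(gen: Genealogy, sites: np.ndarray,
                          states: np.ndarray, length: int,
                          rng: np.random.Generator,
                          sample_keys: Sequence[str],
                          locus_id: str, marker: str) -> Alignment:
    """Expand a variant matrix into a full alignment (non-mutated columns
    get a random root base, shared by all rows)."""
    root = rng.integers(4, size=length).astype(np.int8)
    full = np.tile(root, (gen.n_leaves, 1))
    if len(sites):
        full[:, sites] = states
    lut = np.array(list(BASES), dtype="U1")
    rows = [(key, "".join(lut[full[i]])) for i, key in enumerate(sample_keys)]
    return Alignment(locus_id, rows, marker)  # type: ignore[arg-type]


def simulate(scenario: ScenarioSpec, loci: Sequence[tuple[int, float]],
             seed: int, marker: str = "nuclear",
             prefix: str = "sim") -> MultilocusDataset:
    """Simulate a multilocus dataset under the scenario.

    ``loci`` is a list of (length_bp, mu_per_site_per_generation).  For
    nuclear loci, consecutive pairs of sampled lineages form diploid
    individuals (sample keys ``<ind>/1`` and ``<ind>/2``); chloroplast
    loci keep one row per sampled lineage.  Reproducible bit-for-bit for a
    given (scenario, loci, seed).
    """
    scenario.require_valid()
    rng = np.random.default_rng(seed)
    sample_pops = [p for p, k in scenario.samples.items() for _ in range(k)]
    n = len(sample_pops)
    if marker == "nuclear":
        if n % 2:
            raise ValueError("nuclear simulation needs an even lineage count")
        inds = [f"{prefix}_{sample_pops[2 * i]}_{i}" for i in range(n // 2)]
        keys = [f"{ind}/{c + 1}" for ind in inds for c in range(2)]
        ind_pops = [sample_pops[2 * i] for i in range(n // 2)]
    else:
        inds = [f"{prefix}_{p}_{i}" for i, p in enumerate(sample_pops)]
        keys = list(inds)
        ind_pops = list(sample_pops)

    alignments = []
    for li, (length, mu) in enumerate(loci):
        gen = simulate_genealogy(scenario, rng)
        sites, states = drop_mutations(gen, length, mu, rng)
        alignments.append(variants_to_alignment(
            gen, sites, states, length, rng, keys,
            f"{prefix}_locus{li + 1}", marker))
    samples = SampleTable(pd.DataFrame({
        "individual_id": inds,
        "taxon": ind_pops,
        "population": ind_pops,
        "role": "reference_parent",
    }))
    return MultilocusDataset(alignments, samples)
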