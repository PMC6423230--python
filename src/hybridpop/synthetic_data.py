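"""Fully labeled synthetic datasets emulating a three-species hybrid zone.

Three parental species (spA, spB, spC — think of a white-poplar-like
species pair plus a third relative) are simulated with the coalescent
engine on the species tree ((spA, spC), spB); nuclear loci are phased
diploid alignments, chloroplast loci are haploid with a smaller
effective size and mutation rate, so chloroplast diversity is much lower
than nuclear diversity and chloroplast haplotype pools are well
separated between species.

Hybrids are then constructed mechanically from the simulated parental
haplotypes — F1s take one random haplotype from each parent species per
nuclear locus, F2s are gametes of two independent F1s, backcrosses
combine an F1 gamete with a pure gamete, trihybrids combine a gamete of
an (X x Y) F1 with a pure Z gamete — and every hybrid copies its
chloroplast sequences from one randomly chosen individual of its
designated maternal species.  This gives exact ground-truth labels for
every downstream classifier test.

The default :func:`study_fixture` mirrors a typical hybrid-poplar survey
design at reduced scale: an F1-dominated hybrid swarm with two F2s, a second F1 swarm with
a different maternal parent, a small trihybrid set amounting to ~7.7% of
the second hybrid taxon, and four introgressed parental individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coalsim import ScenarioSpec, Split, simulate
from .seqio import Alignment, MultilocusDataset, SampleTable

__all__ = [
    "FixtureConfig",
    "HybridGroup",
    "SyntheticTruth",
    "generate_parents",
    "make_hybrids",
    "study_fixture",
]

SPECIES = ("spA", "spB", "spC")


@dataclass
class FixtureConfig:
    """Generator parameters (defaults mirror the emulated survey design).

    Nuclear loci: 10 alignments of 400-800 bp with per-site theta
    4*N_nuclear*nuclear_mu = 0.005; chloroplast: 6 loci of 900-2500 bp
    with much lower diversity.  Species split times t1 (spA/spC) and t2
    (ancestor/spB) are deep relative to 2N, giving abundant diagnostic
    sites.
    """

    n_per_species: int = 20
    nuclear_lengths: tuple[int, ...] = (400, 450, 500, 550, 600, 650, 700,
                                        750, 800, 420)
    cp_lengths: tuple[int, ...] = (900, 1200, 1500, 1800, 2100, 2500)
    nuclear_mu: float = 1e-6
    cp_mu: float = 3e-7
    N_nuclear: float = 1250.0
    N_cp: float = 300.0
    t1: float = 10000.0      # spA/spC split, generations
    t2: float = 20000.0      # ancestor/spB split
    seed: int = 0

    @property
    def theta_nuclear(self) -> float:
        return 4 * self.N_nuclear * self.nuclear_mu

    @property
    def theta_cp(self) -> float:
        return 4 * self.N_cp * self.cp_mu


@dataclass
class HybridGroup:
    """A block of constructed hybrids sharing taxon label and pedigree.

    ``parents``: (X, Y) for F1/F2; (X, Y, Z) for BC/trihybrid/introgressed,
    read as 'gamete of an F1(X x Y) combined with a pure Z gamete'.
    ``maternal`` names the species whose chloroplast is inherited.
    """

    taxon: str
    category: str          # F1 | F2 | BC | trihybrid | introgressed
    n: int
    parents: tuple[str, ...]
    maternal: str
    population: str = ""

    def __post_init__(self) -> None:
        need = 3 if self.category in ("BC", "trihybrid", "introgressed") else 2
        if len(self.parents) != need:
            raise ValueError(
                f"{self.category} needs {need} parent species, got "
                f"{self.parents}")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for every generated individual."""

    table: pd.DataFrame  # index individual_id; columns category, maternal,
                         # taxon, seed

    def category_of(self, individual: str) -> str:
        return str(self.table.loc[individual, "category"])

    def individuals_in(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])


def _species_tree(cfg: FixtureConfig, sizes: Mapping[str, float]) -> tuple[list, dict]:
    pops = {**{s: sizes[s] for s in SPECIES},
            "ancAC": sizes["spA"], "root": sizes["spB"]}
    events = [
        Split(cfg.t1, "spA", "ancAC"),
        Split(cfg.t1, "spC", "ancAC"),
        Split(cfg.t2, "ancAC", "root"),
        Split(cfg.t2, "spB", "root"),
    ]
    return events, pops


def generate_parents(cfg: FixtureConfig) -> tuple[MultilocusDataset, SyntheticTruth]:
    """Simulate the three parental species (nuclear + chloroplast loci)."""
    n = cfg.n_per_species
    events, npops = _species_tree(cfg, {s: cfg.N_nuclear for s in SPECIES})
    nuc_scenario = ScenarioSpec("parents_nuclear", npops, events,
                                {s: 2 * n for s in SPECIES})
    nuc = simulate(nuc_scenario, [(L, cfg.nuclear_mu) for L in cfg.nuclear_lengths],
                   seed=cfg.seed, marker="nuclear", prefix="P")

    events_cp, cpops = _species_tree(cfg, {s: cfg.N_cp for s in SPECIES})
    cp_scenario = ScenarioSpec("parents_cp", cpops, events_cp,
                               {s: n for s in SPECIES})
    cp = simulate(cp_scenario, [(L, cfg.cp_mu) for L in cfg.cp_lengths],
                  seed=cfg.seed + 1, marker="chloroplast", prefix="P")
    # the two simulate() calls emit identical individual ids by design
    if nuc.samples.individual_ids != cp.samples.individual_ids:
        raise AssertionError("nuclear/cp individual ids diverged")
    ds = MultilocusDataset(nuc.alignments + cp.alignments, nuc.samples)
    truth = SyntheticTruth(pd.DataFrame({
        "category": [f"pure_{t}" for t in nuc.samples.table["taxon"]],
        "maternal": list(nuc.samples.table["taxon"]),
        "taxon": list(nuc.samples.table["taxon"]),
        "seed": cfg.seed,
    }, index=pd.Index(nuc.samples.individual_ids, name="individual_id")))
    return ds, truth


class _Pools:
    """Per-species haplotype pools drawn from a parental dataset."""

    def __init__(self, parents: MultilocusDataset):
        self.nuclear = parents.loci("nuclear")
        self.cp = parents.loci("chloroplast")
        samples = parents.samples
        self.by_species: dict[str, list[str]] = {
            s: samples.individuals_of(s) for s in
            sorted(set(samples.table["taxon"]))
        }
        self._nuc_rows = [dict(a.rows) for a in self.nuclear]
        self._cp_rows = [dict(a.rows) for a in self.cp]

    def random_haplotype(self, species: str, locus: int,
                         rng: np.random.Generator) -> str:
        inds = self.by_species[species]
        ind = inds[rng.integers(len(inds))]
        copy = rng.integers(2) + 1
        return self._nuc_rows[locus][f"{ind}/{copy}"]

    def f1_genome(self, x: str, y: str, rng: np.random.Generator) -> list[tuple[str, str]]:
        return [(self.random_haplotype(x, l, rng),
                 self.random_haplotype(y, l, rng))
                for l in range(len(self.nuclear))]

    @staticmethod
    def gamete(genome: list[tuple[str, str]],
               rng: np.random.Generator) -> list[str]:
        return [pair[rng.integers(2)] for pair in genome]

    def cp_sequences(self, species: str, rng: np.random.Generator) -> list[str]:
        inds = self.by_species[species]
        ind = inds[rng.integers(len(inds))]
        return [self._cp_rows[l][ind] for l in range(len(self.cp))]


def make_hybrids(parents: MultilocusDataset, groups: Sequence[HybridGroup],
                 seed: int = 0) -> tuple[MultilocusDataset, SyntheticTruth]:
    """Construct hybrid individuals from parental haplotype pools."""
    pools = _Pools(parents)
    for grp in groups:
        for sp in set(grp.parents) | {grp.maternal}:
            if sp not in pools.by_species or not pools.by_species[sp]:
                raise ValueError(f"empty or unknown parent pool {sp!r}")
        if grp.n > 10 * min(len(pools.by_species[s]) for s in grp.parents):
            raise ValueError(f"group {grp.taxon!r} exceeds pool capacity")
    rng = np.random.default_rng(seed)
    nuc_rows: list[list[tuple[str, str]]] = [[] for _ in pools.nuclear]
    cp_rows: list[list[tuple[str, str]]] = [[] for _ in pools.cp]
    meta = []
    truth = []
    counter = 0
    for grp in groups:
        for _ in range(grp.n):
            ind = f"H{counter}_{grp.taxon}"
            counter += 1
            if grp.category == "F1":
                x, y = grp.parents
                genome = pools.f1_genome(x, y, rng)
            elif grp.category == "F2":
                x, y = grp.parents
                g1 = pools.gamete(pools.f1_genome(x, y, rng), rng)
                g2 = pools.gamete(pools.f1_genome(x, y, rng), rng)
                genome = list(zip(g1, g2))
            else:  # BC, trihybrid, introgressed: F1(x,y) gamete + pure z
                x, y, z = grp.parents
                g1 = pools.gamete(pools.f1_genome(x, y, rng), rng)
                g2 = [pools.random_haplotype(z, l, rng)
                      for l in range(len(pools.nuclear))]
                genome = list(zip(g1, g2))
            for l, (h1, h2) in enumerate(genome):
                nuc_rows[l].append((f"{ind}/1", h1))
                nuc_rows[l].append((f"{ind}/2", h2))
            for l, seq in enumerate(pools.cp_sequences(grp.maternal, rng)):
                cp_rows[l].append((ind, seq))
            meta.append({
                "individual_id": ind, "taxon": grp.taxon,
                "population": grp.population or grp.taxon,
                "role": "candidate_hybrid",
            })
            truth.append({
                "individual_id": ind, "category": grp.category,
                "maternal": grp.maternal, "taxon": grp.taxon, "seed": seed,
            })
    alignments = [
        Alignment(a.locus_id, rows, a.marker)
        for a, rows in zip(pools.nuclear, nuc_rows)
    ] + [
        Alignment(a.locus_id, rows, a.marker)
        for a, rows in zip(pools.cp, cp_rows)
    ]
    samples = SampleTable(pd.DataFrame(meta))
    truth_df = pd.DataFrame(truth).set_index("individual_id")
    return (MultilocusDataset(alignments, samples),
            SyntheticTruth(truth_df))


DEFAULT_GROUPS = (
    # hybrid swarm 1: F1-dominated with two F2s (spB maternal)
    HybridGroup("hybAB", "F1", 14, ("spA", "spB"), "spB", "loc_hab1"),
    HybridGroup("hybAB", "F2", 2, ("spA", "spB"), "spB", "loc_hab1"),
    # hybrid swarm 2 (mb1 analogue): pure F1s, spC maternal, 3 localities
    HybridGroup("hybAC", "F1", 10, ("spA", "spC"), "spC", "loc_hac1"),
    HybridGroup("hybAC", "F1", 8, ("spA", "spC"), "spC", "loc_hac2"),
    HybridGroup("hybAC", "F1", 6, ("spA", "spC"), "spC", "loc_hac3"),
    # trihybrid type (mb2 analogue): (spB x spC) F1 gamete + spA gamete,
    # spB maternal; 2 of 26 = 7.7% of the second hybrid taxon
    HybridGroup("triBCA", "trihybrid", 2, ("spB", "spC", "spA"), "spB",
                "loc_hac1"),
    # introgressed parental individuals: mostly spC nuclear, spB cp
    HybridGroup("spC_introgressed", "introgressed", 4, ("spB", "spC", "spC"),
                "spB", "loc_intro"),
)


def study_fixture(seed: int = 0, cfg: FixtureConfig | None = None,
                  groups: Sequence[HybridGroup] = DEFAULT_GROUPS,
                  ) -> tuple[MultilocusDataset, SyntheticTruth]:
    """Parental species plus the default hybrid composition, fully labeled."""
    cfg = replace(cfg, seed=seed) if cfg is not None else FixtureConfig(seed=seed)
    parents, ptruth = generate_parents(cfg)
    hybrids, htruth = make_hybrids(parents, groups, seed=cfg.seed + 2)
    alignments = []
    for pa, ha in zip(parents.alignments, hybrids.alignments):
        if pa.locus_id != ha.locus_id:
            raise AssertionError("locus order mismatch")
        alignments.append(Alignment(pa.locus_id, pa.rows + ha.rows, pa.marker))
    samples = SampleTable(pd.concat([parents.samples.table,
                                     hybrids.samples.table],
                                    ignore_index=True))
    truth = SyntheticTruth(pd.concat([ptruth.table, htruth.table]))
    return MultilocusDataset(alignments, samples), truth
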