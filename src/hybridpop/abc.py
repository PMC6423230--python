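"""Coalescent ABC scenario comparison (rejection + logistic regression).

Candidate demographic scenarios (population splits with or without
admixture pulses) are compared by simulating datasets under parameter
draws from their priors, reducing each to a fixed vector of summary
statistics, retaining the simulations closest to the observed vector,
and fitting a multinomial logistic regression of scenario identity on
the statistic deviations; the fitted class probabilities at the observed
point are the scenario posterior probabilities, with bootstrap 95%
confidence intervals.

Two scenario libraries are built in:

* ``trio`` — seven scenarios for two putative parents (Pop1, Pop2) and a
  focal taxon (Pop3): a simultaneous three-way split; the three
  two-step split topologies; and three admixture-origin scenarios, one
  per choice of which population is the hybrid (scenario 5 = Pop3 is the
  hybrid of Pop1 and Pop2).
* ``quartet`` — seven scenarios for a focal taxon Pop4 against three
  parental species Pop1..Pop3 on the backbone ((Pop1, Pop2), Pop3):
  direct descent from the root ancestor, from Pop3, or from the
  Pop1/Pop2 ancestor; a single hybridization between Pop3 and the
  Pop1/Pop2 ancestor; and the three two-step trihybrid orders through an
  intermediate hybrid population Pop5 (scenario 6 = Pop5 from Pop1 x
  Pop3, then Pop4 from Pop5 x Pop2).

Summary statistics per population: haplotype count, segregating sites,
mean and variance of pairwise differences, Tajima's D; per population
pair: mean between-population difference and Hudson's FST; all averaged
over loci.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import popgen
from .coalsim import (Admixture, ScenarioSpec, Split, drop_mutations,
                      simulate_genealogy)
from .seqio import MultilocusDataset, individual_of_key

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "sample_priors",
    "ScenarioTemplate",
    "scenario_library",
    "summary_statistics",
    "stat_labels",
    "simulate_reference_table",
    "abc_rejection",
    "scenario_posterior",
    "run_abc",
    "AbcResult",
]

# 10 unlinked 600-bp loci; the per-site mutation rate is set so that, at
# population sizes in the middle of the default prior, per-site diversity
# falls in the empirically typical 0.003-0.008 range
DEFAULT_LOCI: tuple[tuple[int, float], ...] = tuple((600, 2.5e-7) for _ in range(10))
DEFAULT_SAMPLES = 10  # haploid lineages per population


@dataclass
class PriorSpec:
    """Independent parameter priors plus pairwise ordering constraints.

    ``params`` maps a name to (family, low, high) with family ``uniform``
    or ``loguniform``; ``constraints`` is a list of (smaller, larger)
    parameter-name pairs enforced by rejection resampling.
    """

    params: dict[str, tuple[str, float, float]]
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (family, lo, hi) in self.params.items():
            if family not in ("uniform", "loguniform"):
                raise ValueError(f"unknown prior family {family!r} for {name}")
            if not (0 < lo < hi) and family == "loguniform":
                raise ValueError(f"loguniform bounds must be positive: {name}")
            if not lo < hi:
                raise ValueError(f"empty prior range for {name}")
        for a, b in self.constraints:
            if a not in self.params or b not in self.params:
                raise ValueError(f"constraint on unknown parameters ({a}, {b})")


def sample_priors(prior: PriorSpec, rng: np.random.Generator,
                  max_attempts: int = 1000) -> dict[str, float]:
    """One joint draw satisfying all ordering constraints."""
    for _ in range(max_attempts):
        draw = {}
        for name, (family, lo, hi) in prior.params.items():
            if family == "uniform":
                draw[name] = float(rng.uniform(lo, hi))
            else:
                draw[name] = float(math.exp(rng.uniform(math.log(lo),
                                                        math.log(hi))))
        if all(draw[a] < draw[b] for a, b in prior.constraints):
            return draw
    raise RuntimeError("prior constraints unsatisfiable after max attempts")


@dataclass
class ScenarioTemplate:
    """A scenario family: prior plus a builder from a parameter draw."""

    name: str
    populations: tuple[str, ...]      # sampled populations, fixed order
    prior: PriorSpec
    build: Callable[[Mapping[str, float]], ScenarioSpec]

    def instantiate(self, params: Mapping[str, float] | None = None,
                    samples: Mapping[str, int] | None = None) -> ScenarioSpec:
        if params is None:  # midpoint draw, handy for validation/examples
            params = {}
            for name, (family, lo, hi) in self.prior.params.items():
                params[name] = (math.sqrt(lo * hi) if family == "loguniform"
                                else 0.5 * (lo + hi))
            # nudge constrained params apart (iterate: chains like
            # th0 < th1 < ta need several passes)
            for _ in range(len(self.prior.constraints) + 1):
                for a, b in self.prior.constraints:
                    if params[a] >= params[b]:
                        params[a] = 0.4 * params[b]
        spec = self.build(params)
        if samples:
            spec.samples = dict(samples)
        return spec


def _n_prior(names: Sequence[str]) -> dict[str, tuple[str, float, float]]:
    return {n: ("loguniform", 1e2, 1e5) for n in names}


def _t_prior(names: Sequence[str]) -> dict[str, tuple[str, float, float]]:
    return {n: ("uniform", 10.0, 1e5) for n in names}


def _r_prior(names: Sequence[str]) -> dict[str, tuple[str, float, float]]:
    return {n: ("uniform", 0.05, 0.95) for n in names}


def _trio_library(n_samples: int) -> list[ScenarioTemplate]:
    pops = ("pop1", "pop2", "pop3")
    samples = {p: n_samples for p in pops}

    def sizes(params: Mapping[str, float]) -> dict[str, float]:
        return {"pop1": params["N1"], "pop2": params["N2"],
                "pop3": params["N3"], "anc": params["Na"]}

    def base_prior(times: Sequence[str], rates: Sequence[str] = (),
                   constraints: Sequence[tuple[str, str]] = ()) -> PriorSpec:
        return PriorSpec(
            {**_n_prior(["N1", "N2", "N3", "Na"]), **_t_prior(times),
             **_r_prior(rates)},
            list(constraints),
        )

    def split_all(params):   # scenario 1: simultaneous three-way split
        t0 = params["t0"]
        return ScenarioSpec("trio_1", sizes(params), [
            Split(t0, "pop1", "anc"), Split(t0, "pop2", "anc"),
            Split(t0, "pop3", "anc")], dict(samples))

    def nested(derived: str, ancestor: str, idx: int):
        def build(params):
            t0, t1 = params["t0"], params["t1"]
            survivors = {"pop1", "pop2", "pop3"} - {derived}
            ev = [Split(t1, derived, ancestor)] + [
                Split(t0, p, "anc") for p in sorted(survivors)]
            return ScenarioSpec(f"trio_{idx}", sizes(params), ev, dict(samples))
        return build

    def admixed(hybrid: str, p1: str, p2: str, idx: int):
        def build(params):
            t0, t1, r = params["t0"], params["t1"], params["r1"]
            ev = [Admixture(t1, hybrid, p1, p2, r),
                  Split(t0, p1, "anc"), Split(t0, p2, "anc")]
            return ScenarioSpec(f"trio_{idx}", sizes(params), ev, dict(samples))
        return build

    ordered = [("t1", "t0")]
    return [
        ScenarioTemplate("trio_1", pops, base_prior(["t0"]), split_all),
        ScenarioTemplate("trio_2", pops, base_prior(["t0", "t1"], (), ordered),
                         nested("pop3", "pop1", 2)),
        ScenarioTemplate("trio_3", pops, base_prior(["t0", "t1"], (), ordered),
                         nested("pop3", "pop2", 3)),
        ScenarioTemplate("trio_4", pops, base_prior(["t0", "t1"], (), ordered),
                         nested("pop2", "pop1", 4)),
        ScenarioTemplate("trio_5", pops, base_prior(["t0", "t1"], ["r1"], ordered),
                         admixed("pop3", "pop1", "pop2", 5)),
        ScenarioTemplate("trio_6", pops, base_prior(["t0", "t1"], ["r1"], ordered),
                         admixed("pop1", "pop2", "pop3", 6)),
        ScenarioTemplate("trio_7", pops, base_prior(["t0", "t1"], ["r1"], ordered),
                         admixed("pop2", "pop1", "pop3", 7)),
    ]


def _quartet_library(n_samples: int) -> list[ScenarioTemplate]:
    pops = ("pop1", "pop2", "pop3", "pop4")
    samples = {p: n_samples for p in pops}

    def sizes(params: Mapping[str, float], extra: Sequence[str] = ()) -> dict[str, float]:
        out = {"pop1": params["N1"], "pop2": params["N2"],
               "pop3": params["N3"], "pop4": params["N4"],
               "anc12": params["Na"], "anc": params["Na"]}
        for p in extra:
            out[p] = params["N5"]
        return out

    def backbone(params) -> list:
        ta, tb = params["ta"], params["tb"]
        return [Split(ta, "pop1", "anc12"), Split(ta, "pop2", "anc12"),
                Split(tb, "anc12", "anc"), Split(tb, "pop3", "anc")]

    def prior(times: Sequence[str], rates: Sequence[str],
              constraints: Sequence[tuple[str, str]],
              n5: bool = False) -> PriorSpec:
        ns = ["N1", "N2", "N3", "N4", "Na"] + (["N5"] if n5 else [])
        return PriorSpec(
            {**_n_prior(ns), **_t_prior(["ta", "tb", *times]),
             **_r_prior(rates)},
            [("ta", "tb"), *constraints],
        )

    def q1(params):  # pop4 branches from the root ancestor directly
        return ScenarioSpec("quartet_1", sizes(params),
                            backbone(params) + [Split(params["tc"], "pop4", "anc")],
                            dict(samples))

    def q2(params):  # pop4 descends from pop3
        return ScenarioSpec("quartet_2", sizes(params),
                            backbone(params) + [Split(params["t0"], "pop4", "pop3")],
                            dict(samples))

    def q3(params):  # pop4 descends from the pop1/pop2 ancestor
        return ScenarioSpec("quartet_3", sizes(params),
                            backbone(params) + [Split(params["tx"], "pop4", "anc12")],
                            dict(samples))

    def q4(params):  # pop4 = hybrid of pop3 and the pop1/pop2 ancestor
        return ScenarioSpec("quartet_4", sizes(params),
                            backbone(params) + [
                                Admixture(params["tx"], "pop4", "pop3",
                                          "anc12", params["r1"])],
                            dict(samples))

    def two_step(x: str, y: str, z: str, idx: int):
        # pop5 = hybrid of (x, y) at th1; pop4 = hybrid of (pop5, z) at th0
        def build(params):
            ev = backbone(params) + [
                Admixture(params["th1"], "pop5", x, y, params["r1"]),
                Admixture(params["th0"], "pop4", "pop5", z, params["r2"]),
            ]
            return ScenarioSpec(f"quartet_{idx}", sizes(params, ["pop5"]),
                                ev, dict(samples))
        return build

    two_step_prior = prior(["th0", "th1"], ["r1", "r2"],
                           [("th0", "th1"), ("th1", "ta")], n5=True)
    return [
        ScenarioTemplate("quartet_1", pops,
                         prior(["tc"], [], [("tb", "tc")]), q1),
        ScenarioTemplate("quartet_2", pops,
                         prior(["t0"], [], [("t0", "tb")]), q2),
        ScenarioTemplate("quartet_3", pops,
                         prior(["tx"], [], [("ta", "tx"), ("tx", "tb")]), q3),
        ScenarioTemplate("quartet_4", pops,
                         prior(["tx"], ["r1"], [("ta", "tx"), ("tx", "tb")]), q4),
        ScenarioTemplate("quartet_5", pops, two_step_prior,
                         two_step("pop1", "pop2", "pop3", 5)),
        ScenarioTemplate("quartet_6", pops, two_step_prior,
                         two_step("pop1", "pop3", "pop2", 6)),
        ScenarioTemplate("quartet_7", pops, two_step_prior,
                         two_step("pop2", "pop3", "pop1", 7)),
    ]


def scenario_library(name: str,
                     n_samples: int = DEFAULT_SAMPLES) -> list[ScenarioTemplate]:
    """The built-in scenario libraries: ``trio`` or ``quartet``."""
    if name == "trio":
        return _trio_library(n_samples)
    if name == "quartet":
        return _quartet_library(n_samples)
    raise ValueError(f"unknown scenario library {name!r}")


# ---------------------------------------------------------------------------
# summary statistics

def stat_labels(pops: Sequence[str]) -> list[str]:
    labels = []
    for p in pops:
        labels += [f"{p}:Nh", f"{p}:S", f"{p}:k", f"{p}:varK", f"{p}:TajD"]
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            labels += [f"{pops[i]}-{pops[j]}:kB", f"{pops[i]}-{pops[j]}:Fst"]
    return labels


from functools import lru_cache


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = popgen.harmonic(n - 1)
    a2 = popgen.harmonic(n - 1, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1**2 + a2)


class _StatPlan:
    """Precomputed index structures for repeated summary-stat evaluation
    on a fixed sample layout."""

    def __init__(self, sample_pops: Sequence[str], pops: Sequence[str]):
        self.pop_slices = [np.flatnonzero(np.asarray(sample_pops) == p)
                           for p in pops]
        self.within = []
        for rows in self.pop_slices:
            ii, jj = np.triu_indices(len(rows), 1)
            self.within.append((rows, rows[ii], rows[jj]))
        self.between = []
        P = len(pops)
        for i in range(P):
            for j in range(i + 1, P):
                a = self.pop_slices[i]
                b = self.pop_slices[j]
                ia = np.repeat(a, len(b))
                jb = np.tile(b, len(a))
                self.between.append((i, j, ia, jb))

    def locus_stats(self, states: np.ndarray) -> np.ndarray:
        """Statistic vector of one locus from its variant-state matrix
        (n_samples, n_variant_columns); undefined Tajima's D (S = 0) is 0."""
        n_rows, m = states.shape
        if m:
            if m > 24:
                # match counts via one-hot matmuls (BLAS) for wide matrices
                match = np.zeros((n_rows, n_rows), dtype=np.float32)
                for v in range(4):
                    X = (states == v).astype(np.float32)
                    match += X @ X.T
                diff = m - match
            else:
                diff = (states[:, None, :] != states[None, :, :]).sum(axis=2)
        else:
            diff = np.zeros((n_rows, n_rows), dtype=np.int64)
        out = []
        ks = []
        for rows, ia, jb in self.within:
            n = len(rows)
            sub = states[rows]
            if states.shape[1]:
                S = int((sub != sub[0]).any(axis=0).sum())
                Nh = len({sub[i].tobytes() for i in range(n)})
            else:
                S, Nh = 0, 1
            pair = diff[ia, jb]
            if pair.size:
                k = float(pair.mean())
                vark = float(pair.var())
            else:
                k = vark = 0.0
            if S > 0:
                a1, e1, e2 = _tajima_constants(n)
                D = (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
            else:
                D = 0.0
            out += [float(Nh), float(S), k, vark, D]
            ks.append(k)
        for i, j, ia, jb in self.between:
            kb = float(diff[ia, jb].mean())
            hw = 0.5 * (ks[i] + ks[j])
            fst = 1.0 - hw / kb if kb > 0 else 0.0
            out += [kb, fst]
        return np.asarray(out)


def _locus_stats(states: np.ndarray, pop_slices: Sequence[np.ndarray]) -> np.ndarray:
    """One-shot wrapper around :class:`_StatPlan` for a single locus."""
    sample_pops = np.empty(states.shape[0], dtype=object)
    for p, rows in enumerate(pop_slices):
        sample_pops[rows] = str(p)
    plan = _StatPlan(list(sample_pops), [str(p) for p in range(len(pop_slices))])
    return plan.locus_stats(states)


def simulate_summary_stats(scenario: ScenarioSpec, pops: Sequence[str],
                           loci: Sequence[tuple[int, float]],
                           rng: np.random.Generator,
                           fast: bool = True) -> np.ndarray:
    """Summary statistics of one dataset simulated under ``scenario``.

    Uses the JIT kernel when available (``fast=True``); otherwise the
    object-based engine.  The two paths draw different random streams but
    target identical distributions.
    """
    from . import _fastsim
    if fast and _fastsim.HAVE_NUMBA:
        scenario.require_valid()
        enc = _fastsim.encode_scenario(scenario, pops)
        return _fastsim.fast_dataset_stats(enc, loci,
                                           int(rng.integers(2**31)))
    return _stats_from_genealogies(scenario, pops, loci, rng)


def _stats_from_genealogies(scenario: ScenarioSpec, pops: Sequence[str],
                            loci: Sequence[tuple[int, float]],
                            rng: np.random.Generator,
                            plan: _StatPlan | None = None) -> np.ndarray:
    sample_pops = [p for p, k in scenario.samples.items() for _ in range(k)]
    if plan is None:
        plan = _StatPlan(sample_pops, pops)
    scenario.require_valid()
    acc = None
    for length, mu in loci:
        gen = simulate_genealogy(scenario, rng, validate=False)
        _, states = drop_mutations(gen, length, mu, rng)
        s = plan.locus_stats(states)
        acc = s if acc is None else acc + s
    return acc / len(loci)


def summary_statistics(d: MultilocusDataset, pops: Mapping[str, str],
                       marker: str = "nuclear") -> np.ndarray:
    """Summary-statistic vector of a dataset.

    ``pops`` maps individual id to population label; every population
    needs at least 2 sampled haplotypes.  Values are averaged over loci
    and match the simulated-table statistics entry for entry.
    """
    loci = d.loci(marker)  # type: ignore[arg-type]
    pop_names = sorted(set(pops.values()))
    acc = None
    for aln in loci:
        keys = aln.sample_keys
        key_pops = [pops.get(individual_of_key(k)) for k in keys]
        pop_slices = [np.flatnonzero([kp == p for kp in key_pops])
                      for p in pop_names]
        for p, rows in zip(pop_names, pop_slices):
            if len(rows) < 2:
                raise ValueError(f"population {p!r} has < 2 haplotypes")
        # restrict to variant columns for speed; stats are unchanged
        codes = np.frombuffer(
            "".join(s for _, s in aln.rows).encode(), dtype="S1"
        ).reshape(len(keys), aln.length)
        variant = np.array([len(np.unique(codes[:, j])) > 1
                            for j in range(aln.length)])
        states = codes[:, variant].view(np.uint8)
        s = _locus_stats(states, pop_slices)
        acc = s if acc is None else acc + s
    if acc is None:
        raise ValueError("dataset has no loci of the requested marker")
    return acc / len(loci)


# ---------------------------------------------------------------------------
# reference table, rejection, posterior

@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, statistics) records."""

    scenario_names: list[str]
    scenario_idx: np.ndarray       # (R,)
    stats: np.ndarray              # (R, S)
    params: list[dict[str, float]]
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=self.labels)
        df.insert(0, "scenario", [self.scenario_names[i]
                                  for i in self.scenario_idx])
        return df


def simulate_reference_table(templates: Sequence[ScenarioTemplate],
                             n_sims: int, seed: int,
                             loci: Sequence[tuple[int, float]] = DEFAULT_LOCI,
                             fast: bool = True) -> ReferenceTable:
    """Simulate ``n_sims`` prior draws per scenario (equal allocation)."""
    from . import _fastsim
    if n_sims <= 0:
        raise ValueError("n_sims must be positive")
    pops = templates[0].populations
    if any(t.populations != pops for t in templates):
        raise ValueError("templates disagree on sampled populations")
    use_fast = fast and _fastsim.HAVE_NUMBA
    rng = np.random.default_rng(seed)
    rows = []
    idx = []
    params_list = []
    plan: _StatPlan | None = None
    for si, tpl in enumerate(templates):
        tpl.instantiate().require_valid()
        for _ in range(n_sims):
            params = sample_priors(tpl.prior, rng)
            scenario = tpl.build(params)
            if use_fast:
                enc = _fastsim.encode_scenario(scenario, pops)
                rows.append(_fastsim.fast_dataset_stats(
                    enc, loci, int(rng.integers(2**31))))
            else:
                if plan is None:
                    sample_pops = [p for p, k in scenario.samples.items()
                                   for _ in range(k)]
                    plan = _StatPlan(sample_pops, pops)
                rows.append(_stats_from_genealogies(scenario, pops, loci,
                                                    rng, plan))
            idx.append(si)
            params_list.append(params)
    return ReferenceTable([t.name for t in templates],
                          np.asarray(idx), np.vstack(rows), params_list,
                          stat_labels(pops))


def abc_rejection(observed: np.ndarray, stats: np.ndarray,
                  tolerance: float) -> np.ndarray:
    """Indices of the retained simulations (closest fraction).

    Distances are Euclidean after dividing every statistic by its
    standard deviation over the simulated table; zero-variance statistics
    are dropped with a warning.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    if len(stats) == 0:
        raise ValueError("empty reference table")
    sd = stats.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance statistics from the "
                       "rejection distance", int((~keep).sum()))
    z = (stats[:, keep] - observed[keep]) / sd[keep]
    dist = np.sqrt((z**2).sum(axis=1))
    n_keep = math.ceil(tolerance * len(stats))
    order = np.argsort(dist, kind="stable")
    return order[:n_keep]


@dataclass
class AbcResult:
    """Per-scenario posterior probabilities with 95% CIs."""

    table: pd.DataFrame            # scenario, pp, ci_low, ci_high, retained
    tolerance: float
    n_retained: int
    method: str                    # "logistic" or "rejection"

    def best_scenario(self) -> str:
        return str(self.table.loc[self.table["pp"].idxmax(), "scenario"])


def _fit_logistic(X: np.ndarray, y: np.ndarray,
                  n_classes: int) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression
    model = LogisticRegression(max_iter=1000, C=100.0)
    model.fit(X, y)
    probs = np.zeros(n_classes)
    p = model.predict_proba(np.zeros((1, X.shape[1])))[0]
    for cls, pi in zip(model.classes_, p):
        probs[int(cls)] = pi
    return probs


def scenario_posterior(table: ReferenceTable, retained: np.ndarray,
                       observed: np.ndarray, n_bootstrap: int = 200,
                       seed: int = 0) -> AbcResult:
    """Logistic-regression posterior probabilities over scenarios.

    Falls back to retained-count proportions if the regression cannot be
    fit (e.g. one scenario retained, or complete separation).
    """
    names = table.scenario_names
    K = len(names)
    y = table.scenario_idx[retained]
    sd = table.stats.std(axis=0)
    keep = sd > 0
    X = (table.stats[retained][:, keep] - observed[keep]) / sd[keep]
    counts = np.bincount(y, minlength=K).astype(float)

    method = "logistic"
    if len(np.unique(y)) < 2:
        pp = counts / counts.sum()
        method = "rejection"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pp = _fit_logistic(X, y, K)
        except Exception:   # separation / convergence failure
            logger.warning("logistic regression failed; falling back to "
                           "retained proportions")
            pp = counts / counts.sum()
            method = "rejection"

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        bi = rng.integers(len(retained), size=len(retained))
        yb = y[bi]
        if len(np.unique(yb)) < 2:
            cb = np.bincount(yb, minlength=K).astype(float)
            boots.append(cb / cb.sum())
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                boots.append(_fit_logistic(X[bi], yb, K))
        except Exception:
            cb = np.bincount(yb, minlength=K).astype(float)
            boots.append(cb / cb.sum())
    if boots:
        arr = np.vstack(boots)
        lo = np.minimum(np.percentile(arr, 2.5, axis=0), pp)
        hi = np.maximum(np.percentile(arr, 97.5, axis=0), pp)
    else:
        lo = hi = pp
    df = pd.DataFrame({
        "scenario": names, "pp": pp, "ci_low": lo, "ci_high": hi,
        "retained": counts.astype(int),
    })
    return AbcResult(df, math.nan, len(retained), method)


def run_abc(observed: np.ndarray, templates: Sequence[ScenarioTemplate],
            n_sims: int, tolerance: float = 0.01, seed: int = 0,
            loci: Sequence[tuple[int, float]] = DEFAULT_LOCI,
            table: ReferenceTable | None = None,
            n_bootstrap: int = 200) -> AbcResult:
    """Full ABC scenario comparison against an observed statistic vector.

    A pre-simulated ``table`` may be supplied to amortize simulation cost
    across repeated observed datasets; otherwise ``n_sims`` draws per
    scenario are simulated here.
    """
    if table is None:
        table = simulate_reference_table(templates, n_sims, seed, loci)
    retained = abc_rejection(observed, table.stats, tolerance)
    result = scenario_posterior(table, retained, observed,
                                n_bootstrap=n_bootstrap, seed=seed + 1)
    result.tolerance = tolerance
    return result


# representative generating parameters for scenario-recovery experiments:
# moderate effective sizes and a split depth of a few 2N generations, with
# recent admixture at a balanced rate
RECOVERY_PARAMS = {
    "trio": {"N1": 5000.0, "N2": 5000.0, "N3": 5000.0, "Na": 5000.0,
             "t0": 20000.0, "t1": 2000.0, "r1": 0.5},
    "quartet": {"N1": 5000.0, "N2": 5000.0, "N3": 5000.0, "N4": 5000.0,
                "N5": 5000.0, "Na": 5000.0, "ta": 10000.0, "tb": 20000.0,
                "tc": 30000.0, "t0": 5000.0, "tx": 15000.0,
                "th1": 3000.0, "th0": 1000.0, "r1": 0.5, "r2": 0.5},
}


def scenario_recovery_experiment(library: str, scenario_name: str,
                                 n_sims: int, n_repeats: int,
                                 tolerance: float = 0.01, seed: int = 0,
                                 params: Mapping[str, float] | None = None,
                                 table: ReferenceTable | None = None,
                                 ) -> tuple[int, ReferenceTable, list[AbcResult]]:
    """Pseudo-observed-data recovery experiment for one scenario.

    Simulates one reference table (``n_sims`` per scenario), then
    ``n_repeats`` pseudo-observed datasets under ``scenario_name`` with
    representative generating parameters, and counts how often the
    generating scenario attains the highest posterior probability.
    """
    templates = scenario_library(library)
    tpl = next(t for t in templates if t.name == scenario_name)
    if params is None:
        params = {k: v for k, v in RECOVERY_PARAMS[library].items()
                  if k in tpl.prior.params}
    if table is None:
        table = simulate_reference_table(templates, n_sims, seed)
    rng = np.random.default_rng(seed + 7)
    wins = 0
    results = []
    for _ in range(n_repeats):
        scen = tpl.build(params)
        obs = simulate_summary_stats(scen, tpl.populations, DEFAULT_LOCI, rng)
        res = run_abc(obs, templates, 0, tolerance=tolerance,
                      seed=seed + 3, table=table, n_bootstrap=0)
        results.append(res)
        wins += res.best_scenario() == scenario_name
    return wins, table, results
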