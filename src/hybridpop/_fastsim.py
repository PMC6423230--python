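"""JIT-compiled fast path for ABC reference-table simulation.

Re-implements the per-locus pipeline of :mod:`hybridpop.coalsim` plus the
summary statistics of :mod:`hybridpop.abc` as a single numba kernel, for
the million-simulation regime of ABC scenario comparison.  The general
object-based engine in :mod:`hybridpop.coalsim` remains the reference
implementation; the two paths are cross-checked statistically in the test
suite (same closed-form expectations, same statistic distributions).

Restricted to <= 64 sampled lineages (descendant leaf sets are stored as
single 64-bit masks).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

from .coalsim import Admixture, ScenarioSpec, Split
from .popgen import harmonic

__all__ = ["HAVE_NUMBA", "encode_scenario", "fast_dataset_stats"]


def _tajima_consts(n: int) -> tuple[float, float, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1**2 + a2)


@njit(cache=True)
def _simulate_dataset_stats(inv2N, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                            lineage_pop, stat_pop, n_pops, n_all,
                            lengths, mus, taj_a1, taj_e1, taj_e2,
                            seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n = lineage_pop.shape[0]
    P = int(n_pops)
    NA = int(n_all)
    E = ev_time.shape[0]
    n_loci = lengths.shape[0]
    n_pairs = P * (P - 1) // 2
    out = np.zeros(5 * P + 2 * n_pairs)

    maxnodes = 2 * n - 1
    parent = np.empty(maxnodes, np.int32)
    ntime = np.empty(maxnodes, np.float64)
    act_id = np.empty(n, np.int32)
    act_pop = np.empty(n, np.int32)
    cnt = np.empty(64, np.int64)
    bl = np.empty(maxnodes, np.float64)
    below = np.empty(maxnodes, np.uint64)

    # per-population row indices for the statistics
    pop_rows_start = np.zeros(P + 1, np.int64)
    for i in range(n):
        pop_rows_start[stat_pop[i] + 1] += 1
    for p in range(P):
        pop_rows_start[p + 1] += pop_rows_start[p]
    pop_rows = np.empty(n, np.int64)
    fill = pop_rows_start[:P].copy()
    for i in range(n):
        p = stat_pop[i]
        pop_rows[fill[p]] = i
        fill[p] += 1

    for locus in range(n_loci):
        L = lengths[locus]
        mu = mus[locus]
        # ---- genealogy ----
        for i in range(maxnodes):
            parent[i] = -1
            ntime[i] = 0.0
        for i in range(n):
            act_id[i] = i
            act_pop[i] = lineage_pop[i]
        n_act = n
        next_node = n
        t = 0.0
        ev = 0
        while n_act > 1 or ev < E:
            if ev < E:
                next_t = ev_time[ev]
            else:
                next_t = np.inf
            while True:
                for p in range(NA):
                    cnt[p] = 0
                for x in range(n_act):
                    cnt[act_pop[x]] += 1
                R = 0.0
                for p in range(NA):
                    if cnt[p] >= 2:
                        R += cnt[p] * (cnt[p] - 1) * 0.5 * inv2N[p]
                if R == 0.0:
                    t = next_t
                    break
                dt = np.random.exponential(1.0 / R)
                if t + dt >= next_t:
                    t = next_t
                    break
                t = t + dt
                u = np.random.random() * R
                acc = 0.0
                chosen = 0
                for p in range(NA):
                    if cnt[p] >= 2:
                        acc += cnt[p] * (cnt[p] - 1) * 0.5 * inv2N[p]
                        if u <= acc:
                            chosen = p
                            break
                k = cnt[chosen]
                i1 = np.random.randint(0, k)
                i2 = np.random.randint(0, k - 1)
                if i2 >= i1:
                    i2 += 1
                if i1 > i2:
                    i1, i2 = i2, i1
                pos1 = -1
                pos2 = -1
                seen = 0
                for x in range(n_act):
                    if act_pop[x] == chosen:
                        if seen == i1:
                            pos1 = x
                        if seen == i2:
                            pos2 = x
                        seen += 1
                a = act_id[pos1]
                b = act_id[pos2]
                parent[a] = next_node
                parent[b] = next_node
                ntime[next_node] = t
                act_id[pos1] = next_node
                act_id[pos2] = act_id[n_act - 1]
                act_pop[pos2] = act_pop[n_act - 1]
                next_node += 1
                n_act -= 1
            if ev < E and t == ev_time[ev]:
                if ev_type[ev] == 0:
                    for x in range(n_act):
                        if act_pop[x] == ev_a[ev]:
                            act_pop[x] = ev_b[ev]
                else:
                    for x in range(n_act):
                        if act_pop[x] == ev_a[ev]:
                            if np.random.random() < ev_r[ev]:
                                act_pop[x] = ev_b[ev]
                            else:
                                act_pop[x] = ev_c[ev]
                ev += 1
        nn = next_node
        # ---- mutations ----
        total = 0.0
        for i in range(nn):
            p = parent[i]
            if p >= 0:
                bl[i] = ntime[p] - ntime[i]
            else:
                bl[i] = 0.0
            total += bl[i]
        m = np.random.poisson(mu * L * total)
        if m > 0:
            for i in range(n):
                below[i] = np.uint64(1) << np.uint64(i)
            for i in range(n, nn):
                below[i] = np.uint64(0)
            for i in range(nn):
                p = parent[i]
                if p >= 0:
                    below[p] |= below[i]
            cum = np.empty(nn, np.float64)
            acc = 0.0
            for i in range(nn):
                acc += bl[i]
                cum[i] = acc
            mb = np.empty(m, np.int64)
            msite = np.empty(m, np.int64)
            mage = np.empty(m, np.float64)
            for j in range(m):
                u = np.random.random() * total
                lo = 0
                hi = nn - 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if cum[mid] < u:
                        lo = mid + 1
                    else:
                        hi = mid
                mb[j] = lo
                msite[j] = np.random.randint(0, L)
                mage[j] = ntime[mb[j]] + np.random.random() * bl[mb[j]]
            order = np.argsort(msite)
            # states matrix over distinct mutated sites
            states = np.empty((n, m), np.int8)
            n_sites = 0
            j = 0
            while j < m:
                j2 = j
                while j2 < m and msite[order[j2]] == msite[order[j]]:
                    j2 += 1
                root = np.int8(np.random.randint(0, 4))
                for i in range(n):
                    states[i, n_sites] = root
                # apply hits oldest first (selection sort over tiny group)
                group = order[j:j2]
                for gi in range(group.shape[0]):
                    best = gi
                    for gj in range(gi + 1, group.shape[0]):
                        if mage[group[gj]] > mage[group[best]]:
                            best = gj
                    if best != gi:
                        tmp = group[gi]
                        group[gi] = group[best]
                        group[best] = tmp
                    h = group[gi]
                    mask = below[mb[h]]
                    cur = np.int8(0)
                    for i in range(n):
                        if mask >> np.uint64(i) & np.uint64(1):
                            cur = states[i, n_sites]
                            break
                    new = np.int8((cur + 1 + np.random.randint(0, 3)) % 4)
                    for i in range(n):
                        if mask >> np.uint64(i) & np.uint64(1):
                            states[i, n_sites] = new
                n_sites += 1
                j = j2
        else:
            states = np.empty((n, 0), np.int8)
            n_sites = 0
        # ---- statistics ----
        diff = np.zeros((n, n), np.float64)
        for i in range(n):
            for jj in range(i + 1, n):
                d = 0
                for s in range(n_sites):
                    if states[i, s] != states[jj, s]:
                        d += 1
                diff[i, jj] = d
                diff[jj, i] = d
        ks = np.empty(P, np.float64)
        for p in range(P):
            lo = pop_rows_start[p]
            hi = pop_rows_start[p + 1]
            np_ = hi - lo
            S = 0
            for s in range(n_sites):
                ref = states[pop_rows[lo], s]
                for x in range(lo + 1, hi):
                    if states[pop_rows[x], s] != ref:
                        S += 1
                        break
            Nh = 0
            for x in range(lo, hi):
                dup = False
                for y in range(lo, x):
                    if diff[pop_rows[x], pop_rows[y]] == 0.0:
                        dup = True
                        break
                if not dup:
                    Nh += 1
            ssum = 0.0
            ssq = 0.0
            cnt_pairs = 0
            for x in range(lo, hi):
                for y in range(x + 1, hi):
                    d = diff[pop_rows[x], pop_rows[y]]
                    ssum += d
                    ssq += d * d
                    cnt_pairs += 1
            if cnt_pairs > 0:
                kmean = ssum / cnt_pairs
                kvar = ssq / cnt_pairs - kmean * kmean
            else:
                kmean = 0.0
                kvar = 0.0
            if S > 0:
                D = ((kmean - S / taj_a1[p])
                     / math.sqrt(taj_e1[p] * S + taj_e2[p] * S * (S - 1)))
            else:
                D = 0.0
            base = 5 * p
            out[base] += Nh
            out[base + 1] += S
            out[base + 2] += kmean
            out[base + 3] += kvar
            out[base + 4] += D
            ks[p] = kmean
        pair_i = 0
        for p in range(P):
            for q in range(p + 1, P):
                ssum = 0.0
                cnt_pairs = 0
                for x in range(pop_rows_start[p], pop_rows_start[p + 1]):
                    for y in range(pop_rows_start[q], pop_rows_start[q + 1]):
                        ssum += diff[pop_rows[x], pop_rows[y]]
                        cnt_pairs += 1
                kb = ssum / cnt_pairs
                if kb > 0:
                    fst = 1.0 - 0.5 * (ks[p] + ks[q]) / kb
                else:
                    fst = 0.0
                base = 5 * P + 2 * pair_i
                out[base] += kb
                out[base + 1] += fst
                pair_i += 1
    return out / n_loci


def encode_scenario(scenario: ScenarioSpec, pops: Sequence[str]):
    """Encode a scenario into the flat arrays the kernel consumes.

    ``pops`` fixes the statistic ordering; extra (ancestral, unsampled)
    populations get indices after the sampled ones.
    """
    names = list(pops)
    for p in scenario.pop_sizes:
        if p not in names:
            names.append(p)
    if len(names) > 56:
        raise ValueError("too many populations for the fast path")
    idx = {p: i for i, p in enumerate(names)}
    inv2N = np.zeros(64)
    for p, s in scenario.pop_sizes.items():
        inv2N[idx[p]] = 0.5 / s
    events = scenario.sorted_events()
    E = len(events)
    ev_time = np.empty(E)
    ev_type = np.empty(E, np.int64)
    ev_a = np.empty(E, np.int64)
    ev_b = np.empty(E, np.int64)
    ev_c = np.empty(E, np.int64)
    ev_r = np.empty(E)
    for i, ev in enumerate(events):
        ev_time[i] = ev.time
        if isinstance(ev, Split):
            ev_type[i] = 0
            ev_a[i] = idx[ev.derived]
            ev_b[i] = idx[ev.ancestor]
            ev_c[i] = -1
            ev_r[i] = 0.0
        else:
            ev_type[i] = 1
            ev_a[i] = idx[ev.hybrid]
            ev_b[i] = idx[ev.parent1]
            ev_c[i] = idx[ev.parent2]
            ev_r[i] = ev.rate
    lineage_pop = np.array(
        [idx[p] for p, k in scenario.samples.items() for _ in range(k)],
        dtype=np.int64)
    if len(lineage_pop) > 64:
        raise ValueError("fast path supports at most 64 sampled lineages")
    stat_pop = np.array(
        [list(pops).index(p) for p, k in scenario.samples.items()
         for _ in range(k)], dtype=np.int64)
    n_per = [int((stat_pop == i).sum()) for i in range(len(pops))]
    taj = [_tajima_consts(max(npp, 2)) for npp in n_per]
    taj_a1 = np.array([c[0] for c in taj])
    taj_e1 = np.array([c[1] for c in taj])
    taj_e2 = np.array([c[2] for c in taj])
    return (inv2N, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
            lineage_pop, stat_pop, len(pops), len(names),
            taj_a1, taj_e1, taj_e2)


def fast_dataset_stats(encoded, loci: Sequence[tuple[int, float]],
                       seed: int) -> np.ndarray:
    """Summary-statistic vector of one simulated dataset (fast path)."""
    (inv2N, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
     lineage_pop, stat_pop, n_pops, n_all, taj_a1, taj_e1, taj_e2) = encoded
    lengths = np.array([l for l, _ in loci], dtype=np.int64)
    mus = np.array([m for _, m in loci], dtype=np.float64)
    return _simulate_dataset_stats(
        inv2N, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
        lineage_pop, stat_pop, n_pops, n_all, lengths, mus,
        taj_a1, taj_e1, taj_e2, int(seed) % (2**31))
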