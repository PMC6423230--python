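"""Per-locus diversity statistics and neutrality tests.

Implements the classic frequency-spectrum statistics on aligned haplotype
samples — segregating sites S, haplotype number Nh, nucleotide diversity
pi, Watterson's theta_W, Tajima's D and Fu & Li's D*/F* (the within-species
variants that need no outgroup) — plus a maximum-likelihood HKA test
(polymorphism/divergence ratios across loci, with free selection
multipliers k at candidate loci).

Columns containing gaps or Ns in any sequence are excluded from all
statistics (complete deletion).  Statistics that are undefined at S = 0
carry an explicit ``undefined`` flag rather than a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .seqio import Alignment, collapse_haplotypes

__all__ = [
    "DiversityStats",
    "site_counts",
    "diversity_stats",
    "tajimas_d",
    "fu_li_d_star",
    "fu_li_f_star",
    "HkaLocus",
    "mlhka_test",
]


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n} 1/i**power (the a1/a2 constants of the tests)."""
    return float(sum(1.0 / i**power for i in range(1, n + 1)))


@dataclass
class DiversityStats:
    """Polymorphism and neutrality summary for one locus x taxon sample."""

    locus_id: str
    taxon: str
    n: int                    # sampled haplotypes
    L: int                    # sites analysed after complete deletion
    S: int                    # segregating sites
    eta: int                  # total mutations (minimum-change per column)
    eta_s: int                # singleton mutations
    Nh: int                   # distinct haplotypes
    k: float                  # mean pairwise difference (count)
    pi: float                 # per-site nucleotide diversity
    theta_w: float            # per-site Watterson estimator
    D: float | None = None        # Tajima's D (None when undefined)
    Dstar: float | None = None    # Fu & Li's D*
    Fstar: float | None = None    # Fu & Li's F*

    @property
    def undefined_tests(self) -> bool:
        return self.S == 0


def _encoded(aln: Alignment) -> np.ndarray:
    """Alignment as uint8 codes restricted to fully-resolved columns."""
    arr = aln.to_array()
    keep = ~((arr == "-") | (arr == "N")).any(axis=0)
    return arr[:, keep]


def site_counts(arr: np.ndarray) -> tuple[int, int, int]:
    """(S, eta, eta_s) from a (n, L) character matrix.

    eta counts the minimum number of mutations per column (alleles - 1);
    eta_s counts variants carried by exactly one sequence.
    """
    S = eta = eta_s = 0
    for j in range(arr.shape[1]):
        _, counts = np.unique(arr[:, j], return_counts=True)
        a = len(counts)
        if a > 1:
            S += 1
            eta += a - 1
            eta_s += int((counts == 1).sum())
    return S, eta, eta_s


def mean_pairwise_difference(arr: np.ndarray) -> float:
    """Mean number of differing sites over all sequence pairs."""
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    # site-wise: pairwise differences at a column = C(n,2) - sum_a C(c_a,2)
    total = 0.0
    npairs = n * (n - 1) / 2
    for j in range(arr.shape[1]):
        _, counts = np.unique(arr[:, j], return_counts=True)
        total += npairs - sum(c * (c - 1) / 2 for c in counts)
    return total / npairs


def diversity_stats(aln: Alignment, taxon: str = "",
                    with_tests: bool = True) -> DiversityStats:
    """Compute all per-locus statistics for one taxon sample.

    The alignment should already be restricted to the taxon's haplotypes;
    complete deletion of gap/N columns is applied here.
    """
    if aln.n_rows < 2:
        raise ValueError("diversity statistics need n >= 2 sequences")
    arr = _encoded(aln)
    n, L = arr.shape
    if L == 0:
        raise ValueError(f"locus {aln.locus_id!r}: no fully resolved columns")
    S, eta, eta_s = site_counts(arr)
    k = mean_pairwise_difference(arr) if S else 0.0
    a1 = harmonic(n - 1)
    st = DiversityStats(
        locus_id=aln.locus_id, taxon=taxon, n=n, L=L, S=S, eta=eta,
        eta_s=eta_s, Nh=collapse_haplotypes(aln).n_haplotypes,
        k=k, pi=k / L, theta_w=S / (a1 * L),
    )
    if with_tests and S > 0 and n >= 4:
        # the variance constants degenerate below n = 4
        st.D = tajimas_d(S, k, n)
        st.Dstar = fu_li_d_star(eta, eta_s, n)
        st.Fstar = fu_li_f_star(eta, eta_s, k, n)
    return st


def tajimas_d(S: int, k: float, n: int) -> float:
    """Tajima's D from segregating sites, mean pairwise difference and n."""
    if S < 1:
        raise ValueError("Tajima's D is undefined at S = 0")
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (k - S / a1) / math.sqrt(var)


def _fu_li_dn(n: int) -> float:
    a = harmonic(n - 1)
    an1 = a + 1.0 / n
    cn = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    return (cn + (n - 2) / (n - 1) ** 2
            + 2 / (n - 1) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n))


def fu_li_d_star(eta: int, eta_s: int, n: int) -> float:
    """Fu & Li's D* (within-species; total vs singleton mutations)."""
    if eta < 1:
        raise ValueError("D* is undefined with no mutations")
    if n < 4:
        raise ValueError("D* needs n >= 4")
    a = harmonic(n - 1)
    b = harmonic(n - 1, 2)
    dn = _fu_li_dn(n)
    vD = ((n / (n - 1)) ** 2 * b + a**2 * dn
          - 2 * (n * a * (a + 1)) / (n - 1) ** 2) / (a**2 + b)
    uD = (n / (n - 1)) * (a - n / (n - 1)) - vD
    return ((n / (n - 1)) * eta - a * eta_s) / math.sqrt(uD * eta + vD * eta**2)


def fu_li_f_star(eta: int, eta_s: int, k: float, n: int) -> float:
    """Fu & Li's F* (mean pairwise difference vs singleton mutations),
    using the corrected variance constants."""
    if eta < 1:
        raise ValueError("F* is undefined with no mutations")
    if n < 4:
        raise ValueError("F* needs n >= 4")
    a = harmonic(n - 1)
    b = harmonic(n - 1, 2)
    an1 = a + 1.0 / n
    vF = ((2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
          + 2 * (n - 1) * a / n**2 - 8 * b / n) / (a**2 + b)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1)
          / (3 * n * (n - 1))) / a - vF
    return (k - ((n - 1) / n) * eta_s) / math.sqrt(uF * eta + vF * eta**2)


# ---------------------------------------------------------------------------
# ML-HKA: joint Poisson model for polymorphism and divergence across loci

@dataclass
class HkaLocus:
    """Observed polymorphism/divergence data for one locus.

    S: segregating sites in the ingroup sample of n haplotypes;
    div: nucleotide differences between ingroup and outgroup;
    L: analysed length in bp.
    """

    locus_id: str
    L: int
    n: int
    S: int
    div: int


@dataclass
class MlhkaResult:
    lnL_neutral: float
    lnL_selection: float
    LRT: float
    df: int
    p: float
    T_neutral: float
    T_selection: float
    k: dict[str, float]          # fitted selection multipliers (candidates)
    converged: bool = True


def _profile_loglik(T: float, loci: Sequence[HkaLocus],
                    free: Sequence[bool]) -> tuple[float, list[float], list[float]]:
    """Profile log-likelihood over theta_i (and k_i where free) at fixed T.

    Model: S_i ~ Poisson(k_i * theta_i * L_i * a_{n_i}),
           div_i ~ Poisson(theta_i * L_i * (T + 1)),
    with theta_i per-site.  At fixed T the per-locus MLEs are closed form:
    constrained loci (k=1): theta = (S + div) / (L (a + T + 1));
    free loci: theta = div / (L (T + 1)), k = S / (theta L a)
    (degenerate observed counts are handled by the Poisson convention
    0*log(0) = 0).
    """
    lnL = 0.0
    thetas: list[float] = []
    ks: list[float] = []

    def pois_ll(x: int, lam: float) -> float:
        if lam <= 0:
            return 0.0 if x == 0 else -math.inf
        return x * math.log(lam) - lam - math.lgamma(x + 1)

    for loc, is_free in zip(loci, free):
        a = harmonic(loc.n - 1)
        if is_free:
            theta = loc.div / (loc.L * (T + 1)) if loc.div > 0 else 1e-12
            kk = loc.S / (theta * loc.L * a) if loc.S > 0 else 1e-12
        else:
            theta = (loc.S + loc.div) / (loc.L * (a + T + 1))
            theta = max(theta, 1e-12)
            kk = 1.0
        lnL += pois_ll(loc.S, kk * theta * loc.L * a)
        lnL += pois_ll(loc.div, theta * loc.L * (T + 1))
        thetas.append(theta)
        ks.append(kk)
    return lnL, thetas, ks


def _maximize(loci: Sequence[HkaLocus], free: Sequence[bool]) -> tuple[float, float, list[float]]:
    """Maximize the profile likelihood over T on a log grid + refinement."""
    def neg(logT: float) -> float:
        return -_profile_loglik(math.exp(logT), loci, free)[0]

    grid = np.linspace(math.log(1e-3), math.log(1e3), 40)
    vals = [neg(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(neg, bounds=(g0 - 1.0, g0 + 1.0),
                                   method="bounded")
    T = float(math.exp(res.x))
    lnL, _, ks = _profile_loglik(T, loci, free)
    return lnL, T, ks


def mlhka_test(loci: Sequence[HkaLocus],
               candidate_loci: Iterable[str] = ()) -> MlhkaResult:
    """Likelihood-ratio HKA test of the candidate loci against neutrality.

    The neutral model fixes every selection multiplier k_i = 1; the
    selection model frees k_i on the candidate set.  Both models share the
    species divergence time T (in 2N generations) and per-locus theta_i.
    The LRT statistic 2*(lnL_sel - lnL_neu) is referred to chi-square with
    df = |candidates|.
    """
    loci = list(loci)
    if len(loci) < 2:
        raise ValueError("MLHKA needs at least 2 loci")
    ids = [l.locus_id for l in loci]
    cand = set(candidate_loci)
    unknown = cand - set(ids)
    if unknown:
        raise ValueError(f"unknown candidate loci: {sorted(unknown)}")

    lnL0, T0, _ = _maximize(loci, [False] * len(loci))
    if not cand:
        return MlhkaResult(lnL0, lnL0, 0.0, 0, 1.0, T0, T0, {})
    free = [l.locus_id in cand for l in loci]
    lnL1, T1, ks = _maximize(loci, free)
    lrt = max(0.0, 2 * (lnL1 - lnL0))
    df = len(cand)
    p = float(stats.chi2.sf(lrt, df))
    kmap = {l.locus_id: k for l, k, f in zip(loci, ks, free) if f}
    return MlhkaResult(lnL0, lnL1, lrt, df, p, T0, T1, kmap)


def diversity_report(stats_list: Iterable[DiversityStats]) -> pd.DataFrame:
    """One row per locus x taxon, mirroring standard diversity tables."""
    rows = []
    for st in stats_list:
        rows.append({
            "locus": st.locus_id, "taxon": st.taxon, "n": st.n, "L": st.L,
            "S": st.S, "Nh": st.Nh, "pi": st.pi, "theta_w": st.theta_w,
            "k": st.k,
            "TajimaD": st.D if st.D is not None else float("nan"),
            "FuLiDstar": st.Dstar if st.Dstar is not None else float("nan"),
            "FuLiFstar": st.Fstar if st.Fstar is not None else float("nan"),
            "tests_defined": not st.undefined_tests,
        })
    return pd.DataFrame(rows)
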