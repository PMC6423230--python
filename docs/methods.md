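# Methods

This note documents the models behind each `hybridpop` module, the
parameters that matter, the numerical choices, and what the synthetic
fixture does and does not establish about real data.

## Data model and conventions

A study is a `MultilocusDataset`: per-locus FASTA alignments plus a
sample table. Nuclear loci carry two phased haplotype rows per diploid
individual (`<ind>/1`, `<ind>/2`); chloroplast loci carry one row per
individual. Coordinates are 0-based half-open internally and 1-based in
reports. For all polymorphism statistics, columns containing a gap or N
in any row are removed first (complete deletion). This mirrors the
default of the standard diversity software; a site-pairwise-deletion
variant would retain slightly more information but complicates the
closed-form estimators, and at the diversity levels involved (π of
order 10⁻³–10⁻²) the difference is negligible.

Indel coding follows the simple-indel-coding rule: every distinct
maximal gap interval becomes a presence/absence character; a sequence
whose own gap strictly contains a character's interval is scored missing
for it, because the shorter indel's state is unobservable there.

## Diversity and neutrality statistics

For n sampled haplotypes over L analysed sites with S segregating sites
and mean pairwise difference k:

* π = k/L, θ_W = S/(a₁L) with a₁ = Σ_{i<n} 1/i;
* Tajima's D = (k − S/a₁) / √(e₁S + e₂S(S−1)) with the 1989 constants;
* Fu & Li's D\* contrasts total mutations η (minimum-change count per
  column, Σ(alleles−1)) against singletons η_s; F\* contrasts k against
  η_s. Both use the corrected ("Simonsen") variance constants, the
  convention of the common implementations. Since no closed reference
  values exist in the source material, these are validated two ways:
  an independent constant-by-constant oracle in the unit tests, and a
  Monte-Carlo null calibration — over 2000 neutral coalescent replicates
  (n=20, θ=5) the means of D, D\*, F\* are within 0.1/0.15 of zero.
* Statistics undefined at S = 0 (and the test statistics below n = 4,
  where the variance constants degenerate) are explicit `None`s, never
  silent zeros.

### ML-HKA

The HKA model treats, per locus i, the polymorphism count
S_i ~ Poisson(k_i·θ_i·L_i·a_{n_i}) and the outgroup divergence count
Div_i ~ Poisson(θ_i·L_i·(T+1)), sharing the divergence time T (in 2N
units) across loci. The neutral model fixes every selection multiplier
k_i = 1; the selection model frees k_i on a declared candidate set. The
LRT 2(lnL₁ − lnL₀) is referred to χ² with df = |candidates|.

Maximization is by profile likelihood: at fixed T the per-locus MLEs are
closed form (constrained loci: θ̂ = (S+Div)/(L(a+T+1)); free loci:
θ̂ = Div/(L(T+1)), k̂ = S/(θ̂La)), leaving a smooth 1-D problem in log T
solved by a coarse grid plus bounded refinement. This replaces generic
multi-start quasi-Newton in many dimensions: the profile is exact, has
no convergence failures, and is deterministic. Calibration: simulated
type-I error 5.5% at nominal 5% (200 replicates); power ≥ 80% against a
five-fold polymorphism excess at desk scale. Divergence counts are raw
differences to a single outgroup without multiple-hit correction — the
intended use is closely related taxa; a correction hook would be the
first extension for deeper outgroups.

## Admixture clustering

Genotypes are haplotype alleles: each locus's allele catalogue is its
set of distinct sequences, so identical information is carried whether a
population contributed two samples or twenty of the same haplotype —
the reason haplotype-level input is used for clustering in the first
place. The Gibbs sampler alternates: allele-copy cluster origins z;
cluster-by-locus allele frequencies P ~ Dirichlet(λ + counts) with
λ = 1; memberships Q_i ~ Dirichlet(α + counts) with a single symmetric
concentration α under a uniform(0, 10) hyperprior updated by random-walk
Metropolis (step 0.25). The model evidence is estimated as
LnP(K) = mean(lnL) − var(lnL)/2 over post-burn-in sweeps. Defaults for
real use would be the long-run plan (10 replicates per K, 10⁵ burn-in,
2×10⁵ sweeps); the tests run hundreds of sweeps, which suffices at
fixture scale because the fixture's clusters are strongly diverged.

The correlated-allele-frequency (F-model) variant is not implemented;
the independent-frequency model is fully adequate for strongly diverged
clusters, and nothing in the test surface depends on the correlated
prior. Hierarchical reruns on taxon subsets reproduce the usual
subset-analysis logic.

**ΔK and its known bias.** The Evanno statistic
ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) is computed from replicate
means and standard deviations, defined only for interior K with
positive sd. For a *hierarchically* diverged trio the second difference
of the likelihood gain can be shown (by an additive caricature of
cluster-merge costs) never to favor K = 3 over K = 2 — ΔK detects the
deepest level of structure, a documented limitation of the method. The
cluster-number recovery test therefore uses the regime ΔK was designed
for: three equally diverged populations at moderate depth
(t = 1.2 × 2N), where the arbitrary choice of which pair merges at
K = 2 destabilizes replicate likelihoods and ΔK correctly peaks at 3 in
~90% of replicate sets.

**Posterior sharpening.** With high haplotype diversity many alleles are
near-singletons, and the evidence for a rare allele's cluster of origin
is weak; the membership prior then pulls copies toward an individual's
majority cluster, so posterior mean Q is systematically more extreme
than realized ancestry (a fixture F2 with 16/20 gene copies from one
side — realized 0.8 — receives Q ≈ 0.97). This is faithful Bayesian
behavior, not a sampler defect, but it means fixed Q cutoffs misjudge
borderline later-generation hybrids; see the discordance screen below.

## Six-class genotype assignment

Each genotype class implies Mendelian probabilities (p11, p12, p22) that
a locus carries two copies from parent species 1, one from each, or two
from species 2: Pure1 (1,0,0), Pure2 (0,0,1), F1 (0,1,0), F2
(¼,½,¼), BC1 (½,½,0), BC2 (0,½,½). The genotype likelihood mixes
Hardy–Weinberg terms over the unknown parental allele frequencies, which
are Gibbs-sampled jointly with class assignments, per-copy origins and
the class mixing proportions (Dirichlet(1)). The allele-frequency prior
is Dirichlet(1/A) per locus ("Jeffreys-like", A = catalogue size) or
Dirichlet(1) (uniform); both are run and cross-checked. Reference
individuals of known origin can be pinned to their class (z) while still
informing the frequency estimates, or excluded from frequency estimation
(s). Two replicate runs are averaged; a maximum per-class posterior
difference above 0.1 raises a convergence warning. The class set is
fixed at the six first/second-generation categories; later backcross
generations are outside the model, and only two parental species are
supported — three-way hybrids are the ABC module's job.

## Coalescent engine

Demography is a set of constant-size populations with backward-in-time
events: `Split(t, derived, ancestor)` moves all derived lineages into
the ancestor; `Admixture(t, hybrid, p1, p2, r)` sends each hybrid
lineage to p1 with probability r, else p2 (a pulse, not a migration
band). Within a population k lineages coalesce at rate k(k−1)/2 per 2N
generations; waiting times are exact exponentials interrupted by events.
Scenario validation replays the event list and rejects structures whose
sampled populations cannot reach a single root. Mutations are
finite-sites Jukes–Cantor: Poisson(μ·L·total branch length) hits placed
uniformly on branches and sites, each replacing the current base with
one of the other three (so reversions and multiple hits are possible).
Loci are unlinked with no intralocus recombination — appropriate for
short amplicons pre-screened for recombination. Diploid individuals are
formed by pairing consecutive sampled lineages.

Verification: E[TMRCA] = 2N and E[π] = 4Nμ within 5% at 5000
replicates; E[S] = a_{n−1}·θ·L; an admixture pulse with r = 1 is
distributionally identical to a pure split (KS test); and the
between-population divergence of a two-population split scenario matches
msprime as an independent oracle.

A numba-compiled fast path (`_fastsim`) re-implements the per-locus
pipeline (genealogy, mutations, summary statistics) for the
reference-table regime of ABC, at ~0.2 ms per 10-locus dataset versus
~7 ms for the object engine; it is restricted to ≤ 64 sampled lineages
(leaf sets as 64-bit masks). The object engine remains the reference
implementation; the two paths are compared statistic-by-statistic in the
test suite (all |z| < 5 over hundreds of replicates) and fall back
transparently if numba is unavailable.

## ABC scenario choice

Summary statistics per population: haplotype count, segregating sites,
mean and variance of pairwise differences, Tajima's D (0 when
undefined); per population pair: mean between-population difference and
Hudson's F_ST = 1 − H_w/H_b; all averaged over loci. The exact published
statistic list being unavailable, this is the standard sequence-data set
of the reference ABC tool.

Priors default to log-uniform N ∈ [10², 10⁵], uniform t ∈ [10, 10⁵]
generations with the scenario's ordering constraints enforced by
rejection resampling, and uniform admixture rates r ∈ [0.05, 0.95] —
weakly informative over plausible forest-tree scales, and user-
overridable. The simulated loci default to ten 600-bp fragments at
μ = 2.5×10⁻⁷/site/generation, chosen so that per-site diversity at
mid-prior population sizes falls in the empirically typical 0.003–0.008
range; an order of magnitude lower and the simulated datasets carry
almost no information, an order higher and finite-sites saturation sets
in.

Rejection retains the ⌈tolerance·rows⌉ simulations closest to the
observed vector in Euclidean distance after dividing each statistic by
its table-wide standard deviation (zero-variance statistics dropped with
a warning). Posteriors come from multinomial logistic regression of
scenario identity on (stats − observed), evaluated at the origin;
complete separation or a single retained class falls back to retained
proportions. 95% CIs are percentile bootstrap over the retained set
(200 resamples by default). The regression uses a mild ridge
(C = 100) purely to keep separation finite; at these retained-set sizes
it does not visibly shrink the probabilities.

**Scenario libraries.** The trio library (three sampled populations, one
ancestor): (1) simultaneous three-way split at t0; (2–4) split at t0
followed by one lineage splitting at t1 < t0, one scenario per
topology; (5–7) two species split at t0 and a pulse at t1 founds the
third as their hybrid, one scenario per choice of hybrid (scenario 5:
pop3 is the hybrid). The quartet library (backbone ((pop1, pop2), pop3)
with a focal pop4): direct descent from the root, from pop3, or from the
pop1/pop2 ancestor; single hybridization between pop3 and that ancestor;
and three two-step trihybrid scenarios through an intermediate pop5
(scenario 6: pop5 = pop1 × pop3, then pop4 = pop5 × pop2). The two-step
scenarios cover the three distinct cross orders, since only three exist
for three parents.

**Recovery experiments.** Confidence in scenario choice is measured the
standard way: one reference table (10,000 draws per scenario), twenty
pseudo-observed datasets generated under the focal scenario at fixed
representative parameters (N = 5000, split at 20,000 generations,
admixture at 2000, r = 0.5), and the fraction of repeats in which the
generating scenario attains the highest posterior probability. Sharing
the table across repeats is what makes the experiment affordable and is
exactly how the reference tool evaluates scenario confidence. Generating
pseudo-observations from full prior draws instead would mix in
unidentifiable corners (t1 ≈ t0, or t0 so small that no divergence
accumulates) where no method could recover the truth; the fixed-
parameter design measures the method, not the prior. Measured at this
scale: the trio admixture-origin scenario is recovered 20/20 with mean
posterior ≈ 0.97, the quartet two-step trihybrid scenario 16/20 with
mean posterior ≈ 0.56 — three-parent histories are intrinsically harder
because the competing two-step orders share most of their signal.

## Chloroplast typing and cytonuclear discordance

Candidates are typed by minimum Hamming distance (gap/N columns excluded
pairwise) between their concatenated cpDNA haplotype and labelled
reference sets; exact ties across sets yield an ambiguity flag, never an
arbitrary label. This distance rule replaces tree-based clade reading:
for well-separated haplotype groups the nearest reference set and the
containing clade coincide, and no tree program is needed. Count tables
recompute all totals from their own cells and round percentages half-up
to one decimal; inconsistent externally supplied totals are thereby
surfaced rather than propagated.

The discordance screen combines nuclear cluster membership with cp type:
an individual is flagged as *hybrid-pattern* when its maximum membership
falls below the purity threshold, or as *introgression-pattern* when its
modal cluster's expected cp side differs from its cp label. The default
threshold is 0.9, the customary purebred cutoff. Because of the
posterior sharpening discussed above, a fixed cutoff cannot separate
extreme-ancestry F2s from pure individuals; passing `threshold=None`
with a list of known pure reference individuals instead calibrates the
cutoff as the minimum membership observed among those references — the
known-genotype calibration strategy recommended in the hybrid-detection
literature. With reference calibration the screen flags exactly the
constructed hybrids and introgressed individuals on the synthetic
fixture across every seed tried.

## Synthetic fixture

Three parental species are simulated on the species tree
((spA, spC), spB) with splits at 10,000 and 20,000 generations,
N = 1250 and μ = 10⁻⁶ for ten nuclear loci of 400–800 bp (per-site θ =
0.005, within the empirical 0.003–0.008 band) and N = 300, μ = 3×10⁻⁷
for six cpDNA loci of 900–2500 bp (θ ≈ 3.6×10⁻⁴, an order of magnitude
lower, with species-private haplotype pools). Hybrids are then built
mechanically from the simulated haplotypes — F1: one random haplotype
from each parent per locus; F2: gametes of two independent F1s; BC: F1
gamete plus pure gamete; trihybrid: (spB × spC) F1 gamete plus spA
gamete — and each copies all cp loci from one random individual of its
designated maternal species. Mechanical construction (rather than
demographic simulation) is deliberate: it yields exact truth labels for
classifier scoring. The ABC module's pseudo-observed data are instead
simulated demographically, so both generation paths exist.

The default composition mirrors the emulated design at ~10× reduced
scale: 20 individuals per species, 14 F1 + 2 F2 in the first swarm
(maternal spB), 24 F1 in the second (maternal spC), 2 trihybrids
(2/26 = 7.7% of the second hybrid taxon), 4 introgressed individuals
(¾ spC nuclear, spB chloroplast).

What passing tests on this fixture show: the estimators and samplers
recover truth when their model assumptions hold exactly. What they do
not show: robustness to phasing error, recombination within loci,
alignment artifacts, null alleles, sampling imbalance, or selection —
none of which the generator emulates.

## Reproducibility

Every stochastic operation takes an explicit seed; replicate r of a scan
uses a deterministic offset of the base seed; coalescent simulation is
bit-for-bit reproducible given (scenario, loci, seed). The acceptance
script derives all of its seeds from its single `--seed` argument. Test
problem sizes (hundreds of Gibbs sweeps, 10⁴ ABC draws per scenario,
2000–5000 coalescent replicates) were chosen as the smallest scales at
which the targeted tolerances are comfortably resolvable.
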