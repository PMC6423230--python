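"""Direct use of the coalescent engine.

Builds a three-population scenario with an admixture pulse, simulates a
phased multilocus dataset, and checks the single-population closed form
E[pi] = 4*N*mu.
"""

import numpy as np

from hybridpop.coalsim import (Admixture, ScenarioSpec, Split,
                               drop_mutations, simulate,
                               simulate_genealogy)

scenario = ScenarioSpec(
    "hybrid_origin",
    {"p1": 5000.0, "p2": 5000.0, "hyb": 5000.0, "anc": 5000.0},
    [Admixture(2000.0, "hyb", "p1", "p2", 0.5),
     Split(20000.0, "p1", "anc"), Split(20000.0, "p2", "anc")],
    {"p1": 8, "p2": 8, "hyb": 8})
print("scenario valid:", scenario.validate() == [])

ds = simulate(scenario, [(600, 2.5e-7)] * 5, seed=3)
print(f"simulated {len(ds.alignments)} loci for "
      f"{len(ds.samples.individual_ids)} diploid individuals; "
      f"locus 1 has {ds.alignments[0].n_rows} phased haplotype rows")

rng = np.random.default_rng(0)
one = ScenarioSpec("one", {"p": 1000.0}, [], {"p": 2})
pis = []
for _ in range(3000):
    gen = simulate_genealogy(one, rng, validate=False)
    _, states = drop_mutations(gen, 500, 2.5e-6, rng)
    pis.append((states[0] != states[1]).sum() / 500)
print(f"\nmean pairwise diversity: {np.mean(pis):.5f} "
      f"(coalescent expectation 4*N*mu = {4 * 1000 * 2.5e-6:.5f})")
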