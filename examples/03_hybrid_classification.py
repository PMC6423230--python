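"""Six-class hybrid genotype assignment.

Classifies the first hybrid swarm of the synthetic fixture against its
two parent species into Pure1/Pure2/F1/F2/BC1/BC2, with reference
parents pinned via the z option.
"""

from hybridpop import seqio
from hybridpop.admixture import GenotypeMatrix
from hybridpop.hybridclass import newhybrids_mcmc
from hybridpop.synthetic_data import study_fixture

ds, truth = study_fixture(seed=7)
keep = {i for i in ds.samples.individual_ids
        if ds.samples.taxon_of(i) in ("spA", "spB", "hybAB")}
alns = [a.subset([k for k in a.sample_keys
                  if seqio.individual_of_key(k) in keep])
        for a in ds.loci("nuclear")]
samples = seqio.SampleTable(
    ds.samples.table[ds.samples.table.individual_id.isin(keep)])
sub = seqio.MultilocusDataset(alns, samples)

g = GenotypeMatrix.from_dataset(sub)
z = {i: "Pure1" for i in samples.individuals_of("spA")}
z.update({i: "Pure2" for i in samples.individuals_of("spB")})
post = newhybrids_mcmc(g, prior="jeffreys_like", z_fixed=z,
                       sweeps=800, burnin=300, seed=0)

frame = post.frame()
hybrids = [i for i in frame.index if i in truth.table.index
           and not truth.table.loc[i, "category"].startswith("pure")]
print(frame.loc[hybrids].round(3).to_string())
print("\ntruth labels:")
print(truth.table.loc[hybrids, "category"].to_string())
print("\nEach row is a posterior over the six genotype classes; the "
      "constructed\nF1s get essentially all mass on F1, and the two F2s "
      "are F2-modal.")
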