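import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hybridpop import seqio

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")
from hybridpop.synthetic_data import study_fixture

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture():
    """The default labeled study-analogue dataset (shared across tests)."""
    return study_fixture(seed=FIXTURE_SEED)


@pytest.fixture
def toy_alignment():
    """4 sequences of length 8 with S=2, Nh=3, k=7/6."""
    rows = [("s1", "AAAAAAAA"), ("s2", "AAAAAAAT"),
            ("s3", "AAAAAATT"), ("s4", "AAAAAAAA")]
    return seqio.Alignment("toy", rows)


def subset_dataset(ds, taxa):
    """Restrict a dataset to the given taxa (all loci)."""
    keep = [i for i in ds.samples.individual_ids
            if ds.samples.taxon_of(i) in taxa]
    keepset = set(keep)
    alns = [a.subset([k for k in a.sample_keys
                      if seqio.individual_of_key(k) in keepset])
            for a in ds.alignments]
    table = seqio.SampleTable(
        ds.samples.table[ds.samples.table.individual_id.isin(keepset)])
    return seqio.MultilocusDataset(alns, table)
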