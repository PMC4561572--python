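import numpy as np
import pytest

from hybridtrace.genotype_io import GenotypeDataset, Locus


def build_dataset(calls, sites, species, individuals=None, locus_names=None):
    """Small-dataset helper: calls is a list (per individual) of lists (per
    locus) of (a1, a2) tuples, (0, 0) = missing."""
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    if individuals is None:
        individuals = [f"ind{i + 1}" for i in range(n)]
    if locus_names is None:
        locus_names = [f"loc{j + 1}" for j in range(L)]
    return GenotypeDataset(
        individuals=list(individuals),
        loci=[Locus(nm) for nm in locus_names],
        calls=calls,
        site_labels=list(sites),
        species_labels=list(species),
    )


@pytest.fixture
def two_pop_dataset():
    """2 populations x 3 loci x 3 individuals each, with one missing call."""
    rng = np.random.default_rng(11)
    calls = rng.choice([150, 152, 154], size=(6, 3, 2))
    calls[0, 1] = (0, 0)
    sites = ["s1"] * 3 + ["s2"] * 3
    species = ["A"] * 3 + ["B"] * 3
    inds = [f"s1_A_{i}" for i in (1, 2, 3)] + [f"s2_B_{i}" for i in (1, 2, 3)]
    return build_dataset(calls, sites, species, individuals=inds)
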