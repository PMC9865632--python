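import numpy as np
import pandas as pd
import pytest

from haplopop.genotypes import GenotypeMatrix


def make_matrix(calls, positions=None, chrom="chr1", ref="A", alt="G", strains=None):
    """Build a small genotype matrix from a 2-D list of calls (rows = sites)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_strains = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    if strains is None:
        strains = [f"s{j + 1}" for j in range(n_strains)]
    if isinstance(ref, str):
        ref = [ref] * n_sites
    if isinstance(alt, str):
        alt = [alt] * n_sites
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=np.int64), "ref": ref, "alt": alt}
    )
    return GenotypeMatrix(sites=sites, calls=calls, strains=list(strains))


def random_matrix(rng, n_sites=50, n_strains=10, missing_rate=0.1, span=10_000):
    """Random biallelic SNP matrix with missing calls, for oracle checks."""
    calls = rng.integers(0, 2, size=(n_sites, n_strains)).astype(np.int8)
    miss = rng.random((n_sites, n_strains)) < missing_rate
    # keep at least one call per site
    for i in np.flatnonzero(miss.all(axis=1)):
        miss[i, rng.integers(n_strains)] = False
    calls[miss] = -1
    positions = np.sort(rng.choice(np.arange(1, span + 1), size=n_sites, replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, n_sites)
    alt = np.array([str(rng.choice(bases[bases != r])) for r in ref])
    return make_matrix(calls, positions=positions, ref=list(ref), alt=list(alt))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
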