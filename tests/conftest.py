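import numpy as np
import pytest

import fastassoc as fa


@pytest.fixture(scope="session")
def small_sim():
    """A small structured study with a couple of phenotypes, reused across tests."""
    cfg = fa.SimConfig(
        n_subjects=400, n_markers=600, n_phenotypes=2, n_covariates=4,
        n_pops=4, fst=0.05, causal_frac=0.02, seed=11,
    )
    return fa.simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_study(rng, n, m, missing_frac=0.0):
    """A random (unstructured) GenotypeStudy, optionally with missing calls."""
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_frac:
        mask = rng.random((n, m)) < missing_frac
        dosage[mask] = fa.MISSING
    markers = [
        fa.MarkerInfo(chrom="1", id=f"m{j}", cm=0.0, bp=j + 1, a1="A", a2="C")
        for j in range(m)
    ]
    samples = [fa.SampleInfo(fid=f"f{i}", iid=f"i{i}") for i in range(n)]
    return fa.GenotypeStudy(dosage=dosage, markers=markers, samples=samples)
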