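import numpy as np
import pandas as pd
import pytest

import lowpass_eval as le


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study reused by read-only tests.

    300 samples (including 20 five-member family blocks at relatedness 0.5),
    4,000 sites, 1x low-depth arm with the default imputation channel.
    """
    cfg = le.CohortConfig(
        n_samples=300,
        n_sites=4000,
        seed=11,
        family_blocks=[(5, 0.5)] * 20,
    )
    return le.simulate_study(cfg)


@pytest.fixture
def toy_sites():
    """Six hand-written SNVs on two chromosomes."""
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2", "2", "2"],
            "pos": [100, 200, 300, 100, 200, 300],
            "ref": ["A", "C", "G", "T", "A", "C"],
            "alt": ["G", "T", "A", "C", "C", "A"],
        }
    )


def make_gm(dosages, chrom="1", start=100, step=100, samples=None):
    """Small GenotypeMatrix from a samples x sites array of dosages."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    refs = np.array(["A", "C", "G", "T"])[np.arange(p) % 4]
    alts = np.array(["G", "T", "A", "C"])[np.arange(p) % 4]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + step * np.arange(p),
            "ref": refs,
            "alt": alts,
        }
    )
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n)]
    return le.GenotypeMatrix(samples=samples, sites=sites, dosages=dosages)
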