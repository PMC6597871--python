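import numpy as np
import pandas as pd
import pytest

from landgen.genotypes import GenotypeTable


def make_genotype_table(dosages, *, lon=None, lat=None, location=None,
                        phred=40.0, depth=30.0, cluster=None, pos=None):
    """Build a GenotypeTable from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    loci = pd.DataFrame({
        "id": [f"l{j}" for j in range(m)],
        "chrom": ["chr1"] * m,
        "pos": pos if pos is not None else (np.arange(m) + 1) * 10,
        "phred_quality": np.broadcast_to(np.asarray(phred, float), (m,)).copy(),
        "mean_depth": np.broadcast_to(np.asarray(depth, float), (m,)).copy(),
    })
    samples = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "lon": lon if lon is not None else np.zeros(n),
        "lat": lat if lat is not None else np.zeros(n),
        "location_id": location if location is not None else ["loc0"] * n,
    })
    if cluster is not None:
        samples["cluster"] = cluster
    return GenotypeTable(dosages, loci, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
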