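import numpy as np
import pandas as pd
import pytest

from chromdar.intervals import RegionSet
from chromdar.quant_qc import CountExperiment


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1000, max_len=80):
    rows = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        rows.append((chrom, start, start + length))
    return rows


@pytest.fixture
def two_group_experiment(rng):
    """Small 2-treatment x 2-timepoint x 3-individual NB experiment, no effects."""
    meta = pd.DataFrame([
        {"sample_id": f"{i}_{t}_{tp}", "individual": i, "treatment": t, "time": tp}
        for i in ("A", "B", "C") for t in ("DRUG", "VEH") for tp in ("3", "24")
    ])
    R = 300
    mu = rng.uniform(20, 500, size=R)[:, None] * np.ones((1, len(meta)))
    n_nb = 10.0
    counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
    regions = RegionSet.from_tuples(
        [("chr1", 1000 * i, 1000 * i + 500) for i in range(R)])
    return CountExperiment(regions=regions, counts=counts, samples=meta)
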