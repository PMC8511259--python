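import numpy as np
import pytest

from arabpop.core import GenotypeMatrix
from arabpop import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample, 8k-site cohort from two drifted populations."""
    model = sd.AncestralModel.uniform(K=2, n_sites=8000, drift=0.08, seed=42)
    spec = sd.AdmixSpec.unadmixed({"P0": 30, "P1": 30}, K=2)
    return sd.simulate_admixed_cohort(model, spec)


@pytest.fixture(scope="session")
def y_locus():
    return sd.simulate_y_locus(n_clusters=4, sizes=12, mu=0.76e-9,
                               region_len_bp=10_000_000, depth_years=12_000,
                               seed=7)


def make_matrix(gt, ploidy=2, chrom=None, pos=None, samples=None):
    """Small-matrix helper for hand-built fixtures."""
    gt = np.asarray(gt, dtype=np.int8)
    n, m = gt.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        chrom=chrom if chrom is not None else ["1"] * m,
        pos=pos if pos is not None else np.arange(1, m + 1) * 1000,
        ref=["A"] * m, alt=["G"] * m, gt=gt, ploidy=ploidy)
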