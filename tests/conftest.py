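import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def genotype_matrix_factory():
    """Build a GenotypeMatrix by simulating HWE genotypes per variant.

    maf_by_variant: dict variant -> MAF (or (maf_A, maf_B) per control
    cohort to induce heterogeneity); missing_rate applies uniformly.
    """
    from rarefx.qc import GenotypeMatrix

    def make(
        maf_by_variant,
        n_per_cohort=200,
        cohorts=("58C", "NBS"),
        missing_rate=0.0,
        seed=7,
    ):
        rng = np.random.default_rng(seed)
        subjects, labels = [], []
        for c in cohorts:
            subjects += [f"{c}_{i}" for i in range(n_per_cohort)]
            labels += [c] * n_per_cohort
        cols = {}
        for vid, maf in maf_by_variant.items():
            col = []
            for ci, c in enumerate(cohorts):
                p = maf[ci] if isinstance(maf, (tuple, list)) else maf
                col.append(rng.binomial(2, p, size=n_per_cohort))
            g = np.concatenate(col).astype(float)
            if missing_rate:
                g[rng.random(g.size) < missing_rate] = np.nan
            cols[vid] = g
        codes = pd.DataFrame(cols, index=subjects)
        return GenotypeMatrix(codes=codes, cohort=pd.Series(labels, index=subjects))

    return make
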