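import numpy as np
import pandas as pd
import pytest

from plasmapqtl import pipeline, simdata


@pytest.fixture(scope="session")
def demo_bundle():
    """A small cohort with planted cis, trans and artefact effects."""
    return simdata.simulate_cohort(pipeline.demo_config(seed=11, n_samples=300))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A minimal clean cohort (no missingness, one protein, no effects)."""
    cfg = simdata.SimConfig(n_samples=120, n_variants=10, n_proteins=2,
                            peptides_per_protein=(2, 2),
                            missing_intercept=-50.0, seed=5)
    return simdata.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_summary_stats(variant_ids, betas, ses, effect="A", other="G"):
    m = len(variant_ids)
    return pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "effect_allele": effect,
        "other_allele": other,
        "eaf": 0.3,
        "beta": betas,
        "se": ses,
        "pval": 0.5,
        "n": 1000,
    })
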