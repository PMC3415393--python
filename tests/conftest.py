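import numpy as np
import pytest

from badgerqc import engine, eqtl, simulate


@pytest.fixture(scope="session")
def clean_cohort():
    """Small clean cohort shared by read-only tests."""
    cfg = simulate.SimulationConfig(seed=101, n_samples=48, n_snps=40, n_probes=100)
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_clean(clean_cohort):
    """Fitted eQTL set plus predicted/observed matrices for the clean cohort."""
    c = clean_cohort
    pairs = eqtl.scan_cis_associations(c.expr, c.geno, c.smap)
    pairs = eqtl.fit_eqtl_set(pairs, c.expr, c.geno, c.smap)
    P = engine.predict_matrix(pairs, c.expr)
    O = engine.observed_matrix(pairs, c.geno)
    return c, pairs, P, O


def pairing(smap):
    return frozenset(
        (r.expression_array, r.genotype_array)
        for r in smap.records
        if r.expression_array and r.genotype_array
    )


def random_mixture_density(rng, n_components=None):
    """A random Gaussian-mixture class density for oracle tests."""
    k = n_components or int(rng.integers(3, 30))
    pts = rng.normal(rng.uniform(-2, 2), rng.uniform(0.2, 1.5), size=k)
    return eqtl.ClassDensity(np.sort(pts), float(rng.uniform(0.05, 0.8)))
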