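import numpy as np
import pytest

from dupsweep import simulate


@pytest.fixture(scope="session")
def cohort():
    """One seeded synthetic cohort shared by the read-only tests."""
    cfg = simulate.CohortSimConfig(n_samples=500, seed=7)
    gm, copies, depths, phen, truth = simulate.simulate_cohort(cfg)
    return {
        "config": cfg, "genotypes": gm, "copies": copies,
        "depths": depths, "phenotypes": phen, "truth": truth,
    }


@pytest.fixture(scope="session")
def sweep_haps():
    return simulate.simulate_sweep(
        simulate.SweepSimConfig(
            n_haplotypes=120, n_variants=300, focal_index=150, seed=11
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
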