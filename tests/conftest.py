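import numpy as np
import pytest

from parthenoscan import simulate as sim


@pytest.fixture(scope="session")
def te_library():
    return sim.default_te_library(seed=777)


@pytest.fixture(scope="session")
def small_aab():
    """A small AAB triploid with 2% homoeolog divergence (shared across tests)."""
    spec = sim.GenomeSpec(120_000, 3, "AAB", {"homoeolog": 0.02}, seed=101)
    return sim.simulate_haplotypes(spec)


@pytest.fixture(scope="session")
def annotated_bundle(te_library):
    """Diploid assembly with genes, one palindrome, HGT implants and contaminants."""
    spec = sim.GenomeSpec(1_000_000, 2, "AB", {"allelic": 0.0}, seed=103)
    haps = sim.simulate_haplotypes(spec)
    plan = sim.FeatureImplantPlan(
        te_library=te_library, te_target_fraction=0.05, n_genes=80,
        palindrome_implants=[(3, 2)], hgt_implants=5, contaminant_scaffolds=2,
        n_scaffolds=20,
    )
    return sim.implant_features(haps, plan, seed=104)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
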