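import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from heattrial.simulate import SyntheticConfig, TraitSpec, generate_trial, paper_scale_config

# printed-style worked example: per-genotype condition-mean yields (g/m2)
# for a top-ranked subset, indexed against the full-panel means 899/674
TOP10_YIELDS = pd.DataFrame({
    "genotype": [75, 74, 139, 185, 5, 140, 71, 186, 143, 93],
    "YP": [979, 988, 898, 1007, 1046, 931, 923, 974, 959, 919],
    "YS": [898, 862, 800, 833, 834, 771, 775, 776, 772, 766],
})
PANEL_XP, PANEL_XS = 899.0, 674.0


@pytest.fixture(scope="session")
def small_trial():
    """12-genotype trial with the reference variance structure, seeded."""
    cfg = paper_scale_config(seed=42, n_genotypes=12)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def tiny_trial():
    """5 x 2 x 2 x 2 trial for brute-force ANOVA oracles."""
    cfg = paper_scale_config(seed=7, n_genotypes=5)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def noise_free_trial():
    """Degenerate trial: all variances zero, 25% stress penalty."""
    cfg = SyntheticConfig(
        n_genotypes=4,
        yield_trait=TraitSpec(mu_normal=899.0, stress_penalty=0.25),
        seed=0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def index_panel():
    """Index table for a moderately sized synthetic panel."""
    from heattrial.dataset import genotype_condition_means
    from heattrial.indices import compute_indices
    ds, _ = generate_trial(paper_scale_config(seed=11, n_genotypes=40))
    return compute_indices(genotype_condition_means(ds, "GY"))
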