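import numpy as np
import pandas as pd
import pytest

from poolvar.cli import make_fixtures
from poolvar.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def fixtures() -> dict[str, pd.DataFrame]:
    return make_fixtures(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def clean_config(**kw) -> SimulationConfig:
    """A registry with no defects, for tests that want pure sampling."""
    defaults = dict(n_missing_id=0, n_duplicates=0, n_twin_pairs=0, n_triplet_sets=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def paper_scale_labeled():
    """One paper-scale discovery run, labelled against the validation oracle."""
    from poolvar.calibration import label_calls
    from poolvar.cli import build_validations
    from poolvar.pool_caller import CallConfig, call_pools
    from poolvar.synthetic_cohort import assign_pools, simulate_pool_pileups

    cfg = SimulationConfig(seed=42)
    cohort = simulate_cohort(cfg, class_counts={"pLoF": 13, "cLoF": 4, "WT-like": 21, "GoF": 2})
    design = assign_pools(cohort, cfg.pool_size, 43)
    pile = simulate_pool_pileups(design, cohort, cfg, seed=44)
    calls = call_pools(pile.frame, CallConfig())
    passing = calls[calls.passed]
    validations = build_validations(passing, design, cohort, pile.sites, seed=45)
    labeled = label_calls(passing, validations, design)
    return {"cohort": cohort, "design": design, "pileups": pile, "labeled": labeled,
            "validations": validations}
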