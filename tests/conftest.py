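import warnings

import pytest

import deplife as dl


@pytest.fixture(scope="session")
def basis():
    """Default cubic basis on ages 18..100 with 21 segments."""
    return dl.build_basis()


@pytest.fixture(scope="session")
def areas300():
    return dl.simulate_areas(300, seed=4)


@pytest.fixture(scope="session")
def sim50k(areas300):
    """A moderate synthetic cohort under the default mortality gradient.

    Returns (config, records-with-quintiles, counts table); shared across
    tests that only need realistic counts, not a specific scenario.
    """
    cfg = dl.SimulationConfig(n_individuals=50_000, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # terminal-age hazard >1 under HR=2
        rec = dl.simulate_microdata(cfg, areas300)
    rec = dl.attach_quintiles(rec, dl.assign_quintiles(areas300))
    counts = dl.aggregate_counts(rec, age_range=cfg.age_range)
    return cfg, rec, counts
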