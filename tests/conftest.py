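import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from fragratio import compute_ratios, enrich_scaffolds, select_candidates
from fragratio.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_sim():
    """One seeded run of the default synthetic study, shared across tests."""
    config = SimConfig(seed=0)
    scaffolds, fragments, truth, table = simulate_experiment(config)
    return {
        "config": config,
        "scaffolds": scaffolds,
        "fragments": fragments,
        "truth": truth,
        "table": table,
    }


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Ratio records, candidates and enrichment for the default study."""
    records = compute_ratios(default_sim["table"])
    candidates = select_candidates(records)
    enrichments = enrich_scaffolds(records, candidates)
    return {"records": records, "candidates": candidates,
            "enrichments": enrichments, **default_sim}
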