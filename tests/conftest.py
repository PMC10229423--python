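import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts():
    """Minimal two-condition screen: 3 elements, 2 replicates per condition."""
    from nutriscreen.core import CountMatrix

    counts = pd.DataFrame(
        {
            "glu_r1": [100, 200, 700],
            "glu_r2": [110, 190, 700],
            "gal_r1": [100, 400, 500],
            "gal_r2": [90, 420, 490],
        },
        index=pd.Index(["e1", "e2", "e3"], name="element_id"),
    )
    meta = pd.DataFrame(
        {
            "condition": ["glucose", "glucose", "galactose", "galactose"],
            "replicate": [1, 2, 1, 2],
            "day": [21.0] * 4,
            "role": ["screen"] * 4,
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)


@pytest.fixture(scope="session")
def crispr_sim_small():
    """Small planted CRISPR screen shared across tests (read-only)."""
    from nutriscreen.synth import simulate_crispr_screen

    return simulate_crispr_screen(
        n_genes=300, n_noncutting=40, n_planted=15, depth=300.0, seed=11
    )
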