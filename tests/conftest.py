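import numpy as np
import pandas as pd
import pytest

from prscreen.synthetic import SimConfig, simulate_cohort, simulate_panel


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One large cohort at the default (calibrated) generator settings,
    shared across calibration-sensitive tests."""
    cfg = SimConfig(n_participants=30_000, seed=7)
    panel, mafs = simulate_panel(cfg)
    cohort, genotypes = simulate_cohort(cfg, panel, mafs)
    return cfg, panel, mafs, cohort, genotypes


@pytest.fixture()
def small_cohort():
    cfg = SimConfig(n_participants=2_000, seed=5)
    cohort, genotypes = simulate_cohort(cfg)
    return cohort, genotypes


@pytest.fixture()
def toy_panel():
    from prscreen.prs import SNPPanel

    table = pd.DataFrame(
        {
            "rsid": ["rs1", "rs2"],
            "risk_allele": ["A", "A"],
            "other_allele": ["G", "G"],
            "published_beta": [0.1, 0.2],
            "published_p": [1e-8, 1e-8],
            "is_agent": [False, False],
        }
    )
    return SNPPanel(table, provenance="toy")
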