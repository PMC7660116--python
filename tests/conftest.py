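import numpy as np
import pandas as pd
import pytest

import periomr as pm


def make_pairs(beta_exposure, beta_outcome, se_outcome, se_exposure=None, variant_ids=None):
    """Assemble a harmonized-pairs table directly from effect arrays."""
    g = np.asarray(beta_exposure, dtype=float)
    G = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    sx = np.zeros_like(g) if se_exposure is None else np.asarray(se_exposure, dtype=float)
    J = g.size
    return pd.DataFrame(
        {
            "variant_id": variant_ids or [f"rs{i}" for i in range(J)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exposure": g,
            "se_exposure": sx,
            "eaf_exposure": 0.3,
            "beta_outcome": G,
            "se_outcome": sy,
            "eaf_outcome": 0.3,
            "palindromic_flag": False,
            "harmonization_action": "as-is",
            "ratio_estimate": G / g,
            "ratio_se_first_order": sy / np.abs(g),
            "weight": g**2 / sy**2,
        }
    )


@pytest.fixture(scope="session")
def instruments():
    return pm.load_periodontitis_instruments()


@pytest.fixture(scope="session")
def influence_table():
    return pm.load_influence_table()


@pytest.fixture
def pairs_factory():
    """Simulate a two-sample dataset and harmonize it into a pairs table."""

    def factory(n_variants=10, theta=0.1, seed=0, **kwargs):
        kwargs.setdefault("palindromic_fraction", 0.0)
        cfg = pm.SyntheticConfig(n_variants=n_variants, theta=theta, seed=seed, **kwargs)
        exposure, outcome, truth = pm.simulate_two_sample(cfg)
        exposure = pm.orient_risk_increasing(exposure)
        pairs, _ = pm.harmonize(exposure, outcome)
        return pairs, truth

    return factory
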