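import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import magcoex as m

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture,
                           HealthCheck.too_slow],
)
settings.load_profile("suite")


def quant_df(records):
    """Build a long-form quant table from (gene, sample, count, length) rows."""
    return pd.DataFrame(
        records, columns=["gene_id", "sample_id", "est_count", "eff_length"]
    )


def meta_df(records):
    """Build gene metadata from (gene, mag, biotype, families) rows."""
    df = pd.DataFrame(
        records, columns=["gene_id", "mag_id", "biotype", "marker_families"]
    )
    df["marker_families"] = df["marker_families"].map(frozenset)
    return df


def samples_df(pairs):
    """Build sample metadata from (sample_id, condition) pairs."""
    return pd.DataFrame(
        {
            "sample_id": [s for s, _ in pairs],
            "condition": [c for _, c in pairs],
            "replicate": [str(i + 1) for i in range(len(pairs))],
        }
    )


@pytest.fixture(scope="session")
def toy_community():
    """Small seeded community exercising every planted feature."""
    cfg = m.SyntheticConfig(
        seed=7,
        n_mags=30,
        genes_per_mag=(5, 10),
        n_samples_per_condition=3,
        target_block=frozenset(range(5)),
        anti_block=frozenset(range(5, 9)),
        role_plantings={
            "co_metabolizer": frozenset({2, 12}),
            "corrinoid_transporter": frozenset({3, 13}),
        },
    )
    return m.simulate(cfg)


@pytest.fixture(scope="session")
def noise_free_community():
    """Deterministic-mean community at the 2x2 study design."""
    return m.simulate(m.SyntheticConfig(seed=11, nb_dispersion=0.0))
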