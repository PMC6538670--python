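import numpy as np
import pandas as pd
import pytest

from seditherm import synthgen


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_sites():
    return [
        synthgen.SiteConfig("near", 0.19),
        synthgen.SiteConfig("mid", 6.0),
        synthgen.SiteConfig("far", 32.8),
    ]


@pytest.fixture(scope="session")
def small_wq(small_sites):
    truth = synthgen.default_truth()
    return synthgen.generate_water_quality(small_sites, 60, truth, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_sites, small_wq):
    truth = synthgen.default_truth()
    panel, latent = synthgen.simulate_health_trajectories(
        small_wq, small_sites, 4, 6, truth, 14, seed=12, return_latent=True
    )
    return panel, latent


def make_panel(rows):
    """Helper: build a colony panel from (colony, site, group, [scores...]) specs."""
    out = []
    for colony_id, site_id, group, mort, bleach in rows:
        for t, (m, b) in enumerate(zip(mort, bleach)):
            out.append(
                {
                    "colony_id": colony_id,
                    "site_id": site_id,
                    "group": group,
                    "survey_idx": t,
                    "mort_score": m,
                    "bleach_score": b,
                }
            )
    return pd.DataFrame(out)
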