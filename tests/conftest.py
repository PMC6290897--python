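"""Shared fixtures: small synthetic cohorts generated at test time."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from irsigflow.events import EventMatrix, default_channel_roles
from irsigflow.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        group_sizes=(8, 8, 8, 8),
        events_per_subject=800,
        n_batches=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """design, events, fm5 controls, plasma for a 32-subject cohort."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a single planted HIV effect: TIGIT +1.5 logits on gd cells."""
    cfg = SyntheticConfig(
        group_sizes=(10, 10, 10, 10),
        events_per_subject=1000,
        n_batches=3,
        seed=11,
    )
    cfg.ir_hiv_effect = {**cfg.ir_hiv_effect, "PD-1": 0.0, "TIGIT": 1.5,
                         "TIM-3": 0.0, "CD160": 0.0, "LAG-3": 0.0}
    cfg.ir_age_effect = {k: 0.0 for k in cfg.ir_age_effect}
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_tree(effect_cohort):
    """Pooled cluster tree + per-sample features for the planted-effect cohort."""
    from irsigflow.citrus import cluster_features, pool_and_cluster

    _, (design, events, _, _) = effect_cohort
    tree = pool_and_cluster(events, max_pooled_events=15_000, seed=1)
    feats = cluster_features(tree)
    return design, tree, feats


def make_events(values: dict[str, list[float]], sample_id: str = "T",
                transform_state: str = "arcsinh") -> EventMatrix:
    """Tiny hand-built event matrix over the full default channel set."""
    df = pd.DataFrame(values)
    roles = default_channel_roles()
    for missing in set(roles) - set(df.columns):
        df[missing] = 0.0
    return EventMatrix(sample_id, df, roles, transform_state)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
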