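"""Shared fixtures: synthetic bundles and assembled feature tables.

Session scope keeps the expensive pieces (bundle generation, feature
assembly, cross-validation of the default scenario) to one computation for
the whole run.
"""

import pytest

from xishumid import evaluation, features, model, observations, synthetic


def make_table(cfg, dv_kind="mean"):
    bundle = synthetic.generate_bundle(cfg)
    days = observations.derive_station_days(
        bundle.observations, observations.CleaningConfig())
    table = features.assemble_features(
        days, bundle.grids, bundle.statics, dv_kind)
    return bundle, table


@pytest.fixture(scope="session")
def small_cfg():
    """A fast scenario for unit-level pipeline tests."""
    return synthetic.SyntheticConfig(n_stations=40, n_days=5, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return synthetic.generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def small_table(small_cfg, small_bundle):
    days = observations.derive_station_days(
        small_bundle.observations, observations.CleaningConfig())
    return features.assemble_features(
        days, small_bundle.grids, small_bundle.statics, "mean")


@pytest.fixture(scope="session")
def default_cfg():
    """The default study conditions: 150 stations, 30 days, 1 K noise."""
    return synthetic.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_table(default_cfg):
    return make_table(default_cfg)[1]


@pytest.fixture(scope="session")
def default_cv(default_table):
    return evaluation.cross_validate(
        default_table, model.default_hyperparameters("mean"), seed=1)
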