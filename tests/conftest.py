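"""Shared fixtures: small synthetic surveys and session-scoped fitted models."""

import numpy as np
import pytest
from hypothesis import settings

import washord as w

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


P3_SPEC = [
    {"name": "hdi", "kind": "continuous", "trend_sd": 1.0, "noise_sd": 0.3},
    {"name": "nightlight", "kind": "continuous", "trend_sd": 1.0,
     "noise_sd": 0.3},
    {"name": "time", "kind": "time", "start": "2006-01-01",
     "end": "2023-12-31"},
]


def make_config(**kw):
    """A K=3, p=3 survey configuration with overridable fields."""
    base = dict(n_clusters=60, households_per_cluster=(25, 30), K=3,
                beta=np.array([0.8, -0.5, 0.3]),
                thresholds=np.array([-1.0, 1.0]),
                sigma_b=0.4, spatial_range=3.0, sigma_u=0.6,
                domain=(0.0, 10.0, 0.0, 10.0),
                covariate_spec=P3_SPEC, seed=11)
    base.update(kw)
    return w.SurveyConfig(**base)


@pytest.fixture(scope="session")
def small_survey():
    """60-cluster spatial survey with truth retained."""
    return w.simulate_survey(make_config())


@pytest.fixture(scope="session")
def nospatial_fit():
    """Cluster-effect-only fit on a small survey (fast, well identified)."""
    cfg = make_config(n_clusters=80, sigma_u=0.0, sigma_b=0.4, seed=21)
    data = w.simulate_survey(cfg)
    model = w.fit(data, fit_config=w.FitConfig(use_spatial=False))
    return cfg, data, model


@pytest.fixture(scope="session")
def small_spatial_fit():
    """Spatial fit on the 60-cluster survey (prediction/diagnostics tests)."""
    cfg = make_config()
    data = w.simulate_survey(cfg)
    model = w.fit(data, mesh_config=w.MeshConfig(buffer_fraction=0.2,
                                                 max_edge=1.25))
    return cfg, data, model


@pytest.fixture(scope="session")
def medium_fit():
    """Correctly specified spatial fit at moderate size (200 clusters × 25).

    Shared by the calibration, posterior-predictive and delta-method
    checks, which all need a well-estimated model on its own data.
    """
    cfg = make_config(n_clusters=200, households_per_cluster=(25, 25),
                      seed=31)
    data = w.simulate_survey(cfg)
    model = w.fit(data, mesh_config=w.MeshConfig(buffer_fraction=0.2,
                                                 max_edge=1.25))
    return cfg, data, model
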