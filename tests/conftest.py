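"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pytest

import floratime as ft


@pytest.fixture(scope="session")
def sim_small():
    """300-gene default study (14 time-points, 3 replicates, 30 % DE)."""
    cfg = ft.SimConfig(n_genes=300, seed=1)
    expr, truth = ft.generate_timecourse(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def sim_annotated():
    """800-gene study with the default annotation plan applied."""
    cfg = ft.SimConfig(n_genes=800, seed=11)
    expr, truth = ft.generate_timecourse(cfg)
    ann = ft.generate_annotations(cfg, truth)
    return cfg, expr, truth, ann


@pytest.fixture(scope="session")
def de_results(sim_small):
    _, expr, _ = sim_small
    return ft.TimecourseDE(expr).fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
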