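"""Shared fixtures.

The two expensive session fixtures are the paired demo runs (determinism
and contract checks) and the recovery run (virtual-species recovery on the
full-size synthetic archipelago with a compute-scaled modelling protocol).
"""

from __future__ import annotations

import numpy as np
import pytest

from islandsdm import demo_config, recovery_config, run_pipeline
from islandsdm import synth
from islandsdm import predictors as pred_mod


@pytest.fixture(scope="session")
def small_arch():
    return synth.make_archipelago(1, n_islands=4, grid_shape=(100, 100))


@pytest.fixture(scope="session")
def small_clim(small_arch):
    return synth.make_monthly_climate(small_arch, seed=2)


@pytest.fixture(scope="session")
def small_env(small_arch, small_clim):
    return pred_mod.build_predictor_stack(small_clim, small_arch)


@pytest.fixture(scope="session")
def small_bio(small_clim):
    return pred_mod.derive_bioclim(small_clim)


@pytest.fixture(scope="session")
def small_vs_env(small_arch, small_bio):
    """Layer stack the virtual-species generator expects (bioclim + heat load)."""
    from islandsdm.grid import LayerStack

    topo = pred_mod.derive_topographic(small_arch.dem)
    env = LayerStack({name: small_bio[name] for name in small_bio.names})
    env.add("hli", topo["hli"])
    return env


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The demo pipeline executed twice with the same master seed."""
    base = tmp_path_factory.mktemp("demo")
    runs = []
    for tag in ("a", "b"):
        p = run_pipeline(demo_config(), base / tag)
        runs.append(p)
    return runs


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full-size synthetic archipelago with archetype species modelled.

    Landscape and scenarios are the default study conditions (150x150
    cells, 12 virtual species, 2 RCPs x 3 time-slices); ESMs are fitted for
    the three archetypes the recovery checks interrogate.
    """
    cfg = recovery_config()
    cfg.fit_species = ("vs_cold_narrow", "vs_montane_sunny", "vs_warm_generalist")
    return run_pipeline(cfg, tmp_path_factory.mktemp("recovery") / "run")
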