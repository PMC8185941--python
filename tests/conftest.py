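"""Shared fixtures: small synthetic tiles and (session-scoped) trained models."""

from __future__ import annotations

import pytest

from pdl1tps import SynthSpec, simulate_tile
from pdl1tps.cli import RunConfig, make_study, train_models


@pytest.fixture(scope="session")
def small_tile():
    """One 96x96 synthetic tile with mixed cell classes."""
    return simulate_tile(SynthSpec(tile_width=96, tile_height=96,
                                   planned_tps=40.0, n_tumor_cells=20,
                                   n_immune_cells=4, n_fibrocytes=3, seed=11))


@pytest.fixture(scope="session")
def study_config():
    """The desk-scale study conditions used by the trained-model checks."""
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def trained_models(study_config):
    """C-Net + R-Net trained once per session on the synthetic study.

    Returns (cnet, rnet, histories, eval_slides, config).  Shared by the
    end-to-end TPS recovery and ensemble-masking checks.
    """
    train, val, slides = make_study(study_config)
    cnet, rnet, hist = train_models(study_config, train, val)
    return cnet, rnet, hist, slides, study_config
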