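import numpy as np
import pytest

import erplocsim as els


@pytest.fixture(scope="session")
def fem_model():
    return els.make_shell_model("fem_meta", els.DEFAULT_RADII_4)


@pytest.fixture(scope="session")
def bem_model():
    return els.make_shell_model("bem_default", els.DEFAULT_RADII_3)


@pytest.fixture(scope="session")
def small_montage(fem_model):
    return els.make_montage(32, fem_model.r_outer, seed=1)


@pytest.fixture(scope="session")
def coarse_sources(fem_model):
    """~450-dipole grid for fast unit tests (too coarse for clustering)."""
    return els.make_source_space(fem_model, spacing_mm=10.0)


@pytest.fixture(scope="session")
def coarse_leadfield(fem_model, small_montage, coarse_sources):
    return els.compute_leadfield(fem_model, small_montage, coarse_sources)


@pytest.fixture(scope="session")
def dense_sources(fem_model):
    """3 mm grid: the study's dipole spacing, needed by the cluster metrics."""
    return els.make_source_space(fem_model, spacing_mm=3.0)


@pytest.fixture(scope="session")
def sim_epochs(fem_model, coarse_sources, coarse_leadfield):
    """Default-size simulated dataset on the fast grid, 0 dB."""
    net = els.make_network("fronto_occipital", coarse_sources)
    cfg = els.SimulationConfig(snr_db=0.0, seed=7)
    return els.simulate_epochs(net, coarse_leadfield, coarse_sources, cfg)


@pytest.fixture(scope="session")
def reduced_study():
    """The reduced cohort study used for the ordering properties.

    6 subjects, 2 networks, SNR -10 dB, 64 sensors, 4 mm grid; three model
    variants (generating subject model, deviant-conductivity subject model,
    template model) scored at 10/30/50 mm. Computed once per session.
    """
    cfg = els.ExperimentConfig(
        n_subjects=6,
        networks=("fronto_occipital", "temporo_occipital"),
        snr_db_levels=(-10.0,),
        model_variants=(
            "subject_fem_meta",
            "subject_fem_default",
            "template_fem_meta",
        ),
        max_dist_mm=(10.0, 30.0, 50.0),
        master_seed=1,
        n_sensors=64,
        spacing_mm=4.0,
    )
    table = els.run_experiment(cfg)
    summary = els.aggregate(table)
    return cfg, table, summary
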