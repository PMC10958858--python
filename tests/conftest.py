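"""Shared fixtures: the default synthetic experiment and one pipeline run.

The session-scoped pipeline run is the expensive fixture every
simulation-based test shares; per-test fixtures stay tiny and are
generated on the fly.
"""

from __future__ import annotations

import pytest

from methage import (PipelineConfig, SimulationConfig, run_pipeline,
                     simulate_experiment, truth_classes, write_experiment)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def experiment(default_config):
    return simulate_experiment(default_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, experiment):
    """The default synthetic experiment written to disk."""
    out = tmp_path_factory.mktemp("fixture")
    write_experiment(experiment, out)
    return out


@pytest.fixture(scope="session")
def classes(experiment):
    """Class label -> set of true site keys."""
    return truth_classes(experiment.truth)


@pytest.fixture(scope="session")
def pipeline_config(fixture_dir, tmp_path_factory):
    return PipelineConfig(
        sample_sheet=str(fixture_dir / "sample_sheet.tsv"),
        genes=str(fixture_dir / "genes.gff3"),
        go_map=str(fixture_dir / "go_map.tsv"),
        outdir=str(tmp_path_factory.mktemp("run")),
        seed=1,
    )


@pytest.fixture(scope="session")
def pipeline_run(pipeline_config):
    """One full pipeline execution on the default fixture."""
    return run_pipeline(pipeline_config)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """A small experiment for fast end-to-end paths (CLI, error cases)."""
    return SimulationConfig(
        seed=7, n_null_unmethylated=400, n_stable_methylated=100,
        n_dmp_hyper=20, n_dmp_hypo=20, n_vmp=10, n_clock=5, lambda_n_sites=50,
    )
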