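"""Shared fixtures: a seeded synthetic experiment and its pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import methylage as ml


@pytest.fixture(scope="session")
def default_config() -> ml.SimulationConfig:
    return ml.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(default_config) -> ml.SyntheticDataset:
    return ml.generate_dataset(default_config)


@pytest.fixture(scope="session")
def groups(dataset) -> pd.Series:
    sheet = dataset.config.sample_sheet()
    return pd.Series(
        sheet["group"].to_numpy(), index=sheet["sample_id"], name="group"
    )


@pytest.fixture(scope="session")
def pipeline_report(dataset, tmp_path_factory):
    config = ml.PipelineConfig(seed=0, n_perm=100)
    outdir = tmp_path_factory.mktemp("pipeline_run")
    return ml.run_pipeline(config, outdir, dataset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def nb_matrix(
    rng: np.random.Generator,
    n_features: int,
    means: np.ndarray,
    dispersion: float,
    depth: np.ndarray,
) -> pd.DataFrame:
    """Plain NB count matrix helper for focused statistical tests."""
    mu = means[:, None] * depth[None, :]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(
        counts,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(len(depth))],
    )


@pytest.fixture()
def two_group_labels():
    def make(n_per_group: int, names=("S1", "S3")) -> pd.Series:
        cols = [f"s{j}" for j in range(2 * n_per_group)]
        return pd.Series(
            [names[0]] * n_per_group + [names[1]] * n_per_group, index=cols
        )

    return make
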