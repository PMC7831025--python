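"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from patchprint.gating import (
    AnomalySpec,
    default_profiles,
    generate_dataset,
    well_separated_profiles,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def separated_profiles():
    return well_separated_profiles()


@pytest.fixture(scope="session")
def boltzmann_profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_dataset(separated_profiles):
    """3 classes x 3 recordings at two potentials, short traces (25 windows
    per recording) — cheap shared input for io/preprocess/classify tests."""
    return generate_dataset(
        separated_profiles, 3, n_points=6000, potentials=(-40.0, 40.0), seed=7
    )


@pytest.fixture(scope="session")
def small_grouped(small_dataset):
    grouped = {}
    for rec in small_dataset:
        grouped.setdefault((rec.cell_label, rec.potential), []).append(rec)
    return grouped


@pytest.fixture(scope="session")
def anomaly_dataset(separated_profiles):
    """One potential with a planted hippocampal anomaly (20 k points)."""
    return generate_dataset(
        separated_profiles,
        3,
        n_points=20_000,
        potentials=(40.0,),
        anomaly_spec=AnomalySpec("hippocampus", 40.0),
        seed=13,
    )
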