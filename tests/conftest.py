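"""Shared fixtures: synthetic charts of several sizes and cached trained runs.

Heavy fixtures (trained sweeps) are session-scoped so the simulation-level
checks share a single set of runs.
"""

import numpy as np
import pytest

import colorgame as cg


@pytest.fixture(scope="session")
def chart330():
    """Full-size synthetic chart with the standard 40x8+10 layout."""
    return cg.make_synthetic_chart(cg.SyntheticChartSpec(seed=0))


@pytest.fixture(scope="session")
def chart_small():
    """17-chip chart (5 hues x 3 values + 2 achromatic) for fast clustering."""
    return cg.make_synthetic_chart(
        cg.SyntheticChartSpec(n_hues=5, n_values=3, n_achromatic=2, seed=1)
    )


@pytest.fixture(scope="session")
def chart_tiny():
    """5-chip noiseless-learnability chart (4 hues x 1 value + 1 achromatic)."""
    return cg.make_synthetic_chart(
        cg.SyntheticChartSpec(n_hues=4, n_values=1, n_achromatic=1, seed=1)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_chips(*coords):
    """Ad-hoc chips with given coordinate tuples, ids 0..n-1."""
    return [cg.ColorChip(i, tuple(map(float, c))) for i, c in enumerate(coords)]


@pytest.fixture(scope="session")
def scaled_game_config():
    """Desk-scale continuous training configuration shared by slow tests."""
    return cg.GameConfig(n_episodes=8000, batch_size=100, kl_probe_interval=500)


@pytest.fixture(scope="session")
def env_sweep(chart330, scaled_game_config):
    """Scaled environmental-noise sweep: 3 levels x 5 replicates."""
    spec = cg.SweepSpec(
        sigma_e_sq_levels=(1.0, 64.0, 512.0), runs_per_level=5,
        base_config=scaled_game_config, seed=7,
    )
    return cg.run_sweep(spec, chart330)


@pytest.fixture(scope="session")
def comm_sweep(chart330, scaled_game_config):
    """Scaled communication-noise sweep: 3 levels x 5 replicates."""
    spec = cg.SweepSpec(
        sigma_e_sq_levels=(0.01, 0.1, 1.0), runs_per_level=5,
        base_config=scaled_game_config, seed=8, vary="sigma_c_sq",
    )
    return cg.run_sweep(spec, chart330)
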