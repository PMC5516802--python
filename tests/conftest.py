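import numpy as np
import pytest

from mirscreen.screens import DiscreteScreen, ScreenMatrix


def make_screen(values, cell_line="A", screen_id="s"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ScreenMatrix(
        [f"miR-{i:03d}" for i in range(n)],
        [f"P{j:03d}" for j in range(p)],
        values,
        cell_line=cell_line,
        screen_id=screen_id,
    )


def make_discrete(states, threshold=1.5, cell_line="A"):
    states = np.asarray(states)
    n, p = states.shape
    return DiscreteScreen(
        [f"miR-{i:03d}" for i in range(n)],
        [f"P{j:03d}" for j in range(p)],
        states,
        threshold,
        cell_line=cell_line,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down study design used by unit tests (fast, same structure)."""
    from mirscreen.simulate import SimulationConfig

    return SimulationConfig(
        n_mirna=220, n_protein=60, cluster_sizes=(30, 50, 35, 45),
        signature_size=6, effect_size=1.0, noise_sd=0.25, n_controls=5, seed=11,
    )


@pytest.fixture(scope="session")
def small_primary(small_sim_config):
    from mirscreen.simulate import simulate_primary_screen

    return simulate_primary_screen(small_sim_config)
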