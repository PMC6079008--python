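import numpy as np
import pandas as pd
import pytest

from colonytrack.simulate import ColonyConfig, default_topology, simulate_colony


@pytest.fixture(scope="session")
def topology():
    return default_topology()


@pytest.fixture(scope="session")
def small_colony():
    """A 4-mouse, 6-hour colony with one planted follower (m02 -> m01)."""
    cfg = ColonyConfig(
        n_mice=4,
        duration_ms=6 * 3_600_000,
        followers={"m02": ("m01", 0.8)},
        seed=11,
    )
    return simulate_colony(cfg)


def make_visits(rows):
    """rows: (mouse_id, compartment, t_enter, t_exit)"""
    return pd.DataFrame(
        rows, columns=["mouse_id", "compartment", "t_enter", "t_exit"]
    )
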