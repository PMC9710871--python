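import numpy as np
import pandas as pd
import pytest

import velonode as vn


@pytest.fixture()
def toy_dataset() -> vn.Dataset:
    """A tiny handmade dataset (5 cells x 3 genes) for I/O and plumbing."""
    rng = np.random.default_rng(42)
    expr = rng.uniform(0, 2, (5, 3))
    vel = rng.normal(0, 0.5, (5, 3))
    return vn.Dataset(expr, vel, ["g0", "g1", "g2"],
                      ["A", "A", "B", "B", "A"],
                      pd.DataFrame({"latent_time": np.linspace(0, 1, 5)}))


@pytest.fixture(scope="session")
def toggle_system() -> vn.SyntheticSystem:
    return vn.make_toggle_switch(18, seed=0)


@pytest.fixture(scope="session")
def toggle_dataset(toggle_system) -> vn.Dataset:
    return vn.sample_cells(toggle_system, 800, seed=0)


@pytest.fixture(scope="session")
def trained_field(toggle_dataset) -> vn.VelocityField:
    """A modestly trained field on the toggle-switch data, shared by tests
    that need realistic (not necessarily converged) dynamics."""
    return vn.train_field(
        toggle_dataset,
        vn.VAEArchitecture(input_dim=toggle_dataset.n_genes),
        vn.TrainConfig(max_epochs=150, seed=0),
    )


@pytest.fixture()
def constant_velocity_dataset() -> vn.Dataset:
    """Velocity identically equal to a fixed vector c for every cell."""
    rng = np.random.default_rng(7)
    n, g = 400, 4
    expr = rng.uniform(0, 2, (n, g))
    c = np.array([0.5, -0.25, 0.1, 0.0])
    vel = np.tile(c, (n, 1))
    ds = vn.Dataset(expr, vel, [f"g{i}" for i in range(g)], ["A"] * n)
    ds.constant = c  # stashed for assertions
    return ds
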