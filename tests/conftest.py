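import numpy as np
import pytest

import srtjoint as sj

# Study conditions for the simulation-based checks: a small checkerboard
# tissue with 3 well-separated cell types, 60 high-res spots aggregated
# into 12 low-res spots, 30 genes of which 20 are on the targeted panel,
# at double coverage so per-gene signal is strong.
STANDARD_SIM = dict(
    grid_side=4,
    n_types=3,
    coverage=2.0,
    n_genes=30,
    panel_size=20,
    n_x_spots=60,
    n_v_spots=12,
)


def standard_pair(seed: int, coverage: float = 2.0):
    cfg = sj.SimulationConfig(**{**STANDARD_SIM, "coverage": coverage, "seed": seed})
    return sj.simulate_pair(cfg)


def true_mean(truth: sj.SimulatedTruth) -> np.ndarray:
    """Latent Poisson mean implied by the ground truth, universe gene order."""
    return truth.x_umi[:, None] * truth.profiles[truth.cell_type]


def assert_model_valid(model: sj.FittedModel, gamma) -> None:
    """Structural contract every fitted model must satisfy."""
    np.testing.assert_allclose(model.P.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(model.Q.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(model.N > 0)
    # M supported only on the mapping, exactly
    off_support = model.M.multiply(1 - gamma.toarray())
    assert off_support.nnz == 0 or np.all(off_support.data == 0)
    # platform scaling fixed to 1 off the trained panel, exactly
    assert np.all(model.phi[~model.trained_gene_mask] == 1.0)
    # best-of-restarts selection
    assert len(model.restart_losses) == model.config.restarts
    assert model.final_loss == min(model.restart_losses)


@pytest.fixture(scope="session")
def small_pair():
    """Tiny simulated pair for fast structural tests."""
    cfg = sj.SimulationConfig(
        grid_side=2, n_types=2, coverage=1.0, n_genes=10, panel_size=6,
        n_x_spots=20, n_v_spots=4, seed=7,
    )
    return sj.simulate_pair(cfg)


@pytest.fixture(scope="session")
def small_fit(small_pair):
    data, truth = small_pair
    cfg = sj.ModelConfig(h=2, epochs=200, restarts=2, seed=11)
    return sj.fit(data, cfg), data, truth
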