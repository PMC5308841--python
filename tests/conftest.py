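"""Shared fixtures: small synthetic instances and short posterior runs
reused across test modules (fitting is the expensive step)."""

import numpy as np
import pytest

import latentconn as lc
from latentconn import synthetic


@pytest.fixture(scope="session")
def small_instance():
    """p = 12, D = 2, K = 4 ground truth with 20% of cells unobserved."""
    params = lc.generate_params(12, 2, 4, seed=5)
    inst = synthetic.generate_connectome(params, seed=6)
    return synthetic.apply_design(inst, ("random_fraction", 0.8))


@pytest.fixture(scope="session")
def small_samples(small_instance):
    """A short two-chain posterior fit of the small instance."""
    cfg = lc.RunConfig(
        latent_dim=2, n_chains=2, n_warmup=200, n_samples=200, seed=7
    )
    return lc.sample_posterior(small_instance.data, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_fake_samples(
    Z_draws,
    b_draws,
    imputed,
    unobserved_edges,
    observed_weights,
    observed_mask,
    n_classes=4,
    n_chains=1,
    sigma=None,
    delta=None,
    eps=None,
):
    """Hand-assembled PosteriorSamples for operation-level tests."""
    from latentconn.inference import PosteriorSamples

    Z_draws = np.asarray(Z_draws, dtype=float)
    T, p, D = Z_draws.shape
    b_draws = np.asarray(b_draws, dtype=float)
    cfg = lc.RunConfig(
        latent_dim=D, n_chains=n_chains, n_warmup=1,
        n_samples=T // n_chains, seed=0,
    )
    return PosteriorSamples(
        variant="lsm",
        n_classes=n_classes,
        node_labels=[f"R{i:02d}" for i in range(p)],
        config=cfg,
        Z=Z_draws,
        b=b_draws,
        sigma=np.ones(T) if sigma is None else np.asarray(sigma, float),
        delta=np.zeros((T, p)) if delta is None else np.asarray(delta, float),
        eps=np.zeros((T, p)) if eps is None else np.asarray(eps, float),
        tau_delta=np.full(T, np.nan),
        tau_eps=np.full(T, np.nan),
        chain_id=np.repeat(np.arange(n_chains), T // n_chains),
        imputed=np.asarray(imputed, dtype=np.int64).reshape(T, -1),
        unobserved_edges=np.asarray(unobserved_edges, dtype=np.int64).reshape(-1, 2),
        observed_weights=np.asarray(observed_weights, dtype=np.int64),
        observed_mask=np.asarray(observed_mask, dtype=bool),
        active_delta=np.ones(p, dtype=bool),
        active_eps=np.ones(p, dtype=bool),
    )
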