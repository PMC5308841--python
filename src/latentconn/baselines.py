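"""Comparison models sharing the latent space model's fit/predict
contract: the empirical-frequency baseline, the zero-dimensional
random-effects model, the fixed anatomical-position model, and the
latent eigenmodel."""

from __future__ import annotations

import numpy as np

from . import model as _m
from .errors import ValidationError
from .inference import PosteriorSamples, sample_posterior
from .io import AnatomicalPositions, OrdinalConnectome, RunConfig


def empirical_frequency(train: OrdinalConnectome) -> _m.ClassProbabilities:
    """One shared class-probability vector: the training-data class
    frequencies (no smoothing; a degenerate class simply has probability
    zero), broadcast to every edge."""
    w = train.weights[train.observed_mask]
    if w.size == 0:
        raise ValidationError("empirical baseline needs >= 1 observed edge")
    counts = np.bincount(w, minlength=train.n_classes).astype(float)
    freq = counts / counts.sum()
    p = train.p
    return _m.ClassProbabilities(np.tile(freq, (p, p, 1)))


def _with_variant(config: RunConfig, variant: str, **overrides) -> RunConfig:
    return RunConfig(**{**config.to_dict(), "model_variant": variant,
                        **overrides})


def zero_dim_model(
    data: OrdinalConnectome,
    config: RunConfig,
    hyper: _m.Hyperparams | None = None,
    second_modality: OrdinalConnectome | None = None,
) -> PosteriorSamples:
    """The D = 0 baseline: no positional term (l_ij = 0 for all pairs);
    only cutpoints, sigma and the sender/receiver effects are free."""
    cfg = _with_variant(config, "zero_dim", latent_dim=0)
    return sample_posterior(data, cfg, hyper=hyper,
                            second_modality=second_modality)


def fixed_position_model(
    data: OrdinalConnectome,
    positions: AnatomicalPositions,
    config: RunConfig,
    hyper: _m.Hyperparams | None = None,
    second_modality: OrdinalConnectome | None = None,
) -> PosteriorSamples:
    """Latent positions frozen at (standardized) anatomical centroids;
    cutpoints, sigma and random effects are learned as usual."""
    cfg = _with_variant(config, "fixed_positions")
    return sample_posterior(data, cfg, hyper=hyper, positions=positions,
                            second_modality=second_modality)


def eigenmodel(
    data: OrdinalConnectome,
    config: RunConfig,
    hyper: _m.Hyperparams | None = None,
    second_modality: OrdinalConnectome | None = None,
) -> PosteriorSamples:
    """The latent eigenmodel: generalized distance -z_i^T Lambda z_j with
    a sampled diagonal spectrum (standard normal priors).  Sign and
    permutation of the latent axes are left unresolved; only predictive
    quantities are reported."""
    cfg = _with_variant(config, "eigenmodel")
    return sample_posterior(data, cfg, hyper=hyper,
                            second_modality=second_modality)


def fit_variant(
    variant: str,
    data: OrdinalConnectome,
    config: RunConfig,
    hyper: _m.Hyperparams | None = None,
    positions: AnatomicalPositions | None = None,
    second_modality: OrdinalConnectome | None = None,
):
    """Uniform dispatch over every model variant (the one-sweep entry
    point for model-comparison figures).  Returns PosteriorSamples for
    Bayesian variants and ClassProbabilities for 'empirical'."""
    if variant == "empirical":
        return empirical_frequency(data)
    if variant == "zero_dim":
        return zero_dim_model(data, config, hyper, second_modality)
    if variant == "fixed_positions":
        if positions is None:
            raise ValidationError("fixed_positions requires centroids")
        return fixed_position_model(data, positions, config, hyper,
                                    second_modality)
    if variant == "eigenmodel":
        return eigenmodel(data, config, hyper, second_modality)
    if variant == "lsm":
        cfg = _with_variant(config, "lsm")
        return sample_posterior(data, cfg, hyper=hyper,
                                second_modality=second_modality)
    raise ValidationError(f"unknown model variant {variant!r}")
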