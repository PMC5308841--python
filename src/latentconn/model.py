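"""The generative model: latent distances, ordered-probit class
probabilities, sender/receiver random effects, priors, and likelihood
evaluation for every model variant (including two-modality fusion).

Model
-----
Each of the *p* regions has a latent position ``z_i`` in R^D.  The
propensity of a directed connection i -> j decreases with the Euclidean
distance ``l_ij = ||z_i - z_j||``.  Ordinal weights (0 = absent ..
K-1 = strongest) arise from a cumulative probit: with strictly increasing
cutpoints ``b_1 < ... < b_{K-1}`` and noise scale ``sigma``, the cumulative
probability of the k-th *distance interval* is ``Phi(h(i,j,k))`` where

    h(i, j, k) = (b_k - l_ij + delta_i + eps_j) / sigma .

``delta`` (sender) and ``eps`` (receiver) are per-node random effects that
let hubs deviate from pure distance dependence.  Because larger distance
means weaker connection, the k-th interval (k = 1..K, between cutpoints
k-1 and k) corresponds to user weight ``K - k``: the reported probability
vector is indexed by weight, 0 = absent first.

The eigenmodel variant replaces the Euclidean distance by the bilinear
form ``l_ij = -z_i^T Lambda z_j`` (a generalized "distance": smaller means
stronger); the zero-dimensional variant sets ``l_ij = 0`` so only the
random effects carry signal; the fixed-position variant freezes Z at
(standardized) anatomical centroids.

Observed weights follow a categorical distribution with the resulting
probability vector; unobserved cells contribute nothing.  In two-modality
fusion both matrices share one probability vector per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr

from .errors import ValidationError
from .io import OrdinalConnectome

PROB_TOL = 1e-12  # normalization guarantee for class probabilities

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class LatentEmbedding:
    """Latent positions Z (p x D); D = 0 means no positional term."""

    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not np.all(np.isfinite(self.Z)):
            raise ValidationError("non-finite latent position")

    @property
    def p(self) -> int:
        return self.Z.shape[0]

    @property
    def D(self) -> int:
        return self.Z.shape[1]


@dataclass
class Cutpoints:
    """Strictly increasing interior cutpoints b_1 < ... < b_{K-1}."""

    b: np.ndarray

    def __post_init__(self):
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if not np.all(np.isfinite(self.b)):
            raise ValidationError("non-finite cutpoint")
        if self.b.size > 1 and not np.all(np.diff(self.b) > 0):
            raise ValidationError("cutpoints must be strictly increasing")

    @property
    def K(self) -> int:
        return self.b.size + 1


@dataclass
class RandomEffects:
    """Sender (delta) and receiver (eps) effects; inactive entries are
    clamped to exactly 0 and excluded from sampling."""

    delta: np.ndarray
    eps: np.ndarray
    active_delta: np.ndarray | None = None
    active_eps: np.ndarray | None = None

    def __post_init__(self):
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        p = self.delta.size
        if self.eps.size != p:
            raise ValidationError("delta and eps must have equal length")
        if self.active_delta is None:
            self.active_delta = np.ones(p, dtype=bool)
        if self.active_eps is None:
            self.active_eps = np.ones(p, dtype=bool)
        self.active_delta = np.asarray(self.active_delta, dtype=bool)
        self.active_eps = np.asarray(self.active_eps, dtype=bool)
        if np.any(self.delta[~self.active_delta] != 0):
            raise ValidationError("clamped delta entries must be exactly 0")
        if np.any(self.eps[~self.active_eps] != 0):
            raise ValidationError("clamped eps entries must be exactly 0")


@dataclass
class ModelParams:
    """Full parameter set of one model variant."""

    embedding: LatentEmbedding
    cutpoints: Cutpoints
    sigma: float
    effects: RandomEffects
    lam: np.ndarray | None = None  # eigenmodel spectrum, else None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.lam is not None:
            self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
            if self.lam.size != self.embedding.D:
                raise ValidationError("Lambda must have length D")

    # convenience accessors used throughout the numerics
    @property
    def Z(self) -> np.ndarray:
        return self.embedding.Z

    @property
    def b(self) -> np.ndarray:
        return self.cutpoints.b

    @property
    def delta(self) -> np.ndarray:
        return self.effects.delta

    @property
    def eps(self) -> np.ndarray:
        return self.effects.eps

    @property
    def K(self) -> int:
        return self.cutpoints.K

    @property
    def p(self) -> int:
        return self.delta.size

    @property
    def D(self) -> int:
        return self.embedding.D


@dataclass
class Hyperparams:
    """Prior scales.  Weakly informative; the latent scale is pinned by
    fixing sigma (the model is invariant under joint rescaling of
    Z, b, delta, eps and sigma, so one scale must be fixed)."""

    z_scale: float = 1.0        # z_i ~ Normal(0, z_scale^2 I)
    effect_scale: float = 1.0   # tau ~ half-Normal(0, effect_scale); effects ~ N(0, tau^2)
    cut_loc_scale: float = 5.0  # b_1 ~ Normal(0, cut_loc_scale^2)
    cut_inc_scale: float = 5.0  # cutpoint increments ~ half-Normal(0, cut_inc_scale)
    sigma_scale: float = 1.0    # sigma ~ half-Normal(0, sigma_scale) when sampled
    lam_scale: float = 1.0      # eigenmodel spectrum ~ Normal(0, lam_scale^2)
    fix_sigma: bool = True

    def __post_init__(self):
        for name in ("z_scale", "effect_scale", "cut_loc_scale",
                     "cut_inc_scale", "sigma_scale", "lam_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class ClassProbabilities:
    """Per-edge class probabilities f (p x p x K, user weight coding)."""

    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 3 or self.f.shape[0] != self.f.shape[1]:
            raise ValidationError("f must be (p, p, K)")


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------


def latent_distance(embedding: LatentEmbedding | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances l_ij = ||z_i - z_j||_2 (p x p)."""
    Z = embedding.Z if isinstance(embedding, LatentEmbedding) else np.atleast_2d(
        np.asarray(embedding, dtype=float)
    )
    if Z.shape[1] == 0:
        return np.zeros((Z.shape[0], Z.shape[0]))
    diff = Z[:, None, :] - Z[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def eigen_distance(
    embedding: LatentEmbedding | np.ndarray, lam: np.ndarray
) -> np.ndarray:
    """Generalized eigenmodel distance l_ij = -z_i^T Lambda z_j.

    Symmetric but signed; smaller values mean stronger connections.
    """
    Z = embedding.Z if isinstance(embedding, LatentEmbedding) else np.atleast_2d(
        np.asarray(embedding, dtype=float)
    )
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.size != Z.shape[1]:
        raise ValidationError(
            f"Lambda has length {lam.size}, embedding dimension is {Z.shape[1]}"
        )
    return -(Z * lam) @ Z.T


def model_distance(params: ModelParams, variant: str) -> np.ndarray:
    """Dispatch the (generalized) distance for a model variant."""
    if variant == "eigenmodel":
        if params.lam is None:
            raise ValidationError("eigenmodel requires Lambda")
        return eigen_distance(params.embedding, params.lam)
    if variant == "zero_dim" or params.D == 0:
        return np.zeros((params.p, params.p))
    return latent_distance(params.embedding)


# --------------------------------------------------------------------------
# ordered probit
# --------------------------------------------------------------------------


def _padded_cutpoints(b: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], b, [np.inf]))


def _log_interval_prob(lo: np.ndarray, up: np.ndarray) -> np.ndarray:
    """log(Phi(up) - Phi(lo)) computed stably for extreme arguments."""
    lo = np.asarray(lo, dtype=float)
    up = np.asarray(up, dtype=float)
    out = np.empty(np.broadcast(lo, up).shape)
    lo, up = np.broadcast_arrays(lo, up)

    left_open = np.isneginf(lo)
    right_open = np.isposinf(up)
    both_neg = ~left_open & ~right_open & (up <= 0)
    both_pos = ~left_open & ~right_open & (lo >= 0)
    middle = ~left_open & ~right_open & ~both_neg & ~both_pos

    if left_open.any():
        out[left_open] = log_ndtr(up[left_open])
    if right_open.any():
        out[right_open] = log_ndtr(-lo[right_open])
    with np.errstate(divide="ignore"):  # a degenerate interval is -inf
        if both_neg.any():  # work in the lower tail where log_ndtr is accurate
            a, c = log_ndtr(up[both_neg]), log_ndtr(lo[both_neg])
            out[both_neg] = a + np.log1p(-np.exp(np.minimum(c - a, -1e-300)))
        if both_pos.any():  # mirror to the lower tail
            a, c = log_ndtr(-lo[both_pos]), log_ndtr(-up[both_pos])
            out[both_pos] = a + np.log1p(-np.exp(np.minimum(c - a, -1e-300)))
    if middle.any():  # straddles 0: direct difference is well conditioned
        out[middle] = np.log(ndtr(up[middle]) - ndtr(lo[middle]))
    return out


def _log_norm_pdf(x: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(x), -np.inf)
    finite = np.isfinite(x)
    xf = np.asarray(x)[finite]
    out[finite] = -0.5 * xf * xf - _LOG_SQRT_2PI
    return out


def class_probs(
    l: float, delta_i: float, eps_j: float,
    cutpoints: Cutpoints | np.ndarray, sigma: float,
) -> np.ndarray:
    """Class-probability vector for one edge, in user weight coding.

    Index 0 is "absent", index K-1 the strongest class; the expected
    weight is non-increasing in the distance ``l`` and non-decreasing in
    the random effects.
    """
    b = cutpoints.b if isinstance(cutpoints, Cutpoints) else np.atleast_1d(cutpoints)
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    if not (np.isfinite(l) and np.isfinite(delta_i) and np.isfinite(eps_j)):
        raise ValidationError("non-finite input to class_probs")
    bpad = _padded_cutpoints(np.asarray(b, dtype=float))
    h = (bpad - l + delta_i + eps_j) / sigma  # h[0] = -inf, h[K] = +inf
    cum = np.concatenate(([0.0], ndtr(h[1:-1]), [1.0]))
    interval = np.diff(cum)  # interval k-1 -> internal class k
    return interval[::-1]  # internal class K-w  <->  user weight w


def class_prob_matrix(params: ModelParams, variant: str = "lsm") -> ClassProbabilities:
    """All-edge class probabilities f (p x p x K, user coding).

    The diagonal is computed like any cell but is meaningless (self-
    connections are never modelled); callers must mask it.
    """
    L = model_distance(params, variant)
    a = -L + params.delta[:, None] + params.eps[None, :]
    bpad = _padded_cutpoints(params.b)
    h = (bpad[None, None, :] + a[:, :, None]) / params.sigma
    cum = np.empty_like(h)
    cum[..., 0] = 0.0
    cum[..., -1] = 1.0
    cum[..., 1:-1] = ndtr(h[..., 1:-1])
    interval = np.diff(cum, axis=-1)
    return ClassProbabilities(interval[..., ::-1])


def expected_weight(f: ClassProbabilities | np.ndarray) -> np.ndarray:
    """Posterior-free expected ordinal weight sum_k k * f_k per edge."""
    arr = f.f if isinstance(f, ClassProbabilities) else np.asarray(f)
    k = np.arange(arr.shape[-1])
    return arr @ k


# --------------------------------------------------------------------------
# likelihood, prior, posterior
# --------------------------------------------------------------------------


def _edge_bounds(
    w: np.ndarray, K: int, bpad: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cutpoint bounds of the probit interval for user weights w."""
    k = K - w  # internal class index, 1..K
    return bpad[k - 1], bpad[k], k - 1, k


def _loglik_edges(
    L: np.ndarray, params: ModelParams, ii, jj, w, want_grad: bool
):
    """Log-likelihood (and edge-level gradient pieces) for observed edges.

    Returns ``(ll, Ge, grad_b, grad_sigma)`` where ``Ge`` is the per-edge
    derivative of the log-probability with respect to the additive term
    (-l_ij + delta_i + eps_j); the chain rule to Z / effects / Lambda is
    applied by the caller.
    """
    K = params.K
    sigma = params.sigma
    bpad = _padded_cutpoints(params.b)
    b_lo, b_up, idx_lo, idx_up = _edge_bounds(w, K, bpad)
    a = -L[ii, jj] + params.delta[ii] + params.eps[jj]
    lo = (b_lo + a) / sigma
    up = (b_up + a) / sigma
    logP = _log_interval_prob(lo, up)
    ll = float(np.sum(logP))
    if not want_grad:
        return ll, None, None, None

    # phi/P ratios; a -inf logP (zero-mass interval, state rejected by the
    # sampler anyway) gets gradient 0 rather than overflowing
    with np.errstate(invalid="ignore", over="ignore"):
        lr_up = _log_norm_pdf(up) - logP
        lr_lo = _log_norm_pdf(lo) - logP
        r_up = np.where(
            np.isfinite(lr_up), np.exp(np.minimum(lr_up, 700.0)), 0.0
        )
        r_lo = np.where(
            np.isfinite(lr_lo), np.exp(np.minimum(lr_lo, 700.0)), 0.0
        )
    Ge = (r_up - r_lo) / sigma

    grad_b = np.zeros(K - 1)
    fin_up = idx_up <= K - 1
    fin_lo = idx_lo >= 1
    np.add.at(grad_b, idx_up[fin_up] - 1, r_up[fin_up] / sigma)
    np.add.at(grad_b, idx_lo[fin_lo] - 1, -r_lo[fin_lo] / sigma)

    up_term = np.zeros_like(up)
    fu = np.isfinite(up)
    up_term[fu] = up[fu] * r_up[fu]
    lo_term = np.zeros_like(lo)
    fl = np.isfinite(lo)
    lo_term[fl] = lo[fl] * r_lo[fl]
    grad_sigma = float(np.sum(-up_term + lo_term) / sigma)
    return ll, Ge, grad_b, grad_sigma


def _check_observed_weights(data: OrdinalConnectome, K: int) -> None:
    w = data.weights[data.observed_mask]
    if w.size and (w.min() < 0 or w.max() >= K):
        raise ValidationError("observed weight outside 0..K-1")


def log_likelihood(
    params: ModelParams,
    data: OrdinalConnectome,
    variant: str = "lsm",
    second_modality: OrdinalConnectome | None = None,
) -> float:
    """Categorical log-likelihood over observed cells.

    Unobserved cells contribute exactly 0.  With a second modality, its
    observed cells are added using the *same* per-edge probability vector
    (fusion shares one latent configuration across tracer directions).
    """
    ll, _ = loglik_and_grad(params, data, variant, second_modality,
                            want_grad=False)
    return ll


def loglik_and_grad(
    params: ModelParams,
    data: OrdinalConnectome,
    variant: str = "lsm",
    second_modality: OrdinalConnectome | None = None,
    want_grad: bool = True,
):
    """Log-likelihood and its gradient w.r.t. the constrained parameters.

    Gradient keys: ``Z`` (p x D), ``b`` (K-1), ``delta``/``eps`` (p, full
    length; clamped entries' components are computed but ignored by the
    sampler), ``sigma`` (scalar), ``lam`` (D, eigenmodel only).
    """
    _check_observed_weights(data, params.K)
    L = model_distance(params, variant)
    p, D = params.p, params.D

    modalities = [data] + ([second_modality] if second_modality is not None else [])
    ll_total = 0.0
    if want_grad:
        gZ = np.zeros((p, D))
        gb = np.zeros(params.K - 1)
        gd = np.zeros(p)
        ge = np.zeros(p)
        gs = 0.0
        glam = np.zeros(D) if variant == "eigenmodel" else None

    for m in modalities:
        _check_observed_weights(m, params.K)
        edges = m.observed_edges()
        if edges.size == 0:
            continue
        ii, jj = edges[:, 0], edges[:, 1]
        w = m.weights[ii, jj]
        ll, Ge, grad_b, grad_sigma = _loglik_edges(L, params, ii, jj, w, want_grad)
        ll_total += ll
        if not want_grad:
            continue
        gb += grad_b
        gs += grad_sigma
        np.add.at(gd, ii, Ge)
        np.add.at(ge, jj, Ge)
        gl_edge = -Ge  # dlogP/d l_ij
        if variant == "eigenmodel":
            # l = -z_i^T Lam z_j
            zi, zj = params.Z[ii], params.Z[jj]
            contrib_i = gl_edge[:, None] * (-(params.lam * zj))
            contrib_j = gl_edge[:, None] * (-(params.lam * zi))
            np.add.at(gZ, ii, contrib_i)
            np.add.at(gZ, jj, contrib_j)
            glam += -np.sum(gl_edge[:, None] * zi * zj, axis=0)
        elif variant != "zero_dim" and D > 0:
            l_e = L[ii, jj]
            safe = np.where(l_e > 0, l_e, 1.0)
            diff = (params.Z[ii] - params.Z[jj]) / safe[:, None]
            diff[l_e == 0] = 0.0
            contrib = gl_edge[:, None] * diff
            np.add.at(gZ, ii, contrib)
            np.add.at(gZ, jj, -contrib)

    if not want_grad:
        return ll_total, None
    grads = {"Z": gZ, "b": gb, "delta": gd, "eps": ge, "sigma": gs}
    if variant == "eigenmodel":
        grads["lam"] = glam
    return ll_total, grads


def _half_normal_logpdf(x, scale) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0,
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def _normal_logpdf(x, scale) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return -0.5 * (x / scale) ** 2 - np.log(scale) - _LOG_SQRT_2PI


def log_prior(
    params: ModelParams,
    hyper: Hyperparams,
    variant: str = "lsm",
    tau_delta: float | None = None,
    tau_eps: float | None = None,
) -> float:
    """Log prior density of the constrained parameters.

    The effect scales tau may be supplied (hierarchical treatment, with
    half-Normal(0, effect_scale) hyperpriors added); when omitted, effects
    are scored against a fixed Normal(0, effect_scale^2).  Clamped effect
    entries contribute no terms.  Returns -inf outside the support
    (sigma <= 0 or non-increasing cutpoints).
    """
    if params.sigma <= 0:
        return -np.inf
    b = params.b
    if b.size > 1 and not np.all(np.diff(b) > 0):
        return -np.inf

    lp = 0.0
    if variant in ("lsm", "eigenmodel") and params.D > 0:
        lp += float(np.sum(_normal_logpdf(params.Z, hyper.z_scale)))
    if variant == "eigenmodel" and params.lam is not None:
        lp += float(np.sum(_normal_logpdf(params.lam, hyper.lam_scale)))

    lp += float(_normal_logpdf(b[0], hyper.cut_loc_scale))
    if b.size > 1:
        lp += float(np.sum(_half_normal_logpdf(np.diff(b), hyper.cut_inc_scale)))

    for vec, active, tau in (
        (params.delta, params.effects.active_delta, tau_delta),
        (params.eps, params.effects.active_eps, tau_eps),
    ):
        scale = hyper.effect_scale if tau is None else tau
        if tau is not None:
            hp = float(_half_normal_logpdf(tau, hyper.effect_scale))
            if not np.isfinite(hp):
                return -np.inf
            lp += hp
        if active.any():
            lp += float(np.sum(_normal_logpdf(vec[active], scale)))

    if not hyper.fix_sigma:
        lp += float(_half_normal_logpdf(params.sigma, hyper.sigma_scale))
    return lp


def log_posterior(
    params: ModelParams,
    data: OrdinalConnectome,
    hyper: Hyperparams,
    variant: str = "lsm",
    second_modality: OrdinalConnectome | None = None,
    **tau_kwargs,
) -> float:
    """log_likelihood + log_prior (the sampler's target, up to Jacobians
    of its unconstrained reparameterization)."""
    lp = log_prior(params, hyper, variant, **tau_kwargs)
    if not np.isfinite(lp):
        return lp
    return lp + log_likelihood(params, data, variant, second_modality)
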