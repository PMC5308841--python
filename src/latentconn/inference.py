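"""Posterior sampling by Hamiltonian Monte Carlo with analytic gradients.

The sampler targets the log-posterior of :mod:`latentconn.model` on an
unconstrained reparameterization:

* cutpoints via ``(b_1, log increments)`` so ordering is automatic;
* effect scales ``tau`` and (optionally) ``sigma`` via log transforms;
* sender/receiver effects non-centered (``delta = tau * raw``) to avoid
  the hierarchical funnel.

Adaptation follows standard practice: dual-averaged step size targeting
0.8 acceptance, a diagonal mass matrix estimated midway through warmup,
and jittered leapfrog path lengths to avoid periodic trajectories.
Unobserved connection weights are imputed per draw from the categorical
edge distribution (exact marginalization over the discrete outcome), so
no discrete parameters are ever sampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as _m
from .errors import ValidationError
from .io import AnatomicalPositions, OrdinalConnectome, RunConfig

logger = logging.getLogger("latentconn")

ADAPT_TARGET_ACCEPT = 0.8
MAX_LEAPFROG = 32
MAX_INIT_RETRIES = 20
DIVERGENCE_ENERGY = 1000.0


# --------------------------------------------------------------------------
# posterior sample container
# --------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """T posterior draws of the model parameters plus per-draw imputed
    weights for every unobserved cell, and a snapshot of the data and
    configuration that produced them."""

    variant: str
    n_classes: int
    node_labels: list[str]
    config: RunConfig
    Z: np.ndarray            # (T, p, D)
    b: np.ndarray            # (T, K-1)
    sigma: np.ndarray        # (T,)
    delta: np.ndarray        # (T, p)
    eps: np.ndarray          # (T, p)
    tau_delta: np.ndarray    # (T,)
    tau_eps: np.ndarray      # (T,)
    chain_id: np.ndarray     # (T,)
    imputed: np.ndarray      # (T, M) imputed weights for unobserved cells
    unobserved_edges: np.ndarray  # (M, 2)
    observed_weights: np.ndarray  # (p, p)
    observed_mask: np.ndarray     # (p, p)
    active_delta: np.ndarray      # (p,)
    active_eps: np.ndarray        # (p,)
    lam: np.ndarray | None = None  # (T, D), eigenmodel only
    divergences: np.ndarray | None = None  # per chain
    accept_rate: np.ndarray | None = None  # per chain

    @property
    def n_draws(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.chain_id.size else 1

    def params_at(self, t: int) -> _m.ModelParams:
        lam = None if self.lam is None else self.lam[t]
        return _m.ModelParams(
            embedding=_m.LatentEmbedding(self.Z[t]),
            cutpoints=_m.Cutpoints(self.b[t]),
            sigma=float(self.sigma[t]),
            effects=_m.RandomEffects(
                self.delta[t], self.eps[t], self.active_delta, self.active_eps
            ),
            lam=lam,
        )

    def data_snapshot(self) -> OrdinalConnectome:
        return OrdinalConnectome(
            list(self.node_labels),
            self.observed_weights,
            self.observed_mask,
            self.n_classes,
        )

    def distance_draws(self) -> np.ndarray:
        """(T, p, p) per-draw (generalized) distance matrices."""
        out = np.empty((self.n_draws, self.p, self.p))
        for t in range(self.n_draws):
            out[t] = _m.model_distance(self.params_at(t), self.variant)
        return out

    def f_draws(self, dtype=np.float64) -> np.ndarray:
        """(T, p, p, K) per-draw class-probability arrays (user coding)."""
        T, p, K = self.n_draws, self.p, self.n_classes
        out = np.empty((T, p, p, K), dtype=dtype)
        for t in range(T):
            out[t] = _m.class_prob_matrix(self.params_at(t), self.variant).f
        return out

    # -- archive plumbing --------------------------------------------------

    _ARRAY_FIELDS = (
        "Z", "b", "sigma", "delta", "eps", "tau_delta", "tau_eps",
        "chain_id", "imputed", "unobserved_edges", "observed_weights",
        "observed_mask", "active_delta", "active_eps", "lam",
        "divergences", "accept_rate",
    )

    def arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name in self._ARRAY_FIELDS:
            v = getattr(self, name)
            if v is not None:
                out[name] = np.asarray(v)
        return out

    @classmethod
    def from_arrays(cls, variant, n_classes, node_labels, config, arrays):
        kwargs = {k: arrays.get(k) for k in cls._ARRAY_FIELDS}
        return cls(
            variant=variant,
            n_classes=n_classes,
            node_labels=list(node_labels),
            config=config,
            **kwargs,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PosteriorSamples):
            return NotImplemented
        if (self.variant, self.n_classes, self.node_labels) != (
            other.variant, other.n_classes, other.node_labels
        ) or self.config != other.config:
            return False
        a, b = self.arrays(), other.arrays()
        if set(a) != set(b):
            return False
        for k in a:
            eq_nan = np.issubdtype(a[k].dtype, np.floating)
            if not np.array_equal(a[k], b[k], equal_nan=eq_nan):
                return False
        return True


# --------------------------------------------------------------------------
# unconstrained parameterization
# --------------------------------------------------------------------------


class _ParamLayout:
    """Packing/unpacking of the unconstrained HMC state vector."""

    def __init__(
        self,
        p: int,
        D: int,
        K: int,
        variant: str,
        active_delta: np.ndarray,
        active_eps: np.ndarray,
        hyper: _m.Hyperparams,
        fixed_Z: np.ndarray | None = None,
    ):
        self.p, self.D, self.K = p, D, K
        self.variant = variant
        self.active_delta = active_delta
        self.active_eps = active_eps
        self.hyper = hyper
        self.fixed_Z = fixed_Z
        self.sample_Z = variant in ("lsm", "eigenmodel") and D > 0
        self.sample_lam = variant == "eigenmodel"
        self.n_ad = int(active_delta.sum())
        self.n_ae = int(active_eps.sum())

        n = 0
        self.sl = {}

        def block(name, size):
            nonlocal n
            self.sl[name] = slice(n, n + size)
            n += size

        if self.sample_Z:
            block("Z", p * D)
        block("c", K - 1)
        if self.n_ad:
            block("raw_d", self.n_ad)
            block("u_td", 1)
        if self.n_ae:
            block("raw_e", self.n_ae)
            block("u_te", 1)
        if not hyper.fix_sigma:
            block("u_s", 1)
        if self.sample_lam:
            block("lam", D)
        self.dim = n
        self._edge_cache: list[dict] | None = None

    def bind(self, data, second) -> None:
        """Precompute per-modality edge indices for the sampler's hot
        loop (probit interval bounds depend only on the observed
        weights, so their cutpoint indices are fixed)."""
        self._edge_cache = []
        for m in [data] + ([second] if second is not None else []):
            edges = m.observed_edges()
            ii, jj = edges[:, 0], edges[:, 1]
            w = m.weights[ii, jj]
            k = self.K - w  # internal class (1..K)
            self._edge_cache.append({
                "ii": ii, "jj": jj,
                "idx_lo": k - 1, "idx_up": k,  # into [-inf, b..., +inf]
                "fin_lo": k - 1 >= 1, "fin_up": k <= self.K - 1,
            })

    def init_from_prior(self, rng: np.random.Generator) -> np.ndarray:
        h = self.hyper
        theta = np.empty(self.dim)
        if self.sample_Z:
            theta[self.sl["Z"]] = rng.normal(0, h.z_scale, self.p * self.D)
        c = np.empty(self.K - 1)
        c[0] = rng.normal(0, h.cut_loc_scale)
        if self.K > 2:
            c[1:] = np.log(np.abs(rng.normal(0, h.cut_inc_scale, self.K - 2)))
        theta[self.sl["c"]] = c
        if self.n_ad:
            theta[self.sl["raw_d"]] = rng.normal(0, 1, self.n_ad)
            theta[self.sl["u_td"]] = np.log(np.abs(rng.normal(0, h.effect_scale)))
        if self.n_ae:
            theta[self.sl["raw_e"]] = rng.normal(0, 1, self.n_ae)
            theta[self.sl["u_te"]] = np.log(np.abs(rng.normal(0, h.effect_scale)))
        if not h.fix_sigma:
            theta[self.sl["u_s"]] = np.log(np.abs(rng.normal(0, h.sigma_scale)))
        if self.sample_lam:
            theta[self.sl["lam"]] = rng.normal(0, h.lam_scale, self.D)
        return theta

    def _raw_state(self, theta: np.ndarray):
        """theta -> (Z, b, delta, eps, sigma, lam, tau_d, tau_e) without
        container construction (used in the sampler hot loop)."""
        h = self.hyper
        if self.sample_Z:
            Z = theta[self.sl["Z"]].reshape(self.p, self.D)
        elif self.fixed_Z is not None:
            Z = self.fixed_Z
        else:
            Z = np.zeros((self.p, 0))
        c = theta[self.sl["c"]]
        b = np.empty(self.K - 1)
        b[0] = c[0]
        if self.K > 2:
            b[1:] = c[0] + np.cumsum(np.exp(np.minimum(c[1:], 700.0)))
        delta = np.zeros(self.p)
        eps = np.zeros(self.p)
        tau_d = tau_e = None
        with np.errstate(over="ignore"):  # out-of-support states rejected later
            if self.n_ad:
                tau_d = float(np.exp(min(theta[self.sl["u_td"]][0], 700.0)))
                delta[self.active_delta] = tau_d * theta[self.sl["raw_d"]]
            if self.n_ae:
                tau_e = float(np.exp(min(theta[self.sl["u_te"]][0], 700.0)))
                eps[self.active_eps] = tau_e * theta[self.sl["raw_e"]]
        sigma = (
            1.0 if h.fix_sigma
            else float(np.exp(min(theta[self.sl["u_s"]][0], 700.0)))
        )
        lam = theta[self.sl["lam"]].copy() if self.sample_lam else None
        return Z, b, delta, eps, sigma, lam, tau_d, tau_e

    def unpack(self, theta: np.ndarray):
        """theta -> (ModelParams, tau_delta, tau_eps)."""
        Z, b, delta, eps, sigma, lam, tau_d, tau_e = self._raw_state(theta)
        params = _m.ModelParams(
            embedding=_m.LatentEmbedding(Z),
            cutpoints=_m.Cutpoints(b),
            sigma=sigma,
            effects=_m.RandomEffects(
                delta, eps, self.active_delta, self.active_eps
            ),
            lam=lam,
        )
        return params, tau_d, tau_e

    def _fast_loglik(self, Z, b, delta, eps, sigma, lam):
        """Likelihood + gradients over the pre-bound edge caches,
        avoiding per-call container construction (sampler hot loop)."""
        p, D, K = self.p, self.D, self.K
        if self.variant == "eigenmodel":
            L = -(Z * lam) @ Z.T
        elif self.variant == "zero_dim" or D == 0:
            L = None
        else:
            diff = Z[:, None, :] - Z[None, :, :]
            L = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        bpad = np.concatenate(([-np.inf], b, [np.inf]))

        ll = 0.0
        gZ = np.zeros((p, D))
        gb = np.zeros(K - 1)
        gd = np.zeros(p)
        ge = np.zeros(p)
        gs = 0.0
        glam = np.zeros(D) if self.sample_lam else None

        for c in self._edge_cache:
            ii, jj = c["ii"], c["jj"]
            l_e = 0.0 if L is None else L[ii, jj]
            a = -l_e + delta[ii] + eps[jj]
            lo = (bpad[c["idx_lo"]] + a) / sigma
            up = (bpad[c["idx_up"]] + a) / sigma
            logP = _m._log_interval_prob(lo, up)
            ll += float(logP.sum())
            with np.errstate(invalid="ignore", over="ignore"):
                lr_up = _m._log_norm_pdf(up) - logP
                lr_lo = _m._log_norm_pdf(lo) - logP
                r_up = np.where(
                    np.isfinite(lr_up), np.exp(np.minimum(lr_up, 700.0)), 0.0
                )
                r_lo = np.where(
                    np.isfinite(lr_lo), np.exp(np.minimum(lr_lo, 700.0)), 0.0
                )
            Ge = (r_up - r_lo) / sigma
            fu, fl = c["fin_up"], c["fin_lo"]
            gb += np.bincount(c["idx_up"][fu] - 1, weights=r_up[fu],
                              minlength=K - 1) / sigma
            gb -= np.bincount(c["idx_lo"][fl] - 1, weights=r_lo[fl],
                              minlength=K - 1) / sigma
            gd += np.bincount(ii, weights=Ge, minlength=p)
            ge += np.bincount(jj, weights=Ge, minlength=p)
            if not self.hyper.fix_sigma:
                gs += float(
                    (-(up[fu] * r_up[fu]).sum() + (lo[fl] * r_lo[fl]).sum())
                    / sigma
                )
            gl = -Ge  # dlogP/d l_ij
            if self.variant == "eigenmodel":
                zi, zj = Z[ii], Z[jj]
                ci = gl[:, None] * (-(lam * zj))
                cj = gl[:, None] * (-(lam * zi))
                for d in range(D):
                    gZ[:, d] += np.bincount(ii, weights=ci[:, d], minlength=p)
                    gZ[:, d] += np.bincount(jj, weights=cj[:, d], minlength=p)
                glam += -np.sum(gl[:, None] * zi * zj, axis=0)
            elif L is not None and self.sample_Z:
                coef = np.where(l_e > 0, gl / np.where(l_e > 0, l_e, 1.0), 0.0)
                for d in range(D):
                    t = coef * (Z[ii, d] - Z[jj, d])
                    col = np.bincount(ii, weights=t, minlength=p)
                    col -= np.bincount(jj, weights=t, minlength=p)
                    gZ[:, d] += col
        g = {"Z": gZ, "b": gb, "delta": gd, "eps": ge, "sigma": gs}
        if glam is not None:
            g["lam"] = glam
        return ll, g

    def logpost_and_grad(self, theta, data, second):
        """Unconstrained-space log density (posterior + Jacobians) and
        its gradient."""
        h = self.hyper
        Z, b, delta, eps, sigma, lam, tau_d, tau_e = self._raw_state(theta)
        # Extreme leapfrog excursions can overflow the transforms or
        # underflow the cutpoint increments into ties.  Beyond ~1e8 the
        # prior density underflows double precision anyway, so such
        # states are rejected as zero-density.
        BIG = 1e8
        if not (
            np.all(np.abs(b) < BIG)
            and (b.size < 2 or np.all(np.diff(b) > 0))
            and np.all(np.abs(delta) < BIG)
            and np.all(np.abs(eps) < BIG)
            and 0 < sigma < BIG
            and (tau_d is None or tau_d < BIG)
            and (tau_e is None or tau_e < BIG)
        ):
            return -np.inf, np.zeros(self.dim)
        if self._edge_cache is not None:
            ll, g = self._fast_loglik(Z, b, delta, eps, sigma, lam)
        else:
            params, _, _ = self.unpack(theta)
            ll, g = _m.loglik_and_grad(params, data, self.variant, second)
        lp = ll
        grad = np.zeros(self.dim)

        # --- Z ---
        if self.sample_Z:
            Zflat = theta[self.sl["Z"]]
            lp += -0.5 * float(Zflat @ Zflat) / h.z_scale**2
            grad[self.sl["Z"]] = g["Z"].ravel() - Zflat / h.z_scale**2

        # --- cutpoints ---
        c = theta[self.sl["c"]]
        gb = g["b"]
        gc = np.empty_like(c)
        gc[0] = gb.sum()
        lp += -0.5 * (c[0] / h.cut_loc_scale) ** 2
        gc[0] += -c[0] / h.cut_loc_scale**2
        if self.K > 2:
            inc = np.exp(c[1:])
            # half-Normal prior on increments + log-Jacobian of exp
            lp += float(np.sum(-0.5 * (inc / h.cut_inc_scale) ** 2 + c[1:]))
            tail = np.cumsum(gb[::-1])[::-1]  # sum(gb[k:]) for k = 1..K-2
            gc[1:] = inc * tail[1:] + (-(inc / h.cut_inc_scale) ** 2 + 1.0)
        grad[self.sl["c"]] = gc

        # --- random effects (non-centered) ---
        for pre, active, tau, key in (
            ("d", self.active_delta, tau_d, "delta"),
            ("e", self.active_eps, tau_e, "eps"),
        ):
            if tau is None:
                continue
            raw = theta[self.sl[f"raw_{pre}"]]
            g_eff = g[key][active]
            lp += -0.5 * float(raw @ raw)
            grad[self.sl[f"raw_{pre}"]] = tau * g_eff - raw
            lp += -0.5 * (tau / h.effect_scale) ** 2 + theta[self.sl[f"u_t{pre}"]][0]
            grad[self.sl[f"u_t{pre}"]] = (
                tau * float(raw @ g_eff) - (tau / h.effect_scale) ** 2 + 1.0
            )

        # --- sigma ---
        if not h.fix_sigma:
            lp += (
                -0.5 * (sigma / h.sigma_scale) ** 2 + theta[self.sl["u_s"]][0]
            )
            grad[self.sl["u_s"]] = (
                sigma * g["sigma"] - (sigma / h.sigma_scale) ** 2 + 1.0
            )

        # --- eigen spectrum ---
        if self.sample_lam:
            lam = theta[self.sl["lam"]]
            lp += -0.5 * float(lam @ lam) / h.lam_scale**2
            grad[self.sl["lam"]] = g["lam"] - lam / h.lam_scale**2

        return lp, grad


# --------------------------------------------------------------------------
# HMC core
# --------------------------------------------------------------------------


def _leapfrog(theta, r, eps, n_steps, m_inv, grad_fn):
    lp, grad = grad_fn(theta)
    for _ in range(n_steps):
        r = r + 0.5 * eps * grad
        theta = theta + eps * m_inv * r
        lp, grad = grad_fn(theta)
        if not np.isfinite(lp):
            return theta, r, lp, grad
        r = r + 0.5 * eps * grad
    return theta, r, lp, grad


def _find_initial_step(theta, lp0, m_inv, grad_fn, rng):
    eps = 1.0
    r0 = rng.normal(size=theta.size) / np.sqrt(m_inv)
    h0 = lp0 - 0.5 * float(r0 * m_inv @ r0)
    t1, r1, lp1, _ = _leapfrog(theta, r0, eps, 1, m_inv, grad_fn)
    h1 = lp1 - 0.5 * float(r1 * m_inv @ r1) if np.isfinite(lp1) else -np.inf
    log_ratio = h1 - h0
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        t1, r1, lp1, _ = _leapfrog(theta, r0, eps, 1, m_inv, grad_fn)
        h1 = lp1 - 0.5 * float(r1 * m_inv @ r1) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


@dataclass
class _DualAveraging:
    mu: float
    target: float = ADAPT_TARGET_ACCEPT
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))


def _run_chain(layout, data, second, n_warmup, n_samples, rng, max_leapfrog):
    grad_fn = lambda th: layout.logpost_and_grad(th, data, second)

    theta = None
    for _ in range(MAX_INIT_RETRIES):
        cand = layout.init_from_prior(rng)
        lp, grad = grad_fn(cand)
        if np.isfinite(lp) and np.all(np.isfinite(grad)):
            theta = cand
            break
    if theta is None:
        raise ValidationError(
            "could not find a finite initialization after "
            f"{MAX_INIT_RETRIES} prior draws"
        )

    m_inv = np.ones(layout.dim)
    eps = _find_initial_step(theta, lp, m_inv, grad_fn, rng)
    da = _DualAveraging(mu=np.log(10 * eps))

    half = n_warmup // 2
    window_start = max(1, n_warmup // 4)
    window: list[np.ndarray] = []
    divergences = 0
    accepts = []
    draws = np.empty((n_samples, layout.dim))
    lp_cur = lp

    total = n_warmup + n_samples
    for it in range(total):
        warming = it < n_warmup
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        r0 = rng.normal(size=layout.dim) / np.sqrt(m_inv)
        h0 = lp_cur - 0.5 * float(r0 * m_inv @ r0)
        theta_new, r_new, lp_new, _ = _leapfrog(
            theta, r0, eps, n_steps, m_inv, grad_fn
        )
        if np.isfinite(lp_new):
            h1 = lp_new - 0.5 * float(r_new * m_inv @ r_new)
            d_energy = h1 - h0
        else:
            d_energy = -np.inf
        if not np.isfinite(d_energy) or d_energy < -DIVERGENCE_ENERGY:
            accept_prob = 0.0
            if not warming:
                divergences += 1
        else:
            accept_prob = min(1.0, float(np.exp(min(d_energy, 0.0))))
        if rng.random() < accept_prob:
            theta, lp_cur = theta_new, lp_new

        if warming:
            eps = da.update(accept_prob)
            if window_start <= it < half:
                window.append(theta.copy())
            if it == half - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                n = len(window)
                m_inv = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                eps = _find_initial_step(theta, lp_cur, m_inv, grad_fn, rng)
                da = _DualAveraging(mu=np.log(10 * eps))
            if it == n_warmup - 1:
                eps = float(np.exp(da.log_eps_bar))
        else:
            accepts.append(accept_prob)
            draws[it - n_warmup] = theta

    return draws, divergences, float(np.mean(accepts)) if accepts else 0.0


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------


def _active_effects(
    data: OrdinalConnectome, second: OrdinalConnectome | None
) -> tuple[np.ndarray, np.ndarray]:
    """A node's sender (receiver) effect is free only if it has at least
    one observed outgoing (incoming) connection; others are clamped to 0."""
    mask = data.observed_mask.copy()
    if second is not None:
        mask |= second.observed_mask
    return mask.any(axis=1), mask.any(axis=0)


def sample_posterior(
    data: OrdinalConnectome,
    config: RunConfig,
    hyper: _m.Hyperparams | None = None,
    second_modality: OrdinalConnectome | None = None,
    positions: AnatomicalPositions | None = None,
    max_leapfrog: int = MAX_LEAPFROG,
) -> PosteriorSamples:
    """Draw posterior samples of the model parameters by HMC.

    ``config.model_variant`` selects the model; ``fixed_positions``
    requires anatomical ``positions`` (centered and globally rescaled to
    unit RMS pairwise distance so that the cutpoint priors stay sensible
    regardless of physical units).  A ``second_modality`` connectome (same
    labels and K) switches on fusion: both matrices share each edge's
    probability vector.  The run is reproducible: a fixed ``config.seed``
    yields bit-identical draws on the same platform.
    """
    if hyper is None:
        hyper = _m.Hyperparams(**config.hyper) if config.hyper else _m.Hyperparams()
    variant = config.model_variant
    if variant == "empirical":
        raise ValidationError(
            "the empirical-frequency baseline has no posterior; use "
            "latentconn.baselines.empirical_frequency"
        )
    if second_modality is not None:
        if second_modality.node_labels != data.node_labels:
            raise ValidationError("fusion modalities must share node labels")
        if second_modality.n_classes != data.n_classes:
            raise ValidationError("fusion modalities must share K")

    p, K = data.p, data.n_classes
    D = 0 if variant == "zero_dim" else config.latent_dim
    fixed_Z = None
    if variant == "fixed_positions":
        if positions is None:
            raise ValidationError("fixed_positions variant requires positions")
        pos = positions.reorder(data.node_labels)
        fixed_Z = standardize_positions(pos.coords)
        D = fixed_Z.shape[1]

    active_d, active_e = _active_effects(data, second_modality)
    layout = _ParamLayout(p, D, K, variant, active_d, active_e, hyper, fixed_Z)
    layout.bind(data, second_modality)

    n_chains = config.n_chains
    per_chain = config.n_samples
    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(n_chains + 1)

    all_draws, divs, acc = [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        draws, ndiv, arate = _run_chain(
            layout, data, second_modality, config.n_warmup, per_chain,
            rng, max_leapfrog,
        )
        logger.info(
            "chain %d/%d: accept=%.2f divergences=%d", c + 1, n_chains,
            arate, ndiv,
        )
        all_draws.append(draws)
        divs.append(ndiv)
        acc.append(arate)
    theta_draws = np.concatenate(all_draws, axis=0)
    T = theta_draws.shape[0]

    Z = np.empty((T, p, D))
    b = np.empty((T, K - 1))
    sig = np.empty(T)
    delta = np.empty((T, p))
    epsv = np.empty((T, p))
    tau_d_a = np.full(T, np.nan)
    tau_e_a = np.full(T, np.nan)
    lam = np.empty((T, D)) if layout.sample_lam else None
    for t in range(T):
        params, td, te = layout.unpack(theta_draws[t])
        Z[t] = params.Z
        b[t] = params.b
        sig[t] = params.sigma
        delta[t] = params.delta
        epsv[t] = params.eps
        if td is not None:
            tau_d_a[t] = td
        if te is not None:
            tau_e_a[t] = te
        if lam is not None:
            lam[t] = params.lam

    samples = PosteriorSamples(
        variant=variant,
        n_classes=K,
        node_labels=list(data.node_labels),
        config=config,
        Z=Z, b=b, sigma=sig, delta=delta, eps=epsv,
        tau_delta=tau_d_a, tau_eps=tau_e_a,
        chain_id=np.repeat(np.arange(n_chains), per_chain),
        imputed=np.empty((T, 0), dtype=np.int64),
        unobserved_edges=np.empty((0, 2), dtype=np.int64),
        observed_weights=data.weights.copy(),
        observed_mask=data.observed_mask.copy(),
        active_delta=active_d,
        active_eps=active_e,
        lam=lam,
        divergences=np.asarray(divs),
        accept_rate=np.asarray(acc),
    )
    _impute_unobserved(samples, np.random.default_rng(chain_seeds[-1]))
    return samples


def standardize_positions(coords: np.ndarray) -> np.ndarray:
    """Center centroids and rescale globally to unit RMS pairwise
    distance (units differ across atlases; sigma and b absorb residual
    scale)."""
    X = np.asarray(coords, dtype=float)
    X = X - X.mean(axis=0)
    d = _m.latent_distance(X)
    iu = np.triu_indices(X.shape[0], 1)
    rms = np.sqrt(np.mean(d[iu] ** 2))
    if rms == 0:
        return X
    return X / rms


def _impute_unobserved(samples: PosteriorSamples, rng: np.random.Generator):
    p = samples.p
    off = ~np.eye(p, dtype=bool)
    unobs = np.argwhere(off & ~samples.observed_mask)
    samples.unobserved_edges = unobs
    T, M, K = samples.n_draws, unobs.shape[0], samples.n_classes
    imp = np.empty((T, M), dtype=np.int64)
    if M:
        for t in range(T):
            f = _m.class_prob_matrix(samples.params_at(t), samples.variant).f
            fe = f[unobs[:, 0], unobs[:, 1], :]
            cum = np.cumsum(fe, axis=1)
            u = rng.random(M)
            imp[t] = np.minimum((u[:, None] > cum).sum(axis=1), K - 1)
    samples.imputed = imp


# --------------------------------------------------------------------------
# convergence diagnostics
# --------------------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    """Split-R-hat and effective sample size for identifiable posterior
    summaries (distances, cutpoints, effects) -- never for raw latent
    coordinates, which are non-identifiable up to rigid motions."""

    table: pd.DataFrame
    divergences: np.ndarray | None = None

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.table["rhat"].to_numpy()))

    @property
    def min_ess(self) -> float:
        return float(np.nanmin(self.table["ess"].to_numpy()))


def diagnose(samples: PosteriorSamples, max_pairs: int = 100) -> DiagnosticsReport:
    """Compute split-R-hat and bulk ESS per monitored scalar quantity.

    Monitored quantities: pairwise distances (a deterministic subset of
    at most ``max_pairs`` node pairs), cutpoints, active random effects,
    and sigma when sampled.  With a single chain, R-hat is omitted with a
    warning.
    """
    import arviz as az

    n_chains = samples.n_chains
    T = samples.n_draws
    per_chain = T // n_chains
    if per_chain * n_chains != T:
        raise ValidationError("draws are not evenly divided across chains")

    quantities: dict[str, np.ndarray] = {}
    p = samples.p
    iu = np.array(np.triu_indices(p, 1)).T
    if len(iu) > max_pairs:
        sel = np.random.default_rng(0).choice(len(iu), max_pairs, replace=False)
        iu = iu[np.sort(sel)]
    dists = samples.distance_draws()
    for i, j in iu:
        quantities[f"l[{i},{j}]"] = dists[:, i, j]
    for k in range(samples.b.shape[1]):
        quantities[f"b[{k + 1}]"] = samples.b[:, k]
    for i in np.flatnonzero(samples.active_delta):
        quantities[f"delta[{i}]"] = samples.delta[:, i]
    for j in np.flatnonzero(samples.active_eps):
        quantities[f"eps[{j}]"] = samples.eps[:, j]
    if np.ptp(samples.sigma) > 0:
        quantities["sigma"] = samples.sigma

    rows = []
    single = n_chains < 2
    if single:
        warnings.warn(
            "R-hat requires at least two chains; reporting ESS only",
            stacklevel=2,
        )
    for name, v in quantities.items():
        if np.ptp(v) == 0:  # constant: no convergence information
            continue
        byc = v.reshape(n_chains, per_chain)
        ess = float(az.ess(np.asarray(byc)))
        rhat = np.nan if single else float(az.rhat(np.asarray(byc)))
        rows.append({"parameter": name, "rhat": rhat, "ess": ess})
    return DiagnosticsReport(
        table=pd.DataFrame(rows), divergences=samples.divergences
    )
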