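"""Ground-truth simulation from the exact generative model: parameter
generation, ordinal connectome sampling (one or two tracer modalities
sharing the same edge probabilities), and the tracer-study observation
designs (full, injection, random fraction).

Two parameter modes exist:

* ``"calibrated"`` (default) -- fixed, realistic settings emulating the
  fitted models on real tracer data: latent positions from the standard
  normal prior, cutpoints spread over the bulk of the latent distance
  distribution so every ordinal class is populated, a noise scale small
  enough for crisp class boundaries, and small hub effects (a few
  percent of the maximum distance).
* ``"prior"`` -- a draw from the model's actual priors; used for
  prior-predictive and calibration checks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import model as _m
from .errors import ValidationError
from .io import OrdinalConnectome

CALIBRATED_SIGMA = 0.5
CALIBRATED_EFFECT_SD = 0.15


def _labels(p: int) -> list[str]:
    return [f"R{i:02d}" for i in range(p)]


@dataclass
class SyntheticInstance:
    """A simulated ground truth plus its (possibly masked) observations.

    ``true_weights[m]`` holds the complete weight matrix of modality m;
    ``connectomes[m]`` the corresponding observed data after the design
    mask.  All randomness descends from ``seed`` through independent
    spawned substreams.
    """

    params: _m.ModelParams
    variant: str
    true_weights: list[np.ndarray]
    connectomes: list[OrdinalConnectome]
    seed: int
    design: str = "full"
    meta: dict = field(default_factory=dict)

    @property
    def data(self) -> OrdinalConnectome:
        return self.connectomes[0]

    @property
    def second(self) -> OrdinalConnectome | None:
        return self.connectomes[1] if len(self.connectomes) > 1 else None

    def true_distances(self) -> np.ndarray:
        return _m.model_distance(self.params, self.variant)


def generate_params(
    p: int,
    D: int,
    K: int,
    hyper: _m.Hyperparams | None = None,
    seed: int = 0,
    mode: str = "calibrated",
    variant: str = "lsm",
) -> _m.ModelParams:
    """Draw a ground-truth parameter set.

    In ``"prior"`` mode every component follows the model's documented
    priors.  In ``"calibrated"`` mode only the latent positions are drawn
    (from their Normal(0, z_scale^2) prior); cutpoints, sigma and effect
    scale take the fixed realistic values described in the module
    docstring.
    """
    if p < 2 or K < 2 or D < 0:
        raise ValidationError("need p >= 2, K >= 2, D >= 0")
    hyper = hyper or _m.Hyperparams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    Z = rng.normal(0, hyper.z_scale, size=(p, D))

    if mode == "calibrated":
        # RMS distance between two N(0, I_D) points is sqrt(2 D)
        m = np.sqrt(2.0 * max(D, 1)) * hyper.z_scale
        if K == 2:
            b = np.array([0.75 * m])
        else:
            b = m * np.linspace(0.4, 1.1, K - 1)
        sigma = CALIBRATED_SIGMA
        delta = rng.normal(0, CALIBRATED_EFFECT_SD, p)
        eps = rng.normal(0, CALIBRATED_EFFECT_SD, p)
        lam = np.ones(D) if variant == "eigenmodel" else None
    elif mode == "prior":
        b = np.empty(K - 1)
        b[0] = rng.normal(0, hyper.cut_loc_scale)
        if K > 2:
            b[1:] = b[0] + np.cumsum(
                np.abs(rng.normal(0, hyper.cut_inc_scale, K - 2))
            )
        sigma = (
            1.0 if hyper.fix_sigma
            else float(np.abs(rng.normal(0, hyper.sigma_scale)))
        )
        tau_d = float(np.abs(rng.normal(0, hyper.effect_scale)))
        tau_e = float(np.abs(rng.normal(0, hyper.effect_scale)))
        delta = rng.normal(0, tau_d, p)
        eps = rng.normal(0, tau_e, p)
        lam = rng.normal(0, hyper.lam_scale, D) if variant == "eigenmodel" else None
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    return _m.ModelParams(
        embedding=_m.LatentEmbedding(Z),
        cutpoints=_m.Cutpoints(b),
        sigma=float(sigma),
        effects=_m.RandomEffects(delta, eps),
        lam=lam,
    )


def generate_connectome(
    params: _m.ModelParams,
    seed: int = 0,
    modalities: int = 1,
    variant: str = "lsm",
    labels: list[str] | None = None,
) -> SyntheticInstance:
    """Sample one or two complete ordinal connectomes from the model.

    Every off-diagonal weight is an independent categorical draw from
    the edge's class-probability vector; with ``modalities = 2`` the two
    matrices are independent draws from the SAME probabilities, so their
    disagreements emulate anterograde/retrograde tracer variability.
    """
    if modalities not in (1, 2):
        raise ValidationError("modalities must be 1 or 2")
    p, K = params.p, params.K
    labels = list(labels) if labels is not None else _labels(p)
    f = _m.class_prob_matrix(params, variant).f
    off = ~np.eye(p, dtype=bool)
    cum = np.cumsum(f, axis=-1)

    ss = np.random.SeedSequence(seed).spawn(modalities)
    true_weights, connectomes = [], []
    for m in range(modalities):
        rng = np.random.default_rng(ss[m])
        u = rng.random((p, p))
        w = np.minimum((u[:, :, None] > cum).sum(axis=-1), K - 1)
        w[~off] = 0
        true_weights.append(w.astype(np.int64))
        connectomes.append(
            OrdinalConnectome(labels, w.astype(np.int64), off.copy(), K)
        )
    return SyntheticInstance(
        params=params,
        variant=variant,
        true_weights=true_weights,
        connectomes=connectomes,
        seed=seed,
    )


def apply_design(
    instance: SyntheticInstance,
    design,
    seed: int | None = None,
) -> SyntheticInstance:
    """Mask a complete instance per an observation design.

    ``design`` is ``"full"``, ``("injection", sources, targets)`` (label
    lists or leading counts; only cells source x target are observed, as
    when tracers are injected into a subset of regions), or
    ``("random_fraction", q)`` keeping a random fraction 0 < q <= 1 of
    off-diagonal cells.  The mask is applied to every modality.
    """
    data = instance.data
    p = data.p
    off = ~np.eye(p, dtype=bool)

    if design == "full" or design == ("full",):
        mask = off.copy()
        desc = "full"
    elif isinstance(design, tuple) and design[0] == "injection":
        _, sources, targets = design
        labels = data.node_labels
        if isinstance(sources, (int, np.integer)):
            sources = labels[: int(sources)]
        if isinstance(targets, (int, np.integer)):
            targets = labels[: int(targets)]
        bad = sorted((set(sources) | set(targets)) - set(labels))
        if bad:
            raise ValidationError(f"design labels outside node list: {bad}")
        s_idx = [labels.index(s) for s in sources]
        t_idx = [labels.index(t) for t in targets]
        mask = np.zeros((p, p), dtype=bool)
        mask[np.ix_(s_idx, t_idx)] = True
        mask &= off
        desc = f"injection({len(s_idx)}x{len(t_idx)})"
    elif isinstance(design, tuple) and design[0] == "random_fraction":
        _, q = design
        if not 0 < q <= 1:
            raise ValidationError("fraction must satisfy 0 < q <= 1")
        rng = np.random.default_rng(
            instance.seed + 1 if seed is None else seed
        )
        cells = np.argwhere(off)
        n_keep = int(round(q * len(cells)))
        keep = rng.choice(len(cells), size=n_keep, replace=False)
        mask = np.zeros((p, p), dtype=bool)
        mask[cells[keep, 0], cells[keep, 1]] = True
        desc = f"random_fraction({q})"
    else:
        raise ValidationError(f"unknown design {design!r}")

    if not mask.any():
        raise ValidationError("design leaves no observed cells")

    new_conn = [
        OrdinalConnectome(list(c.node_labels), w.copy(), mask.copy(),
                          c.n_classes)
        for c, w in zip(instance.connectomes, instance.true_weights)
    ]
    return SyntheticInstance(
        params=instance.params,
        variant=instance.variant,
        true_weights=[w.copy() for w in instance.true_weights],
        connectomes=new_conn,
        seed=instance.seed,
        design=desc,
        meta=dict(instance.meta),
    )


# --------------------------------------------------------------------------
# named presets mirroring the tracer-study designs
# --------------------------------------------------------------------------

#: (p, K, D, modalities, design), full-size and reduced test-size variants
PRESETS = {
    "visual": {
        "full": (32, 2, 2, 1, ("random_fraction", 653 / 992)),
        "reduced": (12, 2, 2, 1, ("random_fraction", 653 / 992)),
    },
    "cerebral": {
        "full": (91, 4, 3, 1, ("injection", 91, 29)),
        "reduced": (20, 4, 2, 1, ("injection", 20, 7)),
    },
    "mouse": {
        "full": (49, 4, 2, 2, "full"),
        "reduced": (14, 4, 2, 2, "full"),
    },
}


def preset_instance(
    name: str, seed: int = 0, reduced: bool = False
) -> SyntheticInstance:
    """A named synthetic instance emulating one of the tracer studies:
    ``"visual"`` (binary, partially probed at the empirical fraction),
    ``"cerebral"`` (K = 4, injection design: all regions as sources, a
    leading subset as injected targets) or ``"mouse"`` (K = 4, fully
    observed, two modalities).  ``reduced`` selects a small variant for
    fast tests; the sizes used are recorded in ``instance.meta``.
    """
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    p, K, D, modalities, design = PRESETS[name]["reduced" if reduced else "full"]
    name_key = zlib.crc32(name.encode()) % (2**31)
    ss = np.random.SeedSequence([seed, name_key]).generate_state(2)
    params = generate_params(p, D, K, seed=int(ss[0]))
    inst = generate_connectome(
        params, seed=int(ss[1]), modalities=modalities
    )
    inst = apply_design(inst, design)
    inst.meta.update(
        {"preset": name, "reduced": reduced, "p": p, "K": K, "D": D,
         "modalities": modalities}
    )
    return inst
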