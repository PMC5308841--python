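"""Cross-validation over observed connections, error measures, latent
dimensionality selection, and analytic observation-design accounting.

Error measures (per held-out edge set F):

* ``mae`` -- mean absolute difference between per-draw predicted and
  observed ordinal weights, averaged over draws (the conservative
  per-sample form; Bayesian averaging first would shrink it).
* ``fpr`` / ``fnr`` -- per-draw false-positive rate (false presences /
  truly absent edges) and false-negative rate (false absences / truly
  present edges), averaged over draws.  Presence means weight > 0.
* ``nll`` -- negative log posterior-mean class probability of the
  observed weight, normalized by |F|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as _m
from .errors import ValidationError
from .inference import PosteriorSamples, sample_posterior
from .io import AnatomicalPositions, OrdinalConnectome, RunConfig

NLL_FLOOR = 1e-12
METRICS = ("nll", "mae", "fpr", "fnr")
BAYESIAN_VARIANTS = ("lsm", "eigenmodel", "zero_dim", "fixed_positions")


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------


@dataclass
class CVFold:
    """One cross-validation fold: the held-out directed edges F."""

    edges: np.ndarray  # (|F|, 2) (source, target) pairs
    index: int
    seed: int

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)


def make_folds(
    data: OrdinalConnectome, n_folds: int, seed: int
) -> list[CVFold]:
    """Partition the observed off-diagonal cells into ``n_folds`` random
    folds of near-equal size (differing by at most one edge)."""
    edges = data.observed_edges()
    if len(edges) < n_folds:
        raise ValidationError(
            f"{len(edges)} observed edges cannot form {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    return [
        CVFold(edges[chunk], i, seed)
        for i, chunk in enumerate(np.array_split(perm, n_folds))
    ]


# --------------------------------------------------------------------------
# error measures
# --------------------------------------------------------------------------


def mae(imputed_draws: np.ndarray, observed: np.ndarray) -> float:
    """Per-draw mean absolute error, averaged over draws.

    ``imputed_draws`` is (T, |F|); ``observed`` is (|F|,).
    """
    imputed_draws = np.atleast_2d(np.asarray(imputed_draws))
    observed = np.asarray(observed)
    if observed.size == 0:
        raise ValidationError("empty held-out edge set")
    return float(np.mean(np.abs(imputed_draws - observed[None, :])))


def fpr_fnr(
    imputed_draws: np.ndarray, observed: np.ndarray
) -> tuple[float, float]:
    """Per-draw false positive / negative rates, averaged over draws.

    Rates are relative to the counts of truly absent / truly present
    edges in F.  If a side has no edges its rate is undefined (NaN, with
    a warning).
    """
    imputed_draws = np.atleast_2d(np.asarray(imputed_draws))
    observed = np.asarray(observed)
    if observed.size == 0:
        raise ValidationError("empty held-out edge set")
    absent = observed == 0
    present = ~absent
    n_absent, n_present = int(absent.sum()), int(present.sum())
    pred_present = imputed_draws > 0

    if n_absent:
        fp = (pred_present & absent[None, :]).sum(axis=1)
        fpr = float(np.mean(fp / n_absent))
    else:
        warnings.warn("no truly absent edges in fold; FPR undefined",
                      stacklevel=2)
        fpr = float("nan")
    if n_present:
        fn = (~pred_present & present[None, :]).sum(axis=1)
        fnr = float(np.mean(fn / n_present))
    else:
        warnings.warn("no truly present edges in fold; FNR undefined",
                      stacklevel=2)
        fnr = float("nan")
    return fpr, fnr


def held_out_nll(f_mean: np.ndarray, observed: np.ndarray) -> float:
    """Negative log posterior-mean probability of the observed weights,
    normalized by |F|; probabilities are floored at 1e-12 (with warning)
    so a degenerate prediction yields a finite score."""
    f_mean = np.atleast_2d(np.asarray(f_mean, dtype=float))
    observed = np.asarray(observed, dtype=int)
    if observed.size == 0:
        raise ValidationError("empty held-out edge set")
    probs = f_mean[np.arange(observed.size), observed]
    if np.any(probs < NLL_FLOOR):
        warnings.warn(
            "zero (or underflowing) predicted probability at an observed "
            f"class; clamped at {NLL_FLOOR}",
            stacklevel=2,
        )
        probs = np.maximum(probs, NLL_FLOOR)
    return float(-np.mean(np.log(probs)))


# --------------------------------------------------------------------------
# cross-validation sweep
# --------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Tidy per-(model, D, fold) metrics with summaries and the selected
    latent dimensionality D-hat (argmin of mean held-out NLL)."""

    table: pd.DataFrame  # columns: model, D, fold, metric, value
    selected_D: int
    selection_model: str = "lsm"

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["model", "D", "metric"])["value"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def mean_metric(self, model: str, D: int, metric: str) -> float:
        sel = self.table[
            (self.table["model"] == model)
            & (self.table["D"] == D)
            & (self.table["metric"] == metric)
        ]
        return float(sel["value"].mean())


def _metric_block(f_mean, imputed, observed) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # one-sided groups
        fpr, fnr = fpr_fnr(imputed, observed)
    return {
        "nll": held_out_nll(f_mean, observed),
        "mae": mae(imputed, observed),
        "fpr": fpr,
        "fnr": fnr,
    }


def _fold_metrics_bayesian(
    samples: PosteriorSamples,
    fold: CVFold,
    observed: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, float]:
    ii, jj = fold.edges[:, 0], fold.edges[:, 1]
    f_draws = samples.f_draws()[:, ii, jj, :]  # (T, |F|, K)
    f_mean = f_draws.mean(axis=0)
    # map fold edges onto the imputation table of the masked training run
    lookup = {
        (int(i), int(j)): m
        for m, (i, j) in enumerate(samples.unobserved_edges)
    }
    cols = [lookup[(int(i), int(j))] for i, j in fold.edges]
    imputed = samples.imputed[:, cols]
    fpr, fnr = fpr_fnr(imputed, observed)
    metrics = {
        "nll": held_out_nll(f_mean, observed),
        "mae": mae(imputed, observed),
        "fpr": fpr,
        "fnr": fnr,
    }
    if groups is not None:
        # breakdown: edges whose opposite direction was also observed
        # vs those observed in one direction only
        for name, sel in (("bidir", groups), ("onedir", ~groups)):
            if sel.any():
                sub = _metric_block(
                    f_mean[sel], imputed[:, sel], observed[sel]
                )
                metrics.update({f"{k}_{name}": v for k, v in sub.items()})
    return metrics


def _fold_metrics_empirical(
    train: OrdinalConnectome,
    fold: CVFold,
    observed: np.ndarray,
    n_draws: int,
    seed: int,
) -> dict[str, float]:
    from .baselines import empirical_frequency

    f = empirical_frequency(train).f[0, 1]  # shared vector
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(f), size=(n_draws, len(observed)), p=f)
    f_mean = np.tile(f, (len(observed), 1))
    fpr, fnr = fpr_fnr(draws, observed)
    return {
        "nll": held_out_nll(f_mean, observed),
        "mae": mae(draws, observed),
        "fpr": fpr,
        "fnr": fnr,
    }


def crossval_sweep(
    data: OrdinalConnectome,
    config: RunConfig,
    D_values=(1, 2, 3, 4, 5),
    models=("lsm",),
    n_folds: int = 10,
    hyper: _m.Hyperparams | None = None,
    positions: AnatomicalPositions | None = None,
    second_modality: OrdinalConnectome | None = None,
    selection_model: str = "lsm",
    reciprocity_breakdown: bool = False,
) -> EvaluationReport:
    """Cross-validate every (model, D) combination over shared folds.

    For each fold the held-out edges are masked as unobserved in the
    training data (the only train/test difference), the model is fitted,
    and NLL / MAE / FPR / FNR are computed on the held-out edges.  D-hat
    is the D minimizing the selection model's mean held-out NLL.  Models
    without a latent dimension (``zero_dim``, ``empirical``,
    ``fixed_positions``) are evaluated once and their scores replicated
    across D for comparison tables.  With ``reciprocity_breakdown``,
    Bayesian models additionally emit each metric split into held-out
    edges observed in both directions vs one direction only (metric
    names suffixed ``_bidir`` / ``_onedir``).
    """
    folds = make_folds(data, n_folds, seed=config.seed)
    D_values = list(D_values)
    rows = []
    dimless = {"zero_dim", "empirical", "fixed_positions"}

    for m_idx, model_name in enumerate(models):
        eff_D = [D_values[0]] if model_name in dimless else D_values
        for D in eff_D:
            for fold in folds:
                train = data.mask_edges(fold.edges)
                observed = data.weights[fold.edges[:, 0], fold.edges[:, 1]]
                run_seed = int(
                    (config.seed * 1000003 + fold.index * 9973
                     + D * 131 + m_idx * 17) % (2**31)
                )
                if model_name == "empirical":
                    metrics = _fold_metrics_empirical(
                        train, fold, observed,
                        n_draws=config.n_samples * config.n_chains,
                        seed=run_seed,
                    )
                else:
                    sub = RunConfig(
                        latent_dim=D,
                        n_chains=config.n_chains,
                        n_warmup=config.n_warmup,
                        n_samples=config.n_samples,
                        seed=run_seed,
                        model_variant=model_name,
                        fusion=config.fusion,
                        hyper=dict(config.hyper),
                    )
                    samples = sample_posterior(
                        train, sub, hyper=hyper,
                        second_modality=second_modality,
                        positions=positions,
                    )
                    groups = (
                        reciprocity_groups(data, fold.edges)
                        if reciprocity_breakdown else None
                    )
                    metrics = _fold_metrics_bayesian(
                        samples, fold, observed, groups=groups
                    )
                for metric, value in metrics.items():
                    rows.append({
                        "model": model_name, "D": D, "fold": fold.index,
                        "metric": metric, "value": value,
                    })
        if model_name in dimless and len(D_values) > 1:
            base = [r for r in rows
                    if r["model"] == model_name and r["D"] == D_values[0]]
            for D in D_values[1:]:
                rows.extend([{**r, "D": D} for r in base])

    table = pd.DataFrame(rows)
    if selection_model in models:
        nll = (
            table[(table["model"] == selection_model)
                  & (table["metric"] == "nll")]
            .groupby("D")["value"].mean()
        )
        selected = int(nll.idxmin())
    else:
        selected = D_values[0]
    return EvaluationReport(table=table, selected_D=selected,
                            selection_model=selection_model)


def reciprocity_groups(
    data: OrdinalConnectome, edges: np.ndarray
) -> np.ndarray:
    """For each directed edge (i, j), True when the opposite direction
    (j, i) is also observed -- the basis for breaking down performance
    into reciprocally vs singly observed connections."""
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    return data.observed_mask[edges[:, 1], edges[:, 0]]


# --------------------------------------------------------------------------
# observation-design accounting
# --------------------------------------------------------------------------


def design_counts(
    p: int, sources, targets, labels: list[str] | None = None
) -> tuple[int, int, int]:
    """Analytic connection counts of a tracer observation design.

    ``sources`` / ``targets`` are either integer counts or label
    collections.  Observed = |S x T| minus the diagonal cells |S & T|;
    with plain counts the target set is assumed nested in the source set
    (the injection designs), so the overlap is min(s, t).  Returns
    (possible, observed, unobserved) with possible = p (p - 1).
    """
    if isinstance(sources, (int, np.integer)):
        n_s = int(sources)
        overlap_known = None
    else:
        sources = [str(s) for s in sources]
        if labels is not None:
            bad = sorted(set(sources) - set(labels))
            if bad:
                raise ValidationError(f"source labels outside region list: {bad}")
        n_s = len(set(sources))
        overlap_known = set(sources)
    if isinstance(targets, (int, np.integer)):
        n_t = int(targets)
        overlap = min(n_s, n_t) if overlap_known is None else None
        if overlap is None:
            raise ValidationError(
                "mixing a label set with a plain count is ambiguous"
            )
    else:
        targets = [str(t) for t in targets]
        if labels is not None:
            bad = sorted(set(targets) - set(labels))
            if bad:
                raise ValidationError(f"target labels outside region list: {bad}")
        n_t = len(set(targets))
        if overlap_known is None:
            raise ValidationError(
                "mixing a label set with a plain count is ambiguous"
            )
        overlap = len(overlap_known & set(targets))
    if n_s > p or n_t > p:
        raise ValidationError("source/target count exceeds p")
    possible = p * (p - 1)
    observed = n_s * n_t - overlap
    return possible, observed, possible - observed
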