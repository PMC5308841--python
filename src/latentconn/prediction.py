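"""Turning posterior samples into completed connectomes, per-edge class
probabilities, credible-interval uncertainty maps and degree summaries.

Conventions: for observed cells the per-draw weight is the observed
weight itself (prediction never overrides data); for unobserved cells it
is the per-draw imputation.  The expected connectome A-hat is the draw
average, so it is real-valued in [0, K-1].  Edge uncertainty is a
credible measure: the width of the central 95% interval of the class
probability across draws, maximized over the K classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .inference import PosteriorSamples
from .io import OrdinalConnectome

CI_LEVEL = 0.95
MIN_DRAWS_FOR_QUANTILES = 40
DEFAULT_PRESENCE_CUTOFF = 0.5


@dataclass
class PredictionReport:
    """Posterior summaries of the completed connectome.

    ``expected`` -- A-hat, draw-mean weight per cell (NaN diagonal);
    ``f_mean`` -- draw-mean class probabilities (p, p, K);
    ``uncertainty`` -- max-over-classes 95% CI width of f (NaN diagonal);
    ``modal`` -- most probable class under f_mean (-1 on the diagonal);
    ``present_prob`` -- draw-mean of the indicator weight > 0.
    """

    node_labels: list[str]
    n_classes: int
    expected: np.ndarray
    f_mean: np.ndarray
    uncertainty: np.ndarray
    modal: np.ndarray
    present_prob: np.ndarray
    observed_mask: np.ndarray

    @property
    def p(self) -> int:
        return len(self.node_labels)


def _weight_draws(samples: PosteriorSamples) -> np.ndarray:
    """(T, p, p) per-draw completed weight matrices: observed cells keep
    their observed weight in every draw, unobserved cells take the
    imputed draw.  The diagonal is left at 0 and must be masked."""
    T, p = samples.n_draws, samples.p
    W = np.broadcast_to(
        samples.observed_weights * samples.observed_mask, (T, p, p)
    ).copy()
    ue = samples.unobserved_edges
    if ue.size:
        W[:, ue[:, 0], ue[:, 1]] = samples.imputed
    return W


def predict_edges(samples: PosteriorSamples) -> PredictionReport:
    """Aggregate posterior draws into a :class:`PredictionReport`."""
    p = samples.p
    diag = np.eye(p, dtype=bool)
    W = _weight_draws(samples)

    expected = W.mean(axis=0)
    present_prob = (W > 0).mean(axis=0)
    f_draws = samples.f_draws()
    f_mean = f_draws.mean(axis=0)
    unc = _uncertainty_from_f(f_draws)
    modal = np.argmax(f_mean, axis=-1)

    expected[diag] = np.nan
    present_prob[diag] = np.nan
    unc[diag] = np.nan
    modal = modal.astype(np.int64)
    modal[diag] = -1
    f_mean[diag] = np.nan
    return PredictionReport(
        node_labels=list(samples.node_labels),
        n_classes=samples.n_classes,
        expected=expected,
        f_mean=f_mean,
        uncertainty=unc,
        modal=modal,
        present_prob=present_prob,
        observed_mask=samples.observed_mask.copy(),
    )


def _uncertainty_from_f(f_draws: np.ndarray) -> np.ndarray:
    lo, hi = np.quantile(
        f_draws, [(1 - CI_LEVEL) / 2, 1 - (1 - CI_LEVEL) / 2], axis=0
    )
    return (hi - lo).max(axis=-1)


def edge_uncertainty(samples: PosteriorSamples) -> np.ndarray:
    """p x p map of 95% credible-interval widths of the class
    probabilities, maximized over classes (NaN diagonal)."""
    if samples.n_draws < MIN_DRAWS_FOR_QUANTILES:
        warnings.warn(
            f"only {samples.n_draws} draws; 95% interval endpoints are "
            "unstable below 40",
            stacklevel=2,
        )
    unc = _uncertainty_from_f(samples.f_draws())
    unc[np.eye(samples.p, dtype=bool)] = np.nan
    return unc


def relative_degree(
    source: OrdinalConnectome | PredictionReport,
    direction: str = "outgoing",
    presence_threshold: float = DEFAULT_PRESENCE_CUTOFF,
) -> np.ndarray:
    """Per-node relative degree: present connections / candidate
    connections.

    For an observed-only connectome the denominator counts *observed*
    candidate cells for that node and direction (a node with none gets
    NaN); for a completed prediction every off-diagonal cell is a
    candidate (denominator p - 1) and an edge counts as present when its
    draw-fraction of presence exceeds ``presence_threshold``.
    """
    if direction not in ("outgoing", "incoming"):
        raise ValidationError("direction must be 'outgoing' or 'incoming'")
    axis = 1 if direction == "outgoing" else 0

    if isinstance(source, OrdinalConnectome):
        present = (source.weights > 0) & source.observed_mask
        candidates = source.observed_mask.sum(axis=axis).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = present.sum(axis=axis) / candidates
        out[candidates == 0] = np.nan
        return out

    if isinstance(source, PredictionReport):
        p = source.p
        hard = source.present_prob > presence_threshold
        hard &= ~np.eye(p, dtype=bool)
        return hard.sum(axis=axis) / float(p - 1)

    raise ValidationError(f"unsupported input type {type(source).__name__}")


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------


def edge_table(report: PredictionReport) -> pd.DataFrame:
    """Long-form per-edge table: source, target, f per class, expected
    weight, modal class, uncertainty, observed flag."""
    p, K = report.p, report.n_classes
    ii, jj = np.where(~np.eye(p, dtype=bool))
    rows = {
        "source": [report.node_labels[i] for i in ii],
        "target": [report.node_labels[j] for j in jj],
        "expected": report.expected[ii, jj],
        "modal": report.modal[ii, jj],
        "uncertainty": report.uncertainty[ii, jj],
        "present_prob": report.present_prob[ii, jj],
        "observed": report.observed_mask[ii, jj],
    }
    for k in range(K):
        rows[f"f{k}"] = report.f_mean[ii, jj, k]
    return pd.DataFrame(rows)


def write_report(report: PredictionReport, directory, missing_code="NA") -> dict:
    """Write the report as three matrices + a long-form edge table."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def matrix(name, values, fmt):
        path = directory / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write("," + ",".join(report.node_labels) + "\n")
            for i, lab in enumerate(report.node_labels):
                cells = [
                    missing_code if not np.isfinite(v) and fmt is float
                    else (f"{v:.6g}" if fmt is float else str(int(v)))
                    for v in values[i]
                ]
                fh.write(lab + "," + ",".join(cells) + "\n")
        paths[name] = path

    matrix("expected_weights", report.expected, float)
    matrix("modal_class", report.modal, int)
    matrix("uncertainty", report.uncertainty, float)
    table_path = directory / "edges.csv"
    edge_table(report).to_csv(table_path, index=False)
    paths["edges"] = table_path
    return paths


def modal_connectome(report: PredictionReport) -> OrdinalConnectome:
    """Hard completed connectome from the modal class (all off-diagonal
    cells observed)."""
    p = report.p
    w = np.where(report.modal >= 0, report.modal, 0)
    mask = ~np.eye(p, dtype=bool)
    return OrdinalConnectome(list(report.node_labels), w, mask, report.n_classes)
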