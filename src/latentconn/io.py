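"""Reading and writing of connectome matrices, centroid tables, run
configuration and posterior sample archives.

File dialect
------------
Matrices are delimited text (comma or tab, auto-detected): the first row
holds target labels, the first column source labels, and cell (i, j) the
ordinal weight of the directed connection *i -> j*.  Unobserved cells carry
a missing token (default ``"NA"``).  The diagonal (self-connections) is
never treated as observed regardless of file content.

Rectangular observation blocks -- e.g. a tracer study in which all *p*
regions are potential sources but only a subset was injected as targets --
are supported by passing the full node-label list; cells outside the block
become unobserved.
"""

from __future__ import annotations

import csv
import dataclasses
import io as _io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ArchiveError, LabelMismatchError, ParseError, ValidationError

ARCHIVE_VERSION = 1
DEFAULT_MISSING = "NA"

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class OrdinalConnectome:
    """A directed, ordinal-weighted, partially observed connectome.

    ``weights[i, j]`` is the ordinal class of the connection i -> j, coded
    0 .. K-1 with 0 = absent; it is only meaningful where
    ``observed_mask[i, j]`` is True.  The diagonal is never observed.
    """

    node_labels: list[str]
    weights: np.ndarray
    observed_mask: np.ndarray
    n_classes: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.int64)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        p = len(self.node_labels)
        if self.weights.shape != (p, p) or self.observed_mask.shape != (p, p):
            raise ValidationError(
                f"weights/mask shape must be ({p}, {p}); got "
                f"{self.weights.shape} and {self.observed_mask.shape}"
            )
        if len(set(self.node_labels)) != p:
            raise ValidationError("duplicate node labels")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.observed_mask.diagonal().any():
            raise ValidationError("diagonal entries cannot be observed")
        w = self.weights[self.observed_mask]
        if w.size and (w.min() < 0 or w.max() >= self.n_classes):
            raise ValidationError(
                f"observed weights must lie in 0..{self.n_classes - 1}"
            )

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def observed_edges(self) -> np.ndarray:
        """(n_observed, 2) array of (source, target) index pairs."""
        return np.argwhere(self.observed_mask)

    def copy(self) -> "OrdinalConnectome":
        return OrdinalConnectome(
            list(self.node_labels),
            self.weights.copy(),
            self.observed_mask.copy(),
            self.n_classes,
        )

    def mask_edges(self, edges: np.ndarray) -> "OrdinalConnectome":
        """Return a copy with the given (i, j) pairs marked unobserved."""
        out = self.copy()
        edges = np.asarray(edges, dtype=int)
        out.observed_mask[edges[:, 0], edges[:, 1]] = False
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, OrdinalConnectome):
            return NotImplemented
        return (
            self.node_labels == other.node_labels
            and self.n_classes == other.n_classes
            and np.array_equal(self.observed_mask, other.observed_mask)
            and np.array_equal(
                self.weights[self.observed_mask], other.weights[other.observed_mask]
            )
        )


@dataclass
class AnatomicalPositions:
    """Region centroids in physical space (2D or 3D), used by the
    fixed-position model and as a Procrustes reference."""

    node_labels: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        p = len(self.node_labels)
        if len(set(self.node_labels)) != p:
            raise ValidationError("duplicate node labels in positions")
        if self.coords.ndim != 2 or self.coords.shape[0] != p:
            raise ValidationError("coords must be (p, dim)")
        if self.coords.shape[1] not in (2, 3):
            raise ValidationError("coords must be 2- or 3-dimensional")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate")

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def match(self, labels: list[str]) -> None:
        """Raise unless labels coincide (as sets) with a connectome's."""
        missing = sorted(set(labels) - set(self.node_labels))
        extra = sorted(set(self.node_labels) - set(labels))
        if missing or extra:
            raise LabelMismatchError(
                "centroid labels do not match connectome labels",
                offending=missing + extra,
            )

    def reorder(self, labels: list[str]) -> "AnatomicalPositions":
        self.match(labels)
        idx = [self.node_labels.index(l) for l in labels]
        return AnatomicalPositions(list(labels), self.coords[idx])


@dataclass
class RunConfig:
    """Configuration of one inference run."""

    latent_dim: int = 2
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int = 0
    model_variant: str = "lsm"
    fusion: bool = False
    hyper: dict = field(default_factory=dict)

    VARIANTS = ("lsm", "eigenmodel", "zero_dim", "fixed_positions", "empirical")

    def __post_init__(self):
        if self.latent_dim < 0:
            raise ValidationError("latent_dim must be >= 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.model_variant not in self.VARIANTS:
            raise ValidationError(
                f"unknown model_variant {self.model_variant!r}; "
                f"expected one of {self.VARIANTS}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# --------------------------------------------------------------------------
# delimited matrix I/O
# --------------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _read_rows(path) -> tuple[list[list[str]], str]:
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError("empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    rows = list(csv.reader(_io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    return rows, delim


def read_connectome(
    path,
    n_classes: int,
    missing_code: str = DEFAULT_MISSING,
    full_labels: list[str] | None = None,
) -> OrdinalConnectome:
    """Read an ordinal connectivity matrix.

    Parameters
    ----------
    path : path-like
        Delimited file; header row = target labels, first column = source
        labels, cell (i, j) = weight of i -> j or ``missing_code``.
    n_classes : int
        Number of ordinal classes K; entries must lie in 0..K-1.
    missing_code : str
        Token marking unobserved cells.
    full_labels : list of str, optional
        Complete node list for rectangular observation blocks.  Row and
        column labels of the file must be subsets; all cells outside the
        block become unobserved.
    """
    rows, _ = _read_rows(path)
    header = [c.strip() for c in rows[0]]
    targets = header[1:] if header[0] == "" or len(header) == len(rows[0]) else header
    # header row: first cell is a corner label (possibly empty)
    targets = [c.strip() for c in rows[0][1:]]
    n_t = len(targets)
    if len(set(targets)) != n_t:
        dup = sorted({t for t in targets if targets.count(t) > 1})
        raise ParseError(f"duplicated target label(s): {dup}", line=1)

    sources: list[str] = []
    cells: list[list[str]] = []
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != n_t + 1:
            raise ParseError(
                f"expected {n_t + 1} fields, found {len(row)}", line=ln
            )
        sources.append(row[0].strip())
        cells.append([c.strip() for c in row[1:]])
    if len(set(sources)) != len(sources):
        dup = sorted({s for s in sources if sources.count(s) > 1})
        raise ParseError(f"duplicated source label(s): {dup}")

    if full_labels is None:
        if sources != targets:
            raise ParseError(
                "row and column labels differ; pass full_labels for "
                "rectangular observation blocks"
            )
        labels = sources
    else:
        labels = [str(l) for l in full_labels]
        if len(set(labels)) != len(labels):
            raise ParseError("duplicated label in full_labels")
        unknown = sorted((set(sources) | set(targets)) - set(labels))
        if unknown:
            raise LabelMismatchError(
                "file labels missing from full_labels", offending=unknown
            )

    p = len(labels)
    pos = {l: i for i, l in enumerate(labels)}
    weights = np.zeros((p, p), dtype=np.int64)
    mask = np.zeros((p, p), dtype=bool)
    diag_warned = False
    for r, src in enumerate(sources):
        i = pos[src]
        for c, tgt in enumerate(targets):
            j = pos[tgt]
            tok = cells[r][c]
            if tok == missing_code:
                continue
            try:
                val = int(tok)
            except ValueError:
                raise ParseError(
                    f"non-integer entry {tok!r} at ({src!r}, {tgt!r})",
                    line=r + 2,
                ) from None
            if not 0 <= val < n_classes:
                raise ParseError(
                    f"weight {val} out of range 0..{n_classes - 1} "
                    f"at ({src!r}, {tgt!r})",
                    line=r + 2,
                )
            if i == j:
                diag_warned = True
                continue
            weights[i, j] = val
            mask[i, j] = True
    if diag_warned:
        warnings.warn(
            "diagonal entries held data; self-connections are forced "
            "unobserved",
            stacklevel=2,
        )
    return OrdinalConnectome(labels, weights, mask, n_classes)


def write_connectome(
    connectome: OrdinalConnectome,
    path,
    missing_code: str = DEFAULT_MISSING,
    delimiter: str = ",",
) -> None:
    """Write a connectome in the dialect :func:`read_connectome` accepts."""
    p = connectome.p
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow([""] + list(connectome.node_labels))
        for i in range(p):
            row = [connectome.node_labels[i]]
            for j in range(p):
                if connectome.observed_mask[i, j]:
                    row.append(str(int(connectome.weights[i, j])))
                else:
                    row.append(missing_code)
            w.writerow(row)


def read_centroids(path) -> AnatomicalPositions:
    """Read a table of region centroids: label, x, y[, z]."""
    rows, _ = _read_rows(path)

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    # optional header: a first row none of whose coordinate fields parse
    start = 0
    if len(rows[0]) >= 3 and not any(_numeric(c) for c in rows[0][1:]):
        start = 1
    labels, coords = [], []
    dim = None
    for ln, row in enumerate(rows[start:], start=start + 1):
        row = [c.strip() for c in row if c.strip() != ""]
        if len(row) not in (3, 4):
            raise ParseError(
                f"expected label + 2 or 3 coordinates, found {len(row)} fields",
                line=ln,
            )
        if dim is None:
            dim = len(row) - 1
        elif len(row) - 1 != dim:
            raise ParseError("inconsistent coordinate dimension", line=ln)
        labels.append(row[0])
        try:
            coords.append([float(c) for c in row[1:]])
        except ValueError as e:
            raise ParseError(f"non-numeric coordinate: {e}", line=ln) from None
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicated label(s): {dup}")
    return AnatomicalPositions(labels, np.asarray(coords))


def write_centroids(positions: AnatomicalPositions, path, delimiter=",") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        dim = positions.coords.shape[1]
        w.writerow(["label"] + ["xyz"[k] for k in range(dim)])
        for l, xyz in zip(positions.node_labels, positions.coords):
            w.writerow([l] + [repr(float(v)) for v in xyz])


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


def read_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ValidationError("config file must hold a mapping")
    return RunConfig.from_dict(d)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# posterior archives
# --------------------------------------------------------------------------


def archive_samples(samples, path) -> None:
    """Write a :class:`~latentconn.inference.PosteriorSamples` archive.

    A self-describing ``.npz`` container: every draw array plus a JSON
    manifest recording the archive version, run configuration (seed
    included) and array shapes, so a restore can verify integrity.
    """
    arrays = dict(samples.arrays())
    manifest = {
        "archive_version": ARCHIVE_VERSION,
        "variant": samples.variant,
        "n_classes": samples.n_classes,
        "node_labels": samples.node_labels,
        "config": samples.config.to_dict(),
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
    }
    arrays["_manifest"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def restore_samples(path):
    from .inference import PosteriorSamples  # deferred: avoid import cycle

    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as e:  # zipfile/BadZipFile/ValueError on truncation
        raise ArchiveError(f"cannot read archive {path}: {e}") from None
    if "_manifest" not in data:
        raise ArchiveError("archive has no manifest")
    manifest = json.loads(bytes(data.pop("_manifest").tobytes()).decode())
    version = manifest.get("archive_version")
    if version != ARCHIVE_VERSION:
        raise ArchiveError(
            f"archive version {version} incompatible with library "
            f"version {ARCHIVE_VERSION}"
        )
    for k, shape in manifest["shapes"].items():
        if k not in data or list(data[k].shape) != shape:
            raise ArchiveError(f"archive array {k!r} missing or misshapen")
    return PosteriorSamples.from_arrays(
        variant=manifest["variant"],
        n_classes=manifest["n_classes"],
        node_labels=manifest["node_labels"],
        config=RunConfig.from_dict(manifest["config"]),
        arrays=data,
    )
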