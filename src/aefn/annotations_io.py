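"""Readers and writers for annotation tables, feature tables and result files.

Annotation tables are delimited text (tab by default) with the instance id in
the first column and one column per annotator; cells are ``0``, ``1`` or a
missing-value code. Feature tables follow the same layout with numeric cells.
Missing labels are stored internally as ``MISSING`` (−1) and every reduction
over annotators in the rest of the package skips them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, InputError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .aggregators import AnnotatorProfile, ConsensusResult

#: Sentinel for an unobserved label cell.
MISSING: int = -1

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass(frozen=True)
class AnnotationMatrix:
    """N×R grid of binary labels ``y_i^j`` with ``MISSING`` for unobserved cells.

    Parameters
    ----------
    labels
        Integer array of shape (N, R) with values in {0, 1, MISSING}.
    instance_ids, annotator_ids
        Unique row/column identifiers, in table order.
    """

    labels: np.ndarray
    instance_ids: tuple[str, ...]
    annotator_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "instance_ids", tuple(str(s) for s in self.instance_ids))
        object.__setattr__(self, "annotator_ids", tuple(str(s) for s in self.annotator_ids))
        if labels.ndim != 2:
            raise ValidationError("labels must be a 2-D grid")
        n, r = labels.shape
        if n < 1 or r < 1:
            raise ValidationError("need at least one instance and one annotator")
        if len(self.instance_ids) != n or len(self.annotator_ids) != r:
            raise ValidationError("id lists must match the label grid shape")
        if len(set(self.instance_ids)) != n:
            raise ValidationError("instance ids must be unique")
        if len(set(self.annotator_ids)) != r:
            raise ValidationError("annotator ids must be unique")
        bad = ~np.isin(labels, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"label cell ({self.instance_ids[i]}, {self.annotator_ids[j]}) "
                f"has non-binary value {labels[i, j]}"
            )
        if (labels == MISSING).all(axis=1).any():
            i = int(np.argwhere((labels == MISSING).all(axis=1))[0][0])
            raise ValidationError(f"instance {self.instance_ids[i]!r} has no observed label")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def r(self) -> int:
        return self.labels.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed cells."""
        return self.labels != MISSING


@dataclass(frozen=True)
class FeatureMatrix:
    """N×d numeric instance features, row-aligned with an :class:`AnnotationMatrix`."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    instance_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(str(s) for s in self.feature_names))
        if values.ndim != 2:
            raise ValidationError("feature values must be a 2-D grid")
        if values.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names must match the number of columns")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(f"non-finite feature value at row {i}, column "
                                  f"{self.feature_names[j]!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def read_annotations(path, missing_code: str = "NA", sep: str = "\t") -> AnnotationMatrix:
    """Read an instance×annotator binary label table.

    The header row names the annotators; the first column holds instance ids.
    Cells equal to *missing_code* become :data:`MISSING`.
    """
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty annotation file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InputError(f"annotation file has no data rows/columns: {path}")
    labels = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        cells = df[col].str.strip()
        for i, cell in enumerate(cells):
            if cell == missing_code:
                labels[i, j] = MISSING
            elif cell in ("0", "1"):
                labels[i, j] = int(cell)
            else:
                raise FormatError(
                    f"non-binary cell {cell!r} at ({df.index[i]}, {col}) in {path}"
                )
    return AnnotationMatrix(labels, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def write_annotations(ann: AnnotationMatrix, path, missing_code: str = "NA",
                      sep: str = "\t") -> None:
    cells = ann.labels.astype(object)
    cells[ann.labels == MISSING] = missing_code
    df = pd.DataFrame(cells, index=list(ann.instance_ids), columns=list(ann.annotator_ids))
    df.to_csv(path, sep=sep, index_label="instance_id")


def read_features(path, sep: str = "\t",
                  annotations: AnnotationMatrix | None = None) -> FeatureMatrix:
    """Read an instance×feature numeric table (instance ids in the first column)."""
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty feature file: {path}") from exc
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"feature table contains non-numeric cells: {path}")
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(f"NaN/inf at ({df.index[i]}, {df.columns[j]}) in {path}")
    fm = FeatureMatrix(values, tuple(map(str, df.columns)), tuple(map(str, df.index)))
    if annotations is not None and fm.n != annotations.n:
        raise AlignmentError(
            f"feature rows ({fm.n}) do not match annotation rows ({annotations.n})"
        )
    return fm


def write_features(features: FeatureMatrix, path, sep: str = "\t") -> None:
    ids = features.instance_ids or tuple(f"i{i}" for i in range(features.n))
    df = pd.DataFrame(features.values, index=list(ids), columns=list(features.feature_names))
    df.to_csv(path, sep=sep, index_label="instance_id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# consensus-result persistence
# ---------------------------------------------------------------------------

def write_result(result: "ConsensusResult", profile: "AnnotatorProfile", path,
                 instance_ids=None, annotator_ids=None, sep: str = "\t",
                 metadata: dict | None = None) -> None:
    """Persist a consensus run as text.

    Writes three artifacts: the per-instance table at *path* (``z``, ``y_hat``,
    prior ``p``), the per-component annotator table at ``<path>.annotators.tsv``
    (α, β, S and an active/filtered status column), and run metadata at
    ``<path>.meta.json`` (thresholds, iterations, convergence trace, prior
    weights). Floats are written with full precision so
    :func:`read_result` is an exact inverse.
    """
    path = str(path)
    n = len(result.z)
    ids = list(instance_ids) if instance_ids is not None else [f"i{i}" for i in range(n)]
    inst = pd.DataFrame(
        {"z": result.z, "y_hat": result.y_hat.astype(int), "p": result.p}, index=ids
    )
    inst.to_csv(path, sep=sep, index_label="instance_id", float_format=_FLOAT_FMT)

    k, r = profile.alpha.shape
    aids = list(annotator_ids) if annotator_ids is not None else [f"ann{j}" for j in range(r)]
    rows = []
    for kk in range(k):
        for j in range(r):
            rows.append({
                "component": kk + 1,
                "annotator": aids[j],
                "alpha": profile.alpha[kk, j],
                "beta": profile.beta[kk, j],
                "score": profile.score[kk, j],
                "status": "active" if profile.active[kk, j] else "filtered",
            })
    pd.DataFrame(rows).to_csv(path + ".annotators.tsv", sep=sep, index=False,
                              float_format=_FLOAT_FMT)

    meta = {
        "gamma": result.gamma,
        "xi_prune": result.xi_prune,
        "epsilon_conv": result.epsilon_conv,
        "iterations": result.iterations,
        "converged": bool(result.converged),
        "delta_trace": [float(d) for d in result.delta_trace],
        "prior_weights": (None if result.prior_weights is None
                          else [float(w) for w in result.prior_weights]),
    }
    meta.update(metadata or {})
    with open(path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_result(path, sep: str = "\t"):
    """Read back a result written by :func:`write_result`.

    Returns ``(ConsensusResult, annotator_table, metadata)`` where the
    annotator table is a :class:`pandas.DataFrame`.
    """
    from .aggregators import ConsensusResult  # local import avoids a cycle

    path = str(path)
    inst = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    annot = pd.read_csv(path + ".annotators.tsv", sep=sep, float_precision="round_trip")
    with open(path + ".meta.json") as fh:
        meta = json.load(fh)
    result = ConsensusResult(
        z=inst["z"].to_numpy(float),
        y_hat=inst["y_hat"].to_numpy(int).astype(bool),
        p=inst["p"].to_numpy(float),
        prior_weights=(None if meta["prior_weights"] is None
                       else np.asarray(meta["prior_weights"], float)),
        iterations=int(meta["iterations"]),
        delta_trace=tuple(meta["delta_trace"]),
        gamma=float(meta["gamma"]),
        xi_prune=float(meta["xi_prune"]),
        epsilon_conv=float(meta["epsilon_conv"]),
        converged=bool(meta["converged"]),
    )
    return result, annot, meta
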