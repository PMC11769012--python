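"""Confusion-matrix accuracy assessment: PA, UA, OA and Cohen's kappa.

Orientation convention, asserted once here and tested: rows index the
reference class i, columns the predicted class j, so n_ij counts samples
with reference i and prediction j.  Producer's accuracy divides the
diagonal by the reference (row) total, user's accuracy by the predicted
(column) total.  Kappa is (po - pe)/(1 - pe) with po the observed
agreement and pe the chance agreement from the marginal products.

Per-class metrics with an empty row or column are reported as None,
never silently 0, so macro averages are not corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SchemaError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts n_ij with rows = reference class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise SchemaError("confusion matrix must be square")
        if counts.shape[0] != len(self.class_order):
            raise SchemaError("class_order length must match matrix size")
        if np.any(counts < 0):
            raise SchemaError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "class_order", tuple(self.class_order))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        """Reference totals n_i+."""
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        """Prediction totals n_+j."""
        return self.counts.sum(axis=0)


def build_confusion(reference, predicted, class_order) -> ConfusionMatrix:
    """Tally n_ij = #{samples with reference i and prediction j}."""
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise SchemaError("reference and predicted must be equal-length 1-D sequences")
    class_order = tuple(class_order)
    index = {c: k for k, c in enumerate(class_order)}
    r = len(class_order)
    counts = np.zeros((r, r), dtype=np.int64)
    for a, b in zip(ref.tolist(), pred.tolist()):
        try:
            counts[index[a], index[b]] += 1
        except KeyError as exc:
            raise SchemaError(f"label {exc.args[0]!r} not in class order {class_order}") from None
    return ConfusionMatrix(counts, class_order)


@dataclass(frozen=True)
class AccuracyReport:
    """Per-class and overall accuracies of one confusion matrix.

    ``pa``/``ua`` map class -> producer's/user's accuracy (None when the
    class has no reference/predicted samples).  ``kappa`` is None when
    chance agreement pe = 1.
    """

    pa: dict
    ua: dict
    oa: float
    po: float
    pe: float
    kappa: float | None

    def macro(self, which: str = "pa") -> float:
        """Mean of the defined per-class accuracies."""
        vals = [v for v in (self.pa if which == "pa" else self.ua).values() if v is not None]
        return float(np.mean(vals))


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """Compute PA_i, UA_i, OA, observed/chance agreement and kappa."""
    n = cm.counts
    total = cm.total
    if total == 0:
        raise SchemaError("metrics undefined for an empty confusion matrix")
    diag = np.diag(n).astype(float)
    row = cm.row_sums.astype(float)
    col = cm.col_sums.astype(float)

    pa = {
        c: (float(diag[i] / row[i]) if row[i] > 0 else None)
        for i, c in enumerate(cm.class_order)
    }
    ua = {
        c: (float(diag[j] / col[j]) if col[j] > 0 else None)
        for j, c in enumerate(cm.class_order)
    }
    po = float(diag.sum() / total)
    pe = float(np.dot(row, col) / total**2)
    kappa = None if pe >= 1.0 else float((po - pe) / (1.0 - pe))
    return AccuracyReport(pa=pa, ua=ua, oa=po, po=po, pe=pe, kappa=kappa)


def evaluate_labels(reference, predicted, class_order) -> AccuracyReport:
    """Confusion matrix + metrics in one call."""
    return accuracy_metrics(build_confusion(reference, predicted, class_order))
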