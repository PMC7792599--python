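"""Evaluation surfaces: confusion matrices, per-class and macro-averaged
sensitivity/specificity/precision/F1, cumulative accuracy over sessions,
and the difficulty↔condition association table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import InsufficientDataError, TaxonomyError
from .schema_io import LabelTaxonomy


@dataclass
class ConfusionMatrix:
    """Square count matrix in taxonomy class order; cell (i, j) counts
    records of true class i predicted as class j."""

    counts: np.ndarray
    taxonomy: LabelTaxonomy

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxonomy.classes, columns=self.taxonomy.classes
        )


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus unweighted macro averages.

    F1 is the harmonic mean of precision and sensitivity per class (0
    when both are 0); a class never predicted has precision defined as 0
    and is listed under ``undefined_precision``.  Macro averages run over
    the classes present in the true labels.
    """

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    undefined_precision: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "accuracy": self.accuracy,
            "undefined_precision": list(self.undefined_precision),
        }


def confusion(
    true_labels, predicted_labels, taxonomy: LabelTaxonomy
) -> ConfusionMatrix:
    """Tally a confusion matrix over integer class codes."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise TaxonomyError("true and predicted label sequences differ in length")
    for arr, name in ((t, "true"), (p, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= taxonomy.n_classes):
            raise TaxonomyError(f"{name} labels outside taxonomy {taxonomy.axis!r}")
    counts = _sk_confusion(t, p, labels=np.arange(taxonomy.n_classes))
    return ConfusionMatrix(counts=counts, taxonomy=taxonomy)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, precision and F1 from a confusion matrix."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    undefined = []
    present = np.flatnonzero(counts.sum(axis=1) > 0)
    for i, name in enumerate(cm.taxonomy.classes):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        if tp + fp:
            prec = tp / (tp + fp)
        else:
            prec = 0.0
            undefined.append(name)
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        per_class[name] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
        }
    names = [cm.taxonomy.classes[i] for i in present]
    macro = {
        m: float(np.mean([per_class[n][m] for n in names]))
        for m in ("sensitivity", "specificity", "precision", "f1")
    }
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        accuracy=cm.accuracy,
        undefined_precision=tuple(undefined),
    )


def cumulative_accuracy(correctness) -> np.ndarray:
    """curve_t = (Σ_{i≤t} correct_i) / t for t = 1..n."""
    c = np.asarray(correctness, dtype=float)
    if c.size == 0:
        raise InsufficientDataError("empty correctness sequence")
    return np.cumsum(c) / np.arange(1, c.size + 1)


def improvement_fraction(runs) -> float:
    """Fraction of runs whose cumulative accuracy ends at or above where
    it started (final value vs first evaluable value)."""
    if not runs:
        return 0.0
    ok = 0
    for run in runs:
        curve = cumulative_accuracy(run)
        if curve.size < 2:
            raise InsufficientDataError("each run needs length >= 2")
        ok += curve[-1] >= curve[0]
    return ok / len(runs)


def association_table(
    difficulty_predictions,
    condition_predictions,
    difficulty_taxonomy: LabelTaxonomy,
    condition_taxonomy: LabelTaxonomy,
) -> pd.DataFrame:
    """Most frequent co-predicted condition per difficulty class.

    Ties break to the lexicographically first condition name; difficulty
    classes with no sessions are omitted.
    """
    d = np.asarray(difficulty_predictions, dtype=int)
    c = np.asarray(condition_predictions, dtype=int)
    if d.shape != c.shape:
        raise TaxonomyError("prediction sequences differ in length")
    rows = []
    for code, name in enumerate(difficulty_taxonomy.classes):
        mask = d == code
        if not mask.any():
            continue
        names = sorted(condition_taxonomy.name(int(v)) for v in c[mask])
        counts = pd.Series(names).value_counts()
        top = counts.max()
        winner = sorted(n for n in counts.index if counts[n] == top)[0]
        rows.append({"difficulty": name, "condition": winner, "sessions": int(mask.sum())})
    return pd.DataFrame(rows, columns=["difficulty", "condition", "sessions"])
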