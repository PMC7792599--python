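"""Data preparation: BMI derivation, >3σ outlier removal, [−1, 1]
normalization with exact inverse, and SMOTE class balancing.

The pipeline order used throughout the package is
encode → outliers → SMOTE → normalize: interpolation happens in raw
(physical) feature space and BMI is recomputed afterwards so the
row-wise identity BMI = weight / height² stays exact at every stage.
SMOTE is applied to the whole labelled pool before any train/test split;
this balances test folds too and is logged as a leakage warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    InsufficientDataError,
    StateError,
    ValidationError,
)
from .schema_io import (
    CONTINUOUS_FEATURES,
    FEATURE_COLUMNS,
    RehabDataset,
)

logger = logging.getLogger(__name__)

OUTLIER_SIGMA = 3.0


def compute_bmi(weight, height):
    """Body mass index, weight / height² (kg/m²).

    Accepts scalars or arrays; every element must be strictly positive.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise DomainError("weight and height must be strictly positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def remove_outliers(
    dataset: RehabDataset, n_sigma: float = OUTLIER_SIGMA
) -> tuple[RehabDataset, list[int]]:
    """Drop records more than ``n_sigma`` column SDs from any column mean.

    A single pass: column means and SDs are computed once on the input
    (not re-estimated after each removal), and a record is removed iff
    any continuous feature violates the bound against those pass-one
    statistics.  The binary sex code is not screened.
    """
    if dataset.normalization is not None:
        raise StateError("outlier removal expects unnormalized data")
    if len(dataset) < 2:
        raise InsufficientDataError("need at least 2 records to estimate spread")
    feats = dataset.frame[list(CONTINUOUS_FEATURES)].to_numpy(dtype=float)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.abs(feats - mu)
        bad = (dev > n_sigma * sd) & (sd > 0)
    removed = np.flatnonzero(bad.any(axis=1))
    kept = dataset.frame.drop(index=dataset.frame.index[removed])
    return dataset.replace_frame(kept), [int(i) for i in removed]


@dataclass
class NormalizationParams:
    """Fitted per-feature (min, max) pairs for the [−1, 1] affine map."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise ValidationError(f"{name}: max {hi} < min {lo}")

    def transform_column(self, name: str, values):
        lo, hi = self.ranges[name]
        values = np.asarray(values, dtype=float)
        if hi == lo:  # degenerate constant feature maps to 0
            return np.zeros_like(values)
        return 2.0 * (values - lo) / (hi - lo) - 1.0

    def invert_column(self, name: str, values):
        lo, hi = self.ranges[name]
        values = np.asarray(values, dtype=float)
        if hi == lo:
            return np.full_like(values, lo)
        return (values + 1.0) * (hi - lo) / 2.0 + lo


def fit_normalizer(dataset: RehabDataset) -> NormalizationParams:
    """Learn per-feature min/max from a (training) dataset."""
    if len(dataset) == 0:
        raise InsufficientDataError("cannot fit a normalizer on an empty dataset")
    ranges = {}
    for col in FEATURE_COLUMNS:
        vals = dataset.frame[col].to_numpy(dtype=float)
        ranges[col] = (float(vals.min()), float(vals.max()))
    return NormalizationParams(ranges)


def apply_normalizer(
    dataset: RehabDataset, params: NormalizationParams | None
) -> RehabDataset:
    """Map each feature affinely so training min → −1 and max → +1."""
    if params is None:
        raise StateError("normalizer has not been fitted")
    frame = dataset.frame.copy()
    for col in FEATURE_COLUMNS:
        frame[col] = params.transform_column(col, frame[col])
    out = dataset.replace_frame(frame)
    out.normalization = params
    return out


def invert_normalizer(dataset: RehabDataset) -> RehabDataset:
    """Undo :func:`apply_normalizer` (identity within 1e−9)."""
    params = dataset.normalization
    if params is None:
        raise StateError("dataset is not normalized")
    frame = dataset.frame.copy()
    for col in FEATURE_COLUMNS:
        frame[col] = params.invert_column(col, frame[col])
    out = dataset.replace_frame(frame)
    out.normalization = None
    return out


@dataclass
class BalanceReport:
    """Audit record of a SMOTE balancing pass."""

    axis: str
    before: dict[str, int]
    after: dict[str, int]
    generated_per_class: dict[str, int] = field(default_factory=dict)

    @property
    def generated_total(self) -> int:
        return sum(self.generated_per_class.values())

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "before": self.before,
            "after": self.after,
            "generated_per_class": self.generated_per_class,
            "generated_total": self.generated_total,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def smote_balance(
    dataset: RehabDataset,
    label_axis: str,
    k_neighbors: int = 5,
    seed: int | None = None,
) -> tuple[RehabDataset, BalanceReport]:
    """Oversample minority classes to the majority count (SMOTE).

    Each synthetic record interpolates a minority record toward one of
    its ``k_neighbors`` nearest same-class neighbours in raw feature
    space: x_new = x + u·(x_nn − x) with u ~ U[0, 1].  BMI is then
    recomputed from the synthetic weight and height so the row identity
    BMI = weight/height² is exact, and the sex code is copied from the
    parent record (a binary code cannot be interpolated).  Majority-class
    records are never modified.
    """
    if seed is None:
        raise ValidationError("smote_balance requires an explicit seed")
    if dataset.normalization is not None:
        raise StateError("SMOTE interpolates in raw feature space")
    tax = dataset.taxonomies[label_axis]
    labels = dataset.labels(label_axis)
    counts = labels.value_counts()
    majority = int(counts.max())

    before = {tax.name(int(c)): int(n) for c, n in counts.items()}
    rng = np.random.default_rng(seed)
    logger.warning(
        "SMOTE is applied to the whole labelled pool; if this pool is later "
        "split for testing, balanced test folds share synthetic neighbours "
        "with training folds (leakage)."
    )

    new_rows: list[pd.DataFrame] = [dataset.frame]
    generated: dict[str, int] = {}
    for code, n in sorted(counts.items()):
        deficit = majority - int(n)
        if deficit == 0:
            continue
        if n < 2:
            raise ValidationError(
                f"cannot oversample class {tax.name(int(code))!r}: only {n} record(s)"
            )
        block = dataset.frame[labels == code].reset_index(drop=True)
        feats = block[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        k = min(k_neighbors, len(block) - 1)
        # exact pairwise distances; class blocks are small
        d2 = ((feats[:, None, :] - feats[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]

        rows = []
        for _ in range(deficit):
            p = int(rng.integers(len(block)))
            q = int(nn_idx[p, int(rng.integers(k))])
            u = float(rng.random())
            parent, neigh = block.iloc[p], block.iloc[q]
            row = parent.copy()
            for col in ("completion_time_s", "age_y", "height_m", "weight_kg"):
                row[col] = parent[col] + u * (neigh[col] - parent[col])
            row["bmi"] = compute_bmi(row["weight_kg"], row["height_m"])
            row["sex"] = int(parent["sex"])
            rows.append(row)
        new_rows.append(pd.DataFrame(rows))
        generated[tax.name(int(code))] = deficit

    frame = pd.concat(new_rows, ignore_index=True)
    out = dataset.replace_frame(frame)
    after = {
        tax.name(int(c)): int(n)
        for c, n in out.labels(label_axis).value_counts().items()
    }
    report = BalanceReport(
        axis=label_axis, before=before, after=after, generated_per_class=generated
    )
    return out, report
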