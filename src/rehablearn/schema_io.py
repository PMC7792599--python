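"""Data model and file I/O for TUG / FTSTS rehabilitation datasets.

The package works on tabular subject records with six numeric features —
test completion time (s), age (y), height (m), weight (kg), BMI (kg/m²)
and a binary sex code (0 = female, 1 = male) — plus up to two categorical
labels: the *difficulty* observed in a test segment and the patient's
medical *condition*.  Label taxonomies are fixed constants so that integer
class codes are reproducible across runs.

Datasets travel as CSV (comma separated, dot decimal, UTF-8, one header
row); cohort generation parameters travel as YAML with one mapping per
class.  The shipped default parameter files are synthetic stand-ins
(``non_canonical: true``): they are bounded by published cohort ranges but
are not harvested from any specific study.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ParseError, SchemaError, TaxonomyError, ValidationError

#: canonical CSV column names, in order
FEATURE_COLUMNS = (
    "completion_time_s",
    "age_y",
    "height_m",
    "weight_kg",
    "bmi",
    "sex",
)
#: continuous measurements (everything but the binary sex code)
CONTINUOUS_FEATURES = FEATURE_COLUMNS[:5]
LABEL_COLUMNS = ("difficulty", "condition")

SEX_FEMALE = 0
SEX_MALE = 1
_SEX_STRINGS = {"female": SEX_FEMALE, "f": SEX_FEMALE, "male": SEX_MALE, "m": SEX_MALE}


@dataclass(frozen=True)
class LabelTaxonomy:
    """An ordered set of class names for one label axis of one test type."""

    test_type: str  # "TUG" | "FTSTS"
    axis: str  # "difficulty" | "condition"
    classes: tuple[str, ...]
    healthy_reference: str

    def __post_init__(self):
        if self.healthy_reference not in self.classes:
            raise TaxonomyError(
                f"healthy_reference {self.healthy_reference!r} not in classes"
            )

    def code(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise TaxonomyError(
                f"unknown {self.axis} label {name!r} for {self.test_type}"
            ) from None

    def name(self, code: int) -> str:
        return self.classes[code]

    @property
    def n_classes(self) -> int:
        return len(self.classes)


TUG_DIFFICULTY = LabelTaxonomy(
    "TUG",
    "difficulty",
    ("walk", "turn", "stand_sit", "normal", "fast"),
    healthy_reference="normal",
)

FTSTS_DIFFICULTY = LabelTaxonomy(
    "FTSTS",
    "difficulty",
    ("slow", "fast"),
    healthy_reference="fast",
)

TUG_CONDITION = LabelTaxonomy(
    "TUG",
    "condition",
    (
        "healthy",
        "geriatric",
        "parkinsons",
        "parkinsons_nonfallers_medication",
        "parkinsons_nonfallers_no_medication",
        "parkinsons_fallers",
        "dementia_mild_moderate",
        "dementia_severe",
        "arthritis_improvement",
        "arthritis_knee_arthroplasty",
        "arthritis",
        "stroke",
        "brain_injury",
        "bilateral_vestibular_hypofunction",
        "unilateral_vestibular_hypofunction",
        "spinal_injury",
        "paraplegia",
        "tetraplegia",
    ),
    healthy_reference="healthy",
)

FTSTS_CONDITION = LabelTaxonomy(
    "FTSTS",
    "condition",
    (
        "healthy",
        "geriatric",
        "geriatric_fallers",
        "parkinsons_stage_1",
        "parkinsons_stage_2",
        "parkinsons_stage_2_5",
        "parkinsons_stage_3",
        "parkinsons_stage_4",
        "parkinsons",
        "arthritis",
        "arthritis_knee_arthroplasty",
        "stroke",
        "vestibular_disorder",
    ),
    healthy_reference="healthy",
)

TAXONOMIES: dict[tuple[str, str], LabelTaxonomy] = {
    ("TUG", "difficulty"): TUG_DIFFICULTY,
    ("TUG", "condition"): TUG_CONDITION,
    ("FTSTS", "difficulty"): FTSTS_DIFFICULTY,
    ("FTSTS", "condition"): FTSTS_CONDITION,
}

#: published plausibility ranges for cohort means, per test type
PLAUSIBILITY_RANGES = {
    "TUG": {"age": (5.0, 112.0), "height": (0.81, 2.20), "weight": (30.0, 136.0)},
    "FTSTS": {"age": (11.0, 93.0), "height": (0.94, 2.35), "weight": (22.0, 120.0)},
}

_BMI_RTOL = 1e-6


@dataclass
class SubjectRecord:
    """One subject measurement: six numeric features plus optional labels."""

    completion_time: float  # seconds
    age: float  # years
    height: float  # meters
    weight: float  # kilograms
    bmi: float  # kg/m²
    sex: int  # 0 = female, 1 = male
    difficulty_label: str | None = None
    condition_label: str | None = None

    def __post_init__(self):
        if self.sex not in (SEX_FEMALE, SEX_MALE):
            raise ValidationError(f"sex must be 0 or 1, got {self.sex}")
        for name in ("completion_time", "height", "weight"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        expected = self.weight / self.height**2
        if not math.isclose(self.bmi, expected, rel_tol=_BMI_RTOL):
            raise ValidationError(
                f"bmi {self.bmi} inconsistent with weight/height² = {expected}"
            )

    def feature_vector(self) -> list[float]:
        return [
            self.completion_time,
            self.age,
            self.height,
            self.weight,
            self.bmi,
            float(self.sex),
        ]


@dataclass
class RehabDataset:
    """A labelled feature table for one test type.

    ``frame`` holds the six feature columns plus integer-coded label
    columns (one per attached taxonomy).  ``normalization`` is set once
    the features have been mapped to [−1, 1] and holds the fitted
    per-feature (min, max) pairs so the mapping is invertible.
    """

    frame: pd.DataFrame
    taxonomies: dict[str, LabelTaxonomy]
    test_type: str
    normalization: object | None = None  # preprocess.NormalizationParams
    provenance: str = "synthetic"  # experimental_fixture | synthetic | user_stream

    def __post_init__(self):
        missing = [c for c in FEATURE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame missing feature columns {missing}")
        for axis, tax in self.taxonomies.items():
            if axis not in self.frame.columns:
                raise SchemaError(f"dataset frame missing label column {axis!r}")
            codes = self.frame[axis]
            bad = codes[(codes < 0) | (codes >= tax.n_classes)]
            if len(bad):
                raise TaxonomyError(
                    f"label codes outside taxonomy for axis {axis!r}: "
                    f"{sorted(bad.unique().tolist())}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[list(FEATURE_COLUMNS)]

    def labels(self, axis: str) -> pd.Series:
        if axis not in self.taxonomies:
            raise TaxonomyError(f"dataset carries no {axis!r} labels")
        return self.frame[axis]

    def label_names(self, axis: str) -> pd.Series:
        tax = self.taxonomies[axis]
        return self.labels(axis).map(lambda c: tax.name(int(c)))

    def replace_frame(self, frame: pd.DataFrame) -> "RehabDataset":
        return RehabDataset(
            frame=frame.reset_index(drop=True),
            taxonomies=dict(self.taxonomies),
            test_type=self.test_type,
            normalization=self.normalization,
            provenance=self.provenance,
        )


@dataclass
class CohortStats:
    """Per-class generation parameters: feature moments plus sex mix."""

    class_name: str
    n: int
    mu_time: float
    sigma_time: float
    mu_age: float
    sigma_age: float
    mu_bmi: float
    sigma_bmi: float
    mu_weight: float
    sigma_weight: float
    mu_height: float
    sigma_height: float
    pct_female: float

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError(f"{self.class_name}: n must be >= 0")
        for name in ("sigma_time", "sigma_age", "sigma_bmi", "sigma_weight", "sigma_height"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.class_name}: {name} must be >= 0")
        for name in ("mu_time", "mu_bmi", "mu_weight", "mu_height"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.class_name}: {name} must be > 0")
        if not 0.0 <= self.pct_female <= 1.0:
            raise ValidationError(f"{self.class_name}: pct_female must lie in [0, 1]")

    def check_plausibility(self, test_type: str) -> list[str]:
        """Soft range check of the means; returns (and warns) messages."""
        msgs = []
        ranges = PLAUSIBILITY_RANGES.get(test_type, {})
        for feat, mu in (
            ("age", self.mu_age),
            ("height", self.mu_height),
            ("weight", self.mu_weight),
        ):
            lo, hi = ranges.get(feat, (-math.inf, math.inf))
            if not lo <= mu <= hi:
                msgs.append(
                    f"{self.class_name}: mu_{feat}={mu} outside the published "
                    f"{test_type} range [{lo}, {hi}]"
                )
        for m in msgs:
            warnings.warn(m, stacklevel=3)
        return msgs


_STAT_FIELDS = (
    "n",
    "mu_time",
    "sigma_time",
    "mu_age",
    "sigma_age",
    "mu_bmi",
    "sigma_bmi",
    "mu_weight",
    "sigma_weight",
    "mu_height",
    "sigma_height",
    "pct_female",
)


def read_cohort_stats(path: str | Path) -> list[CohortStats]:
    """Read a per-class cohort-statistics YAML file.

    Expected layout::

        test_type: TUG
        non_canonical: true
        source_note: "..."
        classes:
          healthy: {n: 280, mu_time: 8.0, sigma_time: 1.5, ...}

    Emits warnings for class means outside the published plausibility
    ranges of the declared test type; raises on structural problems.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "classes" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'classes' section")
    test_type = doc.get("test_type", "")
    out: list[CohortStats] = []
    for name, block in doc["classes"].items():
        missing = [f for f in _STAT_FIELDS if f not in block]
        if missing:
            raise SchemaError(f"{path}: class {name!r} missing fields {missing}")
        stats = CohortStats(class_name=name, **{f: block[f] for f in _STAT_FIELDS})
        stats.check_plausibility(test_type)
        out.append(stats)
    return out


def write_cohort_stats(
    stats: Iterable[CohortStats],
    path: str | Path,
    test_type: str,
    non_canonical: bool = True,
    source_note: str = "",
) -> None:
    doc = {
        "test_type": test_type,
        "non_canonical": non_canonical,
        "source_note": source_note,
        "classes": {
            s.class_name: {f: getattr(s, f) for f in _STAT_FIELDS} for s in stats
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_stats_path(test_type: str) -> Path:
    """Path of the shipped (non-canonical) parameter file for a test type."""
    return Path(__file__).parent / "data" / f"{test_type.lower()}_cohort_stats.yaml"


def _coerce_sex(value, row: int) -> int:
    if isinstance(value, str):
        key = value.strip().lower()
        if key in _SEX_STRINGS:
            return _SEX_STRINGS[key]
        try:
            value = int(float(key))
        except ValueError:
            raise ParseError(
                f"row {row}: unparseable sex value {key!r}", row=row
            ) from None
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: unparseable sex value {value!r}", row=row)
    if iv not in (SEX_FEMALE, SEX_MALE):
        raise ParseError(f"row {row}: sex code must be 0 or 1, got {iv}", row=row)
    return iv


def read_dataset(
    path: str | Path,
    taxonomies: LabelTaxonomy | dict[str, LabelTaxonomy],
    provenance: str = "experimental_fixture",
) -> RehabDataset:
    """Read a subject-record CSV into a :class:`RehabDataset`.

    String labels (and "male"/"female" sex entries) are mapped to integer
    codes per the taxonomy's declared class ordering; row order is
    preserved.  A sidecar ``<path>.meta.json`` written by
    :func:`write_dataset` restores normalization parameters if present.
    """
    if isinstance(taxonomies, LabelTaxonomy):
        taxonomies = {taxonomies.axis: taxonomies}
    path = Path(path)
    raw = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in FEATURE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing feature column(s) {missing}")
    for axis in taxonomies:
        if axis not in raw.columns:
            raise SchemaError(f"{path}: missing label column {axis!r}")

    normalization = None
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        from .preprocess import NormalizationParams  # local import: no cycle at load

        with open(meta_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        if meta.get("normalization"):
            normalization = NormalizationParams(
                {k: tuple(v) for k, v in meta["normalization"].items()}
            )
        provenance = meta.get("provenance", provenance)

    frame = pd.DataFrame(index=raw.index)
    numeric_cols = (
        FEATURE_COLUMNS if normalization is not None else CONTINUOUS_FEATURES
    )
    for col in numeric_cols:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.index[parsed.isna()][0])
            raise ParseError(
                f"{path}: non-numeric value {raw[col][row]!r} in column {col!r} "
                f"at row {row}",
                row=row,
            )
        frame[col] = parsed.astype(float)
    if normalization is None:
        frame["sex"] = [
            _coerce_sex(v, i) for i, v in enumerate(raw["sex"].tolist())
        ]
    test_type = next(iter(taxonomies.values())).test_type
    for axis, tax in taxonomies.items():
        frame[axis] = [tax.code(str(v).strip()) for v in raw[axis].tolist()]
    frame = frame[[*FEATURE_COLUMNS, *taxonomies]]

    return RehabDataset(
        frame=frame,
        taxonomies=taxonomies,
        test_type=test_type,
        normalization=normalization,
        provenance=provenance,
    )


def write_dataset(dataset: RehabDataset, path: str | Path) -> None:
    """Write a dataset as CSV (labels as class-name strings).

    ``read_dataset(write_dataset(d))`` reproduces ``d`` exactly.  When the
    dataset is normalized, the fitted (min, max) pairs go to a sidecar
    ``<path>.meta.json`` so the round trip preserves invertibility.
    """
    if len(dataset) == 0:
        raise ValidationError("refusing to write an empty dataset")
    path = Path(path)
    out = dataset.frame[list(FEATURE_COLUMNS)].copy()
    if dataset.normalization is None:
        out["sex"] = out["sex"].astype(int)
    for axis, tax in dataset.taxonomies.items():
        out[axis] = dataset.frame[axis].map(lambda c: tax.name(int(c)))
    out.to_csv(path, index=False)

    meta_path = path.with_name(path.name + ".meta.json")
    meta: dict = {"provenance": dataset.provenance}
    if dataset.normalization is not None:
        meta["normalization"] = {
            k: list(v) for k, v in dataset.normalization.ranges.items()
        }
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)
    elif meta_path.exists():
        meta_path.unlink()
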