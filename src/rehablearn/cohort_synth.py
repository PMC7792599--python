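"""Synthetic patient-cohort generation from per-class summary statistics.

Each class table is built by drawing every feature independently from its
Gaussian (μ, σ), sorting each draw ascending, and then *partially*
shuffling chosen columns with seeded local index-pair swaps.  Sorting all
columns aligns low-with-low (monotone coupling: slowest completion time ↔
highest rank in every other feature), which encodes the near-linear
time↔age and age↔BMI relationships seen in mobility-test cohorts; the
swaps then relax the coupling to a realistic, tunable strength.  Swaps
applied jointly to a linked block {bmi, weight, sex} preserve the
within-block correlations while decoupling the block from the sorted
columns.  Height is derived from weight and BMI (h = √(w/BMI)) and then
affinely rescaled to hit the class's published height moments exactly,
after which BMI is recomputed row-wise so BMI = weight/height² is an
identity of every generated record (the drift of the recomputed BMI
moments from their targets is reported).

The module also provides an experiment-style fixture generator (a small
cohort with class-separated completion times and demographics matching an
8-participant lab study) and session-stream fixtures that emulate a user
repeating a test over many sessions with a named trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DomainError,
    InfeasibleStatsError,
    SchemaError,
    TaxonomyError,
    ValidationError,
)
from .preprocess import compute_bmi
from .schema_io import (
    FEATURE_COLUMNS,
    FTSTS_DIFFICULTY,
    TUG_DIFFICULTY,
    CohortStats,
    LabelTaxonomy,
    RehabDataset,
)

__all__ = [
    "VariabilityConfig",
    "ClassTable",
    "CorrelationReport",
    "sample_sorted_gaussian",
    "insert_variability",
    "assign_sex",
    "derive_height",
    "generate_class",
    "generate_dataset",
    "validate_correlations",
    "fixture_experiment",
    "fixture_participants",
    "fixture_session_stream",
    "SessionStream",
]


@dataclass(frozen=True)
class VariabilityConfig:
    """Knobs of the partial-shuffle step.

    ``swap_fraction_age`` drives the swaps applied to the age column
    alone; ``swap_fraction_bmi_block`` drives the joint swaps of the
    linked {bmi, weight, sex} block.  ``swap_window`` bounds |i − j| for
    every swapped pair (None → n // 4, resolved per class).
    """

    swap_fraction_age: float = 0.15
    swap_fraction_bmi_block: float = 0.15
    swap_window: int | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("swap_fraction_age", "swap_fraction_bmi_block"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.swap_window is not None and self.swap_window < 1:
            raise ValidationError("swap_window must be >= 1")


@dataclass
class ClassTable:
    """Generated feature columns for one class (pre-labelling)."""

    class_name: str
    time: np.ndarray
    age: np.ndarray
    bmi: np.ndarray
    weight: np.ndarray
    height: np.ndarray
    sex: np.ndarray
    bmi_moment_drift: tuple[float, float] = (0.0, 0.0)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "completion_time_s": self.time,
                "age_y": self.age,
                "height_m": self.height,
                "weight_kg": self.weight,
                "bmi": self.bmi,
                "sex": self.sex.astype(int),
            }
        )


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_sorted_gaussian(
    mu: float,
    sigma: float,
    n: int,
    seed,
    lower: float | None = None,
) -> np.ndarray:
    """Draw n i.i.d. Normal(μ, σ²) values, then sort ascending.

    ``lower`` truncates the distribution at a physical bound by redraw
    (used for strictly-positive quantities); values equal to the bound
    are rejected too, so the output is strictly above it.
    """
    if sigma < 0:
        raise DomainError(f"sigma must be >= 0, got {sigma}")
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    rng = _resolve_rng(seed)
    x = rng.normal(mu, sigma, size=n)
    if lower is not None:
        if sigma == 0 and mu <= lower:
            raise DomainError(f"mu={mu} at or below bound {lower} with sigma=0")
        for _ in range(1000):
            bad = x <= lower
            if not bad.any():
                break
            x[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        else:
            raise DomainError(
                f"truncation at {lower} rejects nearly all draws of N({mu}, {sigma}²)"
            )
    return np.sort(x)


def _swap_plan(
    n: int, swap_fraction: float, swap_window: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Seeded sequence of round(fraction·n) index pairs with |i−j| ≤ window."""
    n_swaps = int(round(swap_fraction * n))
    plan = []
    for _ in range(n_swaps):
        i = int(rng.integers(n))
        lo, hi = max(0, i - swap_window), min(n - 1, i + swap_window)
        j = i
        while j == i:
            j = int(rng.integers(lo, hi + 1))
        plan.append((i, j))
    return plan


def insert_variability(
    columns: Sequence[np.ndarray] | np.ndarray,
    swap_fraction: float,
    swap_window: int | None,
    seed,
) -> list[np.ndarray] | np.ndarray:
    """Partially shuffle one or more linked equal-length columns.

    Performs round(swap_fraction·n) seeded index-pair swaps, each pair at
    most ``swap_window`` apart, and applies the identical swap sequence
    to every column in the linked set (so within-set correlations are
    untouched).  Per-column multisets — hence means and SDs — are exactly
    preserved.  A single array in → a single array out.
    """
    single = isinstance(columns, np.ndarray)
    cols = [columns] if single else list(columns)
    if not cols:
        raise ValidationError("no columns given")
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise SchemaError("linked columns must all have the same length")
    out = [np.array(c, copy=True) for c in cols]
    if n >= 2 and swap_fraction > 0:
        window = swap_window if swap_window is not None else max(1, n // 4)
        rng = _resolve_rng(seed)
        for i, j in _swap_plan(n, swap_fraction, window, rng):
            for c in out:
                c[i], c[j] = c[j], c[i]
    return out[0] if single else out


def assign_sex(n: int, pct_female: float) -> np.ndarray:
    """First floor(n·pct_female) entries female (0), remainder male (1).

    Positional variability comes later via the linked block swaps.
    """
    if not 0.0 <= pct_female <= 1.0:
        raise DomainError("pct_female must lie in [0, 1]")
    n_female = int(np.floor(n * pct_female))
    return np.concatenate(
        [np.zeros(n_female, dtype=int), np.ones(n - n_female, dtype=int)]
    )


def derive_height(
    weight: np.ndarray,
    bmi: np.ndarray,
    target_mu: float,
    target_sigma: float,
    literal_ratio: bool = False,
    drift_warn: float = 0.10,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Derive height from weight and BMI, then match the height moments.

    h_i = √(w_i / BMI_i) — the form consistent with BMI = w/h²
    (``literal_ratio=True`` switches to the dimensionally inconsistent
    h = w/BMI for compatibility experiments).  The heights are affinely
    rescaled so their sample mean and SD equal (target_mu, target_sigma)
    exactly, and BMI is recomputed as w/h² so the row identity holds.
    Returns (height, recomputed bmi, (mean drift, sd drift)) where the
    drifts are the relative departures of the recomputed BMI moments from
    the input BMI moments; a drift above ``drift_warn`` emits a warning.
    """
    weight = np.asarray(weight, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if np.any(weight <= 0) or np.any(bmi <= 0):
        raise DomainError("weight and bmi must be strictly positive")
    if target_mu <= 0 or target_sigma < 0:
        raise DomainError("targets must satisfy mu > 0, sigma >= 0")
    if len(weight) == 0:
        return weight.copy(), bmi.copy(), (0.0, 0.0)

    raw = weight / bmi if literal_ratio else np.sqrt(weight / bmi)
    m, s = raw.mean(), raw.std(ddof=0)
    if s == 0:
        if target_sigma > 0:
            raise InfeasibleStatsError(
                "constant derived heights cannot be rescaled to sigma > 0"
            )
        height = np.full_like(raw, target_mu)
    else:
        height = target_mu + (raw - m) * (target_sigma / s)
    if np.any(height <= 0):
        raise InfeasibleStatsError(
            "height moment targets produce non-positive heights"
        )

    new_bmi = weight / height**2
    mu0, sd0 = bmi.mean(), bmi.std(ddof=0)
    mu_drift = abs(new_bmi.mean() - mu0) / mu0 if mu0 else 0.0
    sd_drift = abs(new_bmi.std(ddof=0) - sd0) / sd0 if sd0 else 0.0
    if max(mu_drift, sd_drift) >= drift_warn:
        warnings.warn(
            f"recomputed BMI moments drifted by (mean {mu_drift:.1%}, "
            f"sd {sd_drift:.1%}) from their targets",
            stacklevel=2,
        )
    return height, new_bmi, (float(mu_drift), float(sd_drift))


def generate_class(
    stats: CohortStats,
    config: VariabilityConfig,
    seed=None,
) -> ClassTable:
    """Generate one class table of n rows from its summary statistics.

    Line order: time sorted; age sorted then varied; bmi sorted then
    varied; weight sorted; sex assigned by proportion; {bmi, weight, sex}
    jointly varied; height derived and moment-matched; BMI recomputed.
    With all swap fractions 0 every column stays sorted, so
    Spearman(time, age) = 1 by construction.
    """
    rng = _resolve_rng(config.seed if seed is None else seed)
    n = stats.n
    if n == 0:
        empty = np.empty(0)
        return ClassTable(stats.class_name, empty, empty, empty, empty, empty,
                          np.empty(0, dtype=int))

    # all Gaussian draws happen before any swap draws, so the pre-swap
    # columns are identical across variability settings at equal seed
    time = sample_sorted_gaussian(stats.mu_time, stats.sigma_time, n, rng, lower=0.0)
    age = sample_sorted_gaussian(stats.mu_age, stats.sigma_age, n, rng, lower=None)
    age = np.clip(age, 0.0, None)  # ages cannot be negative
    bmi = sample_sorted_gaussian(stats.mu_bmi, stats.sigma_bmi, n, rng, lower=0.0)
    weight = sample_sorted_gaussian(
        stats.mu_weight, stats.sigma_weight, n, rng, lower=0.0
    )
    sex = assign_sex(n, stats.pct_female)
    age = insert_variability(age, config.swap_fraction_age, config.swap_window, rng)
    bmi, weight, sex = insert_variability(
        [bmi, weight, sex], config.swap_fraction_bmi_block, config.swap_window, rng
    )
    height, bmi, drift = derive_height(
        weight, bmi, stats.mu_height, stats.sigma_height
    )
    return ClassTable(
        class_name=stats.class_name,
        time=time,
        age=age,
        bmi=bmi,
        weight=weight,
        height=height,
        sex=sex,
        bmi_moment_drift=drift,
    )


def generate_dataset(
    stats_list: Iterable[CohortStats],
    config: VariabilityConfig,
    taxonomy: LabelTaxonomy,
) -> RehabDataset:
    """Concatenate per-class tables into a labelled dataset.

    Requires exactly one CohortStats per taxonomy class; rows are emitted
    in taxonomy class order, total rows = Σ n.  Per-class seeds are
    spawned deterministically from config.seed and the class index, so
    identical (stats, config) reproduce the dataset value-for-value.
    """
    by_name = {s.class_name: s for s in stats_list}
    if set(by_name) != set(taxonomy.classes):
        missing = set(taxonomy.classes) - set(by_name)
        extra = set(by_name) - set(taxonomy.classes)
        raise TaxonomyError(
            f"stats/taxonomy mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    frames = []
    for idx, name in enumerate(taxonomy.classes):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, idx]))
        table = generate_class(by_name[name], config, seed=rng)
        frame = table.to_frame()
        frame[taxonomy.axis] = idx
        frames.append(frame)
    frame = pd.concat(frames, ignore_index=True)
    return RehabDataset(
        frame=frame,
        taxonomies={taxonomy.axis: taxonomy},
        test_type=taxonomy.test_type,
        provenance="synthetic",
    )


@dataclass
class CorrelationReport:
    """Pearson feature-correlation comparison against a reference matrix."""

    features: tuple[str, ...]
    matrix: np.ndarray
    reference: np.ndarray
    tolerance: float
    excluded: tuple[str, ...] = ()

    @property
    def differences(self) -> np.ndarray:
        return np.abs(self.matrix - self.reference)

    @property
    def max_abs_diff(self) -> float:
        mask = ~np.isnan(self.matrix) & ~np.isnan(self.reference)
        return float(self.differences[mask].max())

    @property
    def passed(self) -> bool:
        return self.max_abs_diff <= self.tolerance


def validate_correlations(
    dataset: RehabDataset,
    reference: np.ndarray,
    tolerance: float,
) -> CorrelationReport:
    """Compare the dataset's 6×6 Pearson matrix to a reference.

    Used to tune VariabilityConfig so the synthetic cohort's correlation
    structure matches a recorded dataset's.  Constant features have
    undefined correlations; they are flagged, set to NaN and excluded
    from max_abs_diff.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (len(FEATURE_COLUMNS), len(FEATURE_COLUMNS)):
        raise SchemaError("reference must be 6×6 over the feature columns")
    if not np.allclose(reference, reference.T) or not np.allclose(
        np.diag(reference), 1.0
    ):
        raise ValidationError("reference must be symmetric with unit diagonal")
    feats = dataset.frame[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    sd = feats.std(axis=0, ddof=0)
    excluded = tuple(
        FEATURE_COLUMNS[i] for i in range(len(FEATURE_COLUMNS)) if sd[i] == 0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        matrix = np.corrcoef(feats, rowvar=False)
    for i, name in enumerate(FEATURE_COLUMNS):
        if name in excluded:
            matrix[i, :] = np.nan
            matrix[:, i] = np.nan
    np.fill_diagonal(matrix, np.where(sd == 0, np.nan, 1.0))
    return CorrelationReport(
        features=FEATURE_COLUMNS,
        matrix=matrix,
        reference=reference,
        tolerance=tolerance,
        excluded=excluded,
    )


# --- experiment-style fixtures -------------------------------------------

#: per-difficulty completion-time ranges (s); deliberately disjoint so the
#: fixture is separable on the time feature alone, like the lab data where
#: participants acted each difficulty in turn.
FIXTURE_TIME_RANGES = {
    "TUG": {
        "fast": (4.0, 6.8),
        "normal": (7.0, 9.3),
        "stand_sit": (9.5, 12.3),
        "turn": (12.5, 15.8),
        "walk": (16.0, 20.0),
    },
    "FTSTS": {
        "fast": (5.0, 9.8),
        "slow": (12.0, 20.0),
    },
}

#: default per-difficulty counts, chosen so the minority deficits match a
#: lab-style unbalanced recording session
DEFAULT_FIXTURE_COUNTS = {
    "TUG": {"walk": 40, "turn": 40, "stand_sit": 40, "fast": 39, "normal": 24},
    "FTSTS": {"slow": 33, "fast": 40},
}


def _fixture_participants(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographic profiles of the lab participants.

    Mirrors a young, male-dominated convenience sample: ages 20–45, one
    female in eight (ratio held for any n).
    """
    ages = rng.uniform(20.0, 45.0, size=n).round(0)
    heights = rng.uniform(1.60, 1.90, size=n).round(2)
    weights = rng.uniform(55.0, 95.0, size=n).round(1)
    sex = np.ones(n, dtype=int)
    n_female = max(1, int(round(n / 8)))
    sex[rng.choice(n, size=n_female, replace=False)] = 0
    return pd.DataFrame(
        {
            "age_y": ages,
            "height_m": heights,
            "weight_kg": weights,
            "bmi": compute_bmi(weights, heights),
            "sex": sex,
        }
    )


def fixture_participants(n: int = 8, seed: int = 0) -> pd.DataFrame:
    """Public accessor for n lab-style participant demographic profiles."""
    return _fixture_participants(n, np.random.default_rng(seed))


def fixture_experiment(
    test_type: str,
    participants: int = 8,
    per_class: dict[str, int] | None = None,
    seed: int = 0,
) -> RehabDataset:
    """Build an experiment-style labelled dataset.

    Each row pairs one participant's demographics with a completion time
    drawn uniformly from that difficulty's (disjoint) time range, so the
    classes have zero completion-time overlap by construction.
    """
    if test_type not in FIXTURE_TIME_RANGES:
        raise ConfigError(f"unknown test type {test_type!r}")
    taxonomy = TUG_DIFFICULTY if test_type == "TUG" else FTSTS_DIFFICULTY
    per_class = dict(per_class or DEFAULT_FIXTURE_COUNTS[test_type])
    missing = set(taxonomy.classes) - set(per_class)
    if missing:
        raise ConfigError(f"per_class counts missing {sorted(missing)}")
    rng = np.random.default_rng(seed)
    people = _fixture_participants(participants, rng)

    rows = []
    for code, cls in enumerate(taxonomy.classes):
        lo, hi = FIXTURE_TIME_RANGES[test_type][cls]
        for _ in range(per_class[cls]):
            who = people.iloc[int(rng.integers(participants))]
            rows.append(
                {
                    "completion_time_s": float(rng.uniform(lo, hi)),
                    "age_y": float(who["age_y"]),
                    "height_m": float(who["height_m"]),
                    "weight_kg": float(who["weight_kg"]),
                    "bmi": float(who["bmi"]),
                    "sex": int(who["sex"]),
                    taxonomy.axis: code,
                }
            )
    return RehabDataset(
        frame=pd.DataFrame(rows),
        taxonomies={taxonomy.axis: taxonomy},
        test_type=test_type,
        provenance="experimental_fixture",
    )


TRENDS = ("improving", "worsening", "steady", "forcing", "abandon")


@dataclass
class SessionStream:
    """Ordered completion times for one user, with per-session sensor events.

    ``events[i]`` is the event tuple of session i; a nominal completed
    session is ("start", "complete"), an abandoned one just ("start",).
    """

    times: np.ndarray
    events: list[tuple[str, ...]] = field(default_factory=list)


def fixture_session_stream(
    base_time: float,
    n_sessions: int,
    trend: str,
    seed: int = 0,
    noise_sd: float | None = None,
    slope: float | None = None,
) -> SessionStream:
    """Simulate a user's completion times over n sessions.

    Trends: *improving* — linear decrease with noise; *worsening* —
    linear increase; *steady* — stationary noise around base_time;
    *forcing* — implausibly steep decrease (goal forcing); *abandon* —
    steady, but the final session starts and never completes.
    Times are floored at 20% of base_time so they stay physical.
    """
    if trend not in TRENDS:
        raise ConfigError(f"unknown trend {trend!r}; expected one of {TRENDS}")
    rng = np.random.default_rng(seed)
    noise_sd = 0.02 * base_time if noise_sd is None else noise_sd
    idx = np.arange(n_sessions, dtype=float)
    per_session = {
        "improving": -0.25 * base_time / max(n_sessions - 1, 1),
        "worsening": +0.25 * base_time / max(n_sessions - 1, 1),
        "steady": 0.0,
        "forcing": -0.60 * base_time / max(n_sessions - 1, 1),
        "abandon": 0.0,
    }[trend]
    if slope is not None:
        per_session = slope
    times = base_time + per_session * idx + rng.normal(0.0, noise_sd, n_sessions)
    times = np.clip(times, 0.2 * base_time, None)
    events = [("start", "complete")] * n_sessions
    if trend == "abandon" and n_sessions:
        events[-1] = ("start",)
    return SessionStream(times=times, events=events)
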