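"""The individualised hybrid engine: improvement-rate gating of the two
base classifiers, incremental per-user retraining, and safety flags.

Each session appends the new completion time to the user's history, fits
a low-degree polynomial to the history to get the current improvement
rate (negative = getting faster = improving), and asks both base models
for a prediction on each label axis (difficulty and condition).  The
final prediction per axis is then selected by a fixed rule: while the
user improves, trust the candidate whose class centroid lies *closer* to
the healthy reference centroid; while the user worsens, the *farther*
one; when steady, fall back to the most frequent past prediction.  Both
base models of each axis are then incrementally retrained with the
selected label, closing a self-reinforcing individualisation loop.

The engine also derives safety flags from the raw session events
(possible fall, sensor anomaly, goal forcing, sustained deterioration)
and raises a co-morbidity drift alert when the predicted condition
persistently disagrees with the clinician-initialised one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from .base_models import ModelPair, incremental_update, predict_with_probs
from .errors import ConfigError, InsufficientDataError, ValidationError
from .preprocess import compute_bmi
from .schema_io import SubjectRecord

IMPROVING, WORSENING, STEADY = "improving", "worsening", "steady"

#: expected per-session sensor event grammar: a start marker, optional
#: phase markers, one completion marker
KNOWN_EVENTS = {"start", "walk", "turn", "stand", "sit", "complete"}


@dataclass
class EngineConfig:
    """Tunables of the session loop (all decided defaults, configurable).

    epsilon: half-width of the "steady" band on the improvement rate, in
    seconds/session; None → 1% of the user's mean completion time.
    forcing_threshold: rate below −threshold counts as implausibly fast
    improvement; None → 3 × epsilon.
    """

    degree: int = 2
    epsilon: float | None = None
    forcing_threshold: float | None = None
    deterioration_window: int = 3
    alert_window: int = 10
    alert_fraction: float = 0.8
    distance_mode: str = "centroid"  # or "point"
    fall_timeout_s: float = 120.0
    time_bounds: tuple[float, float] = (1.0, 300.0)

    def __post_init__(self):
        if self.distance_mode not in ("centroid", "point"):
            raise ConfigError(f"unknown distance_mode {self.distance_mode!r}")
        if not 0.0 < self.alert_fraction <= 1.0:
            raise ConfigError("alert_fraction must lie in (0, 1]")

    def resolve_epsilon(self, history: np.ndarray) -> float:
        if self.epsilon is not None:
            return self.epsilon
        return 0.01 * float(np.mean(history))

    def resolve_forcing(self, epsilon: float) -> float:
        return self.forcing_threshold if self.forcing_threshold is not None else 3 * epsilon


@dataclass
class UserState:
    """Safety flags derived from the current session and recent history."""

    possible_fall: bool = False
    sensor_anomaly: bool = False
    forcing: bool = False
    deterioration: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PredictionBundle:
    """Full transparency record of one session's decision, per axis:
    both base predictions with probabilities, candidate distances to the
    healthy centroid, the selected class and the selection branch."""

    session_index: int
    per_axis: dict[str, dict] = field(default_factory=dict)
    improvement_rate: float = 0.0
    improvement_status: str = STEADY
    flags: UserState = field(default_factory=UserState)
    comorbidity_alert: bool = False

    def to_dict(self) -> dict:
        out = {
            "session_index": self.session_index,
            "improvement_rate": self.improvement_rate,
            "improvement_status": self.improvement_status,
            "flags": self.flags.to_dict(),
            "comorbidity_alert": self.comorbidity_alert,
            "per_axis": {},
        }
        for axis, d in self.per_axis.items():
            out["per_axis"][axis] = {
                **d,
                "xgb_probs": [float(p) for p in d["xgb_probs"]],
                "knn_probs": [float(p) for p in d["knn_probs"]],
            }
        return out


@dataclass
class SessionState:
    """One user's evolving state across sessions (histories append-only)."""

    user_id: str
    initial_condition: int | None = None  # clinician-initialised class code
    initial_difficulty: int | None = None
    history: list[float] = field(default_factory=list)
    prediction_history: dict[str, list[int]] = field(
        default_factory=lambda: {"difficulty": [], "condition": []}
    )
    #: raw boosted-model predictions per axis (pre-selection); the
    #: co-morbidity drift alert watches these, because the steady branch
    #: would otherwise perpetuate the initialised condition forever
    model_history: dict[str, list[int]] = field(
        default_factory=lambda: {"difficulty": [], "condition": []}
    )
    status_history: list[str] = field(default_factory=list)
    rate: float = 0.0
    improvement: str = STEADY
    flags: UserState = field(default_factory=UserState)


def improvement_rate(
    history, degree: int = 2, epsilon: float = 0.0
) -> tuple[float, str]:
    """Rate of change of completion time, from a polynomial fit.

    A least-squares polynomial of the given degree is fitted to time vs
    session index and differentiated at the last index.  Rates within
    ±epsilon are "steady"; below −epsilon "improving" (times falling);
    above +epsilon "worsening".  Histories too short to pin the
    polynomial down (< degree + 1 points) report steady with rate 0.
    """
    history = np.asarray(history, dtype=float)
    if history.size == 0:
        raise InsufficientDataError("empty completion-time history")
    if history.size < degree + 1:
        return 0.0, STEADY
    idx = np.arange(history.size, dtype=float)
    coeffs = np.polyfit(idx, history, degree)
    rate = float(np.polyval(np.polyder(coeffs), idx[-1]))
    if rate < -epsilon:
        return rate, IMPROVING
    if rate > epsilon:
        return rate, WORSENING
    return rate, STEADY


def baseline_prediction(
    prediction_history, initial: int | None = None
) -> int:
    """Most frequent past prediction; ties go to the most recent tied class.

    On the first session (empty history) the clinician-initialised class
    is the baseline.
    """
    history = list(prediction_history)
    if not history:
        if initial is None:
            raise ValidationError("no prediction history and no initialised class")
        return int(initial)
    counts = Counter(history)
    top = max(counts.values())
    tied = {c for c, n in counts.items() if n == top}
    for c in reversed(history):  # most recent among the tied
        if c in tied:
            return int(c)
    raise AssertionError("unreachable")


def distance_to_healthy(
    centroids: dict[int, np.ndarray], candidate: int, healthy_ref: int
) -> float:
    """Euclidean distance between a class centroid and the healthy one."""
    for code in (candidate, healthy_ref):
        if code not in centroids:
            raise ValidationError(f"no centroid for class code {code}")
    return float(np.linalg.norm(centroids[candidate] - centroids[healthy_ref]))


def hybrid_select(
    xgb_class: int,
    knn_class: int,
    distances: dict[str, float],
    improvement_status: str,
    baseline: int,
) -> tuple[int, str]:
    """Pick the final class from the two candidates and the baseline.

    improving → the candidate closer to healthy; worsening → the farther
    one; steady → the baseline.  Equal distances break toward the
    boosted-model candidate.
    """
    d_xgb, d_knn = distances["xgb"], distances["knn"]
    if improvement_status == IMPROVING:
        return (int(xgb_class), "closest") if d_xgb <= d_knn else (int(knn_class), "closest")
    if improvement_status == WORSENING:
        return (int(knn_class), "farthest") if d_knn > d_xgb else (int(xgb_class), "farthest")
    if improvement_status == STEADY:
        return int(baseline), "baseline"
    raise ConfigError(f"unknown improvement status {improvement_status!r}")


def state_flags(
    events: tuple[str, ...],
    completion_time: float | None,
    rate: float,
    baseline: int,
    final: int,
    status_history,
    config: EngineConfig,
    elapsed_s: float | None = None,
) -> UserState:
    """Derive the four safety flags from one session.

    possible_fall — the test started but never completed within the
    timeout.  sensor_anomaly — the event stream violates the
    start→(phases)→complete grammar or the time is outside physical
    bounds (malformed streams flag, they do not raise).  forcing —
    implausibly steep improvement while the prediction deviates from the
    baseline.  deterioration — "worsening" for ≥ deterioration_window
    consecutive sessions.
    """
    flags = UserState()
    events = tuple(events)
    started = bool(events) and events[0] == "start"
    completed = "complete" in events

    if started and not completed:
        waited = elapsed_s if elapsed_s is not None else config.fall_timeout_s
        if waited >= config.fall_timeout_s:
            flags.possible_fall = True

    grammar_ok = (
        started
        and completed
        and events[-1] == "complete"
        and events.count("start") == 1
        and events.count("complete") == 1
        and all(e in KNOWN_EVENTS for e in events)
    )
    time_ok = completion_time is None or (
        config.time_bounds[0] <= completion_time <= config.time_bounds[1]
    )
    if (not grammar_ok and not flags.possible_fall) or not time_ok:
        flags.sensor_anomaly = True

    epsilon = config.epsilon if config.epsilon is not None else 0.0
    forcing_threshold = config.resolve_forcing(epsilon)
    if rate < -forcing_threshold and final != baseline:
        flags.forcing = True

    recent = list(status_history)[-config.deterioration_window:]
    if (
        len(recent) >= config.deterioration_window
        and all(s == WORSENING for s in recent)
    ):
        flags.deterioration = True
    return flags


def _axis_step(
    pair: ModelPair,
    x: np.ndarray,
    status: str,
    baseline: int,
    config: EngineConfig,
) -> dict:
    preds = predict_with_probs(pair, x)
    xgb_class, xgb_probs = preds["xgb"]
    knn_class, knn_probs = preds["knn"]
    healthy = pair.taxonomy.code(pair.taxonomy.healthy_reference)
    if config.distance_mode == "point":
        ref = pair.centroids[healthy]
        distances = {
            "xgb": float(np.linalg.norm(x - ref)),
            "knn": float(np.linalg.norm(x - ref)),
        }
    else:
        distances = {
            "xgb": distance_to_healthy(pair.centroids, xgb_class, healthy),
            "knn": distance_to_healthy(pair.centroids, knn_class, healthy),
        }
    final, rationale = hybrid_select(xgb_class, knn_class, distances, status, baseline)
    return {
        "xgb_class": int(xgb_class),
        "xgb_probs": xgb_probs,
        "knn_class": int(knn_class),
        "knn_probs": knn_probs,
        "distances": distances,
        "baseline": int(baseline),
        "final": int(final),
        "rationale": rationale,
    }


def run_session(
    state: SessionState,
    pair_difficulty: ModelPair,
    pair_condition: ModelPair,
    new_time: float,
    demographics: dict,
    config: EngineConfig | None = None,
    events: tuple[str, ...] = ("start", "complete"),
) -> tuple[PredictionBundle, SessionState, ModelPair, ModelPair]:
    """One full session: predict, select, retrain, flag.

    ``demographics`` carries the user's fixed age_y/height_m/weight_kg/sex
    (BMI recomputed).  The state and both pairs are updated in place and
    returned for convenience.
    """
    config = config or EngineConfig()
    state.history.append(float(new_time))
    hist = np.asarray(state.history)
    epsilon = config.resolve_epsilon(hist)
    rate, status = improvement_rate(hist, config.degree, epsilon)
    state.rate, state.improvement = rate, status

    record = SubjectRecord(
        completion_time=float(new_time),
        age=float(demographics["age_y"]),
        height=float(demographics["height_m"]),
        weight=float(demographics["weight_kg"]),
        bmi=compute_bmi(demographics["weight_kg"], demographics["height_m"]),
        sex=int(demographics["sex"]),
    )

    bundle = PredictionBundle(
        session_index=len(state.history) - 1,
        improvement_rate=rate,
        improvement_status=status,
    )
    initials = {"difficulty": state.initial_difficulty, "condition": state.initial_condition}
    for axis, pair in (("difficulty", pair_difficulty), ("condition", pair_condition)):
        baseline = baseline_prediction(state.prediction_history[axis], initials[axis])
        x = pair.normalize_record(record)
        step = _axis_step(pair, x, status, baseline, config)
        bundle.per_axis[axis] = step
        incremental_update(pair, x, step["final"])
        state.prediction_history[axis].append(step["final"])
        state.model_history[axis].append(step["xgb_class"])

    completed = "complete" in events
    flags = state_flags(
        events,
        float(new_time) if completed else None,
        rate,
        bundle.per_axis["difficulty"]["baseline"],
        bundle.per_axis["difficulty"]["final"],
        state.status_history + [status],
        config,
    )
    state.status_history.append(status)
    state.flags = flags
    bundle.flags = flags

    if state.initial_condition is not None:
        recent = state.model_history["condition"][-config.alert_window:]
        if len(recent) >= config.alert_window:
            frac = np.mean([c != state.initial_condition for c in recent])
            bundle.comorbidity_alert = bool(frac >= config.alert_fraction)

    return bundle, state, pair_difficulty, pair_condition


def individualisation_study(
    pair_difficulty: ModelPair,
    pair_condition: ModelPair,
    participants,
    base_times: dict[str, float],
    n_sessions: int,
    seed: int,
    initial_condition: int = 0,
    config: EngineConfig | None = None,
) -> dict[tuple[int, str], list[bool]]:
    """Individual × difficulty simulation with incremental retraining.

    For every (participant row, difficulty class) combination a fresh
    clone of both model pairs runs a stationary single-class session
    stream (``base_times[class]`` seconds, small noise) of ``n_sessions``
    sessions through :func:`run_session`, starting from a correct
    clinician-style initialisation.  Returns per-combination correctness
    sequences (final difficulty prediction vs the stream's true class),
    ready for cumulative-accuracy analysis.
    """
    from .cohort_synth import fixture_session_stream  # local: avoid cycle

    taxonomy = pair_difficulty.taxonomy
    runs: dict[tuple[int, str], list[bool]] = {}
    for p_idx, (_, person) in enumerate(participants.iterrows()):
        demographics = {
            "age_y": float(person["age_y"]),
            "height_m": float(person["height_m"]),
            "weight_kg": float(person["weight_kg"]),
            "sex": int(person["sex"]),
        }
        for cls in taxonomy.classes:
            code = taxonomy.code(cls)
            stream = fixture_session_stream(
                base_times[cls],
                n_sessions,
                "steady",
                seed=(seed * 1009 + p_idx * 31 + code) % (2**31),
            )
            pair_d, pair_c = pair_difficulty.clone(), pair_condition.clone()
            state = SessionState(
                f"p{p_idx}",
                initial_condition=initial_condition,
                initial_difficulty=code,
            )
            correct = []
            for t in stream.times:
                bundle, state, pair_d, pair_c = run_session(
                    state, pair_d, pair_c, float(t), demographics, config
                )
                correct.append(bundle.per_axis["difficulty"]["final"] == code)
            runs[(p_idx, cls)] = correct
    return runs


def evaluate_hybrid(
    pair: ModelPair, dataset, indices, axis: str, config: EngineConfig | None = None
) -> tuple[float, list[dict]]:
    """Static hybrid pass over a test split (no time histories).

    Test records are independent subjects, so there is no improvement
    trend: the status is steady and each record's baseline is the
    boosted model's own prediction for it (the primary model when no
    per-user history exists).  When the two base models agree — the
    common case on well-separated data — the final class is the agreed
    one regardless of branch.  Returns (accuracy, per-record decisions).
    """
    config = config or EngineConfig()
    X = dataset.frame[
        ["completion_time_s", "age_y", "height_m", "weight_kg", "bmi", "sex"]
    ].to_numpy(dtype=float)
    y = dataset.labels(axis).to_numpy(dtype=int)
    finals, steps = [], []
    for i in indices:
        x = X[i]
        preds = predict_with_probs(pair, x)
        step = _axis_step(pair, x, STEADY, int(preds["xgb"][0]), config)
        finals.append(step["final"])
        steps.append(step)
    accuracy = float(np.mean(np.asarray(finals) == y[list(indices)]))
    return accuracy, steps
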