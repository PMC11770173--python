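"""Linear 1–5 metric scoring and the two-level score hierarchy.

Every metric is mapped onto a score in [1, 5] by a per-metric
:class:`ScoreStandard`: values at or beyond ``best_threshold`` score 5,
values at or beyond ``worst_threshold`` score 1, and values strictly
between interpolate linearly.  For the default Orbitrap standard of the
median MS1 raw mass accuracy (best 1 ppm, worst 5 ppm, lower is better)
this gives 1 ppm -> 5 points, 3 ppm -> 3 points, 5 ppm -> 1 point.

Second-level (per-metric) scores are averaged within each first-level
category — by default the five factors of the DIA decomposition — and the
first-level scores are averaged into the total.  Scores are real-valued;
rendering may round for display.  Non-computable metrics are excluded from
every average rather than punished.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .registry import default_hierarchy, intra_registry, load_standards_config

__all__ = [
    "ScoreStandard",
    "ScoreCard",
    "score_metric",
    "aggregate_scores",
    "load_standards",
    "score_run",
    "FLAG_THRESHOLD",
]

#: metrics scoring below this are flagged for attention
FLAG_THRESHOLD = 3.0


@dataclass(frozen=True)
class ScoreStandard:
    """Per-metric thresholds driving the linear 1–5 score."""

    metric_id: str
    best_threshold: float
    worst_threshold: float
    direction: str  # lower_is_better | higher_is_better
    instrument_class: str = "orbitrap"

    def __post_init__(self) -> None:
        if self.direction not in ("lower_is_better", "higher_is_better"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.best_threshold == self.worst_threshold:
            raise ValueError("best and worst thresholds must differ")
        lower = self.direction == "lower_is_better"
        if lower != (self.best_threshold < self.worst_threshold):
            raise ValueError(
                f"{self.metric_id}: direction {self.direction} inconsistent with "
                f"thresholds ({self.best_threshold}, {self.worst_threshold})"
            )


def score_metric(value: float, standard: ScoreStandard) -> float:
    """Score one metric value on the 1–5 scale (monotone, clamped, linear)."""
    value = float(value)
    if value != value or value in (float("inf"), float("-inf")):
        raise ValueError("metric value must be finite")
    best, worst = standard.best_threshold, standard.worst_threshold
    if standard.direction == "lower_is_better":
        if value <= best:
            return 5.0
        if value >= worst:
            return 1.0
    else:
        if value >= best:
            return 5.0
        if value <= worst:
            return 1.0
    return 5.0 - 4.0 * (value - best) / (worst - best)


@dataclass
class ScoreCard:
    """Two-level score hierarchy for one run.

    ``second_level`` maps metric_id to its score; ``first_level`` maps each
    category (by default the five DIA decomposition factors) to the mean of
    its computable second-level scores, and ``total`` is the mean of the
    first-level scores.  ``flags`` lists metrics scoring below the flag
    threshold; ``skipped`` records metrics excluded with their reason.
    """

    run_id: str
    second_level: dict[str, float] = field(default_factory=dict)
    first_level: dict[str, float] = field(default_factory=dict)
    total: float = float("nan")
    flags: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)


def aggregate_scores(second_level: dict[str, float],
                     hierarchy: dict[str, str] | None = None,
                     run_id: str = "",
                     flag_threshold: float = FLAG_THRESHOLD,
                     skipped: dict[str, str] | None = None) -> ScoreCard:
    """Aggregate per-metric scores into first-level and total scores.

    ``hierarchy`` assigns each scored metric to exactly one category;
    metrics missing from it are ignored.  Categories with no computable
    metric are excluded from the total.
    """
    hierarchy = default_hierarchy() if hierarchy is None else hierarchy
    groups: dict[str, list[float]] = {}
    for mid, score in second_level.items():
        cat = hierarchy.get(mid)
        if cat is None:
            continue
        if not 1.0 <= score <= 5.0:
            raise ValueError(f"score for {mid} outside [1, 5]: {score}")
        groups.setdefault(cat, []).append(score)
    first = {cat: sum(v) / len(v) for cat, v in groups.items()}
    total = sum(first.values()) / len(first) if first else float("nan")
    return ScoreCard(
        run_id=run_id,
        second_level=dict(second_level),
        first_level=first,
        total=total,
        flags=sorted(m for m, s in second_level.items() if s < flag_threshold),
        skipped=dict(skipped or {}),
    )


def load_standards(path=None, instrument_class: str = "orbitrap"
                   ) -> dict[str, ScoreStandard]:
    """Load scoring standards for one instrument class.

    Reads the shipped defaults when ``path`` is None; a user file with the
    same layout (instrument_class -> metric_id -> {best, worst}) overrides
    them per metric.
    """
    reg = intra_registry()
    raw = load_standards_config()
    table = dict(raw.get(instrument_class, {}))
    if path is not None:
        user = load_standards_config(path)
        table.update(user.get(instrument_class, {}))
    out = {}
    for mid, spec in table.items():
        direction = str(reg.loc[mid, "direction"]) if mid in reg.index else "lower_is_better"
        if direction == "none":
            continue
        out[mid] = ScoreStandard(
            metric_id=mid,
            best_threshold=float(spec["best"]),
            worst_threshold=float(spec["worst"]),
            direction=direction,
            instrument_class=instrument_class,
        )
    return out


def score_run(metrics, standards: dict[str, ScoreStandard],
              hierarchy: dict[str, str] | None = None,
              run_id: str | None = None,
              flag_threshold: float = FLAG_THRESHOLD) -> ScoreCard:
    """Score a collection of MetricValue objects and build the ScoreCard."""
    second: dict[str, float] = {}
    skipped: dict[str, str] = {}
    rid = run_id or ""
    for m in metrics:
        rid = rid or m.run_id
        if not m.computable or m.value is None:
            skipped[m.metric_id] = m.reason or "not computable"
            continue
        std = standards.get(m.metric_id)
        if std is None:
            skipped[m.metric_id] = "no scoring standard"
            continue
        s = score_metric(m.value, std)
        second[m.metric_id] = s
        m.score = s
        m.flag = s < flag_threshold
    return aggregate_scores(second, hierarchy, run_id=rid,
                            flag_threshold=flag_threshold, skipped=skipped)
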