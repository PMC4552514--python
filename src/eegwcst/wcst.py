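"""Wisconsin Card Sorting Test: trial logs, performance scoring and clustering.

The task: a response card must be matched to one of four decks by the active
sorting rule (color, shape or number of symbols).  Feedback is given after
every choice; the rule changes silently after 10 consecutive correct matches,
and the test ends after nine completed categories or 128 cards.

Performance measures per subject:

* ``completed_categories`` - number of 10-consecutive-correct runs (0-9);
* ``perseverative_errors`` - incorrect choices that still follow the rule
  that was active before the last rule change;
* ``nonperseverative_errors`` - all other incorrect choices, sub-classified
  as *efficient* (search errors before the new rule has been demonstrated)
  or *distraction* (lapses after the current rule was acquired).

Each measure is standardized across the cohort, z = (V - Vbar) / SD with the
sample (n-1) standard deviation, and pooled into a single performance
z-score as a sign-weighted average (categories positive, errors negative).
Subjects are grouped into good/medium/poor performance levels by 1-D
K-means (k = 3) on the pooled z-score.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "RULES",
    "TrialRecord",
    "TrialLog",
    "TrialLogError",
    "PerformanceMeasures",
    "PerformanceClusters",
    "validate_trial_log",
    "score_trial_log",
    "standardize",
    "pool_zscore",
    "cluster_performance",
    "score_cohort",
]

RULES = ("color", "shape", "number")

RUN_LENGTH = 10  # consecutive correct matches that complete a category
MAX_CATEGORIES = 9
MAX_TRIALS = 128


class TrialLogError(ValueError):
    """A trial log violates the task mechanics."""


@dataclasses.dataclass(frozen=True)
class TrialRecord:
    trial: int  # 1-based index
    rule: str  # active sorting rule
    choice: int  # chosen deck, 1-4
    matched: frozenset  # categories by which the choice matches the card
    correct: bool

    def __post_init__(self):
        if self.rule not in RULES:
            raise TrialLogError(f"trial {self.trial}: unknown rule {self.rule!r}")
        if not 1 <= self.choice <= 4:
            raise TrialLogError(f"trial {self.trial}: deck must be 1-4")


@dataclasses.dataclass
class TrialLog:
    """Ordered WCST trial records for one subject."""

    records: list
    subject_id: str = ""

    @property
    def n_trials(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [r.trial for r in self.records],
                "rule": [r.rule for r in self.records],
                "choice": [r.choice for r in self.records],
                "matched_categories": [
                    "|".join(sorted(r.matched)) for r in self.records
                ],
                "feedback": [
                    "correct" if r.correct else "incorrect" for r in self.records
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str = "") -> "TrialLog":
        records = [
            TrialRecord(
                trial=int(row.trial),
                rule=str(row.rule),
                choice=int(row.choice),
                matched=frozenset(
                    c for c in str(row.matched_categories).split("|") if c
                ),
                correct=str(row.feedback) == "correct",
            )
            for row in df.itertuples()
        ]
        return cls(records=records, subject_id=subject_id)

    @classmethod
    def from_csv(cls, path, subject_id: str = "") -> "TrialLog":
        return cls.from_frame(pd.read_csv(path), subject_id=subject_id)


@dataclasses.dataclass
class PerformanceMeasures:
    subject_id: str
    completed_categories: int
    perseverative_errors: int
    nonperseverative_errors: int
    efficient_errors: int
    distraction_errors: int
    n_trials: int
    z_categories: float = np.nan
    z_persev: float = np.nan
    z_nonpersev: float = np.nan
    z_score: float = np.nan


@dataclasses.dataclass
class PerformanceClusters:
    labels: pd.Series  # subject -> good | medium | poor
    summary: pd.DataFrame  # per-cluster n, mean z, SD z
    centers: np.ndarray  # cluster means, descending


def validate_trial_log(log: TrialLog) -> None:
    """Check the task-mechanics invariants, naming the first offending trial.

    Rules change exactly when 10 consecutive correct trials complete a
    category (and then to a different rule), feedback must be consistent
    with the active rule, and the log must terminate at nine completed
    categories or 128 trials, whichever comes first.
    """
    if log.n_trials == 0:
        raise TrialLogError("empty trial log")
    if log.n_trials > MAX_TRIALS:
        raise TrialLogError(
            f"trial {MAX_TRIALS + 1}: log exceeds {MAX_TRIALS} trials"
        )
    run = 0
    completed = 0
    category_done = False  # trial i-1 completed a category
    for i, rec in enumerate(log.records):
        if rec.trial != i + 1:
            raise TrialLogError(f"trial {rec.trial}: indices must be 1..n in order")
        if i > 0:
            last = log.records[i - 1]
            if rec.rule != last.rule and not category_done:
                raise TrialLogError(
                    f"trial {rec.trial}: rule changed without 10 consecutive "
                    "correct trials"
                )
            if rec.rule == last.rule and category_done:
                raise TrialLogError(
                    f"trial {rec.trial}: rule must change to a different "
                    "category after a completed run"
                )
        if rec.correct != (rec.rule in rec.matched):
            raise TrialLogError(
                f"trial {rec.trial}: feedback inconsistent with active rule "
                "and matched categories"
            )
        category_done = False
        if rec.correct:
            run += 1
            if run == RUN_LENGTH:
                completed += 1
                run = 0
                category_done = True
                if completed == MAX_CATEGORIES:
                    if i != log.n_trials - 1:
                        raise TrialLogError(
                            f"trial {rec.trial + 1}: log continues past the "
                            "ninth completed category"
                        )
                    return
        else:
            run = 0
    if log.n_trials != MAX_TRIALS:
        raise TrialLogError(
            f"trial {log.n_trials}: log ends before nine completed categories "
            f"and before {MAX_TRIALS} trials"
        )


def score_trial_log(
    log: TrialLog,
    *,
    perseveration_window: str = "anywhere",
    validate: bool = True,
) -> PerformanceMeasures:
    """Score a trial log into raw WCST performance counts.

    ``perseveration_window`` controls when an incorrect choice matching the
    pre-shift rule counts as perseverative: ``"anywhere"`` (default) any time
    during the current rule period, ``"until_acquisition"`` only before the
    subject first demonstrates the new rule.
    """
    if perseveration_window not in ("anywhere", "until_acquisition"):
        raise ValueError(f"unknown perseveration_window {perseveration_window!r}")
    if validate:
        validate_trial_log(log)

    completed = 0
    run = 0
    prev_rule = None  # rule active before the most recent shift
    acquired = False  # current rule demonstrated at least once
    n_persev = n_efficient = n_distraction = 0

    for i, rec in enumerate(log.records):
        if i > 0 and rec.rule != log.records[i - 1].rule:
            prev_rule = log.records[i - 1].rule
            acquired = False
            run = 0
        if rec.correct:
            acquired = True
            run += 1
            if run == RUN_LENGTH:
                completed += 1
                run = 0
        else:
            run = 0
            persev_eligible = prev_rule is not None and prev_rule in rec.matched
            if persev_eligible and perseveration_window == "until_acquisition":
                persev_eligible = not acquired
            if persev_eligible:
                n_persev += 1
            elif not acquired:
                n_efficient += 1
            else:
                n_distraction += 1

    return PerformanceMeasures(
        subject_id=log.subject_id,
        completed_categories=completed,
        perseverative_errors=n_persev,
        nonperseverative_errors=n_efficient + n_distraction,
        efficient_errors=n_efficient,
        distraction_errors=n_distraction,
        n_trials=log.n_trials,
    )


def standardize(values) -> np.ndarray:
    """Cohort z-scores, z = (V - Vbar) / SD with sample (n-1) SD.

    Raises ``ValueError`` for cohorts smaller than two subjects or with zero
    variance (degenerate cohort).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("standardization needs at least two subjects")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate cohort: measure has zero variance")
    return (values - values.mean()) / sd


def pool_zscore(z_categories, z_persev, z_nonpersev, weights=(1.0, -1.0, -1.0)):
    """Pooled performance z-score: sign-weighted average of the three
    standardized measures, normalized by the sum of absolute weights.

    Completed categories carry a positive weight; perseverative and
    nonperseverative errors carry negative weights.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be three finite numbers")
    if w[0] < 0 or w[1] > 0 or w[2] > 0:
        raise ValueError(
            "category weight must be >= 0 and error weights <= 0"
        )
    denom = np.abs(w).sum()
    if denom == 0:
        raise ValueError("all-zero weight vector")
    z = np.asarray([z_categories, z_persev, z_nonpersev], dtype=float)
    return float(np.dot(w, z) / denom) if z.ndim == 1 else np.dot(w, z) / denom


def cluster_performance(
    z_scores, subject_ids=None, k: int = 3, seed: int = 0, n_init: int = 25
) -> PerformanceClusters:
    """Group subjects into performance levels by 1-D K-means on the pooled
    z-score; clusters are named good/medium/poor by descending cluster mean.
    """
    from sklearn.cluster import KMeans

    z = np.asarray(z_scores, dtype=float)
    if len(np.unique(z)) < k:
        raise ValueError(f"need at least {k} distinct z-scores for k={k}")
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(len(z))]

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)[::-1]  # descending mean
    level_names = ["good", "medium", "poor"] if k == 3 else [
        f"level{i + 1}" for i in range(k)
    ]
    rename = {raw_label: level_names[rank] for rank, raw_label in enumerate(order)}
    labels = pd.Series([rename[r] for r in raw], index=subject_ids, name="cluster")

    rows = []
    for rank, raw_label in enumerate(order):
        members = z[raw == raw_label]
        rows.append(
            {
                "cluster": level_names[rank],
                "n": len(members),
                "mean_z": members.mean(),
                "sd_z": members.std(ddof=1) if len(members) > 1 else 0.0,
            }
        )
    summary = pd.DataFrame(rows)
    return PerformanceClusters(
        labels=labels, summary=summary, centers=np.sort(centers)[::-1]
    )


def score_cohort(
    logs,
    weights=(1.0, -1.0, -1.0),
    *,
    perseveration_window: str = "anywhere",
    cluster_seed: int = 0,
    n_init: int = 25,
):
    """Score a cohort of trial logs end to end.

    Returns ``(measures, clusters)`` where ``measures`` is a list of
    :class:`PerformanceMeasures` with z-scores filled in, and ``clusters``
    the K-means performance levels.
    """
    measures = [
        score_trial_log(log, perseveration_window=perseveration_window)
        for log in logs
    ]
    z_cat = standardize([m.completed_categories for m in measures])
    z_per = standardize([m.perseverative_errors for m in measures])
    z_non = standardize([m.nonperseverative_errors for m in measures])
    pooled = pool_zscore(z_cat, z_per, z_non, weights)
    for m, zc, zp, zn, zs in zip(measures, z_cat, z_per, z_non, pooled):
        m.z_categories, m.z_persev, m.z_nonpersev, m.z_score = (
            float(zc), float(zp), float(zn), float(zs),
        )
    clusters = cluster_performance(
        pooled,
        subject_ids=[m.subject_id for m in measures],
        seed=cluster_seed,
        n_init=n_init,
    )
    return measures, clusters
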