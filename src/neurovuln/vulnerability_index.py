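"""Cumulative neurocognitive vulnerability index.

Each participant completes up to five behavioural tasks, each summarised by
one continuous metric.  A metric is *normative* when it lies within 1 SD of
the combined-sample (both exposure groups pooled) mean and *atypical*
otherwise, with a per-task directionality rule deciding which tail(s) count.
Participants with at least two available tasks receive a trinary category:

* ``low``    — normative on every available task,
* ``medium`` — atypical on exactly one task,
* ``high``   — atypical on two or more tasks,
* ``excluded`` — fewer than two tasks available (not analysable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError

BOTH_TAILS = "both_tails"
HIGH_TAIL = "high_tail"
LOW_TAIL = "low_tail"
RULES = (BOTH_TAILS, HIGH_TAIL, LOW_TAIL)

NORMATIVE = "normative"
ATYPICAL = "atypical"
MISSING = "missing"

LOW, MEDIUM, HIGH, EXCLUDED = "low", "medium", "high", "excluded"
CATEGORIES = (LOW, MEDIUM, HIGH)

#: minimum number of available task metrics for a participant to be scored
MIN_AVAILABLE = 2

#: |z| threshold beyond which a score is atypical (boundary itself is normative)
Z_CUTOFF = 1.0


@dataclass(frozen=True)
class DirectionalityRule:
    """Which tail(s) of a task's pooled z-distribution count as atypical."""

    task_id: str
    rule: str = BOTH_TAILS

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown directionality rule {self.rule!r} for task {self.task_id!r}")


@dataclass
class VulnerabilityProfile:
    """Per-participant index components and the final trinary category."""

    participant_id: str
    z_scores: dict[str, float] = field(default_factory=dict)
    atypical_flags: dict[str, str] = field(default_factory=dict)
    n_available: int = 0
    n_atypical: int = 0
    category: str = EXCLUDED


def _as_rule_map(rules: Iterable[DirectionalityRule] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(rules, Mapping):
        out = dict(rules)
    else:
        out = {r.task_id: r.rule for r in rules}
    for task, rule in out.items():
        if rule not in RULES:
            raise ValueError(f"unknown directionality rule {rule!r} for task {task!r}")
    return out


def standardize(
    metrics: pd.DataFrame,
    *,
    means: Mapping[str, float] | None = None,
    sds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Pooled z-scores per task, computed over all non-missing rows.

    Pooling is always the combined sample handed in: the standardization does
    not look at group labels.  Callers analysing a subsample can pass the
    full-sample ``means``/``sds`` to reuse baseline scale parameters.
    Missing values stay missing.  A task whose non-missing values have zero
    variance raises :class:`DegenerateScaleError`.
    """
    z = pd.DataFrame(index=metrics.index)
    for task in metrics.columns:
        x = pd.to_numeric(metrics[task], errors="coerce")
        if means is not None and sds is not None:
            mu, sd = float(means[task]), float(sds[task])
        else:
            obs = x.dropna()
            if len(obs) < 2:
                raise DegenerateScaleError(f"task {task!r}: fewer than 2 observed values")
            mu = float(obs.mean())
            sd = float(obs.std(ddof=1))
        if sd <= 0 or not np.isfinite(sd):
            raise DegenerateScaleError(f"task {task!r}: zero or undefined variance")
        z[task] = (x - mu) / sd
    return z


def task_scale(metrics: pd.DataFrame) -> tuple[dict[str, float], dict[str, float]]:
    """Combined-sample mean and SD (n-1 denominator) per task column."""
    means, sds = {}, {}
    for task in metrics.columns:
        obs = pd.to_numeric(metrics[task], errors="coerce").dropna()
        if len(obs) < 2:
            raise DegenerateScaleError(f"task {task!r}: fewer than 2 observed values")
        means[task] = float(obs.mean())
        sds[task] = float(obs.std(ddof=1))
        if sds[task] <= 0:
            raise DegenerateScaleError(f"task {task!r}: zero or undefined variance")
    return means, sds


def classify_task(z: float, rule: str | DirectionalityRule = BOTH_TAILS) -> str:
    """Classify one z-score under a directionality rule.

    ``within 1 SD`` is read inclusively: |z| == 1 exactly is normative.
    A missing z yields the ``missing`` flag, not an error.
    """
    if isinstance(rule, DirectionalityRule):
        rule = rule.rule
    if rule not in RULES:
        raise ValueError(f"unknown directionality rule {rule!r}")
    if z is None or (isinstance(z, float) and np.isnan(z)):
        return MISSING
    z = float(z)
    if rule == BOTH_TAILS:
        return ATYPICAL if abs(z) > Z_CUTOFF else NORMATIVE
    if rule == HIGH_TAIL:
        return ATYPICAL if z > Z_CUTOFF else NORMATIVE
    return ATYPICAL if z < -Z_CUTOFF else NORMATIVE


def aggregate(flags: Sequence[str]) -> str:
    """Trinary category from per-task flags; ``excluded`` if < 2 tasks available."""
    n_available = sum(f != MISSING for f in flags)
    n_atypical = sum(f == ATYPICAL for f in flags)
    if n_available < MIN_AVAILABLE:
        return EXCLUDED
    if n_atypical == 0:
        return LOW
    if n_atypical == 1:
        return MEDIUM
    return HIGH


def build_index(
    cohort: pd.DataFrame,
    rules: Iterable[DirectionalityRule] | Mapping[str, str],
    *,
    means: Mapping[str, float] | None = None,
    sds: Mapping[str, float] | None = None,
    id_column: str = "participant_id",
) -> pd.DataFrame:
    """Standardize, flag, and aggregate every participant in one pass.

    Task metrics are looked up either as a column named exactly ``task_id``
    or as ``task_<task_id>``.  Standardization pools over the full input
    table unless precomputed ``means``/``sds`` are given (used when analysing
    a subsample on the baseline sample's scale).

    Returns one row per participant with columns ``participant_id``,
    ``z_<task>``, ``flag_<task>``, ``n_available``, ``n_atypical``,
    ``category``.
    """
    rule_map = _as_rule_map(rules)
    col_of = {}
    for task in rule_map:
        if task in cohort.columns:
            col_of[task] = task
        elif f"task_{task}" in cohort.columns:
            col_of[task] = f"task_{task}"
        else:
            raise KeyError(f"cohort has no metric column for task {task!r}")

    metrics = pd.DataFrame({t: cohort[c] for t, c in col_of.items()}, index=cohort.index)
    z = standardize(metrics, means=means, sds=sds)

    out = pd.DataFrame(index=cohort.index)
    out["participant_id"] = cohort[id_column].astype(str)
    flags = pd.DataFrame(index=cohort.index)
    for task, rule in rule_map.items():
        out[f"z_{task}"] = z[task]
        flags[task] = [classify_task(v, rule) for v in z[task]]
        out[f"flag_{task}"] = flags[task]
    out["n_available"] = (flags != MISSING).sum(axis=1)
    out["n_atypical"] = (flags == ATYPICAL).sum(axis=1)
    out["category"] = [aggregate(row) for row in flags.to_numpy()]
    return out


def profiles_from_frame(frame: pd.DataFrame) -> list[VulnerabilityProfile]:
    """Materialise :class:`VulnerabilityProfile` objects from a build_index frame."""
    tasks = [c[len("flag_"):] for c in frame.columns if c.startswith("flag_")]
    out = []
    for _, row in frame.iterrows():
        out.append(
            VulnerabilityProfile(
                participant_id=row["participant_id"],
                z_scores={t: row[f"z_{t}"] for t in tasks},
                atypical_flags={t: row[f"flag_{t}"] for t in tasks},
                n_available=int(row["n_available"]),
                n_atypical=int(row["n_atypical"]),
                category=row["category"],
            )
        )
    return out
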